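"""Shipped reference gait solution.

The package bundles one optimized mid-range reflex parameter set (the
best set-1 solution near 1.0 m/s from the package's own CMA-ES runs).
It provides the documented starting point for the step-length and
step-duration protocol sets and for scaled-down validation runs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .reflex_controller.params import ReflexParameterSet, load_wiring


def reference_solution_path() -> Path:
    return Path(resources.files("reflexgait") / "data"
                / "reference_solution.yaml")


def reference_solution(params: ReflexParameterSet | None = None) -> np.ndarray:
    """Parameter vector of the bundled mid-range (1.0 m/s) solution."""
    if params is None:
        params, _, _ = load_wiring()
    p = params.replace_values(params.values)
    p.load_values(reference_solution_path())
    return p.values
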