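"""Dataset analysis of optimized gait solutions.

Selection filters (stability + cycle convergence, effort ceilings, joint
penalty ceilings, fixed-band windows for sets 2/3), Pearson correlation
screening of reflex parameters against the gait characteristics (speed on
set 1, step length on set 2, step duration on set 3), key-parameter
identification at |c| > 0.6 with stretch-pair augmentation, bounded-order
polynomial regression (lowest order with R^2 > 0.7, capped at 3), and the
key-only vs nonkey-only range comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gait_objective import GaitMetrics, ObjectiveConfig, detect_steps
from .reflex_controller.params import ReflexParameterSet
from .trace import SimulationTrace

CORRELATION_THRESHOLD = 0.6
R2_THRESHOLD = 0.7
MAX_POLY_ORDER = 3

#: characteristic analyzed on each optimization set
SET_CHARACTERISTIC = {1: "speed", 2: "step_length", 3: "step_duration"}


@dataclass
class SolutionRecord:
    """One evaluated candidate: parameter vector + gait outcome + tags."""
    values: np.ndarray
    metrics: GaitMetrics
    cost: float
    set_id: int
    target: float
    seed: int
    generation: int = 0
    converged: bool = False
    trace: SimulationTrace | None = None
    selected: bool | None = None
    rejection: str | None = None


@dataclass
class SelectionRules:
    """The published solution-selection conditions."""
    effort_ceiling_mid: float = 4.0       # J/(kg*m), speeds in [0.8, 1.3]
    effort_ceiling_ext: float = 8.0       # slower and faster gaits
    mid_speed_range: tuple = (0.8, 1.3)   # m/s
    joint_ceilings: dict = field(default_factory=lambda: {
        "hip": 0.5, "knee": 0.5, "ankle": 3.0})
    sd_window: tuple = (0.68, 0.70)       # s, set 2 (0.69 +- 0.01)
    sl_window: tuple = (0.70, 0.74)       # m, set 3 (0.72 +- 0.02)
    require_convergence: bool = True

    def __post_init__(self):
        if self.effort_ceiling_mid <= 0 or self.effort_ceiling_ext <= 0:
            raise ValueError("effort ceilings must be positive")
        if not (self.sd_window[0] <= 0.69 <= self.sd_window[1]
                and self.sl_window[0] <= 0.72 <= self.sl_window[1]):
            raise ValueError("selection windows must contain their nominal value")


def _first_failure(r: SolutionRecord, rules: SelectionRules) -> str | None:
    m = r.metrics
    if m.fall or not m.usable:
        return "stability:fall"
    if rules.require_convergence and not r.converged:
        return "stability:no-convergence"
    lo, hi = rules.mid_speed_range
    ceiling = rules.effort_ceiling_mid if lo <= m.speed <= hi \
        else rules.effort_ceiling_ext
    if not np.isfinite(m.effort) or m.effort >= ceiling:
        return "effort"
    for joint in ("hip", "knee", "ankle"):
        if m.joint_penalties.get(joint, 0.0) >= rules.joint_ceilings[joint]:
            return f"joints:{joint}"
    if r.set_id == 2 and not (rules.sd_window[0] <= m.step_duration
                              <= rules.sd_window[1]):
        return "window:step_duration"
    if r.set_id == 3 and not (rules.sl_window[0] <= m.step_length
                              <= rules.sl_window[1]):
        return "window:step_length"
    return None


def select(records, rules: SelectionRules | None = None):
    """Flag records in place (idempotent, order-independent); returns them."""
    rules = rules or SelectionRules()
    for r in records:
        rej = _first_failure(r, rules)
        r.selected = rej is None
        r.rejection = rej
    return records


def selected(records, rules: SelectionRules | None = None):
    return [r for r in select(records, rules) if r.selected]


def cycle_convergence(trace: SimulationTrace, tol_deg: float = 2.0) -> bool:
    """True when the last two gait cycles of joint angles agree in RMS.

    Cycles are delimited by same-foot heel strikes; fewer than three full
    cycles returns False.  Trajectories are cycle-normalized to a common
    grid before comparison.
    """
    events, usable = detect_steps(trace)
    if not usable:
        return False
    times = [e.time for e in events if e.foot == "r"]
    if len(times) < 4:        # need at least three full cycles
        return False
    t = trace.time
    grid = np.linspace(0.0, 1.0, 101)
    joints = [f"q_{j}_{s}" for j in ("hip", "knee", "ankle")
              for s in ("r", "l")]
    cycles = []
    for t0, t1 in ((times[-3], times[-2]), (times[-2], times[-1])):
        i0, i1 = np.searchsorted(t, t0), np.searchsorted(t, t1)
        if i1 - i0 < 5:
            return False
        tt = (t[i0:i1] - t[i0]) / (t[i1 - 1] - t[i0])
        cyc = np.stack([np.interp(grid, tt, trace.col(c)[i0:i1])
                        for c in joints])
        cycles.append(cyc)
    rms = np.sqrt(np.mean((cycles[1] - cycles[0]) ** 2))
    return bool(np.degrees(rms) < tol_deg)


def _characteristic_values(records, set_id: int) -> np.ndarray:
    char = SET_CHARACTERISTIC[set_id]
    return np.array([getattr(r.metrics, char) for r in records])


def correlations(records_by_set: dict, params: ReflexParameterSet
                 ) -> pd.DataFrame:
    """Per-reflex-parameter Pearson correlations, one column per set.

    Columns: speed (set 1), step_length (set 2), step_duration (set 3);
    NaN where a set is absent.  Constant parameters report c = 0 with the
    degenerate flag set.
    """
    names = params.reflex_names()
    idx = [params.index[n] for n in names]
    out = pd.DataFrame(index=names,
                       columns=list(SET_CHARACTERISTIC.values()),
                       dtype=float)
    degenerate = pd.DataFrame(False, index=names,
                              columns=list(SET_CHARACTERISTIC.values()))
    for set_id, char in SET_CHARACTERISTIC.items():
        recs = records_by_set.get(set_id)
        if not recs:
            continue
        if len(recs) < 3:
            raise ValueError(f"set {set_id}: need at least 3 selected records")
        y = _characteristic_values(recs, set_id)
        X = np.stack([r.values for r in recs])
        for n, i in zip(names, idx):
            x = X[:, i]
            if np.std(x) < 1e-12 or np.std(y) < 1e-12:
                out.loc[n, char] = 0.0
                degenerate.loc[n, char] = True
            else:
                out.loc[n, char] = stats.pearsonr(x, y).statistic
    out.attrs["degenerate"] = degenerate
    return out


def identify_key(corr_table: pd.DataFrame, params: ReflexParameterSet,
                 threshold: float = CORRELATION_THRESHOLD) -> list[str]:
    """Parameters with |c| > threshold on any characteristic, augmented
    with the stretch partner (kL <-> l0) of any selected stretch entry."""
    key = [n for n in corr_table.index
           if np.nanmax(np.abs(corr_table.loc[n].to_numpy(dtype=float)))
           > threshold]
    augmented = list(key)
    for n in key:
        partner = params.stretch_partner(n)
        if partner is not None and partner not in augmented:
            augmented.append(partner)
    return sorted(augmented)


@dataclass
class RegressionFit:
    order: int
    coefficients: np.ndarray     # highest power first (np.polyfit layout)
    r2: float
    below_threshold: bool = False


def fit_regression(x, y, r2_threshold: float = R2_THRESHOLD,
                   max_order: int = MAX_POLY_ORDER) -> RegressionFit:
    """Lowest-order polynomial with R^2 above threshold (orders 1..3).

    Falls back to the maximum order with ``below_threshold`` set when no
    order reaches the threshold.  Zero-variance x raises ValueError.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size <= 4:
        raise ValueError("need more than 4 points")
    if np.std(x) < 1e-12:
        raise ValueError("degenerate predictor: zero variance")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    best = None
    for order in range(1, max_order + 1):
        coef = np.polyfit(x, y, order)
        resid = y - np.polyval(coef, x)
        r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
        best = RegressionFit(order, coef, r2)
        if r2 > r2_threshold:
            return best
    best.below_threshold = True
    return best


def build_report(records_by_set: dict, params: ReflexParameterSet,
                 threshold: float = CORRELATION_THRESHOLD) -> "KeyParameterReport":
    table = correlations(records_by_set, params)
    key = identify_key(table, params, threshold)
    regressions: dict = {}
    for name in key:
        i = params.index[name]
        regressions[name] = {}
        for set_id, char in SET_CHARACTERISTIC.items():
            recs = records_by_set.get(set_id)
            if not recs or len(recs) <= 4:
                continue
            x = np.stack([r.values for r in recs])[:, i]
            y = _characteristic_values(recs, set_id)
            try:
                regressions[name][char] = fit_regression(x, y)
            except ValueError:
                pass
    return KeyParameterReport(table, key, regressions, threshold)


@dataclass
class KeyParameterReport:
    correlation_table: pd.DataFrame
    key_parameters: list[str]
    regressions: dict
    threshold: float = CORRELATION_THRESHOLD

    def to_json(self, path=None) -> str:
        payload = {
            "threshold": self.threshold,
            "key_parameters": self.key_parameters,
            "correlations": {
                n: {c: (None if pd.isna(v) else float(v))
                    for c, v in self.correlation_table.loc[n].items()}
                for n in self.correlation_table.index},
            "regressions": {
                n: {c: {"order": f.order, "r2": f.r2,
                        "coefficients": list(map(float, f.coefficients)),
                        "below_threshold": f.below_threshold}
                    for c, f in sets.items()}
                for n, sets in self.regressions.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def formatted(self) -> str:
        """Correlation-table text report (key parameters starred)."""
        lines = [f"{'parameter':<22}{'speed':>10}{'step_len':>10}"
                 f"{'step_dur':>10}  key"]
        for n in self.correlation_table.index:
            row = self.correlation_table.loc[n]
            vals = "".join(f"{row[c]:>10.4f}" if pd.notna(row[c])
                           else f"{'--':>10}"
                           for c in self.correlation_table.columns)
            star = "  *" if n in self.key_parameters else ""
            lines.append(f"{n:<22}{vals}{star}")
        return "\n".join(lines)


def compare_ranges(datasets: dict) -> pd.DataFrame:
    """Per-characteristic [min, max] per dataset plus coverage vs 'full'.

    ``datasets`` maps a label (e.g. full / key-only / nonkey-only) to its
    selected records.  Coverage is the achieved range width relative to
    the 'full' dataset (when present).
    """
    rows = []
    for label, recs in datasets.items():
        if not recs:
            raise ValueError(f"dataset {label!r} is empty")
        for char in ("speed", "step_length", "step_duration"):
            vals = np.array([getattr(r.metrics, char) for r in recs])
            rows.append({"dataset": label, "characteristic": char,
                         "min": float(vals.min()), "max": float(vals.max())})
    df = pd.DataFrame(rows)
    if "full" in datasets:
        full = df[df.dataset == "full"].set_index("characteristic")
        cov = []
        for _, r in df.iterrows():
            fw = full.loc[r.characteristic, "max"] \
                - full.loc[r.characteristic, "min"]
            w = r["max"] - r["min"]
            if fw > 0:
                cov.append(w / fw)
            else:
                # a degenerate reference range is covered iff equally tight
                cov.append(1.0 if w == 0 else np.nan)
        df["coverage"] = cov
    return df


def records_to_frame(records, params: ReflexParameterSet) -> pd.DataFrame:
    """Flat DataFrame: tags, metrics and one column per parameter."""
    rows = []
    for r in records:
        d = {"set_id": r.set_id, "target": r.target, "seed": r.seed,
             "generation": r.generation, "cost": r.cost,
             "converged": r.converged, "selected": r.selected,
             "rejection": r.rejection}
        d.update(r.metrics.as_dict())
        d.pop("n_steps", None)
        for name, v in zip(params.names, r.values):
            d[name] = v
        rows.append(d)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame, params: ReflexParameterSet
                     ) -> list[SolutionRecord]:
    """Inverse of :func:`records_to_frame` (traces are not restored)."""
    out = []
    for _, row in df.iterrows():
        metrics = GaitMetrics(
            speed=row["speed"], step_length=row["step_length"],
            step_duration=row["step_duration"], effort=row["effort"],
            joint_penalties={j: row[f"penalty_{j}"]
                             for j in ("hip", "knee", "ankle")},
            head_penalty=row["head_penalty"], time_sim=row["time_sim"],
            events=[], fall=bool(row["fall"]), usable=bool(row["usable"]))
        values = np.array([row[n] for n in params.names], dtype=float)
        out.append(SolutionRecord(
            values=values, metrics=metrics, cost=row["cost"],
            set_id=int(row["set_id"]), target=row["target"],
            seed=int(row["seed"]), generation=int(row["generation"]),
            converged=bool(row["converged"]),
            selected=None if pd.isna(row.get("selected")) else bool(row["selected"]),
            rejection=None if pd.isna(row.get("rejection")) else row["rejection"]))
    return out
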