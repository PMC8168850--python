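"""Reflex pathway laws and activation dynamics.

Each pathway converts a delayed, normalized proprioceptive signal into a
non-negative stimulation contribution:

* length (stretch):   u_L = k_L * max(0, l~(t - t_D) - l_0)
* velocity:           u_V = k_V * max(0, v~(t - t_D))
* force (Golgi):      u_F = k_F * f~(t - t_D)
* PD trunk balance:   u_PD = k_p (theta(t - t_D) - theta_0) + k_v thetadot(t - t_D)

The PD output is sign-indefinite; composition routes its positive part to
the hip extensors and its negative part to the flexors.  Muscle activation
follows da/dt = (u - a)/tau, integrated exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TAU_ACT = 0.01   # s, activation time constant


@njit(cache=True)
def length_feedback(kL, l_delayed, l0):
    x = l_delayed - l0
    if x < 0.0:
        x = 0.0
    return kL * x


@njit(cache=True)
def velocity_feedback(kV, v_delayed):
    if v_delayed < 0.0:
        return 0.0
    return kV * v_delayed


@njit(cache=True)
def force_feedback(kF, f_delayed):
    return kF * f_delayed


@njit(cache=True)
def pd_balance(kp, kv, theta_delayed, thetadot_delayed, theta0):
    return kp * (theta_delayed - theta0) + kv * thetadot_delayed


def update_activation(a, u, dt, tau: float = TAU_ACT):
    """Exact exponential update of da/dt = (u - a)/tau over one step."""
    a = np.asarray(a, dtype=float)
    u = np.asarray(u, dtype=float)
    decay = np.exp(-dt / tau)
    return u + (a - u) * decay


@njit(cache=True)
def update_activation_scalar(a, u, dt, tau):
    return u + (a - u) * np.exp(-dt / tau)
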