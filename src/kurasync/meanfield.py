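"""Mean-field (complete-graph) Kuramoto theory used as an analytic oracle.

For the all-to-all model with incoming weights normalized to unit row sum
and frequency density g, the classical self-consistency analysis gives a
critical coupling

    K_c = 2 / (pi * g(0)),

which for the standard normal g(0) = 1/sqrt(2*pi) evaluates to
K_c = 2*sqrt(2*pi)/pi ~= 1.5958.  Above K_c the stationary order
parameter r solves

    1 = K * Integral_{-pi/2}^{pi/2} cos^2(x) g(K r sin(x)) dx.

These closed-form results are *independent* of the simulation code and
serve as oracles in tests: simulated steady-state R on a normalized full
graph must approach r*(K), and the synchronization onset of a K sweep
must bracket K_c.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = ["critical_coupling", "steady_state_r"]


def critical_coupling() -> float:
    """Mean-field critical coupling for standard-normal frequencies."""
    g0 = 1.0 / math.sqrt(2.0 * math.pi)
    return 2.0 / (math.pi * g0)


def _gain(r: float, K: float) -> float:
    """K * integral of cos^2(x) g(K r sin(x)) over [-pi/2, pi/2]."""

    def integrand(x: float) -> float:
        u = K * r * math.sin(x)
        return math.cos(x) ** 2 * math.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)

    val, _ = quad(integrand, -0.5 * math.pi, 0.5 * math.pi, limit=200)
    return K * val


def steady_state_r(K: float) -> float:
    """Stationary mean-field order parameter r*(K); 0 at or below K_c."""
    if K <= critical_coupling():
        return 0.0

    def h(r: float) -> float:
        return _gain(r, K) - 1.0

    # h(0+) > 0 above K_c and h decreases with r; bracket the root upward
    hi = 1.0
    while h(hi) > 0.0:
        hi *= 1.5
        if hi > 64.0:
            raise RuntimeError("failed to bracket self-consistency root")
    return float(brentq(h, 1e-12, hi, xtol=1e-12))


def steady_state_curve(K_values) -> np.ndarray:
    """Vectorized r*(K) over a coupling grid."""
    return np.array([steady_state_r(float(K)) for K in np.asarray(K_values)])
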