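"""Single-precision variants of the batched integration kernels.

Mirrors the float64 batch kernels in :mod:`kurasync._kernels` with all
arithmetic carried out in float32 (double SIMD width, half the memory
traffic) — used for large production ensembles where the observable is
an ensemble statistic (mean R(t), duration histograms), not an
individual trajectory.  Phase trajectories of this chaotic system
decorrelate from their float64 counterparts regardless of precision;
ensemble-level agreement between the two precisions is asserted in the
test suite.

Time stepping and sampling bookkeeping stay in float64; only the state
update arithmetic is single precision.  Numba promotes float32 operands
mixed with Python float literals to float64, so every constant here is
pre-cast via ``F = np.float32``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

F = np.float32

_TWO_PI = F(2.0 * np.pi)
_INV_TWO_PI = F(1.0 / (2.0 * np.pi))
_HALF_PI = F(0.5 * np.pi)
_PI = F(np.pi)
_ONE = F(1.0)
_NEG_ONE = F(-1.0)
_ZERO = F(0.0)
_HALF = F(0.5)

_S1 = F(1.0); _S3 = F(-1.6666666666666632e-01); _S5 = F(8.3333333333224895e-03)
_S7 = F(-1.9841269835586733e-04); _S9 = F(2.7557313377252534e-06)
_S11 = F(-2.5050747762850355e-08); _S13 = F(1.5896230157654656e-10)
_C0 = F(1.0); _C2 = F(-0.5); _C4 = F(4.1666666666666019e-02)
_C6 = F(-1.3888888888873056e-03); _C8 = F(2.4801587288851704e-05)
_C10 = F(-2.7557315514885002e-07); _C12 = F(2.0875723212981748e-09)
_C14 = F(-1.1359500119358907e-11)

_T_EPS = 1e-9  # float64 time comparisons


@njit(cache=True, fastmath=True, inline="always")
def _poly_sin32(x):
    z = x * x
    return x * (_S1 + z * (_S3 + z * (_S5 + z * (_S7 + z * (_S9 + z * (_S11 + z * _S13))))))


@njit(cache=True, fastmath=True, inline="always")
def _poly_cos32(x):
    z = x * x
    return _C0 + z * (_C2 + z * (_C4 + z * (_C6 + z * (_C8 + z * (_C10 + z * (_C12 + z * _C14))))))


@njit(cache=True, fastmath=True)
def _order_parameter_col32(theta, b):
    n = theta.shape[0]
    zs = 0.0
    zc = 0.0
    for i in range(n):
        x = theta[i, b] - _TWO_PI * np.floor(theta[i, b] * _INV_TWO_PI + _HALF)
        cf = _ONE
        if x > _HALF_PI:
            x = _PI - x
            cf = _NEG_ONE
        elif x < -_HALF_PI:
            x = -_PI - x
            cf = _NEG_ONE
        zs += _poly_sin32(x)
        zc += cf * _poly_cos32(x)
    return np.sqrt(zs * zs + zc * zc) / n


@njit(cache=True, fastmath=True)
def _rhs_stage32(theta_eval, theta0, omega, indptr, indices, data, K,
                 acc, stage_out, s, c, ssb, ccb, n_act,
                 w_acc, w_stage, first, last):
    """One fused RK4 stage: evaluate the RHS at ``theta_eval`` and fold
    the stage update into the running combination in the same pass.

    ``acc`` accumulates theta0 + (h/6)(k1 + 2 k2 + 2 k3 + k4);
    ``stage_out`` receives theta0 + w_stage * k for the next stage's
    evaluation point (unused when ``last``).  Fusing the axpy updates
    into the sparse pass roughly halves the memory traffic per step.
    """
    n = theta_eval.shape[0]
    for i in range(n):
        for b in range(n_act):
            x = theta_eval[i, b] - _TWO_PI * np.floor(theta_eval[i, b] * _INV_TWO_PI + _HALF)
            cf = _ONE
            if x > _HALF_PI:
                x = _PI - x
                cf = _NEG_ONE
            elif x < -_HALF_PI:
                x = -_PI - x
                cf = _NEG_ONE
            s[i, b] = _poly_sin32(x)
            c[i, b] = cf * _poly_cos32(x)
    for i in range(n):
        for b in range(n_act):
            ssb[b] = _ZERO
            ccb[b] = _ZERO
        for p in range(indptr[i], indptr[i + 1]):
            j = indices[p]
            w = data[p]
            for b in range(n_act):
                ssb[b] += w * s[j, b]
                ccb[b] += w * c[j, b]
        if first:
            for b in range(n_act):
                k = omega[i, b] + K * (c[i, b] * ssb[b] - s[i, b] * ccb[b])
                acc[i, b] = theta0[i, b] + w_acc * k
                stage_out[i, b] = theta0[i, b] + w_stage * k
        elif last:
            # write the completed step straight back into theta0
            for b in range(n_act):
                k = omega[i, b] + K * (c[i, b] * ssb[b] - s[i, b] * ccb[b])
                theta0[i, b] = acc[i, b] + w_acc * k
        else:
            for b in range(n_act):
                k = omega[i, b] + K * (c[i, b] * ssb[b] - s[i, b] * ccb[b])
                acc[i, b] += w_acc * k
                stage_out[i, b] = theta0[i, b] + w_stage * k


@njit(cache=True, fastmath=True)
def _rk4_block32(theta, omega, indptr, indices, data, K, h,
                 acc, tmp, s, c, ssb, ccb, n_act):
    """Advance the first ``n_act`` columns by one RK4 step of size h.

    Classical RK4 with the stage combinations folded into the RHS
    passes; on exit ``theta`` holds the updated phases.
    """
    n = theta.shape[0]
    h32 = F(h)
    h_half = _HALF * h32
    sixth = F(h / 6.0)
    third = F(h / 3.0)
    _rhs_stage32(theta, theta, omega, indptr, indices, data, K,
                 acc, tmp, s, c, ssb, ccb, n_act, sixth, h_half, True, False)
    _rhs_stage32(tmp, theta, omega, indptr, indices, data, K,
                 acc, tmp, s, c, ssb, ccb, n_act, third, h_half, False, False)
    _rhs_stage32(tmp, theta, omega, indptr, indices, data, K,
                 acc, tmp, s, c, ssb, ccb, n_act, third, h32, False, False)
    _rhs_stage32(tmp, theta, omega, indptr, indices, data, K,
                 acc, tmp, s, c, ssb, ccb, n_act, sixth, h32, False, True)


@njit(cache=True, fastmath=True)
def run_sparse_batch32(theta, omega, indptr, indices, data, K, dt, sample_times):
    """float32 analogue of ``run_sparse_batch``: returns R of shape (S, B)."""
    n, B = theta.shape
    n_s = sample_times.shape[0]
    R_out = np.empty((n_s, B))
    acc = np.empty((n, B), np.float32); tmp = np.empty((n, B), np.float32)
    s = np.empty((n, B), np.float32); c = np.empty((n, B), np.float32)
    ssb = np.empty(B, np.float32); ccb = np.empty(B, np.float32)
    t = 0.0
    for ks in range(n_s):
        target = sample_times[ks]
        while t < target - _T_EPS:
            h = dt if t + dt <= target + _T_EPS else target - t
            _rk4_block32(theta, omega, indptr, indices, data, K, h,
                         acc, tmp, s, c, ssb, ccb, B)
            t += h
        t = target
        for b in range(B):
            R = _order_parameter_col32(theta, b)
            if not np.isfinite(R):
                raise FloatingPointError("non-finite order parameter: integration blow-up")
            R_out[ks, b] = R
    return R_out


@njit(cache=True, fastmath=True)
def run_sparse_batch_fp32(theta, omega, indptr, indices, data, K, dt,
                          sample_times, threshold):
    """float32 analogue of ``run_sparse_batch_fp`` (first passage with
    column compaction)."""
    n, B = theta.shape
    n_s = sample_times.shape[0]
    cross = np.full(B, -1, dtype=np.int64)
    col_id = np.arange(B)
    acc = np.empty((n, B), np.float32); tmp = np.empty((n, B), np.float32)
    s = np.empty((n, B), np.float32); c = np.empty((n, B), np.float32)
    ssb = np.empty(B, np.float32); ccb = np.empty(B, np.float32)
    n_act = B
    t = 0.0
    for ks in range(n_s):
        target = sample_times[ks]
        while t < target - _T_EPS:
            h = dt if t + dt <= target + _T_EPS else target - t
            _rk4_block32(theta, omega, indptr, indices, data, K, h,
                         acc, tmp, s, c, ssb, ccb, n_act)
            t += h
        t = target
        b = 0
        while b < n_act:
            R = _order_parameter_col32(theta, b)
            if not np.isfinite(R):
                raise FloatingPointError("non-finite order parameter: integration blow-up")
            if R < threshold:
                cross[col_id[b]] = ks
                last = n_act - 1
                if b != last:
                    for i in range(n):
                        theta[i, b] = theta[i, last]
                        omega[i, b] = omega[i, last]
                    col_id[b] = col_id[last]
                n_act -= 1
            else:
                b += 1
        if n_act == 0:
            break
    return cross
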