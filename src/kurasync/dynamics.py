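"""Kuramoto integration, order-parameter sampling, first-passage detection.

The model: N phase oscillators theta_i on a weighted network W,

    dtheta_i/dt = omega_i + K * sum_j W_ij sin(theta_j - theta_i),

with intrinsic frequencies omega_i ~ N(0, 1) drawn fresh per realization
and a global coupling K.  Synchrony is tracked by the Kuramoto order
parameter R(t) = |sum_j exp(i theta_j)| / N, sampled on the exponential
schedule t_k = 1 + base^k (base 1.08 by default), the natural grid for
power-law asymptotics.

A realization either starts incoherent (uniform random phases) and R(t)
grows toward (partial) synchrony, or starts fully coherent (all phases
zero) and R(t) decays.  The first-passage time t_x is the time at which
R first falls below the finite-size noise threshold R_T = 1/sqrt(N),
estimated as the midpoint (t_k + t_{k-1})/2 of the sampling interval in
which the crossing was observed (t_{-1} := 0 when the very first sample
is already below threshold).

Integration is classical fixed-step fourth-order Runge-Kutta with
dt = 0.1 (tested against dt = 0.05/0.01 convergence in the suite), with
the last step before each sampling instant shortened to land on it
exactly.  Ensembles run through compiled kernels (:mod:`kurasync._kernels`);
the pure-NumPy ``kuramoto_rhs``/``rk4_integrate`` path below serves as
the readable reference implementation and cross-check.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace, asdict
from typing import Callable, Optional

import numpy as np

from . import _kernels, _kernels32
from .graphs import FrequencySet, OscillatorNetwork, draw_frequencies

__all__ = [
    "SimulationConfig",
    "PhaseState",
    "Trajectory",
    "EnsembleResult",
    "IntegrationBlowupError",
    "sampling_times",
    "order_parameter",
    "kuramoto_rhs",
    "rk4_integrate",
    "initial_phases",
    "run_realization",
    "run_ensemble",
    "derive_seeds",
]

logger = logging.getLogger("kurasync")


class IntegrationBlowupError(FloatingPointError):
    """Non-finite state encountered during integration."""


@dataclass
class SimulationConfig:
    """Parameters of one Kuramoto integration protocol.

    Parameters
    ----------
    coupling_K : float
        Global coupling strength K (dimensionless).
    dt : float
        RK4 step size; 0.1 is sufficient for this model.
    t_max : float
        Time horizon of a run.
    sample_base : float
        Geometric base of the sampling schedule t_k = 1 + base^k.
    init_kind : str
        ``"incoherent"`` (uniform random phases) or ``"coherent"``
        (all phases zero).
    threshold : float or None
        First-passage level R_T; ``None`` means 1/sqrt(N) at run time.
    omega_seed, phase_seed : int
        Seeds of the two independent RNG streams (frequencies, phases).
    stop_at_crossing : bool
        If True the integration stops at the first sample below R_T
        (duration-statistics mode); if False it always runs to t_max
        (growth/decay-curve mode).
    """

    coupling_K: float
    t_max: float
    dt: float = 0.1
    sample_base: float = 1.08
    init_kind: str = "incoherent"
    threshold: Optional[float] = None
    omega_seed: int = 0
    phase_seed: int = 1
    stop_at_crossing: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_max <= self.dt:
            raise ValueError("t_max must exceed dt")
        if self.sample_base <= 1:
            raise ValueError("sample_base must be > 1")
        if self.threshold is not None and not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if self.init_kind not in ("incoherent", "coherent"):
            raise ValueError(f"unknown init_kind {self.init_kind!r}")

    def resolve_threshold(self, n_nodes: int) -> float:
        """R_T for a given system size (default 1/sqrt(N))."""
        if self.threshold is not None:
            return float(self.threshold)
        return 1.0 / math.sqrt(n_nodes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhaseState:
    """Oscillator phases at one instant (radians, internally unwrapped)."""

    theta: np.ndarray
    time: float = 0.0

    @property
    def wrapped(self) -> np.ndarray:
        """Phases reported modulo 2*pi, in [0, 2*pi)."""
        return np.mod(self.theta, 2.0 * np.pi)


@dataclass
class Trajectory:
    """Sampled (t_k, R(t_k)) series of one realization.

    ``R_values`` may carry a NaN tail when the run stopped at the first
    threshold crossing.  ``t_x`` is the midpoint first-passage estimate,
    set to ``t_max`` (censored) when ``crossed`` is False.
    """

    times: np.ndarray
    R_values: np.ndarray
    realization_id: int
    crossed: bool
    t_x: float


@dataclass
class EnsembleResult:
    """Ensemble of realizations at one coupling.

    ``R`` has shape (n_realizations, n_samples) in trajectory mode and is
    ``None`` in duration-statistics (early-exit) mode.  ``n_live[k]`` is
    the number of realizations that had not yet crossed the threshold at
    sample k.
    """

    times: np.ndarray
    R: Optional[np.ndarray]
    mean_R: Optional[np.ndarray]
    t_x: np.ndarray
    crossed: np.ndarray
    n_live: np.ndarray
    config: SimulationConfig
    base_seed: int
    n_realizations: int

    def durations_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "realization": np.arange(self.n_realizations),
                "t_x": self.t_x,
                "crossed": self.crossed.astype(int),
            }
        )

    def mean_r_frame(self):
        import pandas as pd

        if self.mean_R is None:
            raise ValueError("mean R(t) only available in trajectory mode")
        return pd.DataFrame(
            {"t_k": self.times, "mean_R": self.mean_R, "n_live": self.n_live}
        )

    def write(self, directory) -> None:
        """Write durations CSV, mean-R CSV (if present) and config JSON."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.durations_frame().to_csv(d / "durations.csv", index=False)
        if self.mean_R is not None:
            self.mean_r_frame().to_csv(d / "mean_r.csv", index=False)
        sidecar = {
            "config": self.config.to_dict(),
            "base_seed": int(self.base_seed),
            "n_realizations": int(self.n_realizations),
        }
        (d / "config.json").write_text(json.dumps(sidecar, indent=2))


def sampling_times(t_max: float, base: float = 1.08) -> np.ndarray:
    """Exponential sampling instants t_k = 1 + base^k not exceeding t_max."""
    if t_max <= 2:
        raise ValueError("t_max must exceed 2 (the first sampling instant)")
    if base <= 1:
        raise ValueError("base must be > 1")
    k_max = int(math.floor(math.log(t_max - 1.0) / math.log(base)))
    ks = np.arange(k_max + 1)
    return 1.0 + base ** ks


def order_parameter(state) -> float:
    """Kuramoto order parameter R = |mean phasor| in [0, 1]."""
    theta = state.theta if isinstance(state, PhaseState) else np.asarray(state)
    if theta.size < 1:
        raise ValueError("need at least one oscillator")
    return float(np.abs(np.exp(1j * theta).mean()))


def kuramoto_rhs(state, omega, network: OscillatorNetwork, K: float) -> np.ndarray:
    """Phase velocities dtheta/dt of the weighted Kuramoto model.

    Evaluates omega + K * (cos(theta) * (W @ sin(theta)) - sin(theta) *
    (W @ cos(theta))), i.e. two sparse matrix-vector products — cost
    proportional to the number of stored links, never dense N^2 work.
    """
    theta = state.theta if isinstance(state, PhaseState) else np.asarray(state)
    om = omega.omega if isinstance(omega, FrequencySet) else np.asarray(omega)
    if theta.shape != om.shape or theta.shape[0] != network.n_nodes:
        raise ValueError(
            f"dimension mismatch: theta {theta.shape}, omega {om.shape}, "
            f"network N={network.n_nodes}"
        )
    s, c = np.sin(theta), np.cos(theta)
    W = network.coupling
    return om + K * (c * (W @ s) - s * (W @ c))


def rk4_integrate(
    state: PhaseState,
    rhs: Callable[[np.ndarray], np.ndarray],
    dt: float,
    t_target: float,
) -> PhaseState:
    """Advance a phase state to ``t_target`` with classical fixed-step RK4.

    The last step is shortened to land exactly on ``t_target``.  The
    right-hand side is autonomous: ``rhs(theta) -> dtheta/dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    theta = state.theta.astype(float, copy=True)
    t = state.time
    while t < t_target - _kernels._T_EPS:
        h = dt if t + dt <= t_target + _kernels._T_EPS else t_target - t
        k1 = rhs(theta)
        k2 = rhs(theta + 0.5 * h * k1)
        k3 = rhs(theta + 0.5 * h * k2)
        k4 = rhs(theta + h * k3)
        theta += (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += h
        if not np.all(np.isfinite(theta)):
            raise IntegrationBlowupError(
                f"non-finite phases at t = {t:.3f}"
            )
    return PhaseState(theta=theta, time=t_target)


def initial_phases(config: SimulationConfig, n_nodes: int) -> np.ndarray:
    """Initial phases per protocol: uniform on (0, 2*pi] or all zero."""
    if config.init_kind == "coherent":
        return np.zeros(n_nodes)
    rng = np.random.default_rng(config.phase_seed)
    return rng.uniform(0.0, 2.0 * np.pi, size=n_nodes)


def _csr_arrays(network: OscillatorNetwork):
    W = network.coupling
    return W.indptr, W.indices, W.data


def _is_meanfield(network: OscillatorNetwork) -> bool:
    return network.kind == "full"


def _meanfield_kw(network: OscillatorNetwork, K: float) -> float:
    w = 1.0 / (network.n_nodes - 1) if network.meta.get("normalized") else 1.0
    return K * w


def _first_passage(times: np.ndarray, cross: int, t_max: float) -> tuple[bool, float]:
    if cross < 0:
        return False, float(t_max)
    t_prev = 0.0 if cross == 0 else times[cross - 1]
    return True, float(0.5 * (times[cross] + t_prev))


def run_realization(
    network: OscillatorNetwork,
    config: SimulationConfig,
    realization_id: int = 0,
    engine: str = "auto",
) -> Trajectory:
    """Integrate one realization and sample R(t) on the exponential grid.

    Fresh intrinsic frequencies are drawn from ``config.omega_seed``;
    initial phases from ``config.phase_seed`` (ignored for the coherent
    protocol).  In ``stop_at_crossing`` mode the run ends at the first
    sample below threshold and the remaining R values stay NaN.
    """
    N = network.n_nodes
    omega = draw_frequencies(N, config.omega_seed).omega
    theta = initial_phases(config, N)
    times = sampling_times(config.t_max, config.sample_base)
    thr = config.resolve_threshold(N)
    try:
        if engine == "meanfield" or (engine == "auto" and _is_meanfield(network)):
            R_values, cross = _kernels.run_meanfield_single(
                theta, omega, _meanfield_kw(network, config.coupling_K),
                config.dt, times, thr, config.stop_at_crossing,
            )
        else:
            indptr, indices, data = _csr_arrays(network)
            R_values, cross = _kernels.run_sparse_single(
                theta, omega, indptr, indices, data, config.coupling_K,
                config.dt, times, thr, config.stop_at_crossing,
            )
    except FloatingPointError as exc:
        raise IntegrationBlowupError(str(exc)) from exc
    crossed, t_x = _first_passage(times, cross, config.t_max)
    return Trajectory(
        times=times,
        R_values=R_values,
        realization_id=realization_id,
        crossed=crossed,
        t_x=t_x,
    )


def derive_seeds(base_seed: int, realization: int) -> tuple[int, int]:
    """Deterministic per-realization (omega_seed, phase_seed) pair.

    Derived through :class:`numpy.random.SeedSequence` so that ensembles
    are reproducible and independent of execution order; the returned
    integers are kept below 2**31.
    """
    ss = np.random.SeedSequence(entropy=int(base_seed), spawn_key=(int(realization),))
    a, b = ss.generate_state(2, dtype=np.uint32)
    return int(a >> 1), int(b >> 1)


def run_ensemble(
    network: OscillatorNetwork,
    config: SimulationConfig,
    n_realizations: int,
    base_seed: int = 0,
    engine: str = "auto",
    batch_size: int = 32,
    precision: str = "double",
) -> EnsembleResult:
    """Run many independent realizations and collect R(t) and t_x samples.

    Realization ``r`` uses frequency/phase seeds derived deterministically
    from ``(base_seed, r)``, so the result multiset is independent of
    batching and execution order.  In trajectory mode (the default,
    ``config.stop_at_crossing = False``) realizations are advanced in
    lock-step batches through the compiled batch kernel and the full
    R matrix is retained; in duration mode each realization stops at its
    first threshold crossing and only (t_x, crossed) are stored.

    ``precision="single"`` runs the batched sparse kernels in float32
    (roughly twice the throughput) — appropriate for large production
    ensembles whose observables are ensemble statistics; individual
    chaotic trajectories decorrelate between precisions either way.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if precision not in ("double", "single"):
        raise ValueError(f"unknown precision {precision!r}")
    N = network.n_nodes
    times = sampling_times(config.t_max, config.sample_base)
    thr = config.resolve_threshold(N)
    t_x = np.empty(n_realizations)
    crossed = np.zeros(n_realizations, dtype=bool)
    cross_idx = np.full(n_realizations, -1, dtype=np.int64)

    use_mf = engine == "meanfield" or (engine == "auto" and _is_meanfield(network))

    if config.stop_at_crossing:
        R_matrix = None
        mean_R = None
        if use_mf:
            for r in range(n_realizations):
                om_seed, ph_seed = derive_seeds(base_seed, r)
                cfg_r = replace(config, omega_seed=om_seed, phase_seed=ph_seed)
                traj = run_realization(network, cfg_r, realization_id=r,
                                       engine="meanfield")
                crossed[r] = traj.crossed
                t_x[r] = traj.t_x
                if traj.crossed:
                    finite = np.isfinite(traj.R_values)
                    cross_idx[r] = int(np.flatnonzero(finite & (traj.R_values < thr))[0])
                logger.debug("realization %d: crossed=%s t_x=%.3f",
                             r, traj.crossed, traj.t_x)
        else:
            indptr, indices, data = _csr_arrays(network)
            single = precision == "single"
            if single:
                data = data.astype(np.float32)
            for lo in range(0, n_realizations, batch_size):
                hi = min(lo + batch_size, n_realizations)
                B = hi - lo
                dtype = np.float32 if single else np.float64
                theta = np.empty((N, B), dtype)
                omega = np.empty((N, B), dtype)
                for b, r in enumerate(range(lo, hi)):
                    om_seed, ph_seed = derive_seeds(base_seed, r)
                    cfg_r = replace(config, omega_seed=om_seed, phase_seed=ph_seed)
                    omega[:, b] = draw_frequencies(N, om_seed).omega
                    theta[:, b] = initial_phases(cfg_r, N)
                try:
                    if single:
                        cross = _kernels32.run_sparse_batch_fp32(
                            theta, omega, indptr, indices, data,
                            np.float32(config.coupling_K), config.dt,
                            times, thr,
                        )
                    else:
                        cross = _kernels.run_sparse_batch_fp(
                            theta, omega, indptr, indices, data,
                            config.coupling_K, config.dt, times, thr,
                        )
                except FloatingPointError as exc:
                    raise IntegrationBlowupError(str(exc)) from exc
                cross_idx[lo:hi] = cross
                for b, r in enumerate(range(lo, hi)):
                    crossed[r], t_x[r] = _first_passage(
                        times, int(cross[b]), config.t_max)
                logger.debug("batch %d-%d of %d done", lo, hi, n_realizations)
    else:
        R_matrix = np.empty((n_realizations, len(times)))
        if use_mf:
            for r in range(n_realizations):
                om_seed, ph_seed = derive_seeds(base_seed, r)
                cfg_r = replace(config, omega_seed=om_seed, phase_seed=ph_seed)
                traj = run_realization(network, cfg_r, realization_id=r,
                                       engine="meanfield")
                R_matrix[r] = traj.R_values
        else:
            indptr, indices, data = _csr_arrays(network)
            single = precision == "single"
            if single:
                data = data.astype(np.float32)
            for lo in range(0, n_realizations, batch_size):
                hi = min(lo + batch_size, n_realizations)
                B = hi - lo
                dtype = np.float32 if single else np.float64
                theta = np.empty((N, B), dtype)
                omega = np.empty((N, B), dtype)
                for b, r in enumerate(range(lo, hi)):
                    om_seed, ph_seed = derive_seeds(base_seed, r)
                    cfg_r = replace(config, omega_seed=om_seed, phase_seed=ph_seed)
                    omega[:, b] = draw_frequencies(N, om_seed).omega
                    theta[:, b] = initial_phases(cfg_r, N)
                try:
                    if single:
                        R_out = _kernels32.run_sparse_batch32(
                            theta, omega, indptr, indices, data,
                            np.float32(config.coupling_K), config.dt, times,
                        )
                    else:
                        R_out = _kernels.run_sparse_batch(
                            theta, omega, indptr, indices, data,
                            config.coupling_K, config.dt, times,
                        )
                except FloatingPointError as exc:
                    raise IntegrationBlowupError(str(exc)) from exc
                R_matrix[lo:hi] = R_out.T
                logger.debug("batch %d-%d of %d done", lo, hi, n_realizations)
        below = R_matrix < thr
        for r in range(n_realizations):
            hits = np.flatnonzero(below[r])
            if hits.size:
                cross_idx[r] = hits[0]
            crossed[r], t_x[r] = _first_passage(times, int(cross_idx[r]), config.t_max)
        mean_R = R_matrix.mean(axis=0)

    n_live = np.array([
        int(np.sum((cross_idx < 0) | (cross_idx > k))) for k in range(len(times))
    ])
    logger.info(
        "ensemble K=%.4g: %d/%d crossed, median t_x=%.3g",
        config.coupling_K, int(crossed.sum()), n_realizations,
        float(np.median(t_x)),
    )
    return EnsembleResult(
        times=times,
        R=R_matrix,
        mean_R=mean_R,
        t_x=t_x,
        crossed=crossed,
        n_live=n_live,
        config=config,
        base_seed=int(base_seed),
        n_realizations=int(n_realizations),
    )
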