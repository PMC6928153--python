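"""Config-driven experiment campaigns: graph -> ensembles -> analysis.

An :class:`ExperimentConfig` fully determines an experiment on one
platform: the graph (generator kind + parameters, or an edge-list path,
plus preparation steps), the coupling grid, the ensemble protocol and
the analysis parameters.  The three stages

    generate(cfg)  ->  <out>/graph.tsv
    simulate(cfg)  ->  <out>/K=<value>/{durations.csv, mean_r.csv, config.json}
    analyze(cfg)   ->  <out>/K=<value>/{histogram.csv, fit.json},
                       <out>/{transition.json, summary.csv}

are resumable: completed per-K simulation directories (marked by a
``done`` sentinel) are skipped on re-run, and identical config + seed
reproduce byte-identical duration tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import connectome as cio
from . import graphs, scaling
from .dynamics import SimulationConfig, run_ensemble
from .scaling import NoBracketError

logger = logging.getLogger("kurasync")

__all__ = ["ExperimentConfig", "build_network", "generate", "simulate",
           "analyze", "run_recipe", "recipe", "RECIPES"]


@dataclass
class ExperimentConfig:
    """Serializable description of a full experiment campaign."""

    graph: dict[str, Any]
    K_values: list[float]
    n_realizations: int
    t_max: float
    output_dir: str
    base_seed: int = 0
    dt: float = 0.1
    sample_base: float = 1.08
    init_kind: str = "incoherent"
    threshold: Optional[float] = None
    stop_at_crossing: bool = True
    prep: list[dict[str, Any]] = field(default_factory=list)
    t_min_fit: float = 10.0
    target_bins: int = 40
    width_exponent: float = 1.12
    precision: str = "double"

    def sim_config(self, K: float) -> SimulationConfig:
        return SimulationConfig(
            coupling_K=float(K),
            t_max=self.t_max,
            dt=self.dt,
            sample_base=self.sample_base,
            init_kind=self.init_kind,
            threshold=self.threshold,
            stop_at_crossing=self.stop_at_crossing,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        return cls(**json.loads(text))

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    def k_dir(self, K: float) -> Path:
        return Path(self.output_dir) / f"K={K:g}"


def build_network(cfg: ExperimentConfig) -> graphs.OscillatorNetwork:
    """Build (or load) the graph and apply the preparation steps in order."""
    spec = dict(cfg.graph)
    kind = spec.pop("kind")
    if kind == "2dll":
        net = graphs.make_2dll(L=int(spec["L"]), seed=int(spec.get("seed", cfg.base_seed)))
    elif kind == "full":
        net = graphs.make_full_graph(N=int(spec["N"]), normalized=bool(spec.get("normalized", True)))
    elif kind == "synthetic-connectome":
        net = graphs.make_synthetic_connectome(
            n_nodes=int(spec["n_nodes"]),
            n_modules=int(spec.get("n_modules", 32)),
            intra_density=float(spec.get("intra_density", 0.3)),
            inter_density=float(spec.get("inter_density", 0.01)),
            weight_tail_exponent=float(spec.get("weight_tail_exponent", 3.0)),
            seed=int(spec.get("seed", cfg.base_seed)),
        )
    elif kind == "edge_list":
        net = cio.load_edge_list(spec["path"])
    else:
        raise ValueError(f"unknown graph kind {kind!r}")

    for step in cfg.prep:
        step = dict(step)
        op = step.pop("op")
        if op == "largest_component":
            net = cio.largest_component(net)
        elif op == "normalize_incoming":
            net = cio.normalize_incoming(net)
        elif op == "flip_links":
            net = cio.flip_links(net, **step)
        elif op == "flip_nodes":
            net = cio.flip_nodes(net, **step)
        elif op == "delete_links":
            net = cio.delete_links(net, **step)
        else:
            raise ValueError(f"unknown preparation step {op!r}")
    return net


def generate(cfg: ExperimentConfig) -> Path:
    """Stage 1: build the prepared network and write it as an edge list."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = build_network(cfg)
    path = out / "graph.tsv"
    graphs.write_edge_list(net, str(path))
    meta = {"kind": net.kind, "n_nodes": net.n_nodes, "n_links": net.n_links,
            "is_symmetric": net.is_symmetric}
    (out / "graph_meta.json").write_text(json.dumps(meta, indent=2))
    cfg.save(out / "experiment.json")
    logger.info("generated %s graph: N=%d, %d links", net.kind, net.n_nodes, net.n_links)
    return path


def simulate(cfg: ExperimentConfig) -> list[Path]:
    """Stage 2: run the ensemble for every coupling K (resumable)."""
    net = build_network(cfg)
    out_dirs = []
    for i, K in enumerate(cfg.K_values):
        d = cfg.k_dir(K)
        marker = d / "done"
        if marker.exists():
            logger.info("K=%g already simulated, skipping", K)
            out_dirs.append(d)
            continue
        ens = run_ensemble(net, cfg.sim_config(K), cfg.n_realizations,
                           base_seed=cfg.base_seed + 1000 * i,
                           precision=cfg.precision)
        ens.write(d)
        marker.write_text("ok\n")
        out_dirs.append(d)
        logger.info("K=%g simulated: %d realizations", K, cfg.n_realizations)
    return out_dirs


def analyze(cfg: ExperimentConfig) -> dict[str, Any]:
    """Stage 3: histograms, tail fits, transition location, summary table."""
    out = Path(cfg.output_dir)
    missing = [str(cfg.k_dir(K)) for K in cfg.K_values
               if not (cfg.k_dir(K) / "durations.csv").exists()]
    if missing:
        raise FileNotFoundError(
            "missing simulation outputs: " + ", ".join(missing)
        )
    rows = []
    eta_family = []
    for K in cfg.K_values:
        d = cfg.k_dir(K)
        dur = pd.read_csv(d / "durations.csv")
        censored = dur["crossed"].to_numpy() == 0
        tau = tau_err = np.nan
        cens_frac = float(censored.mean())
        try:
            hist = scaling.build_histogram(
                dur["t_x"].to_numpy(), censored=censored,
                width_exponent=cfg.width_exponent, target_bins=cfg.target_bins,
            )
            pd.DataFrame({
                "edge_lo": hist.bin_edges[:-1], "edge_hi": hist.bin_edges[1:],
                "density": hist.densities, "count": hist.counts,
            }).to_csv(d / "histogram.csv", index=False)
            fit = scaling.fit_tail(hist, t_min=cfg.t_min_fit)
            tau, tau_err = fit.exponent, fit.stderr
            (d / "fit.json").write_text(json.dumps({
                "exponent": fit.exponent, "stderr": fit.stderr,
                "fit_window": list(fit.fit_window), "n_points": fit.n_points,
                "kind": fit.kind, "censoring_fraction": cens_frac,
            }, indent=2))
        except ValueError as exc:
            logger.warning("K=%g: tail fit unavailable (%s)", K, exc)
        eta_late = np.nan
        mr_path = d / "mean_r.csv"
        if mr_path.exists():
            mr = pd.read_csv(mr_path)
            if (mr["mean_R"] > 0).all():
                series = scaling.effective_exponent(
                    mr["t_k"].to_numpy(), mr["mean_R"].to_numpy(), K=float(K))
                eta_family.append(series)
                n = len(series.eta_eff)
                eta_late = float(series.eta_eff[-max(1, n // 3):].mean())
        rows.append({"K": float(K), "tau_t": tau, "tau_t_stderr": tau_err,
                     "eta_eff_late": eta_late, "censoring_fraction": cens_frac})
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)

    transition: dict[str, Any] = {"available": False}
    if len(eta_family) >= 3:
        try:
            est = scaling.locate_transition(eta_family)
            transition = {
                "available": True, "K_c": est.K_c,
                "bracket": list(est.bracket),
                "K_values": est.K_values.tolist(),
                "trends": est.trends.tolist(),
            }
        except NoBracketError as exc:
            transition = {"available": False, "reason": str(exc)}
    (out / "transition.json").write_text(json.dumps(transition, indent=2))
    return {"summary": summary, "transition": transition}


def recipe(name: str, output_dir: str = "runs", base_seed: int = 0) -> ExperimentConfig:
    """A canned, reduced-scale experiment configuration by name."""
    if name not in RECIPES:
        raise KeyError(f"unknown recipe {name!r}; available: {sorted(RECIPES)}")
    cfg = RECIPES[name]
    return ExperimentConfig(**{**asdict(cfg),
                               "output_dir": str(Path(output_dir) / name),
                               "base_seed": base_seed})


def run_recipe(name: str, output_dir: str = "runs", base_seed: int = 0) -> dict[str, Any]:
    """Generate, simulate and analyze one canned recipe end to end."""
    cfg = recipe(name, output_dir, base_seed)
    generate(cfg)
    simulate(cfg)
    return analyze(cfg)


# Canned protocols at reduced scale: lattice growth-duration statistics at
# the critical coupling, surrogate-connectome growth near its crossover,
# and the inhibitory-link variant of the surrogate.
RECIPES: dict[str, ExperimentConfig] = {
    "2dll-critical": ExperimentConfig(
        graph={"kind": "2dll", "L": 64, "seed": 7},
        K_values=[0.4775],
        n_realizations=2000,
        t_max=1000.0,
        stop_at_crossing=True,
        t_min_fit=10.0,
        output_dir="runs/2dll-critical",
    ),
    "2dll-transition": ExperimentConfig(
        graph={"kind": "2dll", "L": 64, "seed": 7},
        K_values=[0.45, 0.465, 0.4775, 0.49, 0.505],
        n_realizations=64,
        t_max=200.0,
        stop_at_crossing=False,
        output_dir="runs/2dll-transition",
    ),
    "connectome-growth": ExperimentConfig(
        graph={"kind": "synthetic-connectome", "n_nodes": 2000, "seed": 3},
        prep=[{"op": "largest_component"}, {"op": "normalize_incoming"}],
        K_values=[1.2, 1.5, 1.8, 2.1, 2.4],
        n_realizations=64,
        t_max=200.0,
        stop_at_crossing=False,
        t_min_fit=20.0,
        output_dir="runs/connectome-growth",
    ),
    "inhibitory-links": ExperimentConfig(
        graph={"kind": "synthetic-connectome", "n_nodes": 2000, "seed": 3},
        prep=[{"op": "largest_component"}, {"op": "normalize_incoming"},
              {"op": "flip_links", "fraction": 0.05, "mode": "symmetric", "seed": 11}],
        K_values=[1.2, 1.5, 1.8, 2.1, 2.4],
        n_realizations=64,
        t_max=200.0,
        stop_at_crossing=False,
        t_min_fit=20.0,
        output_dir="runs/inhibitory-links",
    ),
}
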