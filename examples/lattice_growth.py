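"""Order-parameter growth and local slopes on the small-world lattice.

Averages R(t) over incoherent-start realizations of the 2d lattice with
long-range links (mean degree 5) around its critical coupling
K_c ~= 0.4775 and prints the effective growth exponent
eta_eff(t) — the discretized logarithmic derivative of <R(t)>.  At
criticality eta_eff levels off (here around 0.4-0.6 at this small size);
off-critical couplings veer up or down at late times.
"""

from kurasync import SimulationConfig, effective_exponent, make_2dll, run_ensemble


def main() -> None:
    net = make_2dll(48, seed=7)  # N = 2304 nodes
    for K in (0.46, 0.4775, 0.50):
        cfg = SimulationConfig(coupling_K=K, t_max=60.0)
        ens = run_ensemble(net, cfg, 64, base_seed=11)
        series = effective_exponent(ens.times, ens.mean_R, K=K)
        late = series.eta_eff[-6:].mean()
        print(f"K = {K:6.4f}  late-time eta_eff ~ {late:+.3f}  "
              f"(<R> grew {ens.mean_R[0]:.3f} -> {ens.mean_R[-1]:.3f})")
    print(
        "\nNegative late-time trend = subcritical (veering down), strongly "
        "positive = supercritical (veering up); the critical coupling sits "
        "where the trend changes sign.  At this small size the crossover "
        "lies slightly below the large-lattice K_c = 0.4775."
    )


if __name__ == "__main__":
    main()
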