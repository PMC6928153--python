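"""First-passage (desynchronization) duration statistics on the lattice.

Runs growth realizations from random phases near criticality, records
the first time t_x at which R(t) drops below the noise threshold
1/sqrt(N), histograms the durations with power-law-growing bins
(dt_x ~ t_x^1.12) and fits the tail exponent tau_t of
p(t_x) ~ t_x^(-tau_t).

At this small demo size (L = 48, N = 2304) the coupling is effectively
supercritical and the tail is flatter than the mean-field-like ~1.6
measured on larger lattices — the fat tail itself (1 < tau_t < 2) is
the robust feature.  scripts/acceptance.py runs the L = 128 version
that recovers tau_t ~ 1.6.  Note also how the plain Hill/MLE estimate
exceeds the binned least-squares fit: the MLE assumes an untruncated
power law and is biased upward by the finite horizon.
"""

import numpy as np

from kurasync import (
    SimulationConfig,
    build_histogram,
    fit_tail,
    fit_tail_mle,
    make_2dll,
    run_ensemble,
)


def main() -> None:
    net = make_2dll(48, seed=7)
    cfg = SimulationConfig(coupling_K=0.4775, t_max=100.0, stop_at_crossing=True)
    ens = run_ensemble(net, cfg, 400, base_seed=21, batch_size=64)
    frac = ens.crossed.mean()
    print(f"{ens.crossed.sum()} of {ens.n_realizations} realizations "
          f"desynchronized within t <= {cfg.t_max:g} ({100*frac:.0f}%)")

    hist = build_histogram(ens.t_x, censored=~ens.crossed)
    fit = fit_tail(hist, t_min=5.0)
    mle = fit_tail_mle(ens.t_x[ens.crossed], t_min=5.0)
    print(f"least-squares tail fit: tau_t = {fit.exponent:.2f} "
          f"+- {fit.stderr:.2f} over t_x in {fit.fit_window}")
    print(f"MLE cross-check:        tau_t = {mle.exponent:.2f} +- {mle.stderr:.2f}")
    print(
        "\ntau_t is the power-law exponent of the duration density; values "
        "between 1 and 2 signal scale-free desynchronization events.\n"
        "(The MLE exceeds the binned fit because it ignores the finite "
        "horizon; the least-squares fit on binned densities is primary.)"
    )


if __name__ == "__main__":
    main()
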