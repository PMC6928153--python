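"""Synchronization onset on the complete graph versus mean-field theory.

Sweeps the global coupling K on a normalized all-to-all network and
compares the simulated stationary order parameter R with the
self-consistency fixed point r*(K) of mean-field theory, which predicts
a critical coupling K_c = 2*sqrt(2*pi)/pi ~= 1.596 for standard-normal
intrinsic frequencies.
"""

import numpy as np

from kurasync import (
    SimulationConfig,
    critical_coupling,
    make_full_graph,
    steady_state_R,
    steady_state_r,
)


def main() -> None:
    net = make_full_graph(1000, normalized=True)
    cfg = SimulationConfig(coupling_K=0.0, t_max=120.0)
    K_grid = [1.2, 1.4, 1.6, 1.8, 2.0, 2.4]
    table = steady_state_R(net, K_grid, cfg, n_realizations=10, base_seed=1)

    print(f"mean-field K_c = {critical_coupling():.4f}")
    print(f"{'K':>5} {'R_sim':>8} {'R_theory':>9}")
    for _, row in table.iterrows():
        theory = steady_state_r(row.K)
        print(f"{row.K:5.2f} {row.R_mean:8.3f} {theory:9.3f}")
    print(
        "\nBelow K_c the simulated R sits at the finite-size noise floor "
        f"~1/sqrt(N) = {1/np.sqrt(net.n_nodes):.3f}; above K_c it follows "
        "the mean-field fixed point."
    )


if __name__ == "__main__":
    main()
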