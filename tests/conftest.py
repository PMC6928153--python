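import numpy as np
import pytest
import scipy.sparse as sp

from kurasync.graphs import OscillatorNetwork


def network_from_dense(dense, kind="loaded", symmetric=None):
    """Build an OscillatorNetwork straight from a dense coupling matrix."""
    dense = np.asarray(dense, dtype=float)
    W = sp.csr_matrix(dense)
    W.setdiag(0)
    W.eliminate_zeros()
    if symmetric is None:
        symmetric = bool(np.allclose(dense, dense.T))
    return OscillatorNetwork(
        n_nodes=dense.shape[0],
        coupling=W,
        is_symmetric=symmetric,
        kind=kind,
        meta={},
    )


def ring_network(n):
    """Periodic ring: every node coupled to its two neighbours, weight 1."""
    idx = np.arange(n)
    rows = np.concatenate([idx, idx])
    cols = np.concatenate([(idx + 1) % n, (idx - 1) % n])
    W = sp.csr_matrix((np.ones(2 * n), (rows, cols)), shape=(n, n))
    return OscillatorNetwork(n_nodes=n, coupling=W, is_symmetric=True,
                             kind="loaded", meta={})


def path_network(n):
    """Open chain of n nodes."""
    idx = np.arange(n - 1)
    rows = np.concatenate([idx, idx + 1])
    cols = np.concatenate([idx + 1, idx])
    W = sp.csr_matrix((np.ones(2 * (n - 1)), (rows, cols)), shape=(n, n))
    return OscillatorNetwork(n_nodes=n, coupling=W, is_symmetric=True,
                             kind="loaded", meta={})


def lattice_network(L):
    """Pure periodic L x L lattice, 4 nearest neighbours, no extra links."""
    N = L * L
    idx = np.arange(N)
    x, y = idx // L, idx % L
    right = x * L + (y + 1) % L
    down = ((x + 1) % L) * L + y
    rows = np.concatenate([idx, right, idx, down])
    cols = np.concatenate([right, idx, down, idx])
    W = sp.csr_matrix((np.ones(4 * N), (rows, cols)), shape=(N, N))
    return OscillatorNetwork(n_nodes=N, coupling=W, is_symmetric=True,
                             kind="loaded", meta={"L": L})


def star_network(n_spokes):
    """Hub (node 0) with unit-weight spokes."""
    hub = np.zeros(n_spokes, dtype=int)
    spokes = np.arange(1, n_spokes + 1)
    rows = np.concatenate([hub, spokes])
    cols = np.concatenate([spokes, hub])
    W = sp.csr_matrix((np.ones(2 * n_spokes), (rows, cols)),
                      shape=(n_spokes + 1, n_spokes + 1))
    return OscillatorNetwork(n_nodes=n_spokes + 1, coupling=W,
                             is_symmetric=True, kind="loaded", meta={})


def powerlaw_samples(tau, n, rng, t_lo=1.0, t_hi=1000.0):
    """Inverse-CDF samples from p(t) ~ t^-tau truncated to [t_lo, t_hi]."""
    u = rng.random(n)
    a = 1.0 - tau
    return (t_lo ** a + u * (t_hi ** a - t_lo ** a)) ** (1.0 / a)


@pytest.fixture(scope="session")
def small_2dll():
    from kurasync.graphs import make_2dll

    return make_2dll(8, seed=3)
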