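"""Network and intrinsic-frequency generators for Kuramoto simulations.

All graphs produced here are in-memory :class:`OscillatorNetwork` objects
holding a sparse coupling matrix ``W`` in CSR form, with the row index
denoting the *receiving* oscillator.  Three families are provided:

* ``make_2dll`` — a periodic two-dimensional lattice augmented with random
  long-range links up to mean degree 5, a small-world graph expected to
  behave mean-field-like for synchronization.
* ``make_full_graph`` — the complete graph (optionally with incoming
  weights normalized to unit row sums), the classical mean-field setting.
* ``make_synthetic_connectome`` — a hierarchical-modular weighted surrogate
  for large DTI connectomes: two nested levels of modules, dense wiring
  inside modules, sparse wiring between them, and heavy-tailed (Pareto)
  positive weights, mirroring fiber-count statistics.

Intrinsic frequencies are i.i.d. standard normal, drawn per realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp

__all__ = [
    "OscillatorNetwork",
    "FrequencySet",
    "make_2dll",
    "make_full_graph",
    "make_synthetic_connectome",
    "draw_frequencies",
    "validate_network",
    "write_edge_list",
]


class InvalidSizeError(ValueError):
    """Raised when a requested graph size is below the minimum."""


class InvalidParameterError(ValueError):
    """Raised when generator parameters fall outside their legal range."""


@dataclass
class OscillatorNetwork:
    """Weighted, generally directed coupling network for phase oscillators.

    Attributes
    ----------
    n_nodes : int
        Number of oscillators N.
    coupling : scipy.sparse.csr_matrix
        Coupling weights ``W[i, j]``: influence of sender ``j`` on
        receiver ``i``.  The diagonal is structurally zero.
    is_symmetric : bool
        True when ``W == W.T`` exactly (entrywise, including values).
    kind : str
        One of ``"2dll"``, ``"full"``, ``"synthetic-connectome"``,
        ``"loaded"``.
    meta : dict
        Free-form provenance (generator parameters, seeds, applied
        modifications).
    """

    n_nodes: int
    coupling: sp.csr_matrix
    is_symmetric: bool
    kind: str
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_links(self) -> int:
        """Number of stored directed entries of W."""
        return int(self.coupling.nnz)

    @property
    def n_undirected_links(self) -> int:
        """Number of undirected link positions (pairs i<j with an entry)."""
        upper = sp.triu(self.coupling, k=1)
        lower = sp.tril(self.coupling, k=-1).T
        return int((abs(upper) + abs(lower)).nnz)

    def copy(self) -> "OscillatorNetwork":
        return OscillatorNetwork(
            n_nodes=self.n_nodes,
            coupling=self.coupling.copy(),
            is_symmetric=self.is_symmetric,
            kind=self.kind,
            meta=dict(self.meta),
        )


@dataclass
class FrequencySet:
    """Intrinsic frequencies ω_i of one realization (standard normal)."""

    omega: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.omega)


def validate_network(net: OscillatorNetwork) -> None:
    """Check the structural invariants every generated network must obey.

    Raises ``ValueError`` on: self-coupling, non-finite weights, a symmetry
    flag contradicted by the matrix, or a shape mismatch.
    """
    W = net.coupling
    if W.shape != (net.n_nodes, net.n_nodes):
        raise ValueError(
            f"coupling shape {W.shape} does not match n_nodes={net.n_nodes}"
        )
    if W.diagonal().any():
        raise ValueError("self-coupling detected: nonzero diagonal entries")
    if not np.all(np.isfinite(W.data)):
        raise ValueError("non-finite coupling weights")
    if net.is_symmetric:
        if (W != W.T).nnz != 0:
            raise ValueError("is_symmetric is set but W != W.T")


def _finalize(W: sp.spmatrix) -> sp.csr_matrix:
    W = sp.csr_matrix(W)
    W.setdiag(0)
    W.eliminate_zeros()
    W.sum_duplicates()
    W.sort_indices()
    return W


def make_2dll(L: int, seed: int) -> OscillatorNetwork:
    """Periodic L×L lattice plus ⌊N/2⌋ random long-range links (⟨k⟩ ≈ 5).

    Every node couples with weight 1 to its four nearest neighbours on the
    periodic square lattice (N = L² nodes, row-major indexing, wrap via
    modular arithmetic).  On top, exactly ``N // 2`` additional distinct
    undirected links between uniformly random node pairs are added
    (rejecting self-loops and duplicates of existing edges), which brings
    the mean degree to 4 + 2⌊N/2⌋/N ≈ 5.

    Parameters
    ----------
    L : int
        Lattice side length, at least 3.
    seed : int
        Seed for the long-range link RNG stream.
    """
    if L < 3:
        raise InvalidSizeError(f"lattice side L must be >= 3, got {L}")
    N = L * L
    idx = np.arange(N)
    x, y = idx // L, idx % L
    right = x * L + (y + 1) % L
    down = ((x + 1) % L) * L + y
    lat_a = np.concatenate([idx, idx])
    lat_b = np.concatenate([right, down])

    n_extra = N // 2
    rng = np.random.default_rng(seed)
    # canonical codes (min*N + max) of existing lattice edges, for rejection
    lo = np.minimum(lat_a, lat_b).astype(np.int64)
    hi = np.maximum(lat_a, lat_b).astype(np.int64)
    forbidden = np.sort(lo * N + hi)

    chosen = np.empty(0, dtype=np.int64)
    while chosen.size < n_extra:
        m = int(1.3 * (n_extra - chosen.size)) + 16
        a = rng.integers(0, N, size=m)
        b = rng.integers(0, N, size=m)
        ok = a != b
        a, b = a[ok], b[ok]
        code = np.minimum(a, b).astype(np.int64) * N + np.maximum(a, b)
        # drop lattice edges and duplicates (within batch and across batches)
        code = code[np.searchsorted(forbidden, code) == np.searchsorted(forbidden, code, side="right")]
        code = np.unique(code)
        code = np.setdiff1d(code, chosen, assume_unique=True)
        take = code[: n_extra - chosen.size] if code.size else code
        chosen = np.concatenate([chosen, take])
    ex_a, ex_b = chosen // N, chosen % N

    rows = np.concatenate([lat_a, lat_b, ex_a, ex_b])
    cols = np.concatenate([lat_b, lat_a, ex_b, ex_a])
    W = _finalize(
        sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(N, N))
    )
    # duplicates cannot occur by construction; guard anyway
    W.data[:] = 1.0
    return OscillatorNetwork(
        n_nodes=N,
        coupling=W,
        is_symmetric=True,
        kind="2dll",
        meta={"L": L, "seed": int(seed), "n_long_range": int(n_extra)},
    )


def make_full_graph(N: int, normalized: bool = True) -> OscillatorNetwork:
    """Complete graph on N nodes; optionally row-normalized to 1/(N−1).

    With ``normalized=True`` every incoming row of W sums to exactly 1,
    which makes the critical coupling of the mean-field Kuramoto model
    with standard-normal frequencies K_c = 2√(2π)/π ≈ 1.596 independent
    of N.
    """
    if N < 2:
        raise InvalidSizeError(f"full graph needs N >= 2, got {N}")
    w = 1.0 / (N - 1) if normalized else 1.0
    dense = np.full((N, N), w)
    np.fill_diagonal(dense, 0.0)
    W = sp.csr_matrix(dense)
    return OscillatorNetwork(
        n_nodes=N,
        coupling=W,
        is_symmetric=True,
        kind="full",
        meta={"normalized": bool(normalized)},
    )


def make_synthetic_connectome(
    n_nodes: int,
    n_modules: int = 32,
    intra_density: float = 0.3,
    inter_density: float = 0.01,
    weight_tail_exponent: float = 3.0,
    seed: int = 0,
) -> OscillatorNetwork:
    """Hierarchical-modular weighted surrogate of a large human connectome.

    Two nested hierarchy levels are planted: ``n_modules`` modules of
    uneven size are grouped into roughly ``sqrt(n_modules)`` super-modules.
    Node pairs are wired with probability ``intra_density`` inside a
    module, ``inter_density`` between modules of the same super-module and
    ``inter_density / 4`` across super-modules.  Link weights are drawn
    from a Pareto law with density ∝ w^(−weight_tail_exponent) on [1, ∞),
    emulating the heavy-tailed fiber-count weights of DTI connectomes.
    A random spanning backbone over modules is always added so the graph
    comes out connected.

    Module sizes are drawn from a heavy-tailed (Pareto) split so that the
    module-size distribution spans a wide range, as observed in
    Louvain partitions of real connectomes.
    """
    if n_modules < 2:
        raise InvalidParameterError("n_modules must be >= 2")
    if n_nodes < 2 * n_modules:
        raise InvalidParameterError("n_nodes must allow >= 2 nodes per module")
    for name, d in (("intra_density", intra_density), ("inter_density", inter_density)):
        if not (0.0 < d <= 1.0):
            raise InvalidParameterError(f"{name} must be in (0, 1], got {d}")
    if weight_tail_exponent <= 1.0:
        raise InvalidParameterError("weight_tail_exponent must be > 1")

    rng = np.random.default_rng(seed)

    # uneven module sizes: heavy-tailed split, minimum 2 nodes per module
    raw = rng.pareto(1.5, size=n_modules) + 0.5
    sizes = np.maximum(2, np.floor(raw / raw.sum() * n_nodes).astype(int))
    while sizes.sum() > n_nodes:
        sizes[np.argmax(sizes)] -= 1
    sizes[np.argmax(sizes)] += n_nodes - sizes.sum()
    labels = np.repeat(np.arange(n_modules), sizes)
    perm = rng.permutation(n_nodes)
    labels = labels[np.argsort(perm, kind="stable")]  # scatter modules over ids

    n_super = max(2, int(round(np.sqrt(n_modules))))
    super_of = rng.integers(0, n_super, size=n_modules)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    members = [np.flatnonzero(labels == m) for m in range(n_modules)]

    def _sample_pairs(a: np.ndarray, b: np.ndarray, p: float) -> None:
        """Bernoulli(p) wiring between node sets a and b (a == b allowed)."""
        same = a is b
        n_pairs = len(a) * (len(a) - 1) // 2 if same else len(a) * len(b)
        if n_pairs == 0 or p <= 0:
            return
        k = rng.binomial(n_pairs, p)
        if k == 0:
            return
        flat = rng.choice(n_pairs, size=k, replace=False)
        if same:
            # unrank upper-triangle pairs
            i = (np.floor((1 + np.sqrt(1 + 8 * flat.astype(float))) / 2)).astype(int)
            j = (flat - i * (i - 1) // 2).astype(int)
            rows.append(a[i])
            cols.append(a[j])
        else:
            rows.append(a[flat // len(b)])
            cols.append(b[flat % len(b)])

    for m in range(n_modules):
        _sample_pairs(members[m], members[m], intra_density)
    for m1 in range(n_modules):
        for m2 in range(m1 + 1, n_modules):
            p = inter_density if super_of[m1] == super_of[m2] else inter_density / 4.0
            _sample_pairs(members[m1], members[m2], p)
    # spanning backbone over modules (random module order, one edge each)
    order = rng.permutation(n_modules)
    for m1, m2 in zip(order[:-1], order[1:]):
        rows.append(np.array([rng.choice(members[m1])]))
        cols.append(np.array([rng.choice(members[m2])]))

    r = np.concatenate(rows)
    c = np.concatenate(cols)
    lo, hi = np.minimum(r, c), np.maximum(r, c)
    code = np.unique(lo.astype(np.int64) * n_nodes + hi)
    code = code[code // n_nodes != code % n_nodes]
    lo, hi = code // n_nodes, code % n_nodes
    weights = 1.0 + rng.pareto(weight_tail_exponent - 1.0, size=lo.size)

    W = _finalize(
        sp.coo_matrix(
            (
                np.concatenate([weights, weights]),
                (np.concatenate([lo, hi]), np.concatenate([hi, lo])),
            ),
            shape=(n_nodes, n_nodes),
        )
    )
    net = OscillatorNetwork(
        n_nodes=n_nodes,
        coupling=W,
        is_symmetric=True,
        kind="synthetic-connectome",
        meta={
            "seed": int(seed),
            "n_modules": int(n_modules),
            "module_labels": labels,
            "intra_density": float(intra_density),
            "inter_density": float(inter_density),
            "weight_tail_exponent": float(weight_tail_exponent),
        },
    )
    _connect_components(net, rng)
    return net


def _connect_components(net: OscillatorNetwork, rng: np.random.Generator) -> None:
    """Stitch any residual disconnected components together (in place)."""
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(abs(net.coupling), directed=False)
    if n_comp <= 1:
        return
    W = net.coupling.tolil()
    anchors = [np.flatnonzero(labels == c) for c in range(n_comp)]
    for c in range(1, n_comp):
        a = rng.choice(anchors[0])
        b = rng.choice(anchors[c])
        W[a, b] = W[b, a] = 1.0
    net.coupling = _finalize(W)


def draw_frequencies(N: int, seed: int) -> FrequencySet:
    """Draw N i.i.d. standard-normal intrinsic frequencies, reproducibly."""
    if N < 1:
        raise InvalidSizeError(f"need N >= 1 frequencies, got {N}")
    rng = np.random.default_rng(seed)
    return FrequencySet(omega=rng.standard_normal(N), seed=int(seed))


def write_edge_list(net: OscillatorNetwork, path: str) -> None:
    """Write a network as a tab-separated ``source  target  weight`` file.

    Symmetric networks are written with one line per undirected edge
    (i < j); directed/asymmetric ones with one line per stored entry.
    A ``#`` header records kind and generator metadata.
    """
    validate_network(net)
    scalar_meta = {
        k: v for k, v in net.meta.items() if isinstance(v, (int, float, str, bool))
    }
    header = f"# kind={net.kind} n_nodes={net.n_nodes} " + " ".join(
        f"{k}={v}" for k, v in scalar_meta.items()
    )
    if net.is_symmetric:
        part = sp.coo_matrix(sp.triu(net.coupling, k=1))
    else:
        part = sp.coo_matrix(net.coupling)
    order = np.lexsort((part.col, part.row))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i, j, w in zip(part.row[order], part.col[order], part.data[order]):
            fh.write(f"{i}\t{j}\t{w:.12g}\n")
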