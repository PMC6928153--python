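import numpy as np
import pytest
import scipy.sparse as sp

from kurasync.connectome import (
    DisconnectedGraphError,
    EdgeListParseError,
    delete_links,
    flip_links,
    flip_nodes,
    largest_component,
    load_edge_list,
    normalize_incoming,
    topological_dimension,
)
from conftest import lattice_network, network_from_dense, path_network, ring_network, star_network


class TestLoadEdgeList:
    def test_duplicate_edges_merge_by_sum(self, tmp_path):
        p = tmp_path / "toy.tsv"
        p.write_text("0 1 2\n1 2 1\n0 1 1\n")
        net = load_edge_list(str(p))
        assert net.n_nodes == 3
        assert net.coupling[0, 1] == 3.0
        assert net.coupling[1, 0] == 3.0
        assert net.coupling[1, 2] == 1.0

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("# only a header\n")
        with pytest.raises(EdgeListParseError):
            load_edge_list(str(p))

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("0 1 1\n0 2\n")
        with pytest.raises(EdgeListParseError, match=":2:"):
            load_edge_list(str(p))

    def test_negative_weight_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("0 1 -1.0\n")
        with pytest.raises(EdgeListParseError):
            load_edge_list(str(p))

    def test_sparse_ids_remapped_densely(self, tmp_path):
        p = tmp_path / "ids.tsv"
        p.write_text("5 9 1\n9 12 2\n")
        net = load_edge_list(str(p))
        assert net.n_nodes == 3
        assert list(net.meta["node_map"]) == [5, 9, 12]
        assert net.coupling[1, 2] == 2.0


class TestGraphmlImport:
    def test_round_trip_via_networkx(self, tmp_path):
        import networkx as nx

        from kurasync.connectome import load_graphml

        g = nx.Graph()
        g.add_edge(0, 1, weight=2.0)
        g.add_edge(1, 2, weight=0.5)
        path = tmp_path / "g.graphml"
        nx.write_graphml(g, path)
        net = load_graphml(str(path))
        assert net.n_nodes == 3
        assert net.coupling[0, 1] == 2.0
        assert net.coupling[2, 1] == 0.5


class TestLargestComponent:
    def test_tie_break_keeps_smallest_id(self):
        dense = np.zeros((6, 6))
        for a, b in [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]:
            dense[a, b] = dense[b, a] = 1.0
        net = network_from_dense(dense)
        out = largest_component(net)
        assert out.n_nodes == 3
        assert list(out.meta["component_nodes"]) == [0, 1, 2]

    def test_connected_graph_unchanged(self):
        net = ring_network(10)
        out = largest_component(net)
        assert out.n_nodes == 10
        assert (out.coupling != net.coupling).nnz == 0

    def test_isolated_node_dropped(self):
        dense = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (2, 0)]:
            dense[a, b] = dense[b, a] = 1.0
        out = largest_component(network_from_dense(dense))
        assert out.n_nodes == 3


class TestNormalizeIncoming:
    def test_star_hub_rows(self):
        net = star_network(4)
        out = normalize_incoming(net)
        assert np.allclose(out.coupling[0].toarray().ravel()[1:], 0.25)
        rows = np.asarray(out.coupling.sum(axis=1)).ravel()
        assert np.allclose(rows, 1.0, atol=1e-12)

    def test_idempotent(self):
        net = ring_network(8)
        once = normalize_incoming(net)
        twice = normalize_incoming(once)
        assert np.allclose(once.coupling.toarray(), twice.coupling.toarray(),
                           atol=1e-14)

    def test_generic_row_sums_one(self):
        rng = np.random.default_rng(0)
        dense = rng.random((12, 12)) * (rng.random((12, 12)) < 0.4)
        dense = dense + dense.T
        np.fill_diagonal(dense, 0)
        dense[0, 1] = dense[1, 0] = 1.0  # ensure no isolated node
        out = normalize_incoming(network_from_dense(dense))
        rows = np.asarray(out.coupling.sum(axis=1)).ravel()
        assert np.allclose(rows, 1.0, atol=1e-12)

    def test_isolated_node_named_in_error(self):
        dense = np.zeros((3, 3))
        dense[0, 1] = dense[1, 0] = 1.0
        with pytest.raises(ValueError, match="2"):
            normalize_incoming(network_from_dense(dense))


class TestFlipLinks:
    def test_zero_fraction_identity(self, small_2dll):
        net = normalize_incoming(small_2dll)
        out = flip_links(net, 0.0, seed=1)
        assert (out.coupling != net.coupling).nnz == 0

    def test_full_fraction_negates_everything(self, small_2dll):
        net = normalize_incoming(small_2dll)
        out = flip_links(net, 1.0, mode="symmetric", seed=1)
        assert np.all(out.coupling.data < 0)
        assert np.allclose(abs(out.coupling).toarray(),
                           abs(net.coupling).toarray())

    def test_flip_count_contract(self, small_2dll):
        net = normalize_incoming(small_2dll)
        M = net.n_undirected_links
        out = flip_links(net, 0.05, mode="symmetric", seed=3)
        neg = sp.triu(sp.csr_matrix(
            (out.coupling.toarray() < 0).astype(int)), k=1).nnz
        assert neg == round(0.05 * M)

    def test_symmetric_flip_preserves_structural_symmetry(self, small_2dll):
        out = flip_links(small_2dll, 0.1, mode="symmetric", seed=5)
        assert (out.coupling != out.coupling.T).nnz == 0
        assert out.is_symmetric

    def test_anisotropic_flip_breaks_symmetry(self, small_2dll):
        net = normalize_incoming(small_2dll)
        out = flip_links(net, 0.1, mode="anisotropic", seed=5)
        assert not out.is_symmetric
        dense = out.coupling.toarray()
        assert np.any(dense != dense.T)
        # each selected pair lost its reverse direction
        assert out.coupling.nnz < net.coupling.nnz

    def test_fraction_out_of_range(self, small_2dll):
        with pytest.raises(ValueError):
            flip_links(small_2dll, 1.5)


class TestFlipNodes:
    def test_zero_fraction_identity(self, small_2dll):
        out = flip_nodes(small_2dll, 0.0, seed=2)
        assert (out.coupling != small_2dll.coupling).nnz == 0

    def test_star_hub_out_flip(self):
        net = star_network(5)
        out = flip_nodes(net, fraction=1.0 / 6.0, direction="out", seed=0)
        # with fraction 1/6 on 6 nodes exactly one node was selected
        sel = out.meta["flipped_nodes"]
        assert len(sel) == 1
        j = sel[0]
        col = out.coupling.toarray()[:, j]
        assert np.all(col[col != 0] < 0)

    def test_selected_count_contract(self):
        net = ring_network(40)
        out = flip_nodes(net, 0.05, direction="in", seed=1)
        assert len(out.meta["flipped_nodes"]) == round(0.05 * 40)

    def test_in_direction_negates_rows(self):
        net = ring_network(10)
        out = flip_nodes(net, 0.2, direction="in", seed=4)
        dense = out.coupling.toarray()
        for j in out.meta["flipped_nodes"]:
            row = dense[j]
            assert np.all(row[row != 0] < 0)


class TestDeleteLinks:
    def test_fraction_removed(self):
        net = ring_network(50)
        out = delete_links(net, 0.2, seed=9)
        assert out.coupling.nnz == net.coupling.nnz - round(0.2 * net.coupling.nnz)


class TestTopologicalDimension:
    def test_ring_dimension_one(self):
        fit = topological_dimension(ring_network(1000), n_sources=8, seed=0)
        assert 0.9 <= fit.d_estimate <= 1.1

    def test_path_dimension_one(self):
        fit = topological_dimension(path_network(500), n_sources=8, seed=0)
        assert 0.8 <= fit.d_estimate <= 1.2

    def test_lattice_dimension_two(self):
        fit = topological_dimension(lattice_network(64), n_sources=8, seed=0)
        assert 1.8 <= fit.d_estimate <= 2.2

    def test_shell_counts_are_nonnegative(self):
        fit = topological_dimension(ring_network(100), n_sources=4, seed=1)
        assert np.all(fit.shell_counts >= 0)
        # ring shells: exactly two nodes per shell before wrap-around
        assert np.allclose(fit.shell_counts[:-1], 2.0)

    def test_disconnected_raises(self):
        dense = np.zeros((6, 6))
        for a, b in [(0, 1), (2, 3), (4, 5)]:
            dense[a, b] = dense[b, a] = 1.0
        with pytest.raises(DisconnectedGraphError):
            topological_dimension(network_from_dense(dense))
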