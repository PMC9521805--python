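import numpy as np
import pandas as pd
import pytest

from ecocausal import (BipartiteNetwork, CommunityDataset, ConfigurationError,
                       DataError, PairedSample, degree, normalized_degree,
                       paired_sample_from_community, read_bipartite_network,
                       read_species_table, write_bipartite_network)


def write_csv(path, text):
    path.write_text(text)
    return path


class TestSpeciesTable:
    CMAP = {"id": "species", "x": "degree", "y": "abundance"}

    def test_direct_parse_preserves_rows(self, tmp_path):
        p = write_csv(tmp_path / "t.csv",
                      "species,abundance,degree\na,10,1\nb,5,2\nc,1,3\n")
        s = read_species_table(p, self.CMAP)
        assert len(s) == 3
        assert s.ids == ["a", "b", "c"]
        np.testing.assert_array_equal(s.x, [1, 2, 3])
        np.testing.assert_array_equal(s.y, [10, 5, 1])

    def test_missing_values_dropped(self, tmp_path, caplog):
        rows = "\n".join(f"s{i},{i + 1},{i + 2}" for i in range(4))
        p = write_csv(tmp_path / "t.csv",
                      f"species,abundance,degree\n{rows}\nsx,,9\n")
        with caplog.at_level("INFO"):
            s = read_species_table(p, self.CMAP)
        assert len(s) == 4
        assert "dropped 1" in caplog.text

    def test_absent_column_is_configuration_error(self, tmp_path):
        p = write_csv(tmp_path / "t.csv", "species,abundance\na,1\nb,2\nc,3\n")
        with pytest.raises(ConfigurationError):
            read_species_table(p, self.CMAP)

    def test_too_few_complete_rows(self, tmp_path):
        p = write_csv(tmp_path / "t.csv",
                      "species,abundance,degree\na,1,1\nb,2,\nc,,3\n")
        with pytest.raises(DataError):
            read_species_table(p, self.CMAP)


class TestNetworkIO:
    def test_edge_list_construction(self, tmp_path):
        p = write_csv(tmp_path / "e.tsv", "A\tp1\nA\tp2\nB\tp1\n")
        net = read_bipartite_network(p, "edge_list")
        assert net.row_labels == ["A", "B"]
        assert net.col_labels == ["p1", "p2"]
        np.testing.assert_array_equal(net.adjacency, [[1, 1], [1, 0]])

    def test_duplicate_edges_collapse(self, tmp_path):
        p1 = write_csv(tmp_path / "a.tsv", "A\tp1\nA\tp1\nB\tp1\n")
        p2 = write_csv(tmp_path / "b.tsv", "A\tp1\nB\tp1\n")
        np.testing.assert_array_equal(
            read_bipartite_network(p1, "edge_list").adjacency,
            read_bipartite_network(p2, "edge_list").adjacency)

    def test_visitation_counts_binarized(self, tmp_path):
        p = write_csv(tmp_path / "m.csv", ",p1,p2\nA,0,3\nB,7,0\n")
        net = read_bipartite_network(p, "adjacency")
        np.testing.assert_array_equal(net.adjacency, [[0, 1], [1, 0]])

    def test_non_numeric_cell_is_error(self, tmp_path):
        p = write_csv(tmp_path / "m.csv", ",p1,p2\nA,0,x\nB,1,0\n")
        with pytest.raises(DataError):
            read_bipartite_network(p, "adjacency")

    def test_empty_edge_list_is_error(self, tmp_path):
        p = write_csv(tmp_path / "e.tsv", "")
        with pytest.raises(DataError):
            read_bipartite_network(p, "edge_list")

    @pytest.mark.parametrize("fmt", ["adjacency", "edge_list"])
    def test_round_trip(self, tmp_path, rng, fmt):
        adj = (rng.random((6, 8)) < 0.4).astype(int)
        adj[adj.sum(axis=1) == 0, 0] = 1  # no empty rows so edge list round-trips
        net = BipartiteNetwork([f"r{i}" for i in range(6)],
                               [f"c{j}" for j in range(8)], adj)
        path = tmp_path / ("net.tsv" if fmt == "edge_list" else "net.csv")
        write_bipartite_network(net, path, fmt)
        back = read_bipartite_network(path, fmt)
        # edge-list readers order labels by first appearance: align on labels
        orig = pd.DataFrame(net.adjacency, index=net.row_labels, columns=net.col_labels)
        redo = pd.DataFrame(back.adjacency, index=back.row_labels,
                            columns=back.col_labels).reindex(
            index=net.row_labels, columns=net.col_labels, fill_value=0)
        np.testing.assert_array_equal(redo.to_numpy(), orig.to_numpy())


class TestDegreeMetrics:
    NET = BipartiteNetwork(["A", "B"], ["p1", "p2"], np.array([[1, 1], [1, 0]]))

    @pytest.mark.parametrize("side,expected", [("rows", [2, 1]), ("cols", [2, 1])])
    def test_degree(self, side, expected):
        assert degree(self.NET, side).tolist() == expected

    def test_degree_identity_case(self):
        one = BipartiteNetwork(["A"], ["p"], np.array([[1]]))
        assert degree(one, "rows").tolist() == [1]
        assert degree(one, "cols").tolist() == [1]

    @pytest.mark.parametrize("side,expected", [("rows", [1.0, 0.5]), ("cols", [1.0, 0.5])])
    def test_normalized_degree(self, side, expected):
        assert normalized_degree(self.NET, side).tolist() == expected

    def test_full_matrix_saturates(self):
        net = BipartiteNetwork(["a", "b", "c"], list("wxyz"), np.ones((3, 4), dtype=int))
        assert normalized_degree(net, "rows").tolist() == [1.0] * 3

    def test_zero_degree_column_flagged(self, caplog):
        net = BipartiteNetwork(["A", "B"], ["p1", "p2"], np.array([[1, 0], [1, 0]]))
        with caplog.at_level("WARNING"):
            nd = normalized_degree(net, "cols")
        assert nd.tolist() == [1.0, 0.0]
        assert "zero degree" in caplog.text

    def test_permutation_invariance(self, rng):
        adj = (rng.random((7, 9)) < 0.5).astype(int)
        adj[0, 0] = 1
        net = BipartiteNetwork([f"r{i}" for i in range(7)],
                               [f"c{j}" for j in range(9)], adj)
        pr, pc = rng.permutation(7), rng.permutation(9)
        perm = BipartiteNetwork([net.row_labels[i] for i in pr],
                                [net.col_labels[j] for j in pc],
                                adj[np.ix_(pr, pc)])
        assert degree(net, "rows").sort_index().equals(degree(perm, "rows").sort_index())
        assert normalized_degree(net, "cols").sort_index().equals(
            normalized_degree(perm, "cols").sort_index())

    def test_normalized_degree_is_degree_over_partner_count(self, rng):
        adj = (rng.random((5, 11)) < 0.5).astype(int)
        adj[0, 0] = 1
        net = BipartiteNetwork([f"r{i}" for i in range(5)],
                               [f"c{j}" for j in range(11)], adj)
        np.testing.assert_array_equal(normalized_degree(net, "rows").to_numpy(),
                                      degree(net, "rows").to_numpy() / 11)


class TestPairedSample:
    def test_rejects_length_mismatch(self):
        with pytest.raises(DataError):
            PairedSample(["a", "b", "c"], [1, 2, 3], [1, 2])

    def test_rejects_constant_marginal(self):
        with pytest.raises(DataError):
            PairedSample(["a", "b", "c"], [1, 1, 1], [1, 2, 3])

    def test_rejects_non_finite(self):
        with pytest.raises(DataError):
            PairedSample(["a", "b", "c"], [1, 2, np.nan], [1, 2, 3])

    def test_swapped_exchanges_roles(self):
        s = PairedSample(["a", "b", "c"], [1, 2, 3], [4, 5, 6])
        sw = s.swapped()
        np.testing.assert_array_equal(sw.x, s.y)
        assert sw.x_name == s.y_name


def test_zero_degree_species_excluded_from_pairs(caplog):
    net = BipartiteNetwork(["A", "B", "C", "D"], ["p1", "p2"],
                           np.array([[1, 1], [1, 0], [0, 0], [1, 1]]))
    ds = CommunityDataset(network=net,
                          abundance={"rows": {"A": 3.0, "B": 1.0, "C": 9.0, "D": 2.0},
                                     "cols": {}})
    with caplog.at_level("INFO"):
        sample = paired_sample_from_community(ds, "rows", "degree")
    assert sample.ids == ["A", "B", "D"]
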