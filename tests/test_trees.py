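import numpy as np
import pytest

from sdtrace import trees as tr
from sdtrace.trees import (
    NodeTimes,
    apply_node_times,
    is_ultrametric,
    lca,
    parse_newick,
    time_from_root,
    validate_inputs,
    write_newick,
)
from sdtrace.spatial_sd import LeafLocations
from sdtrace.sequence_pmm import CharacterMatrix

from conftest import random_tree


class TestParseNewick:
    def test_basic_structure(self, cherry):
        assert cherry.n_nodes == 4  # r, u, A, B
        assert len(cherry.children[cherry.root]) == 1
        names = sorted(cherry.leaf_name.values())
        assert names == ["A", "B"]
        a = next(v for v, n in cherry.leaf_name.items() if n == "A")
        assert time_from_root(cherry, a) == pytest.approx(2.0)

    def test_bifurcating_root_rejected_in_strict_mode(self):
        with pytest.raises(tr.TreeStructureError, match="unifurcating"):
            parse_newick("(A:1,B:1);")

    def test_lenient_mode_wraps_bifurcating_root(self):
        t = parse_newick("(A:1,B:1)u;", strict=False)
        assert len(t.children[t.root]) == 1
        wrapper_child = t.children[t.root][0]
        assert t.branch_length[wrapper_child] == 0.0
        assert sorted(t.leaf_name.values()) == ["A", "B"]

    def test_malformed_string_raises_with_position(self):
        with pytest.raises(ValueError, match="column"):
            parse_newick("((A:1,B:1)u:1r;")

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("((A:1,A:1)u:1)r;")

    def test_multifurcation_rejected(self):
        with pytest.raises(tr.TreeStructureError):
            parse_newick("((A:1,B:1,C:1)u:1)r;")


class TestWriteNewick:
    def test_round_trip_identity(self, cherry):
        text = write_newick(cherry)
        again = parse_newick(text)
        assert write_newick(again) == text
        # child order preserved: A listed before B
        assert text.index("A") < text.index("B")

    def test_single_leaf(self):
        t = parse_newick("(A:2)r;")
        assert write_newick(t) == "(A:2.0)r;"

    def test_length_precision_survives(self):
        t = parse_newick("((A:0.123456789,B:1)u:1)r;")
        t2 = parse_newick(write_newick(t))
        a = next(v for v, n in t2.leaf_name.items() if n == "A")
        assert t2.branch_length[a] == pytest.approx(0.123456789, abs=1e-12)

    def test_topology_only_requires_flag(self, cherry):
        cherry.branch_length[cherry.children[cherry.root][0]] = None
        with pytest.raises(ValueError, match="topology_only"):
            write_newick(cherry)
        assert "(" in write_newick(cherry, topology_only=True)

    def test_random_trees_round_trip(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            t, _ = random_tree(rng)
            assert write_newick(parse_newick(write_newick(t))) \
                == write_newick(t)


class TestQueries:
    def test_lca_cases(self, cherry):
        a = next(v for v, n in cherry.leaf_name.items() if n == "A")
        b = next(v for v, n in cherry.leaf_name.items() if n == "B")
        u = cherry.parent[a]
        assert lca(cherry, a, b) == u
        assert lca(cherry, a, a) == a
        assert lca(cherry, a, u) == u
        with pytest.raises(KeyError):
            lca(cherry, a, 999)

    def test_time_from_root(self, cherry):
        a = next(v for v, n in cherry.leaf_name.items() if n == "A")
        u = cherry.parent[a]
        assert time_from_root(cherry, a) == pytest.approx(2.0)
        assert time_from_root(cherry, u) == pytest.approx(1.0)
        assert time_from_root(cherry, cherry.root) == 0.0

    def test_time_additivity_and_lca_depth_bound(self):
        rng = np.random.default_rng(7)
        t, _ = random_tree(rng)
        for v in t.preorder():
            if v != t.root:
                assert time_from_root(t, v) == pytest.approx(
                    time_from_root(t, t.parent[v]) + t.branch_length[v])
        leaves = t.leaves()
        for v in leaves[:3]:
            for w in leaves[-3:]:
                assert time_from_root(t, lca(t, v, w)) <= min(
                    time_from_root(t, v), time_from_root(t, w)) + 1e-12


class TestUltrametric:
    def test_exact(self, cherry):
        ok, dev = is_ultrametric(cherry, 2.0)
        assert ok and dev == pytest.approx(0.0)

    def test_wrong_tau(self, cherry):
        ok, dev = is_ultrametric(cherry, 3.0)
        assert not ok
        assert dev == pytest.approx(1.0)

    def test_uneven_leaves(self):
        t = parse_newick("((A:1,B:1.5)u:1)r;")
        ok, _ = is_ultrametric(t, 2.0)
        assert not ok


class TestApplyNodeTimes:
    def test_sets_branch_lengths(self, cherry):
        a = next(v for v, n in cherry.leaf_name.items() if n == "A")
        b = next(v for v, n in cherry.leaf_name.items() if n == "B")
        u = cherry.parent[a]
        nt = NodeTimes(time={cherry.root: 0.0, u: 1.0, a: 2.0, b: 2.0},
                       tau_end=2.0)
        out = apply_node_times(cherry, nt)
        assert out.branch_length[u] == pytest.approx(1.0)
        assert out.branch_length[a] == pytest.approx(1.0)
        ok, dev = is_ultrametric(out, 2.0, tol=0.0)
        assert ok and dev == 0.0

    def test_ordering_violation_names_edge(self, cherry):
        a = next(v for v, n in cherry.leaf_name.items() if n == "A")
        b = next(v for v, n in cherry.leaf_name.items() if n == "B")
        u = cherry.parent[a]
        nt = NodeTimes(time={cherry.root: 0.0, u: 2.5, a: 2.0, b: 2.0},
                       tau_end=2.0)
        with pytest.raises(ValueError, match="ordering"):
            apply_node_times(cherry, nt)


class TestValidateInputs:
    def _inputs(self, names):
        loc = LeafLocations(names=list(names),
                            x=np.zeros(len(names)), y=np.zeros(len(names)))
        mat = CharacterMatrix(cells=list(names),
                              data=np.zeros((len(names), 2), dtype=int))
        return mat, loc

    def test_matching_names_ok(self, cherry):
        mat, loc = self._inputs(["A", "B"])
        _, diag = validate_inputs(cherry, mat, loc)
        assert diag.ok() and not diag.pruned

    def test_missing_name_reported(self, cherry):
        mat, loc = self._inputs(["A"])
        with pytest.raises(ValueError, match="'B'"):
            validate_inputs(cherry, mat, loc)

    def test_prune_to_intersection(self, five_leaf):
        names = ["A", "B", "C", "D"]  # E missing from data
        mat, loc = self._inputs(names)
        pruned, diag = validate_inputs(five_leaf, mat, loc, prune=True)
        assert diag.pruned
        assert sorted(pruned.leaf_name.values()) == names
        pruned.validate()
        # total depth preserved for surviving leaves
        for v in pruned.leaves():
            assert time_from_root(pruned, v) == pytest.approx(8.0)

    def test_empty_intersection_fatal(self, cherry):
        mat, loc = self._inputs(["X", "Y"])
        with pytest.raises(ValueError, match="no cell name"):
            validate_inputs(cherry, mat, loc, prune=True)


class TestTabularIO:
    def test_locations_round_trip(self, tmp_path):
        loc = LeafLocations(names=["A", "B"], x=[0.25, -1.5], y=[3.0, 0.125])
        p = tmp_path / "loc.csv"
        tr.write_locations(loc, p)
        back = tr.read_locations(p)
        assert back.names == ["A", "B"]
        np.testing.assert_allclose(back.x, loc.x)
        np.testing.assert_allclose(back.y, loc.y)

    def test_matrix_round_trip_with_missing(self, tmp_path):
        mat = CharacterMatrix(
            cells=["A", "B"],
            data=np.array([[0, 2, tr.MISSING], [1, tr.MISSING, 2]]),
        )
        p = tmp_path / "mat.csv"
        tr.write_character_matrix(mat, p)
        back = tr.read_character_matrix(p)
        np.testing.assert_array_equal(back.data, mat.data)
        assert [ab.n_states for ab in back.alphabets] == [1, 2, 2]

    def test_invalid_state_raises(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cell,site0\nA,zebra\n")
        with pytest.raises(ValueError, match="zebra"):
            tr.read_character_matrix(p)
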