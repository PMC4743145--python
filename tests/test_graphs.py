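"""Subset partition, complete/reduced graphs, R-group trees, selectivity."""

import math
import random
from itertools import combinations

import pytest

from analogsar.graphs import (
    RGroupTree,
    SiteCombination,
    SubsetPartition,
    assign_stereo_indices,
    build_complete_graph,
    build_reduced_graph,
    build_rgroup_tree,
    build_selectivity_views,
    node_statistics,
    partition_series,
    reduce_graph,
)
from analogsar.mcs import RGroupAssignment
from analogsar.series import AnalogSeries


def _assignment(cid, groups, n_sites, sig=(), constitution=None):
    full = {s: groups.get(s, "H") for s in range(1, n_sites + 1)}
    key = constitution or "|".join(f"{s}:{g}" for s, g in sorted(full.items()))
    return RGroupAssignment(cid, full, tuple(sig), key)


def _series(cids):
    return AnalogSeries(series_id="S1", scaffold=None, members=list(cids))


class TestSiteCombination:
    def test_label_round_trip(self):
        for sites in [(), (1,), (1, 3, 4, 5), (2, 10), (9, 10, 11)]:
            c = SiteCombination.from_sites(sites)
            assert SiteCombination.from_label(c.label) == c

    def test_dot_separation_above_nine(self):
        assert SiteCombination.from_sites({2, 10}).label == "2.10"
        assert SiteCombination.from_sites({1, 3}).label == "13"
        assert SiteCombination.from_sites(()).label == "0"


class TestPartitionSeries:
    def test_exact_non_h_site_sets(self):
        asg = {
            "c1": _assignment("c1", {1: "*C"}, 2),
            "c2": _assignment("c2", {1: "*CC"}, 2),
            "c3": _assignment("c3", {1: "*C", 2: "*O"}, 2),
        }
        part = partition_series(_series(["c1", "c2", "c3"]), asg)
        labels = {c.label: cids for c, cids in part.subsets.items()}
        assert labels == {"1": ["c1", "c2"], "12": ["c3"]}

    def test_core_identical_compound_goes_to_root(self):
        asg = {"c1": _assignment("c1", {}, 3)}
        part = partition_series(_series(["c1"]), asg)
        assert [c.label for c in part.subsets] == ["0"]

    def test_conservation_on_random_assignments(self):
        rng = random.Random(5)
        asg = {}
        for i in range(25):
            sites = {s: "*C" for s in rng.sample(range(1, 6), rng.randint(0, 5))}
            asg[f"c{i}"] = _assignment(f"c{i}", sites, 5)
        part = partition_series(_series(asg), asg)
        assert part.n_compounds == 25
        all_cids = [cid for cids in part.subsets.values() for cid in cids]
        assert len(all_cids) == len(set(all_cids))

    def test_missing_assignment_is_integrity_error(self):
        with pytest.raises(ValueError, match="no R-group assignment"):
            partition_series(_series(["c1"]), {})


class TestNodeStatistics:
    @pytest.mark.parametrize("values,expected", [
        ([5.0, 7.0], (2, 6.0, 2.0)),
        ([8.2], (1, 8.2, 0.0)),
        ([6.0, 6.0, 6.0], (3, 6.0, 0.0)),
    ])
    def test_count_mean_range(self, values, expected):
        pots = {f"c{i}": {"pKi": v} for i, v in enumerate(values)}
        assert node_statistics(list(pots), pots, "pKi") == expected

    def test_empty_node_is_undefined(self):
        assert node_statistics([], {}, "pKi") == (0, None, None)


def _graph_for(labels_to_cids, n_sites, potency=6.0):
    subsets = {SiteCombination.from_label(l): cids for l, cids in labels_to_cids.items()}
    part = SubsetPartition("S1", subsets)
    pots = {cid: {"pKi": potency + 0.5 * i}
            for i, cid in enumerate(c for cids in labels_to_cids.values() for c in cids)}
    return build_complete_graph(part, n_sites, pots, "pKi"), part, pots


class TestCompleteGraph:
    def test_five_sites_layer_structure(self):
        g, _, _ = _graph_for({"1": ["a"]}, 5)
        assert g.n_nodes == 32
        layer_sizes = [sum(1 for _, d in g.g.nodes(data=True) if d["layer"] == k)
                       for k in range(6)]
        assert layer_sizes == [1, 5, 10, 10, 5, 1]
        # edge count equals the enumeration over adjacent subset pairs
        assert g.n_edges == sum(k * math.comb(5, k) for k in range(6)) == 80

    def test_one_site_graph(self):
        g, _, _ = _graph_for({"1": ["a"]}, 1)
        assert (g.n_nodes, g.n_edges) == (2, 1)

    def test_unoccupied_root_is_empty(self):
        g, _, _ = _graph_for({"1": ["a"]}, 2)
        assert g.node("0")["empty"] and g.node("0")["count"] == 0
        assert not g.node("1")["empty"]

    def test_every_edge_crosses_one_layer(self):
        g, _, _ = _graph_for({"12": ["a", "b"]}, 4)
        for u, v in g.g.edges:
            assert g.node(v)["layer"] == g.node(u)["layer"] + 1
            assert set(g.node(u)["sites"]) < set(g.node(v)["sites"])

    def test_ceiling_refusal(self):
        with pytest.raises(ValueError, match="ceiling"):
            _graph_for({"1": ["a"]}, 13)


class TestReduceGraph:
    def test_two_occupied_nodes_one_edge(self):
        g, _, _ = _graph_for({"1": ["a", "b"], "12": ["c"]}, 2)
        r = reduce_graph(g)
        assert set(r.g.nodes) == {"1", "12"}
        assert list(r.g.edges) == [("1", "12")]

    def test_no_transitive_rewiring_across_removed_nodes(self):
        # "1" and "123" occupied, "12"/"13" empty: induced subgraph keeps
        # the two survivors isolated
        g, _, _ = _graph_for({"1": ["a"], "123": ["b"]}, 3)
        r = reduce_graph(g)
        assert set(r.g.nodes) == {"1", "123"}
        assert r.n_edges == 0

    def test_reduction_idempotent_and_noop_without_empties(self):
        occupied = {"".join(map(str, c)) if c else "0": [f"x{i}"]
                    for i, c in enumerate(
                        sum([list(combinations(range(1, 4), k)) for k in range(4)], []))}
        g, _, _ = _graph_for(occupied, 3)
        r = reduce_graph(g)
        assert set(r.g.nodes) == set(g.g.nodes) and r.n_edges == g.n_edges
        rr = reduce_graph(r)
        assert set(rr.g.nodes) == set(r.g.nodes) and rr.n_edges == r.n_edges

    def test_direct_reduced_equals_reduce_of_complete(self):
        g, part, pots = _graph_for({"1": ["a"], "13": ["b", "c"], "123": ["d"]}, 3)
        direct = build_reduced_graph(part, 3, pots, "pKi")
        via_complete = reduce_graph(g)
        assert set(direct.g.nodes) == set(via_complete.g.nodes)
        assert set(direct.g.edges) == set(via_complete.g.edges)


class TestRGroupTree:
    def test_layer_order_by_unique_rgroup_count(self):
        # site 1 conserved (1 unique group), site 2 varied (3 groups)
        asg = {
            "c1": _assignment("c1", {1: "*C", 2: "*O"}, 2),
            "c2": _assignment("c2", {1: "*C", 2: "*Cl"}, 2),
            "c3": _assignment("c3", {1: "*C", 2: "*Br"}, 2),
        }
        pots = {c: {"pKi": 6.0} for c in asg}
        tree = build_rgroup_tree(SiteCombination.from_label("12"), list(asg), asg, pots, "pKi")
        assert tree.layer_order == [1, 2]
        groups = [n for n, d in tree.g.nodes(data=True) if d.get("kind") == "group"]
        leaves = [n for n, d in tree.g.nodes(data=True) if d.get("kind") == "leaf"]
        assert len(groups) == 1 and len(leaves) == 3

    def test_single_site_subset_leaf_per_constitution(self):
        asg = {
            "c1": _assignment("c1", {1: "*C"}, 1),
            "c2": _assignment("c2", {1: "*O"}, 1),
        }
        pots = {c: {"pKi": 6.0} for c in asg}
        tree = build_rgroup_tree(SiteCombination.from_label("1"), list(asg), asg, pots, "pKi")
        assert set(tree.g.successors("root")) == {"leaf:c1", "leaf:c2"}

    def test_identical_constitution_yields_stereo_leaves(self):
        asg = {
            "c1": _assignment("c1", {1: "*C(O)C"}, 1, sig=("R",), constitution="k"),
            "c2": _assignment("c2", {1: "*C(O)C"}, 1, sig=("S",), constitution="k"),
        }
        pots = {c: {"pKi": 6.0} for c in asg}
        tree = build_rgroup_tree(SiteCombination.from_label("1"), list(asg), asg, pots, "pKi")
        kids = list(tree.g.successors("root"))
        assert len(kids) == 1 and tree.g.nodes[kids[0]]["kind"] == "group"
        assert sorted(tree.g.successors(kids[0])) == ["leaf:c1", "leaf:c2"]

    def test_leaf_count_equals_subset_size(self, default_analysis):
        for label, tree in default_analysis.trees.items():
            combo = SiteCombination.from_label(label)
            assert len(tree.leaves()) == len(default_analysis.partition.subsets[combo])

    def test_intermediate_counts_sum_children(self, default_analysis):
        for tree in default_analysis.trees.values():
            for n, d in tree.g.nodes(data=True):
                kids = list(tree.g.successors(n))
                if kids:
                    assert d["count"] == sum(tree.g.nodes[k]["count"] for k in kids)


class TestStereoIndices:
    def _tree(self, classes):
        """classes: list of (constitution, n_members)."""
        asg, pots = {}, {}
        i = 0
        for const, n in classes:
            for j in range(n):
                cid = f"c{i}"
                asg[cid] = _assignment(cid, {1: f"*{const}"}, 1,
                                       sig=(f"{j}",), constitution=const)
                pots[cid] = {"pKi": 6.0}
                i += 1
        tree = build_rgroup_tree(SiteCombination.from_label("1"), list(asg), asg, pots, "pKi")
        return assign_stereo_indices(tree)

    def test_three_stereoisomers_share_index_one(self):
        tree = self._tree([("A", 3)])
        assert sorted(tree.stereo_indices.values()) == [1, 1, 1]

    def test_two_separate_pairs_get_incremental_indices(self):
        tree = self._tree([("A", 2), ("B", 2)])
        by_idx = {}
        for cid, idx in tree.stereo_indices.items():
            by_idx.setdefault(idx, []).append(cid)
        assert sorted(by_idx) == [1, 2]
        assert all(len(v) == 2 for v in by_idx.values())

    def test_no_stereo_mates_no_indices(self):
        tree = self._tree([("A", 1), ("B", 1)])
        assert tree.stereo_indices == {}

    def test_every_index_class_has_at_least_two_members(self, stereo_analysis):
        for tree in stereo_analysis.trees.values():
            counts = {}
            for idx in tree.stereo_indices.values():
                counts[idx] = counts.get(idx, 0) + 1
            assert all(c >= 2 for c in counts.values())


class TestSelectivityViews:
    def _inputs(self, pot_a, pot_b):
        asg = {f"c{i}": _assignment(f"c{i}", {1: f"*C{'C' * i}"}, 2)
               for i in range(len(pot_a))}
        part = partition_series(_series(list(asg)), asg)
        pots = {f"c{i}": {"A": pot_a[i], "B": pot_b[i]} for i in range(len(pot_a))}
        series = _series(list(asg))
        return series, part, pots

    def test_equal_potencies_give_identical_graphs(self):
        series, part, pots = self._inputs([6.0, 7.0], [6.0, 7.0])
        ga, gb = build_selectivity_views(series, part, pots, "A", "B")
        assert set(ga.g.nodes) == set(gb.g.nodes)
        for n in ga.g.nodes:
            assert ga.node(n)["mean_potency"] == gb.node(n)["mean_potency"]
            assert ga.node(n)["delta_mean"] == 0

    def test_singleton_node_difference(self):
        series, part, pots = self._inputs([8.0], [5.0])
        ga, _ = build_selectivity_views(series, part, pots, "A", "B")
        assert ga.node("1")["delta_mean"] == pytest.approx(3.0)

    def test_counts_identical_across_targets(self):
        series, part, pots = self._inputs([6.0, 7.5, 8.0], [5.0, 5.5, 9.0])
        ga, gb = build_selectivity_views(series, part, pots, "A", "B")
        assert sum(d["count"] for _, d in ga.g.nodes(data=True)) == \
               sum(d["count"] for _, d in gb.g.nodes(data=True)) == 3

    def test_missing_target_is_an_error(self):
        series, part, pots = self._inputs([6.0], [6.0])
        del pots["c0"]["B"]
        with pytest.raises(ValueError, match="lacks potency"):
            build_selectivity_views(series, part, pots, "A", "B")

    def test_same_target_twice_is_an_error(self):
        series, part, pots = self._inputs([6.0], [6.0])
        with pytest.raises(ValueError, match="distinct"):
            build_selectivity_views(series, part, pots, "A", "A")
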