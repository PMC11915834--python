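"""Midpoint rooting, ultrametricization, clade extraction and depth."""

import math

import dendropy
import numpy as np
import pytest

from vespscope.clade_depth import (
    DepthRecord,
    UntaggedTipError,
    clade_depth,
    depth_report,
    domains_from_labels,
    find_viral_clades,
    flag_long_branches,
    midpoint_root,
    tree_height,
    ultrametricize,
)
from vespscope.simulate import gen_ultrametric_tree, plant_viral_clade

from conftest import random_resolved_tree, tree_to_graph


def newick(s: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=s, schema="newick")
    return t


def rooted(s: str) -> dendropy.Tree:
    t = newick(s)
    t.is_rooted = True
    return t


def root_tip_distances(tree):
    return {lf.taxon.label: lf.distance_from_root() for lf in tree.leaf_node_iter()}


def oracle_minmax_height(tree) -> float:
    """Brute-force optimal max root-to-tip distance over all edge points.

    For every edge, placing the root at offset x changes tip distances
    piecewise-linearly; the optimum on an edge is at the crossing of the
    two farthest-tip lines from its endpoints.  Equivalent to half the
    tree diameter.
    """
    import networkx as nx

    g, label = tree_to_graph(tree)
    tips = [n for n in label]
    best = math.inf
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for u, v, data in list(g.edges(data=True)):
        w = data["weight"]
        g.remove_edge(u, v)
        side_u = nx.node_connected_component(g, u)
        g.add_edge(u, v, weight=w)
        # farthest tip on each side of the edge (0 if a side has no tip)
        fu = max((lengths[u][t] for t in tips if t in side_u), default=0.0)
        fv = max((lengths[v][t] for t in tips if t not in side_u), default=0.0)
        # root at offset x from u: max(fu + x, fv + (w - x)) minimised
        x = max(0.0, min(w, (fv - fu + w) / 2.0))
        best = min(best, max(fu + x, fv + w - x))
    return best


class TestMidpointRoot:
    def test_symmetric_two_tip_tree(self):
        r = midpoint_root(newick("(A:3,B:3);"))
        assert root_tip_distances(r) == pytest.approx({"A": 3.0, "B": 3.0})

    def test_worked_example_root_on_longest_branch(self):
        # diameter path B..C (and A..C) is 8; root 4 from C on C's branch
        r = midpoint_root(newick("(A:1,(B:2,C:6):1);"))
        d = root_tip_distances(r)
        assert d["C"] == pytest.approx(4.0)
        assert d["B"] == pytest.approx(4.0)
        assert d["A"] == pytest.approx(4.0)  # 2 + 1 + 1

    def test_idempotent(self, rng):
        tree = random_resolved_tree(9, rng)
        once = midpoint_root(tree)
        twice = midpoint_root(once)
        assert root_tip_distances(twice) == pytest.approx(
            root_tip_distances(once)
        )

    def test_preserves_pairwise_tip_distances(self, rng):
        tree = random_resolved_tree(8, rng)
        pdm_before = tree.phylogenetic_distance_matrix()
        taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
        before = {
            (a.label, b.label): pdm_before.distance(a, b)
            for a in taxa for b in taxa if a.label < b.label
        }
        r = midpoint_root(tree)
        pdm_after = r.phylogenetic_distance_matrix()
        taxa_after = {t.label: t for t in r.taxon_namespace}
        for (la, lb), dist in before.items():
            assert pdm_after.distance(
                taxa_after[la], taxa_after[lb]
            ) == pytest.approx(dist)

    def test_equals_brute_force_minmax_search(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            tree = random_resolved_tree(n, rng)
            optimum = oracle_minmax_height(tree)
            r = midpoint_root(tree)
            assert tree_height(r) == pytest.approx(optimum, rel=1e-9)

    def test_all_zero_lengths_rejected(self):
        with pytest.raises(ValueError, match="midpoint undefined"):
            midpoint_root(newick("(A:0,(B:0,C:0):0);"))


class TestUltrametricize:
    def test_already_ultrametric_unchanged(self):
        tree = gen_ultrametric_tree(8, seed=3)
        before = root_tip_distances(tree)
        after = root_tip_distances(ultrametricize(tree))
        assert after == pytest.approx(before, abs=1e-12)

    def test_mean_path_length_worked_example(self):
        u = ultrametricize(rooted("((A:1,B:3):2,C:5);"))
        # internal node age (1+3)/2 = 2; root age (3+5+5)/3 = 13/3
        assert tree_height(u) == pytest.approx(13 / 3)
        internal = [
            n for n in u.preorder_node_iter()
            if n.parent_node is not None and not n.is_leaf()
        ]
        assert internal[0].edge.length == pytest.approx(13 / 3 - 2)

    def test_equalises_root_tip_distances(self, rng):
        tree = random_resolved_tree(12, rng)
        tree.is_rooted = True
        u = ultrametricize(tree)
        d = list(root_tip_distances(u).values())
        assert max(d) - min(d) <= 1e-9 * max(d)
        for edge in u.preorder_edge_iter():
            if edge.tail_node is not None:
                assert edge.length >= 0.0

    def test_topology_unchanged(self, rng):
        from vespscope.tree_certainty import extract_bipartitions

        tree = random_resolved_tree(10, rng)
        tree.is_rooted = True
        before = {
            frozenset({b.side_a, b.side_b}) for b in extract_bipartitions(tree)
        }
        after = {
            frozenset({b.side_a, b.side_b})
            for b in extract_bipartitions(ultrametricize(tree))
        }
        assert before == after

    def test_unrooted_input_rejected(self):
        tree = newick("((A:1,B:3):2,C:5);")
        tree.is_rooted = False
        with pytest.raises(ValueError, match="rooted"):
            ultrametricize(tree)


class TestViralClades:
    def domains(self, tree, viral):
        return {
            lf.taxon.label: ("virus" if lf.taxon.label in viral else "eukaryote")
            for lf in tree.leaf_node_iter()
        }

    def test_no_viral_tips_no_clades(self):
        t = rooted("((a:1,b:1):1,(c:1,d:1):1);")
        assert find_viral_clades(t, self.domains(t, set())) == []

    def test_all_viral_single_clade_is_whole_tree(self):
        t = rooted("((a:1,b:1):1,(c:1,d:1):1);")
        clades = find_viral_clades(t, self.domains(t, {"a", "b", "c", "d"}))
        assert len(clades) == 1
        assert clades[0].tip_labels == frozenset("abcd")
        assert clades[0].attachment is None

    def test_mixed_tree_maximal_clades(self):
        t = rooted("(((v1:1,v2:1):1,e1:2):1,(v3:2,e2:2):1);")
        domains = self.domains(t, {"v1", "v2", "v3"})
        clades = find_viral_clades(t, domains)
        assert {c.tip_labels for c in clades} == {
            frozenset({"v1", "v2"}), frozenset({"v3"})
        }

    def test_clades_partition_viral_tips(self, rng):
        for _ in range(20):
            tree = random_resolved_tree(12, rng)
            tree.is_rooted = True
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            viral = {l for l in labels if rng.random() < 0.4}
            clades = find_viral_clades(tree, self.domains(tree, viral))
            union = set()
            for c in clades:
                assert not (union & c.tip_labels)  # disjoint
                union |= c.tip_labels
                # maximality: attachment has a non-viral descendant tip
                if c.attachment is not None:
                    tips_above = {
                        lf.taxon.label for lf in c.attachment.leaf_iter()
                    }
                    assert tips_above - viral
            assert union == viral

    def test_untagged_tip_named_in_error(self):
        t = rooted("((a:1,b:1):1,c:2);")
        with pytest.raises(UntaggedTipError, match="'c'"):
            find_viral_clades(t, {"a": "virus", "b": "eukaryote"})

    def test_min_tips_filters_singletons(self):
        t = rooted("(((v1:1,v2:1):1,e1:2):1,(v3:2,e2:2):1);")
        clades = find_viral_clades(t, self.domains(t, {"v1", "v2", "v3"}), min_tips=2)
        assert {c.tip_labels for c in clades} == {frozenset({"v1", "v2"})}


class TestCladeDepth:
    def test_child_of_root_has_depth_zero(self):
        t = rooted("((v1:1,v2:1):2,((e1:1,e2:1):1,e3:2):1);")
        domains = {"v1": "virus", "v2": "virus", "e1": "eukaryote",
                   "e2": "eukaryote", "e3": "eukaryote"}
        (clade,) = find_viral_clades(t, domains)
        assert clade_depth(t, clade) == 0.0

    def test_constructed_forty_percent_depth(self):
        # height 10; viral stem diverges at a node 4 below the root
        t = rooted("((v1:6,e1:6):4,e2:10);")
        domains = {"v1": "virus", "e1": "eukaryote", "e2": "eukaryote"}
        (clade,) = find_viral_clades(t, domains)
        assert clade_depth(t, clade) == pytest.approx(0.4)

    def test_scale_invariance(self, rng):
        tree = gen_ultrametric_tree(15, seed=8)
        planted, domains, _ = plant_viral_clade(tree, 0.63, 3, seed=9)
        (clade,) = find_viral_clades(planted, domains)
        base = clade_depth(planted, clade)
        for edge in planted.preorder_edge_iter():
            if edge.tail_node is not None:
                edge.length *= 37.5
        (clade2,) = find_viral_clades(planted, domains)
        assert abs(clade_depth(planted, clade2) - base) <= 1e-12

    def test_depths_bounded_in_unit_interval(self, rng):
        for seed in range(15):
            tree = gen_ultrametric_tree(12, seed=seed)
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            domains = {
                l: ("virus" if rng.random() < 0.4 else "eukaryote") for l in labels
            }
            for clade in find_viral_clades(tree, domains):
                assert 0.0 <= clade_depth(tree, clade) <= 1.0

    def test_non_ultrametric_tree_rejected(self):
        t = rooted("((v1:1,e1:9):1,e2:2);")
        domains = {"v1": "virus", "e1": "eukaryote", "e2": "eukaryote"}
        (clade,) = find_viral_clades(t, domains)
        with pytest.raises(ValueError, match="ultrametric"):
            clade_depth(t, clade)


class TestLongBranchesAndReport:
    def test_uniform_lengths_flag_nothing(self):
        t = rooted("((a:1,b:1):1,(c:1,d:1):1);")
        assert flag_long_branches(t) == []

    def test_extreme_branch_flagged(self):
        t = rooted("((a:1,b:50):1,(c:1,d:1):1);")
        assert flag_long_branches(t, k=10) == ["b"]

    def test_infinite_factor_disables(self):
        t = rooted("((a:1,b:50):1,(c:1,d:1):1);")
        assert flag_long_branches(t, k=math.inf) == []

    def test_report_counts_and_median(self):
        records = [
            DepthRecord("t1", "t1.c1", 2, 0.7, "trafficking"),
            DepthRecord("t2", "t2.c1", 1, 0.2, "cytoskeleton"),
            DepthRecord("t2", "t2.c2", 3, 0.8, "cytoskeleton"),
        ]
        report = depth_report(records).set_index("category")
        assert report.loc["trafficking", "n_depth_gt_0.5"] == 1
        assert report.loc["cytoskeleton", "median_depth"] == pytest.approx(0.5)

    def test_depth_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            DepthRecord("t", "c", 1, 1.2)

    def test_label_prefix_domains(self):
        out = domains_from_labels(["virus_x", "euk_y", "asg_z", "weird"])
        assert out == {
            "virus_x": "virus", "euk_y": "eukaryote", "asg_z": "asgard"
        }


class TestPlantedDepthRecovery:
    def test_full_pipeline_recovers_planted_depth(self, rng):
        """Midpoint root -> ultrametricize -> extract -> score, 40 trees."""
        ok = 0
        for i in range(40):
            d = float(rng.uniform(0.05, 0.95))
            m = int(rng.integers(1, 5))
            host = gen_ultrametric_tree(20, seed=1000 + i, label_prefix="euk_")
            try:
                planted, domains, truth = plant_viral_clade(
                    host, d, m, seed=2000 + i
                )
            except ValueError:
                ok += 1  # no spanning edge at this depth; nothing to test
                continue
            ultra = ultrametricize(midpoint_root(planted))
            clades = find_viral_clades(ultra, domains)
            est = [clade_depth(ultra, c) for c in clades
                   if c.tip_labels == frozenset(truth["clade_tips"])]
            assert len(est) == 1
            ok += abs(est[0] - d) <= 0.05
        assert ok >= 38
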