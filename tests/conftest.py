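"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools

import dendropy
import networkx as nx
import numpy as np
import pytest

from vespscope.occurrence import GROUPS, GenomeRecord


def make_metadata(counts: dict[str, int]) -> dict[str, GenomeRecord]:
    """Metadata table with counts[group] genomes per group."""
    orders = ("Imitervirales", "Asfuvirales")
    meta = {}
    for group, n in counts.items():
        for i in range(n):
            gid = f"{group}_{i:03d}"
            order = orders[i % 2] if group == "virus" else None
            meta[gid] = GenomeRecord(gid, group, order)
    return meta


def random_resolved_tree(
    n_tips: int, rng: np.random.Generator, max_len: float = 1.0
) -> dendropy.Tree:
    """Random binary tree with exponential branch lengths (test-side builder).

    Built by sequential random coalescence of subtrees, independent of the
    package's Yule generator.
    """
    tree = dendropy.Tree()
    tree.is_rooted = True
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node()
        node.taxon = tree.taxon_namespace.new_taxon(label=f"T{i+1}")
        node.edge.length = float(rng.exponential(max_len)) + 1e-3
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(max_len)) + 1e-3
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for node in nodes:
        tree.seed_node.add_child(node)
    return tree


def tree_to_graph(tree: dendropy.Tree) -> tuple[nx.Graph, dict]:
    """Undirected weighted graph view of a tree (for brute-force oracles)."""
    g = nx.Graph()
    label = {}
    for node in tree.preorder_node_iter():
        g.add_node(id(node))
        if node.is_leaf():
            label[id(node)] = node.taxon.label
        if node.parent_node is not None:
            g.add_edge(
                id(node.parent_node), id(node), weight=node.edge.length or 0.0
            )
    return g, label


def oracle_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits via graph edge removal (independent of traversal).

    Returns, for each internal edge, the frozenset-of-frozensets of the two
    tip-label sides.
    """
    g, label = tree_to_graph(tree)
    tips = set(label.values())
    splits = set()
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(lbl for nid, lbl in label.items() if nid in comp)
        g.add_edge(u, v)
        if 2 <= len(side) <= len(tips) - 2:
            splits.add(frozenset({side, frozenset(tips - side)}))
    return splits


def oracle_conflicts(s1: frozenset, s2: frozenset) -> bool:
    """Split conflict by exhaustive intersection enumeration."""
    (a1, b1), (a2, b2) = tuple(s1), tuple(s2)
    return all(
        x & y for x, y in itertools.product((a1, b1), (a2, b2))
    )


def oracle_tree_certainty(ref: dendropy.Tree, reps: list[dendropy.Tree]):
    """Brute-force TC: count every split of every replicate, re-derive IC."""
    from collections import Counter

    counts: Counter = Counter()
    for rep in reps:
        for split in oracle_bipartitions(rep):
            counts[split] += 1
    ics = []
    for split in oracle_bipartitions(ref):
        f_ref = counts.get(split, 0)
        rivals = [
            n for other, n in counts.items() if oracle_conflicts(split, other)
        ]
        f_con = max(rivals, default=0)
        if f_ref == 0 and f_con == 0:
            ics.append(0.0)
            continue
        ps = [f / (f_ref + f_con) for f in (f_ref, f_con) if f > 0]
        ic = 1.0 + sum(p * np.log2(p) for p in ps)
        ics.append(-ic if f_con > f_ref else ic)
    n = len([l for l in ref.leaf_node_iter()])
    return sum(ics), sum(ics) / (n - 3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
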