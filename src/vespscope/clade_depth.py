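"""Midpoint rooting, ultrametricization, and viral-clade depth scoring.

Gene trees mixing viral and eukaryotic homologs usually lack an outgroup, so
the root is estimated by midpoint rooting (halfway along the longest
tip-to-tip path).  The rooted tree is then made ultrametric by mean-path-
length smoothing, every maximal monophyletic clade of virus-tagged tips is
extracted, and each clade receives a normalized depth in [0, 1]: the distance
from the root down to the clade's *attachment* node (where its stem edge
diverges from the non-viral sister), divided by tree height.  Depth 0 means
the viral lineage is the most basal branch in the tree; depth 1 means the
divergence sits at tip level.  Shallow depths therefore read as recent gene
acquisitions and deep clades as ancient transfer events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

DOMAINS = ("virus", "eukaryote", "archaea", "asgard", "bacteria", "other")

#: Tip-label prefixes (token before the first underscore, lowercased) mapped
#: to domains; an explicit tip-metadata table takes precedence over these.
DEFAULT_PREFIX_MAP = {
    "virus": "virus", "vir": "virus", "v": "virus", "ncldv": "virus",
    "euk": "eukaryote", "e": "eukaryote", "eukaryote": "eukaryote",
    "arch": "archaea", "a": "archaea", "archaea": "archaea",
    "bacteria": "bacteria",
    "asgard": "asgard", "asg": "asgard",
    "bact": "bacteria", "b": "bacteria",
}


class UntaggedTipError(KeyError):
    """A tip without a domain assignment."""


def _require_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and edge.length is None:
            raise ValueError("tree has edges without branch lengths")


def _tip_distances_from(node: dendropy.Node) -> dict[str, float]:
    """Path distance from ``node`` to every tip label (Dijkstra-free: tree)."""
    dist: dict[dendropy.Node, float] = {node: 0.0}
    stack = [node]
    seen = {node}
    out: dict[str, float] = {}
    while stack:
        cur = stack.pop()
        neighbours = list(cur.child_nodes())
        if cur.parent_node is not None:
            neighbours.append(cur.parent_node)
        for nxt in neighbours:
            if nxt in seen:
                continue
            edge = nxt.edge if nxt.parent_node is cur else cur.edge
            dist[nxt] = dist[cur] + (edge.length or 0.0)
            seen.add(nxt)
            stack.append(nxt)
        if cur.is_leaf():
            out[cur.taxon.label] = dist[cur]
    return out


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest tip-to-tip path.

    The input is not modified.  The two diameter endpoints are equidistant
    from the new root, and unrooted pairwise tip distances are preserved.
    Ties between equally long paths break by the lexicographically smallest
    (sorted) endpoint-label pair, so rooting is reproducible; re-rooting an
    already midpoint-rooted tree leaves the root position unchanged.

    Raises
    ------
    ValueError
        On fewer than two tips or an all-zero-length tree (midpoint
        undefined).
    """
    work = tree.clone(depth=1)
    _require_lengths(work)
    leaves = {lf.taxon.label: lf for lf in work.leaf_node_iter()}
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least two tips")
    # diameter pair, ties -> lexicographically smallest sorted label pair
    best: tuple[float, tuple[str, str]] | None = None
    dist_from: dict[str, dict[str, float]] = {}
    for a in sorted(leaves):
        dist_from[a] = _tip_distances_from(leaves[a])
        for b, d in dist_from[a].items():
            if b <= a:
                continue
            cand = (d, (a, b))
            if best is None or d > best[0] + 1e-15 or (
                abs(d - best[0]) <= 1e-15 and cand[1] < best[1]
            ):
                best = cand
    diameter, (tip_a, tip_b) = best
    if diameter <= 0.0:
        raise ValueError("all path lengths are zero; midpoint undefined")

    # walk the path tip_a -> tip_b, locating the half-way point
    path = _node_path(leaves[tip_a], leaves[tip_b])
    half = diameter / 2.0
    walked = 0.0
    work.is_rooted = True
    for cur, nxt in zip(path, path[1:]):
        edge = nxt.edge if nxt.parent_node is cur else cur.edge
        length = edge.length or 0.0
        if walked + length >= half - 1e-12:
            offset = half - walked  # distance from `cur` into this edge
            if offset <= 1e-12:
                work.reroot_at_node(cur, suppress_unifurcations=True)
            elif length - offset <= 1e-12:
                work.reroot_at_node(nxt, suppress_unifurcations=True)
            else:
                if edge.head_node is nxt:
                    # cur is the parent: tail side holds cur
                    work.reroot_at_edge(
                        edge, length1=offset, length2=length - offset
                    )
                else:
                    work.reroot_at_edge(
                        edge, length1=length - offset, length2=offset
                    )
            work.is_rooted = True
            return work
        walked += length
    raise AssertionError("midpoint not found on diameter path")


def _node_path(a: dendropy.Node, b: dendropy.Node) -> list[dendropy.Node]:
    """Node sequence along the unique tree path from a to b."""
    up_a = [a]
    while up_a[-1].parent_node is not None:
        up_a.append(up_a[-1].parent_node)
    ancestors = {id(n): i for i, n in enumerate(up_a)}
    up_b = [b]
    while id(up_b[-1]) not in ancestors:
        up_b.append(up_b[-1].parent_node)
    lca_i = ancestors[id(up_b[-1])]
    return up_a[: lca_i + 1] + list(reversed(up_b[:-1]))


def ultrametricize(tree: dendropy.Tree) -> dendropy.Tree:
    """Make a rooted tree ultrametric by mean-path-length smoothing.

    Bottom-up, each internal node's age is the mean path length to its
    descendant tips (the tip-count-weighted mean of child age + child branch
    length); tips have age 0.  A child age exceeding
    its parent's (possible on pathological length configurations) is clamped
    to the parent age, producing a zero-length branch.  Branch lengths are
    rewritten as age differences, so all root-to-tip distances are exactly
    equal and the topology is untouched.  Already-ultrametric trees are
    returned unchanged (up to float round-off).
    """
    if not tree.is_rooted:
        raise ValueError("ultrametricization requires a rooted tree")
    work = tree.clone(depth=1)
    _require_lengths(work)
    age: dict[dendropy.Node, float] = {}
    ntips: dict[dendropy.Node, int] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            age[node], ntips[node] = 0.0, 1
        else:
            kids = node.child_nodes()
            ntips[node] = sum(ntips[c] for c in kids)
            age[node] = (
                sum(ntips[c] * (age[c] + c.edge.length) for c in kids)
                / ntips[node]
            )
    for node in work.preorder_node_iter():
        if node.parent_node is not None and age[node] > age[node.parent_node]:
            age[node] = age[node.parent_node]
    for node in work.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = age[node.parent_node] - age[node]
    return work


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(
        lf.distance_from_root() for lf in tree.leaf_node_iter()
    )


@dataclass
class ViralClade:
    """A maximal monophyletic set of virus-tagged tips."""

    tip_labels: frozenset[str]
    mrca: dendropy.Node
    attachment: dendropy.Node | None  # parent of the stem edge; None at root

    @property
    def size(self) -> int:
        return len(self.tip_labels)


def find_viral_clades(
    tree: dendropy.Tree,
    tip_domains: Mapping[str, str],
    min_tips: int = 1,
) -> list[ViralClade]:
    """All maximal nodes whose descendant tips are exclusively viral.

    The returned clades are mutually disjoint and (with ``min_tips=1``)
    their tip sets partition the set of virus-tagged tips.  Every tip must
    have a domain tag.
    """
    viral: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_domains:
                raise UntaggedTipError(f"tip {label!r} has no domain tag")
            viral[node] = tip_domains[label] == "virus"
        else:
            viral[node] = all(viral[c] for c in node.child_nodes())
    clades: list[ViralClade] = []
    for node in tree.preorder_node_iter():
        if viral[node] and (node.parent_node is None or not viral[node.parent_node]):
            tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(tips) >= min_tips:
                clades.append(ViralClade(tips, node, node.parent_node))
    return clades


def clade_depth(
    tree: dendropy.Tree, clade: ViralClade, rtol: float = 1e-6
) -> float:
    """Normalized depth of a viral clade in a rooted ultrametric tree.

    Depth is the distance from the root to the clade's attachment node
    (where the viral stem diverges from its non-viral sister) divided by
    tree height: 0 at the root, 1 at tip level.  Scale-invariant by
    construction.

    Raises
    ------
    ValueError
        If the tree has zero height or is not ultrametric within ``rtol``
        relative tolerance.
    """
    heights = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
    height = max(heights)
    if height <= 0.0:
        raise ValueError("tree height is zero; depth undefined")
    if (height - min(heights)) > rtol * height:
        raise ValueError("tree is not ultrametric within tolerance")
    if clade.attachment is None:
        return 0.0
    return clade.attachment.distance_from_root() / height


def flag_long_branches(tree: dendropy.Tree, k: float = 10.0) -> list[str]:
    """Tips whose terminal branch exceeds k times the median terminal branch.

    Advisory only (candidate rogue taxa); nothing is removed.  ``k=inf``
    disables flagging.
    """
    if math.isinf(k):
        return []
    leaves = list(tree.leaf_node_iter())
    lengths = np.array([lf.edge.length or 0.0 for lf in leaves])
    med = float(np.median(lengths))
    return [
        lf.taxon.label for lf, ln in zip(leaves, lengths) if ln > k * med
    ]


@dataclass
class DepthRecord:
    """One viral clade's depth score in one gene tree."""

    tree_id: str
    clade_id: str
    n_tips: int
    depth: float
    category: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError(f"depth {self.depth} outside [0, 1]")


def records_frame(records: Sequence[DepthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tree_id": r.tree_id,
                "clade_id": r.clade_id,
                "n_tips": r.n_tips,
                "depth": r.depth,
                "category": r.category or "uncategorized",
            }
            for r in records
        ]
    )


def depth_report(records: Sequence[DepthRecord]) -> pd.DataFrame:
    """Per-category summary of clade depths.

    Counts of clades above/below the 0.5 depth mark (above reads as recent
    acquisition) plus min/median/max depth, one row per category.
    """
    if not records:
        raise ValueError("no depth records to summarise")
    frame = records_frame(records)
    rows = []
    for category, grp in frame.groupby("category", sort=True):
        depths = grp["depth"]
        rows.append(
            {
                "category": category,
                "n_clades": len(grp),
                "n_depth_gt_0.5": int((depths > 0.5).sum()),
                "n_depth_le_0.5": int((depths <= 0.5).sum()),
                "min_depth": float(depths.min()),
                "median_depth": float(depths.median()),
                "max_depth": float(depths.max()),
            }
        )
    return pd.DataFrame(rows)


def read_tip_metadata(
    path: str | Path,
) -> tuple[dict[str, str], dict[str, str]]:
    """Read a tip-metadata TSV (label, domain, optional category).

    Returns (domains, categories) keyed by tip label.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    domains, categories = {}, {}
    for row in frame.itertuples(index=False):
        if row.domain not in DOMAINS:
            raise ValueError(
                f"tip {row.label!r}: unknown domain {row.domain!r}"
            )
        domains[row.label] = row.domain
        cat = getattr(row, "category", "")
        if cat:
            categories[row.label] = cat
    return domains, categories


def domains_from_labels(
    labels: Sequence[str], prefix_map: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Infer tip domains from label prefixes (token before first '_')."""
    pmap = dict(DEFAULT_PREFIX_MAP if prefix_map is None else prefix_map)
    out = {}
    for label in labels:
        token = label.split("_", 1)[0].lower()
        if token in pmap:
            out[label] = pmap[token]
    return out
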