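"""Internode certainty (IC) and tree certainty (TC) from bootstrap replicates.

Every internal branch of an unrooted tree induces a bipartition (split) of
the tip set.  The internode certainty of a reference branch measures how
decisively the bootstrap replicate set favours that split over the single
most prevalent split conflicting with it: with bootstrap counts ``f_ref`` and
``f_conflict`` normalised to frequencies ``p``, ``IC = 1 + sum p*log2(p)``,
so a split with no observed conflict scores 1 and an even contest scores 0.
The sign is flipped when the conflicting split is the more frequent one.
Tree certainty is the sum of IC over the reference tree's internal branches;
the *relative* TC divides by the number of internal branches of a fully
resolved unrooted tree, ``n_tips - 3``, putting concordant trees at 1.  Trees
whose relative TC exceeds 0.5 pass the reliability screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import dendropy


class TipSetMismatchError(ValueError):
    """Reference and replicate trees disagree on the tip set."""


@dataclass(frozen=True)
class Bipartition:
    """An unordered split of a tip set into two non-trivial sides.

    ``side_a`` is the lexicographically smaller side, so equal splits compare
    and hash equal regardless of the order the sides were supplied in.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    @classmethod
    def of(cls, one: Iterable[str], other: Iterable[str]) -> "Bipartition":
        a, b = frozenset(one), frozenset(other)
        if a & b:
            raise ValueError("bipartition sides overlap")
        if len(a) < 2 or len(b) < 2:
            raise ValueError("bipartition sides must each hold >= 2 tips")
        if tuple(sorted(a)) > tuple(sorted(b)):
            a, b = b, a
        return cls(a, b)

    @property
    def tip_set(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(sorted(self.side_a))


def extract_bipartitions(tree: dendropy.Tree) -> set[Bipartition]:
    """Non-trivial bipartitions of a tree, viewed as unrooted.

    A fully resolved tree on n tips yields exactly n-3 splits; polytomies
    yield fewer.  The root's position contributes nothing (its two child
    edges induce the same split, which deduplicates).
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = [t for t, c in Counter(labels).items() if c > 1]
        raise ValueError(f"duplicate tip labels: {dupes}")
    all_tips = frozenset(labels)
    splits: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= len(all_tips) - 2:
            splits.add(Bipartition.of(side, all_tips - side))
    return splits


def are_compatible(b1: Bipartition, b2: Bipartition) -> bool:
    """Standard split compatibility: some pairwise side intersection is empty."""
    if b1.tip_set != b2.tip_set:
        raise TipSetMismatchError(
            "bipartitions are defined on different tip sets"
        )
    return (
        not (b1.side_a & b2.side_a)
        or not (b1.side_a & b2.side_b)
        or not (b1.side_b & b2.side_a)
        or not (b1.side_b & b2.side_b)
    )


def internode_certainty(f_ref: int, f_conflict: int) -> float:
    """IC of a branch from its bootstrap count and its strongest rival's.

    ``f_conflict`` is the count of the single most prevalent bipartition
    conflicting with the reference branch.  The magnitude is one minus the
    binary entropy of the two normalised frequencies; the value is negative
    when the rival split is the more frequent of the two.
    """
    if f_ref < 0 or f_conflict < 0:
        raise ValueError("bipartition counts must be non-negative")
    total = f_ref + f_conflict
    if total == 0:
        raise ValueError("IC undefined: branch unseen and unopposed")
    ic = 1.0
    for f in (f_ref, f_conflict):
        p = f / total
        if p > 0.0:
            ic += p * math.log2(p)
    return -ic if f_conflict > f_ref else ic


@dataclass
class BranchCertainty:
    """Per-branch IC record of a tree certainty report."""

    split_key: tuple[str, ...]
    f_ref: int
    f_conflict: int
    ic: float
    flagged: bool = False  # branch absent from all replicates, no conflict


@dataclass
class TreeCertaintyReport:
    """TC of one reference tree against its bootstrap replicate set."""

    per_branch: list[BranchCertainty]
    tc: float
    relative_tc: float
    n_internal: int
    n_replicates: int
    flagged_branches: list[tuple[str, ...]] = field(default_factory=list)

    def passes(self, threshold: float = 0.5) -> bool:
        """Reliability screen: relative TC strictly above ``threshold``."""
        return self.relative_tc > threshold

    def to_dict(self, threshold: float = 0.5) -> dict:
        return {
            "tc": self.tc,
            "relative_tc": self.relative_tc,
            "n_internal": self.n_internal,
            "n_replicates": self.n_replicates,
            f"pass_{threshold}": self.passes(threshold),
            "per_branch": [
                {
                    "split_key": list(b.split_key),
                    "f_ref": b.f_ref,
                    "f_conflict": b.f_conflict,
                    "ic": b.ic,
                    "flagged": b.flagged,
                }
                for b in self.per_branch
            ],
        }


def bipartition_profile(
    bootstraps: Sequence[dendropy.Tree],
) -> tuple[Counter, dict[tuple[str, ...], Bipartition]]:
    """Split counts across a replicate set, keyed canonically."""
    freq: Counter = Counter()
    by_key: dict[tuple[str, ...], Bipartition] = {}
    for rep in bootstraps:
        for split in extract_bipartitions(rep):
            freq[split.key] += 1
            by_key[split.key] = split
    return freq, by_key


def tree_certainty(
    ref: dendropy.Tree, bootstraps: Sequence[dendropy.Tree]
) -> TreeCertaintyReport:
    """TC/relative-TC of a reference topology against bootstrap replicates.

    For each internal reference branch, ``f_ref`` is the number of replicates
    containing the branch's split and ``f_conflict`` the highest replicate
    count among splits incompatible with it.  A branch never observed and
    never opposed contributes IC = 0 and is flagged.  Branch lengths play no
    role; the statistic is purely topological.
    """
    if not bootstraps:
        raise ValueError("need at least one bootstrap replicate")
    ref_tips = frozenset(lf.taxon.label for lf in ref.leaf_node_iter())
    for i, rep in enumerate(bootstraps):
        rep_tips = frozenset(lf.taxon.label for lf in rep.leaf_node_iter())
        if rep_tips != ref_tips:
            missing = sorted(ref_tips - rep_tips)
            extra = sorted(rep_tips - ref_tips)
            raise TipSetMismatchError(
                f"replicate {i}: missing tips {missing}, unexpected {extra}"
            )
    freq, by_key = bipartition_profile(bootstraps)
    branches: list[BranchCertainty] = []
    flagged: list[tuple[str, ...]] = []
    for split in sorted(extract_bipartitions(ref), key=lambda s: s.key):
        f_ref = freq.get(split.key, 0)
        f_conflict = 0
        for key, count in freq.items():
            if count > f_conflict and not are_compatible(split, by_key[key]):
                f_conflict = count
        if f_ref == 0 and f_conflict == 0:
            branches.append(BranchCertainty(split.key, 0, 0, 0.0, flagged=True))
            flagged.append(split.key)
        else:
            ic = internode_certainty(f_ref, f_conflict)
            branches.append(BranchCertainty(split.key, f_ref, f_conflict, ic))
    n_internal = len(ref_tips) - 3
    if n_internal <= 0:
        raise ValueError("tree certainty needs at least 4 tips")
    tc = sum(b.ic for b in branches)
    return TreeCertaintyReport(
        per_branch=branches,
        tc=tc,
        relative_tc=tc / n_internal,
        n_internal=n_internal,
        n_replicates=len(bootstraps),
        flagged_branches=flagged,
    )


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a single Newick tree."""
    return dendropy.Tree.get(path=str(path), schema="newick")


def read_bootstrap_trees(path: str | Path) -> list[dendropy.Tree]:
    """Read a multi-tree Newick file (one replicate per line)."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(trees)
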