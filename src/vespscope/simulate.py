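"""Synthetic data generators with known ground truth.

Everything the pipeline consumes can be generated here at desk scale:
group-structured Bernoulli occurrence matrices with planted prevalence
archetypes, ultrametric pure-birth (Yule) host trees with viral clades
grafted at exactly known normalized depths, bootstrap replicate sets with a
controlled concordance fraction, and toy alignments with an exact number of
parsimony-informative sites.  Every generator is deterministic given a seed
(or a caller-supplied :class:`numpy.random.Generator`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .occurrence import GROUPS, GenomeRecord, OccurrenceMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Genome counts per taxon group of the study compilation this package's
#: synthetic matrices emulate (bacteria, archaea, Asgard, eukaryote, virus).
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "bacteria": 230,
    "archaea": 97,
    "asgard": 182,
    "eukaryote": 127,
    "virus": 343,
}

VIRAL_ORDERS = (
    "Imitervirales",
    "Pimascovirales",
    "Algavirales",
    "Chitovirales",
    "Pandoravirales",
    "Asfuvirales",
)

#: Six planted prevalence archetypes, two per category: pan-cellular
#: families are common across cellular life, true vESPs essentially
#: restricted to eukaryotes (and viruses), archaea-vESPs shared by
#: eukaryotes and archaea/Asgards but absent from bacteria.  Probabilities
#: are per-genome Bernoulli presence rates in GROUPS order.  Within the
#: category constraints, the six profiles are placed approximately
#: equidistantly (pairwise separations 1.0-1.5, large against per-family
#: prevalence noise), so the planted structure has six clusters and no
#: coarser super-cluster level.
DEFAULT_ARCHETYPES: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("pan_cellular", (1.00, 0.40, 0.45, 0.60, 0.00)),
    ("pan_cellular", (1.00, 0.90, 0.40, 0.95, 0.90)),
    ("true_vesp", (0.15, 0.15, 0.15, 0.60, 1.00)),
    ("true_vesp", (0.05, 0.00, 0.00, 1.00, 0.00)),
    ("archaea_vesp", (0.10, 0.50, 1.00, 1.00, 0.00)),
    ("archaea_vesp", (0.00, 0.95, 0.90, 1.00, 1.00)),
)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Bundle of generator settings for a full synthetic dataset."""

    seed: int = 42
    n_genomes_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_pfams: int = 480
    archetypes: tuple = DEFAULT_ARCHETYPES
    flip_noise: float = 0.05
    tree_n_tips: int = 30
    planted_depths: tuple[float, ...] = (0.4,)
    clade_sizes: tuple[int, ...] = (3,)
    boot_concordance: float = 0.9
    n_bootstraps: int = 200

    def __post_init__(self) -> None:
        for cat, probs in self.archetypes:
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"archetype {cat}: probabilities outside [0,1]")
        if any(not 0.0 < d < 1.0 for d in self.planted_depths):
            raise ValueError("planted depths must lie strictly inside (0, 1)")
        if not 0.0 <= self.boot_concordance <= 1.0:
            raise ValueError("bootstrap concordance must lie in [0, 1]")
        counts = [
            self.n_pfams, self.tree_n_tips, self.n_bootstraps,
            *self.n_genomes_per_group.values(), *self.clade_sizes,
        ]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")


def gen_occurrence(
    n_genomes_per_group: Mapping[str, int] | None = None,
    archetypes: Sequence[tuple[str, Sequence[float]]] = DEFAULT_ARCHETYPES,
    n_pfams: int = 480,
    flip_noise: float = 0.05,
    seed: int | np.random.Generator = 42,
) -> tuple[OccurrenceMatrix, pd.DataFrame]:
    """Occurrence matrix with planted archetype structure, plus truth labels.

    Each synthetic Pfam is assigned an archetype (round-robin); presence of
    the family in a genome of group g is Bernoulli with the archetype's
    probability for g, then flipped with probability ``flip_noise``.  Virus
    genomes cycle through the six nucleocytovirus orders.  Returns the
    matrix and a truth frame (pfam -> archetype index, category).
    """
    rng = _as_rng(seed)
    sizes = dict(DEFAULT_GROUP_SIZES if n_genomes_per_group is None else n_genomes_per_group)
    if any(n <= 0 for n in sizes.values()):
        raise ValueError(f"every group needs >= 1 genome, got {sizes}")
    metadata: dict[str, GenomeRecord] = {}
    genome_group: list[str] = []
    genome_ids: list[str] = []
    for group in GROUPS:
        for i in range(sizes[group]):
            gid = f"{group}_{i:03d}"
            order = VIRAL_ORDERS[i % len(VIRAL_ORDERS)] if group == "virus" else None
            metadata[gid] = GenomeRecord(gid, group, order)
            genome_ids.append(gid)
            genome_group.append(group)

    pfam_ids = [f"PFS{i:05d}" for i in range(n_pfams)]
    arch_idx = np.arange(n_pfams) % len(archetypes)
    prob_of_group = {
        g: np.array([archetypes[a][1][GROUPS.index(g)] for a in arch_idx])
        for g in GROUPS
    }
    columns = {}
    for gid, group in zip(genome_ids, genome_group):
        p = prob_of_group[group]
        present = rng.random(n_pfams) < p
        if flip_noise > 0.0:
            flips = rng.random(n_pfams) < flip_noise
            present = present ^ flips
        columns[gid] = present.astype(np.int8)
    presence = pd.DataFrame(columns, index=pfam_ids)
    truth = pd.DataFrame(
        {
            "archetype": arch_idx,
            "category": [archetypes[a][0] for a in arch_idx],
        },
        index=pfam_ids,
    )
    return OccurrenceMatrix(presence, metadata), truth


def gen_ultrametric_tree(
    n_tips: int,
    seed: int | np.random.Generator = 42,
    label_prefix: str = "t",
) -> dendropy.Tree:
    """Pure-birth (Yule) tree rescaled to height 1; ultrametric by construction.

    Lineages split at unit rate: with k extant lineages the waiting time to
    the next split is Exp(k), and the splitting lineage is chosen uniformly.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = _as_rng(seed)
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0), (root, 0.0)]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = int(rng.integers(k))
        parent, start = active.pop(idx)
        node = parent.new_child(edge_length=t - start)
        active.append((node, t))
        active.append((node, t))
    t += rng.exponential(1.0 / n_tips)  # grow to the present
    height = t if t > 0 else 1.0
    for i, (parent, start) in enumerate(active, start=1):
        leaf = parent.new_child(edge_length=t - start)
        leaf.taxon = tree.taxon_namespace.new_taxon(
            label=f"{label_prefix}{i}"
        )
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            edge.length /= height
    return tree


def _node_age(node: dendropy.Node, height: float) -> float:
    return height - node.distance_from_root()


def plant_viral_clade(
    tree: dendropy.Tree,
    depth: float,
    clade_size: int = 1,
    seed: int | np.random.Generator = 42,
    label_prefix: str = "virus_",
) -> tuple[dendropy.Tree, dict[str, str], dict]:
    """Graft a virus-tagged ultrametric clade at an exact normalized depth.

    A new attachment node is inserted at distance ``depth * height`` from the
    root on a uniformly chosen edge spanning that height, and an ultrametric
    subtree of ``clade_size`` viral tips (reaching down to the present) hangs
    from it, so the host tree stays ultrametric and the planted depth is
    exact.  The input tree is not modified.  All pre-existing tips are tagged
    ``eukaryote`` and the new tips ``virus``.

    Returns (tree, tip_domains, truth) where truth records the planted depth.

    Raises
    ------
    ValueError
        When no edge spans the requested height (caller may retry with a
        different host tree or depth).
    """
    if not 0.0 < depth < 1.0:
        raise ValueError("planted depth must lie strictly inside (0, 1)")
    rng = _as_rng(seed)
    work = tree.clone(depth=1)
    height = max(lf.distance_from_root() for lf in work.leaf_node_iter())
    a_star = height * (1.0 - depth)  # age of the attachment node
    candidates = []
    for edge in work.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        head_age = _node_age(edge.head_node, height)
        tail_age = _node_age(edge.tail_node, height)
        if head_age < a_star < tail_age:
            candidates.append(edge)
    if not candidates:
        raise ValueError(
            f"no edge spans the requested attachment age {a_star:.4f}"
        )
    edge = candidates[int(rng.integers(len(candidates)))]
    parent, child = edge.tail_node, edge.head_node
    child_age = _node_age(child, height)
    parent_age = _node_age(parent, height)
    parent.remove_child(child)
    attach = parent.new_child(edge_length=parent_age - a_star)
    attach.add_child(child)
    child.edge.length = a_star - child_age

    if clade_size == 1:
        leaf = attach.new_child(edge_length=a_star)
        leaf.taxon = work.taxon_namespace.new_taxon(label=f"{label_prefix}1")
        clade_tips = [leaf.taxon.label]
    else:
        sub_height = a_star * float(rng.uniform(0.4, 0.9))
        sub = gen_ultrametric_tree(clade_size, rng, label_prefix=label_prefix)
        for e in sub.preorder_edge_iter():
            if e.tail_node is not None:
                e.length *= sub_height
        attach.add_child(sub.seed_node)
        sub.seed_node.edge.length = a_star - sub_height
        clade_tips = [lf.taxon.label for lf in sub.seed_node.leaf_iter()]
        work.update_taxon_namespace()
    domains = {
        lf.taxon.label: ("virus" if lf.taxon.label in clade_tips else "eukaryote")
        for lf in work.leaf_node_iter()
    }
    truth = {
        "depth": depth,
        "clade_size": clade_size,
        "clade_tips": sorted(clade_tips),
        "attachment_age": a_star,
        "height": height,
    }
    return work, domains, truth


def _nni_neighbor(tree: dendropy.Tree, rng: np.random.Generator) -> dendropy.Tree:
    """A single random nearest-neighbour-interchange neighbour (topology)."""
    work = tree.clone(depth=1)
    # exclude edges hanging off a degree-2 root: in the unrooted view the
    # root is not a real vertex, and a swap across it leaves the topology
    # unchanged
    cands = [
        e
        for e in work.preorder_edge_iter()
        if e.tail_node is not None
        and not e.head_node.is_leaf()
        and len(e.tail_node.child_nodes()) >= 2
        and (
            e.tail_node.parent_node is not None
            or len(e.tail_node.child_nodes()) >= 3
        )
    ]
    if not cands:
        raise ValueError("tree has no internal edge for an NNI move")
    edge = cands[int(rng.integers(len(cands)))]
    v, u = edge.head_node, edge.tail_node
    children = v.child_nodes()
    x = children[int(rng.integers(len(children)))]
    siblings = [c for c in u.child_nodes() if c is not v]
    s = siblings[int(rng.integers(len(siblings)))]
    v.remove_child(x)
    u.remove_child(s)
    v.add_child(s)
    u.add_child(x)
    return work


def gen_bootstrap_set(
    ref: dendropy.Tree,
    concordance: float,
    n_replicates: int,
    seed: int | np.random.Generator = 42,
    fixed_neighbor: bool = False,
    resample_lengths: bool = True,
    n_moves: int = 1,
) -> list[dendropy.Tree]:
    """Bootstrap replicate topologies with a controlled concordance fraction.

    Each replicate is the reference topology with probability ``concordance``
    and otherwise a neighbour ``n_moves`` nearest-neighbour interchanges away
    (a fresh random one per replicate, or one fixed neighbour for all
    discordant replicates when ``fixed_neighbor`` is set).  One NNI disturbs
    a single internal branch; stacking moves degrades the tree certainty of
    the reference progressively.  Branch lengths are resampled exponentially
    around the reference mean unless disabled.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = _as_rng(seed)
    lengths = [
        e.length or 0.0
        for e in ref.preorder_edge_iter()
        if e.tail_node is not None
    ]
    mean_len = float(np.mean(lengths)) if lengths else 0.1

    def perturbed() -> dendropy.Tree:
        rep = _nni_neighbor(ref, rng)
        for _ in range(n_moves - 1):
            rep = _nni_neighbor(rep, rng)
        return rep

    neighbor = perturbed() if fixed_neighbor else None
    replicates = []
    for _ in range(n_replicates):
        if rng.random() < concordance:
            rep = ref.clone(depth=1)
        elif neighbor is not None:
            rep = neighbor.clone(depth=1)
        else:
            rep = perturbed()
        if resample_lengths and mean_len > 0:
            for e in rep.preorder_edge_iter():
                if e.tail_node is not None:
                    e.length = float(rng.exponential(mean_len))
        replicates.append(rep)
    return replicates


def gen_toy_alignment(
    n_seqs: int,
    length: int,
    n_informative: int,
    seed: int | np.random.Generator = 42,
    label_prefix: str = "s",
) -> list[tuple[str, str]]:
    """Protein alignment with an exact parsimony-informative site count.

    Informative columns carry two residues, each in at least two sequences;
    the remaining columns are constant.  Column order is shuffled.
    """
    if n_seqs < 4:
        raise ValueError("need >= 4 sequences to build informative columns")
    if not 0 <= n_informative <= length:
        raise ValueError("need 0 <= n_informative <= length")
    rng = _as_rng(seed)
    columns: list[np.ndarray] = []
    for _ in range(n_informative):
        r1, r2 = rng.choice(len(AMINO_ACIDS), size=2, replace=False)
        n_first = int(rng.integers(2, n_seqs - 1))  # both states >= 2 seqs
        members = rng.permutation(n_seqs) < n_first
        col = np.where(members, AMINO_ACIDS[r1], AMINO_ACIDS[r2])
        columns.append(col)
    for _ in range(length - n_informative):
        res = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
        columns.append(np.full(n_seqs, res))
    order = rng.permutation(length)
    matrix = np.array(columns)[order] if length else np.empty((0, n_seqs), dtype="<U1")
    seqs = ["".join(matrix[:, i]) for i in range(n_seqs)]
    return [(f"{label_prefix}{i+1}", seq) for i, seq in enumerate(seqs)]


def write_alignment_fasta(rows: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for label, seq in rows:
            fh.write(f">{label}\n{seq}\n")
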