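"""Pfam occurrence matrices, taxon-group prevalence, and ESP/vESP filters.

The unit of observation is a protein-domain family (a Pfam accession) and the
question asked of it is purely presence/absence: in how many genomes of each
taxon group (bacteria, archaea, Asgard archaea, eukaryotes, nucleocytoviruses)
does at least one domain hit occur?  Eukaryotic signature proteins (ESPs) are
families prevalent in eukaryotes but rare elsewhere; vESPs are ESPs that also
occur in at least one giant-virus genome.  Filters use strict inequalities
("greater than 95%", "greater than 10 genomes") and are configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical taxon-group order used for every five-vector in the package.
GROUPS = ("bacteria", "archaea", "asgard", "eukaryote", "virus")

#: Per-order genome totals of the Giant Virus Database compilation; pass as
#: ``order_totals`` to :func:`order_prevalence_table` to express percentages
#: against the full database rather than the genomes in the metadata table.
GVDB_ORDER_TOTALS = {
    "Imitervirales": 1001,
    "Pimascovirales": 146,
    "Algavirales": 120,
    "Chitovirales": 43,
    "Pandoravirales": 38,
    "Asfuvirales": 32,
}

# domtblout rows carry 22 fixed whitespace-delimited fields followed by a
# free-text description; the Pfam accession is the query accession (field 5).
_DOMTBLOUT_MIN_FIELDS = 22


class DomtbloutParseError(ValueError):
    """A malformed row in a HMMER3 per-domain table."""


class MetadataError(KeyError):
    """A genome id with no record in the metadata table."""


@dataclass(frozen=True)
class GenomeRecord:
    """One genome: its identifier, taxon group, and (for viruses) order."""

    genome_id: str
    group: str
    viral_order: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown taxon group {self.group!r} for genome "
                f"{self.genome_id!r}; expected one of {GROUPS}"
            )
        if self.viral_order is not None and self.group != "virus":
            raise ValueError(
                f"genome {self.genome_id!r}: viral_order given but group is "
                f"{self.group!r}, not 'virus'"
            )


class OccurrenceMatrix:
    """Binary Pfam-by-genome presence matrix joined to genome metadata.

    Parameters
    ----------
    presence
        DataFrame with Pfam accessions as the index and genome ids as
        columns; entries must be 0/1.
    metadata
        Mapping from genome id to :class:`GenomeRecord`; every column of
        ``presence`` must have a record.
    """

    def __init__(
        self, presence: pd.DataFrame, metadata: Mapping[str, GenomeRecord]
    ) -> None:
        vals = presence.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0 or 1")
        missing = [g for g in presence.columns if g not in metadata]
        if missing:
            raise MetadataError(
                f"genomes without metadata records: {missing[:5]}"
            )
        if presence.index.has_duplicates or presence.columns.has_duplicates:
            raise ValueError("duplicate Pfam or genome identifiers")
        self.presence = presence.astype(np.int8)
        self.metadata = dict(metadata)

    @property
    def pfam_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.presence.columns)

    def group_of(self, genome_id: str) -> str:
        return self.metadata[genome_id].group

    def genomes_in_group(self, group: str) -> list[str]:
        return [g for g in self.presence.columns if self.metadata[g].group == group]

    @classmethod
    def from_tsv(
        cls, matrix_path: str | Path, metadata: Mapping[str, GenomeRecord]
    ) -> "OccurrenceMatrix":
        """Read a 0/1 occurrence TSV (rows = Pfams, columns = genomes)."""
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
        return cls(frame, metadata)

    def to_tsv(self, path: str | Path) -> None:
        self.presence.to_csv(path, sep="\t")


def read_genome_metadata(path: str | Path) -> dict[str, GenomeRecord]:
    """Read a metadata TSV with header ``genome_id<TAB>group<TAB>viral_order``.

    An empty or missing ``viral_order`` cell means no order label.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records: dict[str, GenomeRecord] = {}
    for row in frame.itertuples(index=False):
        gid = row.genome_id
        if gid in records:
            raise ValueError(f"duplicate genome_id {gid!r} in {path}")
        order = getattr(row, "viral_order", "") or None
        records[gid] = GenomeRecord(gid, row.group, order)
    return records


def _pfam_accession(query_name: str, query_acc: str) -> str:
    """Pfam accession of a hit, version suffix stripped (PF00022.12 → PF00022)."""
    acc = query_acc if query_acc != "-" else query_name
    return re.sub(r"\.\d+$", "", acc)


def parse_domtblout(
    paths: Sequence[str | Path],
    metadata: Mapping[str, GenomeRecord],
    genome_map: Mapping[str, str] | None = None,
) -> OccurrenceMatrix:
    """Build an :class:`OccurrenceMatrix` from HMMER3 ``--domtblout`` files.

    Each file holds the domain hits of one genome's proteome searched against
    Pfam profile HMMs; hits are trusted as already thresholded upstream (the
    searches are run with the Pfam noise cutoff, ``--cut_nc``).  Presence is
    binary: one or many hits of a family in a genome both record 1.

    Parameters
    ----------
    paths
        domtblout files, one per genome.  A file with only comment lines
        yields an all-zero column.
    metadata
        Genome metadata; every mapped genome id must have a record.
    genome_map
        Optional mapping from file path (as given) to genome id; by default
        the file stem is the genome id.
    """
    hits: dict[str, set[str]] = {}
    for raw in paths:
        path = Path(raw)
        gid = (genome_map or {}).get(str(raw), path.stem)
        if gid not in metadata:
            raise MetadataError(f"genome {gid!r} (file {path}) has no metadata")
        seen = hits.setdefault(gid, set())
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.split()
                if len(fields) < _DOMTBLOUT_MIN_FIELDS:
                    raise DomtbloutParseError(
                        f"{path}:{lineno}: expected ≥{_DOMTBLOUT_MIN_FIELDS} "
                        f"fields, found {len(fields)}"
                    )
                seen.add(_pfam_accession(fields[3], fields[4]))
    pfams = sorted(set().union(*hits.values())) if hits else []
    genomes = list(hits)
    presence = pd.DataFrame(
        [[1 if p in hits[g] else 0 for g in genomes] for p in pfams],
        index=pfams,
        columns=genomes,
        dtype=np.int8,
    )
    return OccurrenceMatrix(presence, metadata)


@dataclass
class PrevalenceTable:
    """Per-Pfam occurrence fractions and counts in each taxon group.

    ``prevalence`` and ``counts`` are Pfam-by-group DataFrames;
    ``group_totals`` holds the number of genomes per group, so
    ``prevalence = counts / group_totals`` exactly.
    """

    prevalence: pd.DataFrame
    counts: pd.DataFrame
    group_totals: pd.Series

    def to_frame(self) -> pd.DataFrame:
        """Wide table: prev_<group> then count_<group> columns."""
        prev = self.prevalence.add_prefix("prev_")
        cnt = self.counts.add_prefix("count_")
        return pd.concat([prev, cnt], axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="pfam")


def compute_prevalence(
    m: OccurrenceMatrix, merge_asgard: bool = False
) -> PrevalenceTable:
    """Per-group occurrence fractions for every Pfam in the matrix.

    Parameters
    ----------
    m
        Occurrence matrix with metadata for every genome.
    merge_asgard
        Count Asgard archaea within the ``archaea`` group (four groups
        instead of five).  By default Asgards are a distinct fifth group.

    Raises
    ------
    ValueError
        If any taxon group has zero genomes (its fraction is undefined).
    """
    groups = [g for g in GROUPS if not (merge_asgard and g == "asgard")]
    membership: dict[str, list[str]] = {g: [] for g in groups}
    for gid in m.genome_ids:
        grp = m.group_of(gid)
        if merge_asgard and grp == "asgard":
            grp = "archaea"
        membership[grp].append(gid)
    empty = [g for g, ids in membership.items() if not ids]
    if empty:
        raise ValueError(f"taxon groups with zero genomes: {empty}")
    counts = pd.DataFrame(
        {g: m.presence[ids].sum(axis=1) for g, ids in membership.items()}
    )
    totals = pd.Series({g: len(ids) for g, ids in membership.items()})
    prevalence = counts / totals
    return PrevalenceTable(prevalence, counts.astype(int), totals)


def filter_esps(
    table: PrevalenceTable,
    euk_threshold: float = 0.95,
    min_virus_genomes_vesp: int = 1,
    min_virus_genomes_phylo: int = 11,
) -> pd.DataFrame:
    """Flag ESPs, vESPs, and families retained for phylogenetics.

    A family is an ESP when its eukaryote prevalence is *strictly* greater
    than ``euk_threshold``; a vESP when it is an ESP found in at least
    ``min_virus_genomes_vesp`` virus genomes; and phylogenetically selected
    when found in at least ``min_virus_genomes_phylo`` virus genomes (the
    default 11 encodes the strict "more than 10 genomes" rule).

    Returns a DataFrame indexed by Pfam with columns ``is_esp``, ``is_vesp``,
    ``phylo_selected`` and ``virus_genome_count``.
    """
    if not 0.0 <= euk_threshold <= 1.0:
        raise ValueError(f"euk_threshold must lie in [0, 1], got {euk_threshold}")
    if min_virus_genomes_vesp < 0 or min_virus_genomes_phylo < 0:
        raise ValueError("minimum virus-genome counts must be non-negative")
    euk_prev = table.prevalence["eukaryote"]
    virus_count = table.counts["virus"]
    is_esp = euk_prev > euk_threshold
    is_vesp = is_esp & (virus_count >= min_virus_genomes_vesp)
    phylo = is_esp & (virus_count >= min_virus_genomes_phylo)
    return pd.DataFrame(
        {
            "is_esp": is_esp,
            "is_vesp": is_vesp,
            "phylo_selected": phylo,
            "virus_genome_count": virus_count,
        }
    )


def order_prevalence_table(
    m: OccurrenceMatrix,
    pfams: Iterable[str] | None = None,
    order_totals: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Long-format per-viral-order prevalence percentages.

    For each requested Pfam and each viral order, the percentage of that
    order's genomes encoding the family, to two decimals.  Denominators
    default to order sizes counted from the metadata table; pass
    :data:`GVDB_ORDER_TOTALS` (or any mapping) to use external totals such as
    the full Giant Virus Database compilation.
    """
    pfam_list = list(pfams) if pfams is not None else m.pfam_ids
    order_members: dict[str, list[str]] = {}
    for gid in m.genome_ids:
        rec = m.metadata[gid]
        if rec.group == "virus" and rec.viral_order:
            order_members.setdefault(rec.viral_order, []).append(gid)
    totals = (
        dict(order_totals)
        if order_totals is not None
        else {o: len(ids) for o, ids in order_members.items()}
    )
    bad = [o for o, n in totals.items() if n <= 0]
    if bad:
        raise ValueError(f"viral orders with zero genome total: {bad}")
    rows = []
    for pfam in pfam_list:
        for order, total in totals.items():
            members = order_members.get(order, [])
            n_hit = int(m.presence.loc[pfam, members].sum()) if members else 0
            rows.append(
                {
                    "pfam": pfam,
                    "viral_order": order,
                    "percent": round(100.0 * n_hit / total, 2),
                }
            )
    return pd.DataFrame(rows, columns=["pfam", "viral_order", "percent"])
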