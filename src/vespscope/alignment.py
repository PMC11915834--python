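"""Alignment statistics: length, parsimony-informative sites, identity.

Operates on trimmed protein alignments.  Gap characters ('-') and the
ambiguity code 'X' are excluded both from the per-column state counts behind
the parsimony-informative-site definition and from the denominator of
pairwise percent identity.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

EXCLUDED = {"-", "X", "."}

Rows = Sequence[tuple[str, str]]


def _as_rows(aln: MultipleSeqAlignment | Rows) -> list[tuple[str, str]]:
    if isinstance(aln, MultipleSeqAlignment):
        rows = [(rec.id, str(rec.seq).upper()) for rec in aln]
    else:
        rows = [(label, seq.upper()) for label, seq in aln]
    if not rows:
        raise ValueError("empty alignment")
    length = len(rows[0][1])
    ragged = [label for label, seq in rows if len(seq) != length]
    if ragged:
        raise ValueError(f"ragged alignment; offending rows: {ragged[:5]}")
    return rows


def read_alignment(path: str | Path) -> MultipleSeqAlignment:
    """Read an aligned FASTA file."""
    return AlignIO.read(str(path), "fasta")


def alignment_length(aln: MultipleSeqAlignment | Rows) -> int:
    return len(_as_rows(aln)[0][1])


def parsimony_informative_sites(aln: MultipleSeqAlignment | Rows) -> int:
    """Number of parsimony-informative columns.

    A column is informative when at least two distinct unambiguous residues
    each occur in at least two sequences; gaps and 'X' carry no state.
    """
    rows = _as_rows(aln)
    if len(rows) < 2:
        raise ValueError("need at least two sequences")
    count = 0
    for column in zip(*(seq for _, seq in rows)):
        states = Counter(c for c in column if c not in EXCLUDED)
        if sum(1 for n in states.values() if n >= 2) >= 2:
            count += 1
    return count


def pairwise_identity(s1: str, s2: str) -> float | None:
    """Percent identity over columns where neither row is a gap/ambiguous.

    Returns None when no comparable column exists (undefined identity).
    """
    if len(s1) != len(s2):
        raise ValueError(
            f"aligned rows differ in length ({len(s1)} vs {len(s2)})"
        )
    matches = compared = 0
    for a, b in zip(s1.upper(), s2.upper()):
        if a in EXCLUDED or b in EXCLUDED:
            continue
        compared += 1
        if a == b:
            matches += 1
    if compared == 0:
        return None
    return 100.0 * matches / compared


def identity_range(
    aln: MultipleSeqAlignment | Rows, tip_domains: Mapping[str, str]
) -> tuple[float, float]:
    """(min, max) of per-viral-row best identities against eukaryote rows.

    For every virus-tagged row, its best percent identity to any
    eukaryote-tagged row is taken; the range of these best-hit identities is
    returned.  Viral rows with no comparable column against any eukaryote
    (all-gap overlap) are excluded from the range.
    """
    rows = _as_rows(aln)
    viral = [(l, s) for l, s in rows if tip_domains.get(l) == "virus"]
    euk = [(l, s) for l, s in rows if tip_domains.get(l) == "eukaryote"]
    if not viral or not euk:
        missing = "virus" if not viral else "eukaryote"
        raise ValueError(f"no {missing}-tagged sequences in alignment")
    best_hits = []
    for _, vs in viral:
        idents = [
            ident
            for _, es in euk
            if (ident := pairwise_identity(vs, es)) is not None
        ]
        if idents:
            best_hits.append(max(idents))
    if not best_hits:
        raise ValueError("no viral row comparable to any eukaryote row")
    return min(best_hits), max(best_hits)


def alignment_stats(
    aln: MultipleSeqAlignment | Rows, tip_domains: Mapping[str, str] | None = None
) -> dict:
    """Length, PIS, and (when domains are supplied) identity range."""
    stats: dict = {
        "length": alignment_length(aln),
        "n_sequences": len(_as_rows(aln)),
        "parsimony_informative_sites": parsimony_informative_sites(aln),
    }
    if tip_domains is not None:
        lo, hi = identity_range(aln, tip_domains)
        stats["min_identity"] = lo
        stats["max_identity"] = hi
    return stats
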