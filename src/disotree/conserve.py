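"""Sequence-side conservation scores and the homolog candidate filter.

Provides BLOSUM62 mean-score-per-residue for named alignment regions
(e.g. conserved homology boxes), identity fractions over regions and
aligned pairs, and the strict score/length filter applied to BLASTP
tabular hit lists when collecting candidate family members.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from Bio.Align import substitution_matrices

from .errors import IntervalRangeError, UndefinedScoreError
from .seqio import GAP, Alignment

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    """Symmetric BLOSUM62 lookup; unknown residues fall back to 'X'."""
    alpha = _BLOSUM62.alphabet
    a = a if a in alpha else "X"
    b = b if b in alpha else "X"
    return float(_BLOSUM62[a, b])


@dataclass(frozen=True)
class RegionDefinition:
    """A named alignment-column interval (1-based, inclusive)."""

    name: str
    start_col: int
    end_col: int

    def __post_init__(self):
        if not (1 <= self.start_col <= self.end_col):
            raise IntervalRangeError(
                f"region {self.name}: bad columns [{self.start_col}, {self.end_col}]"
            )


@dataclass(frozen=True)
class BlastHit:
    query: str
    subject: str
    score: float
    length: int

    def __post_init__(self):
        if self.score < 0 or self.length < 1:
            raise ValueError(f"invalid hit {self.query}->{self.subject}")


def _region_columns(aln: Alignment, region: RegionDefinition) -> range:
    if region.end_col > aln.n_cols:
        raise IntervalRangeError(
            f"region {region.name} ends at column {region.end_col}, "
            f"alignment has {aln.n_cols}"
        )
    return range(region.start_col - 1, region.end_col)


def region_blosum_score(
    aln: Alignment,
    region: RegionDefinition,
    subject_id: str,
    reference_id: str,
) -> tuple[float, int]:
    """Mean BLOSUM62 score per residue of a subject against a reference.

    Only columns where both rows carry a residue are scored — a gap is
    not a substitution.  Returns (mean score, number of scored columns).
    """
    subj = aln.row(subject_id)
    ref = aln.row(reference_id)
    scores = [
        blosum62(subj[c], ref[c])
        for c in _region_columns(aln, region)
        if subj[c] != GAP and ref[c] != GAP
    ]
    if not scores:
        raise UndefinedScoreError(
            f"region {region.name}: no column where both {subject_id!r} and "
            f"{reference_id!r} have residues"
        )
    return sum(scores) / len(scores), len(scores)


def region_identity(
    aln: Alignment,
    region: RegionDefinition,
    subject_id: str,
    reference_id: str,
) -> tuple[float, int]:
    """Identity fraction over mutually ungapped region columns."""
    subj = aln.row(subject_id)
    ref = aln.row(reference_id)
    pairs = [
        (subj[c], ref[c])
        for c in _region_columns(aln, region)
        if subj[c] != GAP and ref[c] != GAP
    ]
    if not pairs:
        raise UndefinedScoreError(
            f"region {region.name}: no mutually ungapped column"
        )
    matches = sum(1 for a, b in pairs if a == b)
    return matches / len(pairs), len(pairs)


def pairwise_identity(row1: str, row2: str) -> float:
    """Percent identity of an aligned pair over mutually ungapped columns."""
    if len(row1) != len(row2):
        raise IntervalRangeError("aligned rows differ in length")
    pairs = [(a, b) for a, b in zip(row1, row2) if a != GAP and b != GAP]
    if not pairs:
        raise UndefinedScoreError("no mutually ungapped column")
    matches = sum(1 for a, b in pairs if a == b)
    return round(100.0 * matches / len(pairs), 1)


def filter_blast_hits(
    hits: Sequence[BlastHit], min_score: float = 140.0, min_length: int = 300
) -> list[BlastHit]:
    """Keep hits with score strictly above ``min_score`` AND aligned length
    strictly above ``min_length`` residues (both inequalities strict)."""
    return [h for h in hits if h.score > min_score and h.length > min_length]


def read_blast_tabular(path: Union[str, Path]) -> list[BlastHit]:
    """Read BLAST tabular output (outfmt 6 default columns).

    Columns used: qseqid (1), sseqid (2), length (4), bitscore (12).
    """
    hits = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            hits.append(
                BlastHit(
                    query=row[0],
                    subject=row[1],
                    score=float(row[11]),
                    length=int(row[3]),
                )
            )
    return hits


def read_regions(path: Union[str, Path]) -> list[RegionDefinition]:
    """Read a region CSV with header ``name,start_col,end_col``."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                RegionDefinition(
                    name=row["name"].strip(),
                    start_col=int(row["start_col"]),
                    end_col=int(row["end_col"]),
                )
            )
    return out
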