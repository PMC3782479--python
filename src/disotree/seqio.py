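"""Reading, writing, and coordinate mapping for the pipeline's file formats.

Handles aligned FASTA (via Biopython), per-residue disorder score tables
(CSV), motif/region annotation tables (CSV), and Newick trees, plus the
two coordinate transforms everything downstream relies on: substituting
per-residue scores into alignment columns (gaps become missing values)
and remapping residue intervals to alignment columns.

Conventions: residue positions and alignment columns are 1-based and
inclusive, matching the residue numbering used in the literature (T58,
S62, ...).  The gap character is ``-``; ``.`` is accepted on read and
normalised.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    AlignmentShapeError,
    DuplicateIdError,
    IntervalRangeError,
    MissingPositionError,
    ProfileMismatchError,
    ScoreRangeError,
    UnknownIdError,
)
from .tree import Dendrogram

GAP = "-"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X"}

MOTIF_CATEGORIES = ("CLV", "LIG", "MOD", "TRG", "ANCHOR")


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped amino-acid sequence with an accession-like id."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: invalid residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """An ordered multiple alignment of gapped rows of equal length."""

    records: list[tuple[str, str]]  # (id, gapped_row)

    def __post_init__(self):
        if not self.records:
            raise AlignmentShapeError("alignment has no records")
        n_cols = len(self.records[0][1])
        seen = set()
        normalised = []
        for rid, row in self.records:
            row = row.replace(".", GAP).upper()
            if len(row) != n_cols:
                raise AlignmentShapeError(
                    f"row {rid!r} has length {len(row)}, expected {n_cols}"
                )
            if rid in seen:
                raise DuplicateIdError(f"duplicate record id {rid!r}")
            seen.add(rid)
            SequenceRecord(rid, row.replace(GAP, ""))  # validates alphabet, non-empty
            normalised.append((rid, row))
        self.records = normalised

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1])

    def row(self, protein_id: str) -> str:
        for rid, row in self.records:
            if rid == protein_id:
                return row
        raise UnknownIdError(f"unknown protein id {protein_id!r}")

    def ungapped(self, protein_id: str) -> SequenceRecord:
        return SequenceRecord(protein_id, self.row(protein_id).replace(GAP, ""))

    def residue_columns(self, protein_id: str) -> np.ndarray:
        """1-based alignment column of each ungapped residue, in order."""
        row = self.row(protein_id)
        return np.array([i + 1 for i, ch in enumerate(row) if ch != GAP])


@dataclass
class DisorderProfile:
    """Per-residue disorder scores in [0, 1] for one ungapped sequence."""

    id: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ScoreRangeError(f"{self.id}: profile must be a non-empty vector")
        if not np.all(np.isfinite(self.scores)):
            raise ScoreRangeError(f"{self.id}: non-finite score")
        if self.scores.min() < 0.0 or self.scores.max() > 1.0:
            raise ScoreRangeError(
                f"{self.id}: scores outside [0, 1] "
                f"(min {self.scores.min():.3g}, max {self.scores.max():.3g})"
            )

    def __len__(self) -> int:
        return self.scores.size


class AlignedDisorderMatrix:
    """Disorder scores substituted into alignment columns.

    ``values`` is an (n_proteins, n_cols) float array with NaN exactly
    where the alignment row has a gap.
    """

    def __init__(self, ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != len(ids):
            raise ValueError("values must be (n_proteins, n_cols)")
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ScoreRangeError("matrix contains scores outside [0, 1]")
        self.ids = list(ids)
        self.values = values

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def profile(self, protein_id: str) -> DisorderProfile:
        """Recover the ungapped profile of one protein (drops NaN cells)."""
        try:
            i = self.ids.index(protein_id)
        except ValueError:
            raise UnknownIdError(f"unknown protein id {protein_id!r}") from None
        row = self.values[i]
        return DisorderProfile(protein_id, row[np.isfinite(row)])


@dataclass(frozen=True)
class MotifAnnotation:
    """An ELM or ANCHOR interval on an ungapped sequence (1-based, inclusive)."""

    protein_id: str
    motif_id: str
    category: str
    start: int
    end: int

    def __post_init__(self):
        if self.category not in MOTIF_CATEGORIES:
            raise ValueError(
                f"{self.motif_id}: category {self.category!r} not in "
                f"{MOTIF_CATEGORIES}"
            )
        if not (1 <= self.start <= self.end):
            raise IntervalRangeError(
                f"{self.motif_id} on {self.protein_id}: bad interval "
                f"[{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ----------------------------------------------------------------------
# FASTA alignments
# ----------------------------------------------------------------------
def read_alignment(path: Union[str, Path]) -> Alignment:
    """Read an aligned FASTA file; all rows must have equal length."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentShapeError(f"{path}: no FASTA records found")
    return Alignment(records)


def write_alignment(aln: Alignment, path: Union[str, Path]) -> None:
    recs = [
        _BioSeqRecord(Seq(row), id=rid, description="") for rid, row in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


# ----------------------------------------------------------------------
# score tables
# ----------------------------------------------------------------------
def read_scores(path: Union[str, Path]) -> list[DisorderProfile]:
    """Read a long-format score CSV with header ``id,position,score``.

    Positions per id must be contiguous from 1; scores must lie in [0, 1].
    """
    by_id: dict[str, list[tuple[int, float]]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise MissingPositionError(f"{path}: empty file")
        start = 0 if _looks_like_header(header) else None
        rows = reader if start == 0 else _chain_first(header, reader)
        for lineno, row in enumerate(rows, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise MissingPositionError(
                    f"{path}:{lineno}: expected id,position,score"
                )
            rid, pos_s, score_s = row[0].strip(), row[1], row[2]
            try:
                pos = int(pos_s)
                score = float(score_s)
            except ValueError as exc:
                raise ScoreRangeError(f"{path}:{lineno}: {exc}") from exc
            if rid not in by_id:
                by_id[rid] = []
                order.append(rid)
            by_id[rid].append((pos, score))
    return [_assemble_profile(rid, by_id[rid], path) for rid in order]


def read_scores_single(path: Union[str, Path], protein_id: str) -> DisorderProfile:
    """Read a two-column per-protein predictor output (``position,score``)."""
    pairs: list[tuple[int, float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            try:
                pairs.append((int(row[0]), float(row[1])))
            except ValueError:
                if not pairs:  # tolerate a single header line
                    continue
                raise
    return _assemble_profile(protein_id, pairs, path)


def write_scores(profiles: Iterable[DisorderProfile], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "position", "score"])
        for prof in profiles:
            for pos, score in enumerate(prof.scores, start=1):
                writer.writerow([prof.id, pos, f"{score:.6g}"])


def _looks_like_header(row: list[str]) -> bool:
    try:
        int(row[1])
        return False
    except (ValueError, IndexError):
        return True


def _chain_first(first, rest):
    yield first
    yield from rest


def _assemble_profile(rid, pairs, path) -> DisorderProfile:
    pairs.sort()
    positions = [p for p, _ in pairs]
    if positions != list(range(1, len(positions) + 1)):
        expected = next(
            (i + 1 for i, p in enumerate(positions) if p != i + 1),
            len(positions) + 1,
        )
        raise MissingPositionError(
            f"{path}: {rid}: positions not contiguous from 1 "
            f"(first problem at position {expected})"
        )
    return DisorderProfile(rid, np.array([s for _, s in pairs]))


# ----------------------------------------------------------------------
# motif tables
# ----------------------------------------------------------------------
def read_motifs(path: Union[str, Path]) -> list[MotifAnnotation]:
    """Read a motif CSV with header ``protein_id,motif_id,category,start,end``."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                MotifAnnotation(
                    protein_id=row["protein_id"].strip(),
                    motif_id=row["motif_id"].strip(),
                    category=row["category"].strip().upper(),
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
    return out


def write_motifs(motifs: Iterable[MotifAnnotation], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["protein_id", "motif_id", "category", "start", "end"])
        for m in motifs:
            writer.writerow([m.protein_id, m.motif_id, m.category, m.start, m.end])


# ----------------------------------------------------------------------
# coordinate mapping
# ----------------------------------------------------------------------
def map_scores_to_alignment(
    aln: Alignment, profiles: Iterable[DisorderProfile]
) -> AlignedDisorderMatrix:
    """Substitute per-residue scores into alignment columns.

    The k-th non-gap column of each row receives the k-th profile score;
    gap columns become NaN (missing).  Every alignment row must have a
    profile of exactly its ungapped length.
    """
    by_id = {p.id: p for p in profiles}
    values = np.full((len(aln.records), aln.n_cols), np.nan)
    for i, (rid, row) in enumerate(aln.records):
        if rid not in by_id:
            raise ProfileMismatchError(f"no disorder profile for {rid!r}")
        prof = by_id[rid]
        cols = aln.residue_columns(rid)
        if len(prof) != cols.size:
            raise ProfileMismatchError(
                f"{rid!r}: profile length {len(prof)} != ungapped length {cols.size}"
            )
        values[i, cols - 1] = prof.scores
    return AlignedDisorderMatrix(aln.ids, values)


def map_interval_to_columns(aln: Alignment, ann: MotifAnnotation) -> set[int]:
    """Alignment columns (1-based) of residues ``start..end`` of a motif."""
    cols = aln.residue_columns(ann.protein_id)
    if ann.end > cols.size:
        raise IntervalRangeError(
            f"{ann.motif_id} on {ann.protein_id}: interval end {ann.end} exceeds "
            f"ungapped length {cols.size}"
        )
    return set(int(c) for c in cols[ann.start - 1 : ann.end])


def column_to_residue(aln: Alignment, protein_id: str, column: int) -> int | None:
    """Inverse map: 1-based residue index at an alignment column, or None at a gap."""
    row = aln.row(protein_id)
    if not (1 <= column <= len(row)):
        raise IntervalRangeError(f"column {column} outside alignment")
    if row[column - 1] == GAP:
        return None
    return sum(1 for ch in row[:column] if ch != GAP)


# ----------------------------------------------------------------------
# Newick
# ----------------------------------------------------------------------
def read_newick(path: Union[str, Path]) -> Dendrogram:
    with open(path) as fh:
        return Dendrogram.from_newick(fh.read())


def write_newick(tree: Dendrogram, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
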