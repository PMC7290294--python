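"""Aligned FASTA I/O, alignment cleaning, and codon encoding.

A :class:`RawAlignment` is the gap-aware nucleotide matrix as it comes out
of an aligner; a :class:`CodonAlignment` is the cleaned, frame-consistent
codon matrix the likelihood machinery consumes.  Cleaning mirrors the
standard pre-processing for codeml-style selection analyses: frameshift
insertion columns, lineage-specific in-frame insertions, and codon sites
carrying in-frame stops are all removed before any model fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import MISSING, NUCLEOTIDES, GeneticCode

logger = logging.getLogger(__name__)

_VALID = set("ACGTN-")
#: IUPAC ambiguity codes folded to N on input.
_AMBIGUOUS = set("RYSWKMBDHV")


class AlignmentShapeError(ValueError):
    """Rows of an alignment have unequal lengths."""


class AlignmentFormatError(ValueError):
    """File is not a readable aligned FASTA."""


class DegenerateAlignmentError(ValueError):
    """Cleaning removed every codon site."""


@dataclass
class RawAlignment:
    """Gap-aware aligned nucleotide matrix.

    Parameters
    ----------
    taxa:
        Ordered taxon identifiers, unique.
    rows:
        Per-taxon aligned strings over ``{A,C,G,T,N,-}``, equal length.
    frame_anchor:
        1-based alignment column where the reference reading frame starts.
    """

    taxa: list[str]
    rows: list[str]
    frame_anchor: int = 1

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentShapeError("taxa and rows differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentFormatError(f"duplicate taxon identifiers: {dup}")
        if self.rows:
            n = len(self.rows[0])
            for t, r in zip(self.taxa, self.rows):
                if len(r) != n:
                    raise AlignmentShapeError(
                        f"row for taxon {t!r} has length {len(r)}, expected {n}"
                    )
        if self.frame_anchor < 1:
            raise ValueError("frame_anchor must be >= 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def subset(self, taxa: Sequence[str]) -> "RawAlignment":
        """Restrict to the given taxa, preserving their given order."""
        return RawAlignment(
            taxa=list(taxa),
            rows=[self.row(t) for t in taxa],
            frame_anchor=self.frame_anchor,
        )


@dataclass
class CodonAlignment:
    """Cleaned codon matrix: one string of 3*n_sites nucleotides per taxon.

    Invariant: no taxon carries an in-frame stop codon.
    """

    taxa: list[str]
    codon_rows: list[str]

    def __post_init__(self) -> None:
        if self.codon_rows and len(self.codon_rows[0]) % 3 != 0:
            raise ValueError("codon alignment length must be divisible by 3")

    @property
    def n_sites(self) -> int:
        return len(self.codon_rows[0]) // 3 if self.codon_rows else 0

    def codon(self, taxon_idx: int, site: int) -> str:
        return self.codon_rows[taxon_idx][3 * site : 3 * site + 3]


@dataclass
class CleaningPolicy:
    """Controls which columns the cleaner removes.

    ``minor_insertion_fraction``: an insertion run carried by fewer than
    this fraction of active taxa counts as lineage-specific and is removed
    (the in-frame case) or removed as a frameshift insertion (length not a
    multiple of 3).  ``active_taxa`` restricts the analysis to a subset;
    None means all taxa.
    """

    minor_insertion_fraction: float = 0.10
    active_taxa: list[str] | None = None


@dataclass
class RemovalRecord:
    rule: str
    columns: list[int]  # 1-based alignment columns removed
    detail: str = ""


def read_fasta_alignment(path: str | Path) -> RawAlignment:
    """Read an aligned FASTA file into a :class:`RawAlignment`.

    Bases are uppercased; gaps preserved; IUPAC ambiguity codes other than
    N are folded to N with a logged warning.  Unequal record lengths raise
    :class:`AlignmentShapeError` naming the offending taxon.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: no FASTA records found")
    if len(records) < 2:
        raise AlignmentFormatError(f"{path}: an alignment needs >= 2 records")
    taxa: list[str] = []
    rows: list[str] = []
    folded = 0
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        amb = bad & _AMBIGUOUS
        if amb:
            folded += sum(seq.count(c) for c in amb)
            seq = "".join("N" if c in _AMBIGUOUS else c for c in seq)
            bad = set(seq) - _VALID
        if bad:
            raise AlignmentFormatError(
                f"{path}: record {rec.id!r} contains non-IUPAC symbols {sorted(bad)}"
            )
        taxa.append(rec.id)
        rows.append(seq)
    if folded:
        logger.warning("%s: folded %d ambiguity bases to N", path, folded)
    n = len(rows[0])
    for t, r in zip(taxa, rows):
        if len(r) != n:
            raise AlignmentShapeError(
                f"{path}: record {t!r} has length {len(r)}, expected {n}"
            )
    return RawAlignment(taxa=taxa, rows=rows)


def write_fasta_alignment(aln: RawAlignment | CodonAlignment, path: str | Path) -> None:
    """Write an alignment back to FASTA, preserving taxon order."""
    rows = aln.rows if isinstance(aln, RawAlignment) else aln.codon_rows
    records = [
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.taxa, rows)
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def _insertion_runs(
    rows: list[str], n_cols: int, minor_fraction: float
) -> list[list[int]]:
    """Contiguous runs of 0-based columns where <minor_fraction of taxa have bases."""
    n_taxa = len(rows)
    minor = [
        sum(r[c] != "-" for r in rows) < max(1, minor_fraction * n_taxa)
        and any(r[c] != "-" for r in rows)
        for c in range(n_cols)
    ]
    runs: list[list[int]] = []
    cur: list[int] = []
    for c in range(n_cols):
        if minor[c]:
            cur.append(c)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def clean_alignment(
    raw: RawAlignment,
    code: GeneticCode,
    policy: CleaningPolicy | None = None,
) -> tuple[CodonAlignment, list[RemovalRecord]]:
    """Clean a raw alignment into an analyzable codon matrix.

    Three removal rules, applied in order:

    1. minority insertion runs whose inserted length is not a multiple of 3
       (frameshift insertions) are removed column-wise;
    2. minority in-frame insertion runs (lineage-specific insertions) are
       removed likewise;
    3. codon sites where any active taxon carries an in-frame stop are
       removed for all taxa.

    Returns the cleaned :class:`CodonAlignment` and a removal log.
    Cleaning is idempotent: applying it to its own output removes nothing.
    """
    policy = policy or CleaningPolicy()
    if raw.frame_anchor > raw.n_columns:
        raise IndexError(
            f"frame_anchor {raw.frame_anchor} beyond alignment length {raw.n_columns}"
        )
    active = policy.active_taxa if policy.active_taxa is not None else raw.taxa
    missing = set(active) - set(raw.taxa)
    if missing:
        raise KeyError(f"active taxa not in alignment: {sorted(missing)}")
    act_rows = [raw.row(t) for t in active]

    removals: list[RemovalRecord] = []
    keep = [True] * raw.n_columns
    # columns before the frame anchor are outside the reading frame
    for c in range(raw.frame_anchor - 1):
        keep[c] = False
    if raw.frame_anchor > 1:
        removals.append(
            RemovalRecord("pre_frame", list(range(1, raw.frame_anchor)), "before frame anchor")
        )

    # rules (1) and (2): minority insertion runs
    for run in _insertion_runs(act_rows, raw.n_columns, policy.minor_insertion_fraction):
        run = [c for c in run if keep[c]]
        if not run:
            continue
        carrier_lengths = {
            t: sum(raw.row(t)[c] != "-" for c in run)
            for t in active
            if any(raw.row(t)[c] != "-" for c in run)
        }
        max_len = max(carrier_lengths.values(), default=0)
        rule = "frameshift_insertion" if max_len % 3 != 0 else "lineage_specific_insertion"
        for c in run:
            keep[c] = False
        removals.append(
            RemovalRecord(rule, [c + 1 for c in run], f"carriers={sorted(carrier_lengths)}")
        )

    kept_cols = [c for c in range(raw.n_columns) if keep[c]]
    # trim a trailing partial codon
    trailing = len(kept_cols) % 3
    if trailing:
        removals.append(
            RemovalRecord("trailing_partial_codon", [c + 1 for c in kept_cols[-trailing:]])
        )
        kept_cols = kept_cols[:-trailing]

    # rule (3): remove codon sites with an in-frame stop in any active taxon
    act_idx = [raw.taxa.index(t) for t in active]
    final_cols: list[int] = []
    for s in range(len(kept_cols) // 3):
        triple = kept_cols[3 * s : 3 * s + 3]
        has_stop = False
        for i in act_idx:
            codon = "".join(raw.rows[i][c] for c in triple)
            if code.is_stop(codon):
                has_stop = True
                break
        if has_stop:
            removals.append(
                RemovalRecord("stop_codon_site", [c + 1 for c in triple], f"codon site {s + 1}")
            )
        else:
            final_cols.extend(triple)

    if not final_cols:
        raise DegenerateAlignmentError("cleaning removed every codon site")

    codon_rows = ["".join(raw.row(t)[c] for c in final_cols) for t in active]
    return CodonAlignment(taxa=list(active), codon_rows=codon_rows), removals


def encode_codons(aln: CodonAlignment, code: GeneticCode) -> np.ndarray:
    """Encode a cleaned codon alignment as an (n_taxa, n_sites) int matrix.

    Sense codons map to their index in the fixed lexicographic order of the
    61 sense codons; any triplet containing N or a gap maps to MISSING.  An
    in-frame stop at this stage indicates a cleaning failure and raises.
    """
    out = np.full((len(aln.taxa), aln.n_sites), MISSING, dtype=np.int16)
    idx = {c: i for i, c in enumerate(code.sense_codons)}
    for ti, row in enumerate(aln.codon_rows):
        for s in range(aln.n_sites):
            codon = row[3 * s : 3 * s + 3]
            if any(ch not in NUCLEOTIDES for ch in codon):
                continue  # MISSING
            if code.is_stop(codon):
                raise ValueError(
                    f"in-frame stop {codon} at codon site {s + 1} in taxon "
                    f"{aln.taxa[ti]!r} after cleaning"
                )
            out[ti, s] = idx[codon]
    return out


def decode_codons(matrix: np.ndarray, code: GeneticCode) -> list[str]:
    """Inverse of :func:`encode_codons` on non-MISSING states (NNN otherwise)."""
    rows = []
    for r in matrix:
        rows.append("".join(code.sense_codons[s] if s != MISSING else "NNN" for s in r))
    return rows
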