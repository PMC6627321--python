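"""Sequence and alignment I/O plus the transcript data model.

Coordinate system
-----------------
All positions are 1-based inclusive; position 1 is the transcription start
site (first base of the spliced transcript).  Intron 1 is absent from all
sequences: it exists only as ``intron1_offset``, the last 5'UTR position that
belongs to the before-Intron-1 section.  The main-ORF start (``morf_start``)
is the position of the A of the annotated start codon and, when present,
always equals ``utr5_len + 1``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

GAP = "-"
ALPHABET = set("ACGTN")

GROUPS = (
    "primates",
    "rodents",
    "other_placental",
    "marsupials",
    "platypus",
    "reptiles_birds",
    "coelacanth",
    "rayfinned_a",
    "rayfinned_b",
    "other",
)


class ParseError(ValueError):
    """Malformed sequence, alignment or annotation input."""


class AnnotationError(ValueError):
    """Annotation row violates the transcript invariants."""


def _normalize_seq(raw: str, where: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - ALPHABET
    if bad:
        offender = sorted(bad)[0]
        raise ParseError(f"{where}: invalid character {offender!r} in sequence")
    return seq


@dataclass
class TranscriptRecord:
    """One species' spliced 5'UTR (optionally followed by CDS)."""

    id: str
    seq: str
    species: str = ""
    group: str = "other"
    utr5_len: int | None = None
    intron1_offset: int | None = None
    morf_start: int | None = None
    intron1_len: int | None = None  # genomic intron length, metadata only
    protein_len: int | None = None  # metadata only

    def __post_init__(self) -> None:
        if not self.species:
            self.species = self.id

    # -- sections ---------------------------------------------------------
    @property
    def has_intron(self) -> bool:
        return self.intron1_offset is not None

    def sections(self) -> dict[str, tuple[int, int]]:
        """Named 1-based inclusive 5'UTR section intervals.

        Introned records have ``before`` = [1, intron1_offset] and ``after`` =
        [intron1_offset+1, utr5_len]; intronless records a single ``whole``.
        """
        if self.utr5_len is None:
            raise AnnotationError(f"{self.id}: utr5_len not annotated")
        if self.intron1_offset is None:
            return {"whole": (1, self.utr5_len)}
        return {
            "before": (1, self.intron1_offset),
            "after": (self.intron1_offset + 1, self.utr5_len),
        }

    def section_of(self, pos: int) -> str:
        """Section containing 1-based position ``pos`` (by its first base)."""
        for name, (lo, hi) in self.sections().items():
            if lo <= pos <= hi:
                return name
        raise ValueError(f"{self.id}: position {pos} outside the 5'UTR")

    def utr5_seq(self) -> str:
        if self.utr5_len is None:
            raise AnnotationError(f"{self.id}: utr5_len not annotated")
        return self.seq[: self.utr5_len]

    def validate(self) -> None:
        if self.group not in GROUPS:
            raise AnnotationError(f"{self.id}: unknown group {self.group!r}")
        if self.utr5_len is not None:
            if not 1 <= self.utr5_len <= len(self.seq):
                raise AnnotationError(
                    f"{self.id}: utr5_len {self.utr5_len} outside sequence "
                    f"of length {len(self.seq)}"
                )
        if self.intron1_offset is not None:
            if self.utr5_len is None:
                raise AnnotationError(f"{self.id}: intron1_offset without utr5_len")
            if not 1 <= self.intron1_offset < self.utr5_len:
                raise AnnotationError(
                    f"{self.id}: intron1_offset {self.intron1_offset} must lie "
                    f"in [1, utr5_len) = [1, {self.utr5_len})"
                )
        if self.morf_start is not None:
            if self.utr5_len is not None and self.morf_start != self.utr5_len + 1:
                raise AnnotationError(
                    f"{self.id}: morf_start {self.morf_start} != utr5_len + 1 "
                    f"= {self.utr5_len + 1}"
                )
            codon = self.seq[self.morf_start - 1 : self.morf_start + 2]
            if codon != "ATG":
                raise AnnotationError(
                    f"{self.id}: no ATG at morf_start {self.morf_start} "
                    f"(found {codon!r})"
                )


@dataclass
class AlignmentMatrix:
    """Gapped multiple alignment of 5'UTRs, rows linked to transcripts by id."""

    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ParseError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def nrow(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row_seq(self, row: int) -> str:
        return self.rows[row][1]

    def column(self, col: int) -> str:
        """Characters of 1-based column ``col``, one per row."""
        if not 1 <= col <= self.ncol:
            raise IndexError(f"column {col} outside [1, {self.ncol}]")
        return "".join(s[col - 1] for _, s in self.rows)

    def col_to_seq_map(self, row: int) -> list[int | None]:
        """Per-column 1-based ungapped position (None at gaps) for one row."""
        out: list[int | None] = []
        pos = 0
        for ch in self.rows[row][1]:
            if ch == GAP:
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    def validate_against(self, records: dict[str, TranscriptRecord]) -> None:
        for rid, gapped in self.rows:
            if rid not in records:
                raise ParseError(f"alignment row {rid!r} has no transcript record")
            ungapped = gapped.replace(GAP, "")
            expected = records[rid].utr5_seq()
            if ungapped != expected:
                raise ParseError(
                    f"alignment row {rid!r} does not reproduce the stored "
                    f"5'UTR after removing gaps"
                )


def column_to_seq(aln: AlignmentMatrix, row: int, col: int) -> int | None:
    """Map 1-based alignment column to a 1-based sequence position.

    Returns None when the row carries a gap at that column.
    """
    if not 1 <= col <= aln.ncol:
        raise IndexError(f"column {col} outside [1, {aln.ncol}]")
    prefix = aln.rows[row][1][:col]
    if prefix[-1] == GAP:
        return None
    return len(prefix) - prefix.count(GAP)


# -- FASTA ----------------------------------------------------------------


def read_fasta(path) -> list[TranscriptRecord]:
    """Read FASTA into sequence-only transcript records, keeping file order.

    Sequences are upper-cased and U is normalized to T; RNA input is fine.
    """
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        parsed = list(SeqIO.parse(fh, "fasta"))
    if not parsed:
        raise ParseError(f"{path}: empty or not FASTA")
    for sr in parsed:
        if sr.id in seen:
            raise ParseError(f"{path}: duplicate id {sr.id!r}")
        seen.add(sr.id)
        seq = _normalize_seq(str(sr.seq), f"{path}:{sr.id}")
        records.append(TranscriptRecord(id=sr.id, seq=seq))
    return records


def write_fasta(records, path) -> None:
    srs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(srs, fh, "fasta")


# -- annotations ----------------------------------------------------------

_ANN_COLS = ("id", "group", "utr5_len", "intron1_offset", "morf_start")


def read_annotations(path, records: list[TranscriptRecord]) -> list[TranscriptRecord]:
    """Attach a TSV annotation table to transcript records (in place).

    Required columns: id, group, utr5_len, intron1_offset (may be empty),
    morf_start (may be empty).  Optional: species, intron1_len, protein_len.
    '#' starts a comment line.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _ANN_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    by_id = {r.id: r for r in records}

    def _opt_int(val) -> int | None:
        if val is None or (isinstance(val, float) and pd.isna(val)):
            return None
        s = str(val).strip()
        return int(s) if s else None

    for _, row in df.iterrows():
        rid = str(row["id"])
        if rid not in by_id:
            raise ParseError(f"{path}: annotation for unknown transcript {rid!r}")
        rec = by_id[rid]
        rec.group = str(row["group"]).strip()
        rec.utr5_len = _opt_int(row["utr5_len"])
        rec.intron1_offset = _opt_int(row["intron1_offset"])
        rec.morf_start = _opt_int(row["morf_start"])
        for opt in ("species", "intron1_len", "protein_len"):
            if opt in df.columns:
                val = row[opt]
                if opt == "species":
                    if isinstance(val, str) and val.strip():
                        rec.species = val.strip()
                else:
                    setattr(rec, opt, _opt_int(val))
        rec.validate()
    return records


def write_annotations(records, path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "species": r.species,
                "group": r.group,
                "utr5_len": r.utr5_len,
                "intron1_offset": r.intron1_offset,
                "morf_start": r.morf_start,
                "intron1_len": r.intron1_len,
                "protein_len": r.protein_len,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- alignments -----------------------------------------------------------

_FMT = {"afa": "fasta", "clustal": "clustal"}


def read_alignment(path, fmt: str = "afa", records=None) -> AlignmentMatrix:
    """Read an aligned FASTA ('afa') or Clustal alignment.

    If ``records`` (list or id->record dict) is given, each row is checked to
    ungap back to exactly the stored 5'UTR of the matching transcript.
    """
    if fmt not in _FMT:
        raise ParseError(f"unknown alignment format {fmt!r} (use afa|clustal)")
    try:
        with open(path) as fh:
            aln = AlignIO.read(fh, _FMT[fmt])
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    rows = []
    for sr in aln:
        gapped = str(sr.seq).upper().replace("U", "T")
        bad = set(gapped) - ALPHABET - {GAP}
        if bad:
            raise ParseError(
                f"{path}:{sr.id}: invalid character {sorted(bad)[0]!r}"
            )
        rows.append((sr.id, gapped))
    matrix = AlignmentMatrix(rows)
    if records is not None:
        if not isinstance(records, dict):
            records = {r.id: r for r in records}
        matrix.validate_against(records)
    return matrix


def write_alignment(aln: AlignmentMatrix, path, fmt: str = "afa") -> None:
    if fmt not in _FMT:
        raise ParseError(f"unknown alignment format {fmt!r} (use afa|clustal)")
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.rows]
    )
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, _FMT[fmt])


def alignment_to_string(aln: AlignmentMatrix, fmt: str = "afa") -> str:
    buf = io.StringIO()
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.rows]
    )
    AlignIO.write(msa, buf, _FMT[fmt])
    return buf.getvalue()
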