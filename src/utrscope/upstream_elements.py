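"""Upstream start/stop codon census, uORF calling and Kozak-context logic.

A uORF is an ORF whose start codon lies upstream of the main-ORF start
(sATG).  ORF coordinates are stop-inclusive, so a 111-nt uORF codes for
111/3 - 1 = 36 amino acids.  The gap to the main ORF is
``morf_start - stop_end - 1``: negative values mean the uORF runs past the
sATG (an overlapping uORF).

Start-codon context follows the Kozak convention: *strong* needs a purine
(A/G) at -3 and G at +4, *weak* has neither, *adequate* exactly one; a
context truncated so that -3 or +4 is missing is *undetermined*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .seqio import TranscriptRecord

STOP_CODONS = ("TAA", "TAG", "TGA")
CENSUS_CODONS = ("ATG", "GTG", "CTG", "TTG", "ACG", "TAG", "TAA", "TGA")

CONTEXT_UP = 9  # bases shown upstream of the ATG
CONTEXT_DOWN = 9  # bases shown downstream of the ATG


def scan_codons(seq: str, codon: str) -> list[int]:
    """1-based start positions of every (overlapping) occurrence of a codon."""
    if len(codon) != 3:
        raise ValueError(f"codon must be 3 nt, got {codon!r}")
    codon = codon.upper()
    return [i + 1 for i in range(len(seq) - 2) if seq[i : i + 3] == codon]


@dataclass
class CodonCensus:
    """Per-codon occurrence positions split by 5'UTR section.

    A codon belongs to the section containing its first base; codons whose
    third base would straddle past the 5'UTR end are excluded.  For introned
    records ``whole`` is the union of ``before`` and ``after``.
    """

    positions: dict[str, dict[str, list[int]]]

    def count(self, codon: str, section: str = "whole") -> int:
        return len(self.positions[codon].get(section, []))

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(self.positions)


def census_by_section(
    rec: TranscriptRecord, codons: tuple[str, ...] = CENSUS_CODONS
) -> CodonCensus:
    utr = rec.utr5_seq()
    sections = rec.sections()
    out: dict[str, dict[str, list[int]]] = {}
    for codon in codons:
        hits = scan_codons(utr, codon)  # confined to the 5'UTR by slicing
        per: dict[str, list[int]] = {name: [] for name in sections}
        per.setdefault("whole", [])
        for pos in hits:
            per[rec.section_of(pos)].append(pos)
            if "before" in sections:  # introned: whole = before + after
                per["whole"].append(pos)
        out[codon] = per
    return CodonCensus(out)


@dataclass
class Orf:
    start: int
    stop_end: int
    has_stop: bool

    @property
    def len_nt(self) -> int:
        return self.stop_end - self.start + 1


@dataclass
class OrfConfig:
    start_codons: tuple[str, ...] = ("ATG",)
    min_len_nt: int = 0


def find_orfs(seq: str, cfg: OrfConfig | None = None) -> list[Orf]:
    """All forward-strand ORFs: each start codon extended to the first
    in-frame stop (stop-inclusive coordinates).

    When no in-frame stop exists before the sequence end the ORF is open:
    ``has_stop`` is False and ``stop_end`` is the last full-codon base.
    """
    cfg = cfg or OrfConfig()
    seq = seq.upper()
    orfs: list[Orf] = []
    for start_codon in cfg.start_codons:
        for start in scan_codons(seq, start_codon):
            stop_end = None
            for i in range(start + 2, len(seq) - 2, 3):
                if seq[i : i + 3] in STOP_CODONS:
                    stop_end = i + 3  # 1-based last base of the stop codon
                    break
            if stop_end is not None:
                orf = Orf(start, stop_end, True)
            else:
                n_codons = (len(seq) - start + 1) // 3
                orf = Orf(start, start + 3 * n_codons - 1, False)
            if orf.len_nt >= cfg.min_len_nt:
                orfs.append(orf)
    orfs.sort(key=lambda o: (o.start, o.stop_end))
    return orfs


@dataclass
class UorfRecord:
    """A called upstream ORF with its geometry relative to the main ORF."""

    id: str
    start: int
    stop_end: int
    len_nt: int
    len_aa: int
    peptide: str
    frame_offset: int
    gap_to_morf: int
    overlaps_morf: bool
    has_stop: bool


def uorf_geometry(
    start: int, stop_end: int, morf_start: int, has_stop: bool = True
) -> dict:
    """uORF geometry from coordinates alone (no sequence needed).

    Stop-inclusive length, amino-acid count (len/3 - 1 for a stopped ORF),
    gap to the main ORF (negative = overlap) and frame offset.
    """
    if start >= morf_start:
        raise ValueError(f"start {start} is not upstream of morf_start {morf_start}")
    len_nt = stop_end - start + 1
    return {
        "len_nt": len_nt,
        "len_aa": len_nt // 3 - 1 if has_stop else len_nt // 3,
        "gap_to_morf": morf_start - stop_end - 1,
        "overlaps_morf": stop_end >= morf_start,
        "frame_offset": (start - morf_start) % 3,
    }


def characterize_uorf(rec: TranscriptRecord, orf: Orf) -> UorfRecord:
    """Length, peptide and mORF geometry of an upstream ORF.

    ``gap_to_morf = morf_start - stop_end - 1`` (negative means overlap);
    the peptide excludes the stop codon and uses the standard genetic code.
    """
    if rec.morf_start is None:
        raise ValueError(f"{rec.id}: morf_start not annotated")
    if orf.start >= rec.morf_start:
        raise ValueError(
            f"{rec.id}: ORF at {orf.start} is not upstream of the mORF "
            f"(morf_start {rec.morf_start})"
        )
    geom = uorf_geometry(orf.start, orf.stop_end, rec.morf_start, orf.has_stop)
    coding_end = orf.stop_end - 3 if orf.has_stop else orf.stop_end
    peptide = str(Seq(rec.seq[orf.start - 1 : coding_end]).translate())
    return UorfRecord(
        id=rec.id,
        start=orf.start,
        stop_end=orf.stop_end,
        peptide=peptide,
        has_stop=orf.has_stop,
        **geom,
    )


def call_uorfs(
    rec: TranscriptRecord,
    cfg: OrfConfig | None = None,
    include_open: bool = False,
) -> list[UorfRecord]:
    """uORFs of one transcript: ORFs starting before the annotated sATG."""
    if rec.morf_start is None:
        raise ValueError(f"{rec.id}: morf_start not annotated")
    out = []
    for orf in find_orfs(rec.seq, cfg):
        if orf.start >= rec.morf_start:
            continue
        if not orf.has_stop and not include_open:
            continue
        out.append(characterize_uorf(rec, orf))
    return out


@dataclass
class ContextRecord:
    """Up-to-21-nt start-codon context: 9 upstream + ATG + 9 downstream.

    The window is clipped at the sequence ends, so an ATG close to the 5'
    end yields a shorter window and possibly a missing -3 base.
    """

    window: str
    atg_offset: int  # 0-based index of the A within window
    minus3: str | None
    plus4: str | None
    klass: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.klass:
            self.klass = classify_context(self)


def extract_context(rec_or_seq, atg_pos: int) -> ContextRecord:
    seq = rec_or_seq if isinstance(rec_or_seq, str) else rec_or_seq.seq
    if seq[atg_pos - 1 : atg_pos + 2] != "ATG":
        raise ValueError(f"no ATG at position {atg_pos}")
    lo = max(atg_pos - CONTEXT_UP, 1)
    hi = min(atg_pos + 2 + CONTEXT_DOWN, len(seq))
    window = seq[lo - 1 : hi]
    minus3 = seq[atg_pos - 4] if atg_pos - 3 >= 1 else None
    plus4 = seq[atg_pos + 2] if atg_pos + 3 <= len(seq) else None
    return ContextRecord(window=window, atg_offset=atg_pos - lo, minus3=minus3, plus4=plus4)


def classify_context(ctx: ContextRecord) -> str:
    """strong / adequate / weak / undetermined from the -3 and +4 bases."""
    if ctx.minus3 is None or ctx.plus4 is None:
        return "undetermined"
    purine_m3 = ctx.minus3 in ("A", "G")
    g_p4 = ctx.plus4 == "G"
    if purine_m3 and g_p4:
        return "strong"
    if not purine_m3 and not g_p4:
        return "weak"
    return "adequate"


def context_from_window(window: str) -> ContextRecord:
    """Context record for a pre-extracted window whose ATG sits 9 bases from
    the window end minus 12 (i.e., 9 downstream bases follow the codon).

    Left-truncated windows (shorter than 21) are supported; the ATG is
    located so that exactly 9 bases follow it.
    """
    atg_offset = len(window) - 12
    if window[atg_offset : atg_offset + 3] != "ATG":
        raise ValueError(f"window {window!r} has no ATG at the codon slot")
    minus3 = window[atg_offset - 3] if atg_offset >= 3 else None
    plus4 = window[atg_offset + 3] if atg_offset + 3 < len(window) else None
    return ContextRecord(window=window, atg_offset=atg_offset, minus3=minus3, plus4=plus4)


def codon_at_offset(rec_or_seq, morf_start: int | None, offset_start: int) -> str:
    """Codon occupying [morf_start + offset_start, +2] in sATG-relative
    coordinates, where -1 is the base immediately 5' of the sATG A."""
    seq = rec_or_seq if isinstance(rec_or_seq, str) else rec_or_seq.seq
    if morf_start is None and not isinstance(rec_or_seq, str):
        morf_start = rec_or_seq.morf_start
    if morf_start is None:
        raise ValueError("morf_start not annotated")
    start = morf_start + offset_start
    if start < 1 or start + 2 > len(seq):
        raise ValueError(f"codon window [{start}, {start + 2}] outside sequence")
    return seq[start - 1 : start + 2]


def has_inframe_utga(rec_or_seq, morf_start: int | None = None) -> bool:
    """True when a TGA occupies -9..-7 from the sATG (in frame with it)."""
    return codon_at_offset(rec_or_seq, morf_start, -9) == "TGA"
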