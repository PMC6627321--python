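"""Synthetic ortholog-family generator with known ground truth.

The generator emulates the statistical structure a comparative 5'UTR
analysis assumes for a vertebrate ortholog family:

* phylogenetic groups whose after-Intron-1 section length is constant within
  the group while before-Intron-1 lengths vary (drawn per species);
* a short highly conserved block at the start of the after section carrying
  a single out-of-frame uATG;
* a planted uORF starting at that uATG, with a group-configurable gap to —
  or overlap with — the main ORF;
* section-specific GC targets;
* background substitution, low within-block/uORF substitution, and gaps.

The alignment is *emitted* directly from the consensus rather than computed,
so ground truth (hot-spot columns, uORF coordinates, per-record offsets) is
exact by construction.  Species are i.i.d. around the consensus within their
group; there is no tree-aware evolution.

Substitutions resample the base from the section's target base distribution,
so composition stays stationary (a "substitution" may be silent).  Deletions
and background-rate substitutions never touch the conserved block/uORF
region, whose divergence is governed solely by ``block_sub_rate``; planted
hot-spot columns therefore keep full occupancy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .overlap_stats import VariantSet, merge_intervals
from .seqio import GAP, AlignmentMatrix, TranscriptRecord
from .structure import DotBracket
from .upstream_elements import STOP_CODONS, scan_codons

BASES = np.array(list("ACGT"))


class SpecError(ValueError):
    """Internally inconsistent family specification."""


@dataclass
class GroupSpec:
    label: str
    n_species: int
    after_len: int
    before_len_range: tuple[int, int]
    # gap/overlap between the planted uORF stop and the mORF start;
    # ('gap', k): k nt between the stop and the sATG, ('overlap', k): the
    # uORF stop ends k nt past the sATG.  None falls back to the family-wide
    # relation in UorfSpec.
    relation: tuple[str, int] | None = None


@dataclass
class UorfSpec:
    len_nt: int = 90  # stop-inclusive
    relation: tuple[str, int] = ("gap", 1)


@dataclass
class FamilySpec:
    groups: list[GroupSpec]
    block_seq: str = "CAGTTAATGACCAGC"  # one out-of-frame uATG inside
    block_offset: int = 0  # block start relative to the after-section start
    uorf: UorfSpec = field(default_factory=UorfSpec)
    gc_targets: dict[str, float] = field(
        default_factory=lambda: {"before": 59.0, "after": 67.0}
    )
    sub_rate: float = 0.35
    block_sub_rate: float = 0.02
    indel_rate: float = 0.02
    cds_tail_len: int = 45  # CDS emitted beyond the overlap tail / sATG
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate, self.block_sub_rate, self.indel_rate):
            if not 0 <= rate <= 1:
                raise SpecError(f"rates must lie in [0, 1], got {rate}")
        if len(scan_codons(self.block_seq, "ATG")) != 1:
            raise SpecError("conserved block must contain exactly one ATG")

    @property
    def uatg_in_block(self) -> int:
        """0-based offset of the uATG within the conserved block."""
        return scan_codons(self.block_seq, "ATG")[0] - 1

    @property
    def head_len(self) -> int:
        """Bases of the after section preceding the uATG."""
        return self.block_offset + self.uatg_in_block

    def group_relation(self, g: GroupSpec) -> tuple[str, int]:
        return g.relation if g.relation is not None else self.uorf.relation

    def overlap_of(self, g: GroupSpec) -> int:
        rel, k = self.group_relation(g)
        return k if rel == "overlap" else 0

    def validate(self) -> None:
        if self.uorf.len_nt % 3 != 0 or self.uorf.len_nt < 6:
            raise SpecError("uORF length must be a positive multiple of 3 (>= 6)")
        block_rest = len(self.block_seq) - self.uatg_in_block
        if self.uorf.len_nt == block_rest:
            # uORF fully inside the block: the block itself must end the ORF
            if self.block_seq[-3:] not in STOP_CODONS:
                raise SpecError(
                    "uORF coincides with the block remainder but the block "
                    "does not end with a stop codon"
                )
        elif self.uorf.len_nt < block_rest + 3:
            raise SpecError("uORF shorter than the block remainder plus a stop")
        for g in self.groups:
            rel, k = self.group_relation(g)
            if rel not in ("gap", "overlap") or k < 0:
                raise SpecError(f"{g.label}: bad relation {rel}:{k}")
            if rel == "overlap" and not 6 <= k <= self.uorf.len_nt - block_rest:
                raise SpecError(
                    f"{g.label}: overlap must lie in [6, uORF len - block part]"
                )
            gap = k if rel == "gap" else -k
            required = self.head_len + self.uorf.len_nt + gap
            if g.after_len != required:
                raise SpecError(
                    f"{g.label}: after_len {g.after_len} inconsistent with uORF "
                    f"geometry (block offset + uATG offset + len + gap = {required})"
                )
            # uATG must be out of frame with the sATG
            if (self.head_len - g.after_len) % 3 == 0:
                raise SpecError(f"{g.label}: planted uATG is in frame with the sATG")
            lo, hi = g.before_len_range
            if not 1 <= lo <= hi:
                raise SpecError(f"{g.label}: bad before_len_range {g.before_len_range}")


def abca1_like_family(seed: int = 0, **overrides) -> FamilySpec:
    """Default family: 59 transcripts in vertebrate-style groups with
    group-banded uORF gap/overlap bands and GC-richer after sections."""
    uorf_len = 90
    head = 6  # block_offset 0 + uATG at block offset 6

    def grp(label, n, rel, rng):
        k = rel[1] if rel[0] == "gap" else -rel[1]
        return GroupSpec(label, n, head + uorf_len + k, rng, rel)

    groups = [
        grp("primates", 17, ("overlap", 22), (280, 320)),
        grp("rodents", 16, ("gap", 1), (180, 260)),
        grp("other_placental", 7, ("gap", 7), (200, 280)),
        grp("marsupials", 2, ("gap", 29), (40, 330)),
        grp("platypus", 1, ("gap", 7), (40, 60)),
        grp("reptiles_birds", 4, ("gap", 16), (30, 140)),
        grp("coelacanth", 1, ("gap", 22), (230, 250)),
        grp("rayfinned_a", 5, ("gap", 4), (50, 150)),
        grp("rayfinned_b", 6, ("gap", 4), (50, 150)),
    ]
    kwargs = dict(groups=groups, seed=seed)
    kwargs.update(overrides)
    spec = FamilySpec(**kwargs)
    spec.validate()
    return spec


@dataclass
class RecordTruth:
    """Planted coordinates for one emitted transcript (1-based)."""

    id: str
    group: str
    before_len: int  # realized (post-deletion) before-section length
    after_len: int  # realized after-section length
    uorf_start: int
    uorf_stop_end: int
    morf_start: int
    block_interval: tuple[int, int]
    gc_targets: dict[str, float]


@dataclass
class GroundTruth:
    block_columns: list[int]  # alignment columns of the conserved block
    records: dict[str, RecordTruth]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "block_columns": self.block_columns,
                "records": {rid: asdict(rt) for rid, rt in self.records.items()},
            },
            indent=2,
            sort_keys=True,
        )


def _section_base_probs(gc_pct: float) -> np.ndarray:
    g = gc_pct / 100.0
    return np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A C G T


def _random_bases(rng, n, probs) -> str:
    return "".join(rng.choice(BASES, size=n, p=probs)) if n > 0 else ""


def _consensus_bases(rng, n, probs) -> str:
    """Consensus emission with composition matched to the target exactly
    (rounded counts, random order), so section GC recovery is limited by
    per-record mutation noise rather than by a single consensus draw."""
    if n == 0:
        return ""
    counts = np.floor(probs * n).astype(int)
    while counts.sum() < n:
        counts[int(np.argmax(probs * n - counts))] += 1
    pool = np.repeat(BASES, counts)
    return "".join(rng.permutation(pool))


def _uorf_frame_stop_before_end(uorf_seq: str) -> bool:
    """True when an in-frame stop occurs before the planted terminal stop."""
    for i in range(0, len(uorf_seq) - 3, 3):
        if uorf_seq[i : i + 3] in STOP_CODONS:
            return True
    return False


def _build_uorf_consensus(spec: FamilySpec, rng) -> str:
    """uORF consensus (uATG..stop, stop-inclusive) honoring every overlap
    constraint: for each overlap k used by a group, the bases at offset
    len-k..len-k+2 must read ATG (they double as the sATG of that group).

    Rejection-sampled: candidates are redrawn until no premature in-frame
    stop exists and every imposed ATG survives.
    """
    from_uatg = spec.block_seq[spec.uatg_in_block :]
    if spec.uorf.len_nt == len(from_uatg):
        # the block remainder IS the uORF (its own stop included)
        if _uorf_frame_stop_before_end(from_uatg):
            raise SpecError("block carries a premature in-frame stop")
        return from_uatg
    n_fill = spec.uorf.len_nt - len(from_uatg) - 3
    p_after = _section_base_probs(spec.gc_targets["after"])
    overlaps = sorted({spec.overlap_of(g) for g in spec.groups if spec.overlap_of(g)})
    for _ in range(10_000):
        body = _random_bases(rng, n_fill, p_after)
        cand = list(from_uatg + body + "TGA")
        ok = True
        for k in overlaps:
            at = spec.uorf.len_nt - k  # 0-based patch start within the uORF
            if at < len(from_uatg) or at + 3 > spec.uorf.len_nt - 3:
                ok = False
                break
            cand[at : at + 3] = "ATG"
        if not ok:
            raise SpecError("overlap patch collides with the block or the stop codon")
        cand_s = "".join(cand)
        if _uorf_frame_stop_before_end(cand_s):
            continue
        if scan_codons(cand_s[3:], "ATG") and not overlaps:
            # keep the planted uATG unique within the uORF when no overlap
            # group needs an internal ATG
            continue
        return cand_s
    raise SpecError("could not sample a stop-free uORF consensus")


def generate_family(
    spec: FamilySpec,
) -> tuple[list[TranscriptRecord], AlignmentMatrix, GroundTruth]:
    """Emit records, their alignment, and exact ground truth.

    Deterministic given ``spec.seed``.  Alignment columns: a left-gap-padded
    before region of width max(before_len), then the after region of width
    max(after_len) right-padded with gaps for groups with shorter after
    sections.  The CDS is part of each record's sequence but not of the
    alignment, which covers 5'UTRs only.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p_before = _section_base_probs(spec.gc_targets["before"])
    p_after = _section_base_probs(spec.gc_targets["after"])

    max_before = max(g.before_len_range[1] for g in spec.groups)
    max_after = max(g.after_len for g in spec.groups)
    before_cons_full = _consensus_bases(rng, max_before, p_before)
    spacer_cons = _consensus_bases(rng, spec.block_offset, p_after)
    pre_uorf = spec.block_seq[: spec.uatg_in_block]
    uorf_cons = _build_uorf_consensus(spec, rng)
    cds_tail_cons = _consensus_bases(rng, spec.cds_tail_len, p_after)

    block_cols = list(
        range(
            max_before + spec.block_offset + 1,
            max_before + spec.block_offset + len(spec.block_seq) + 1,
        )
    )

    records: list[TranscriptRecord] = []
    rows: list[tuple[str, str]] = []
    truths: dict[str, RecordTruth] = {}

    for g in spec.groups:
        overlap_k = spec.overlap_of(g)
        utr_uorf_part = uorf_cons[: spec.uorf.len_nt - overlap_k]
        gap_fill_len = g.after_len - spec.head_len - len(utr_uorf_part)
        # the conserved block/uORF content is fixed, so the filler between
        # the uORF stop and the sATG is composition-solved to bring the
        # whole after section onto its GC target
        fixed_part = spacer_cons + pre_uorf + utr_uorf_part
        p_fill = p_after
        if gap_fill_len > 0:
            gc_fixed = sum(1 for c in fixed_part if c in "GC")
            want = spec.gc_targets["after"] / 100.0 * g.after_len - gc_fixed
            fill_gc = min(1.0, max(0.0, want / gap_fill_len))
            p_fill = _section_base_probs(100.0 * fill_gc)
        gap_fill = _consensus_bases(rng, gap_fill_len, p_fill)
        after_cons = fixed_part + gap_fill
        assert len(after_cons) == g.after_len
        if overlap_k:
            # the sATG codon is the imposed ATG inside the uORF tail
            cds_cons = uorf_cons[spec.uorf.len_nt - overlap_k :] + cds_tail_cons
        else:
            cds_cons = "ATG" + cds_tail_cons
        # 0-based span of the conserved region within the after section
        cons_lo = spec.block_offset
        cons_hi = spec.head_len + len(utr_uorf_part)  # exclusive

        for s_idx in range(g.n_species):
            rid = f"{g.label}_{s_idx + 1}"
            before_len = int(
                rng.integers(g.before_len_range[0], g.before_len_range[1] + 1)
            )
            before_cons = before_cons_full[max_before - before_len :]

            seq_chars: list[str] = []
            row_chars: list[str] = [GAP] * (max_before - before_len)
            n_before_kept = 0
            n_kept_pre_uorf_after = 0  # kept after-section bases before uATG

            def emit(base: str, conserved: bool, probs) -> bool:
                """Mutate/delete one consensus base; returns True if kept."""
                if conserved:
                    if rng.random() < spec.block_sub_rate:
                        base = str(rng.choice(BASES, p=probs))
                else:
                    if rng.random() < spec.indel_rate:
                        row_chars.append(GAP)
                        return False
                    if rng.random() < spec.sub_rate:
                        base = str(rng.choice(BASES, p=probs))
                seq_chars.append(base)
                row_chars.append(base)
                return True

            for base in before_cons:
                if emit(base, False, p_before):
                    n_before_kept += 1
            fill_start = spec.head_len + len(utr_uorf_part)
            for idx, base in enumerate(after_cons):
                conserved = cons_lo <= idx < cons_hi
                kept = emit(base, conserved, p_fill if idx >= fill_start else p_after)
                if kept and idx < spec.head_len:
                    n_kept_pre_uorf_after += 1
            row_chars.extend([GAP] * (max_after - g.after_len))

            utr_seq = "".join(seq_chars)
            utr5_len = len(utr_seq)
            # CDS mutates at the conserved (coding) rate; the sATG codon and,
            # for overlap groups, the planted stop codon are never mutated
            protected = {0, 1, 2}
            if overlap_k:
                protected |= {overlap_k - 3, overlap_k - 2, overlap_k - 1}
            cds_chars = []
            for i, base in enumerate(cds_cons):
                if i not in protected and rng.random() < spec.block_sub_rate:
                    base = str(rng.choice(BASES, p=p_after))
                cds_chars.append(base)
            seq = utr_seq + "".join(cds_chars)

            morf_start = utr5_len + 1
            uorf_start = n_before_kept + n_kept_pre_uorf_after + 1
            uorf_stop_end = uorf_start + spec.uorf.len_nt - 1
            rec = TranscriptRecord(
                id=rid,
                seq=seq,
                species=rid,
                group=g.label if g.label in _KNOWN_GROUPS else "other",
                utr5_len=utr5_len,
                intron1_offset=n_before_kept,
                morf_start=morf_start,
            )
            rec.validate()
            records.append(rec)
            rows.append((rid, "".join(row_chars)))
            block_lo = n_before_kept + n_kept_pre_uorf_after - spec.uatg_in_block + 1
            truths[rid] = RecordTruth(
                id=rid,
                group=g.label,
                before_len=n_before_kept,
                after_len=utr5_len - n_before_kept,
                uorf_start=uorf_start,
                uorf_stop_end=uorf_stop_end,
                morf_start=morf_start,
                block_interval=(block_lo, block_lo + len(spec.block_seq) - 1),
                gc_targets=dict(spec.gc_targets),
            )

    aln = AlignmentMatrix(rows)
    truth = GroundTruth(block_columns=block_cols, records=truths, seed=spec.seed)
    return records, aln, truth


_KNOWN_GROUPS = {
    "primates", "rodents", "other_placental", "marsupials", "platypus",
    "reptiles_birds", "coelacanth", "rayfinned_a", "rayfinned_b", "other",
}


def plant_variants(
    rec: TranscriptRecord, hs_intervals, n_total: int, n_inside: int, seed: int = 0
) -> VariantSet:
    """Exactly ``n_inside`` distinct variant positions inside the hot-spot
    intervals and ``n_total - n_inside`` outside, sampled uniformly without
    replacement over [1, utr5_len]."""
    if not 0 <= n_inside <= n_total:
        raise ValueError("need 0 <= n_inside <= n_total")
    if rec.utr5_len is None:
        raise ValueError(f"{rec.id}: utr5_len not annotated")
    merged = merge_intervals(hs_intervals)
    inside_pool = [
        p for lo, hi in merged for p in range(lo, hi + 1) if 1 <= p <= rec.utr5_len
    ]
    inside_set = set(inside_pool)
    outside_pool = [p for p in range(1, rec.utr5_len + 1) if p not in inside_set]
    if n_inside > len(inside_pool):
        raise ValueError(
            f"cannot place {n_inside} variants inside {len(inside_pool)} hot-spot nts"
        )
    if n_total - n_inside > len(outside_pool):
        raise ValueError(
            f"cannot place {n_total - n_inside} variants outside hot spots "
            f"({len(outside_pool)} nts available)"
        )
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(inside_pool, size=n_inside, replace=False)) + list(
        rng.choice(outside_pool, size=n_total - n_inside, replace=False)
    )
    return VariantSet(rec.id, tuple(int(p) for p in chosen))


def plant_stemloops(
    length: int, loops: list[tuple[int, int]], stem_len: int = 3
) -> DotBracket:
    """Dot-bracket structure with exactly one hairpin per requested closing
    pair (i, j), each under a ``stem_len``-deep stem; stems must not overlap.

    The emitted sequence is G/C complementary at the paired positions and A
    elsewhere, so the structure is realizable with canonical pairs.
    """
    struct = ["."] * length
    seq = ["A"] * length
    used: list[tuple[int, int]] = []
    for i, j in loops:
        if j - i - 1 < 1:
            raise ValueError(f"loop ({i}, {j}) has no unpaired interior")
        lo, hi = i - stem_len + 1, j + stem_len - 1
        if lo < 1 or hi > length:
            raise ValueError(f"stem around ({i}, {j}) outside [1, {length}]")
        if any(not (hi < a or lo > b) for a, b in used):
            raise ValueError(f"stem around ({i}, {j}) overlaps another stem")
        used.append((lo, hi))
        for d in range(stem_len):
            struct[i - 1 - d] = "("
            struct[j - 1 + d] = ")"
            seq[i - 1 - d] = "G"
            seq[j - 1 + d] = "C"
    return DotBracket("planted", "".join(seq), "".join(struct))
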