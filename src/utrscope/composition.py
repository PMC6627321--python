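"""GC content and base-repetition-rich subregion segmentation.

GC percent is Count(G+C)/Count(A+T+G+C) x 100; N is excluded from both the
numerator and the denominator.  Section profiles flag transcripts whose
after-Intron-1 section is more than 8 percentage points GC-richer than the
before section, or whose before section leads by more than 14 points.

Segmentation re-casts the qualitative notion of a subregion "rich in
repetitions of a specific base subset" (e.g. G/C-rich, T/C-rich) as a
sliding-window rule: windows whose subset fraction reaches ``fraction_min``
are merged into maximal segments, and overlapping candidates of different
labels are resolved by higher fraction, then smaller subset, then 5'-most
start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import TranscriptRecord

DEFAULT_SUBSETS = ("G/C", "T/C", "G/A", "G/C/A")

AFTER_DOMINANT_PP = 8.0
BEFORE_DOMINANT_PP = 14.0


def gc_percent(seq: str) -> float:
    """GC percentage of a sequence; N bases are ignored entirely."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("no unambiguous bases: GC content undefined")
    return 100.0 * gc / denom


@dataclass
class GcProfile:
    whole_pct: float
    before_pct: float | None
    after_pct: float | None
    diff_after_minus_before: float | None
    after_dominant: bool
    before_dominant: bool


def section_gc(rec: TranscriptRecord) -> GcProfile:
    """GC of the whole 5'UTR and of each section, with dominance flags."""
    utr = rec.utr5_seq()
    whole = gc_percent(utr)
    sections = rec.sections()
    if "before" not in sections:
        return GcProfile(whole, None, None, None, False, False)
    b_lo, b_hi = sections["before"]
    a_lo, a_hi = sections["after"]
    before = gc_percent(utr[b_lo - 1 : b_hi])
    after = gc_percent(utr[a_lo - 1 : a_hi])
    diff = after - before
    return GcProfile(
        whole_pct=whole,
        before_pct=before,
        after_pct=after,
        diff_after_minus_before=diff,
        after_dominant=diff > AFTER_DOMINANT_PP,
        before_dominant=-diff > BEFORE_DOMINANT_PP,
    )


def gc_window_series(seq: str, window: int, step: int = 1) -> list[tuple[float, float]]:
    """Sliding-window GC series as (window center, pct); incomplete tail
    windows are omitted."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(seq):
        raise ValueError("window longer than sequence")
    out = []
    for start in range(0, len(seq) - window + 1, step):
        sub = seq[start : start + window]
        center = start + 1 + (window - 1) / 2
        out.append((center, gc_percent(sub)))
    return out


@dataclass
class Segment:
    """A maximal subregion enriched for a base subset such as G/C or T/C."""

    label: str
    start: int
    end: int
    fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentationConfig:
    window: int = 30
    step: int = 1
    subsets: tuple[str, ...] = DEFAULT_SUBSETS
    fraction_min: float = 0.8
    min_len: int = 20
    merge_gap: int = 5

    def __post_init__(self) -> None:
        for label in self.subsets:
            bases = set(label.split("/"))
            if not bases < set("ACGT") or not 2 <= len(bases) <= 3:
                raise ValueError(
                    f"subset {label!r} must name 2-3 distinct bases from A,C,G,T"
                )


def _subset_fraction(member: np.ndarray, lo: int, hi: int) -> float:
    """Fraction of member bases on the 1-based inclusive interval [lo, hi]."""
    return float(member[lo - 1 : hi].mean())


def _candidate_segments(
    member: np.ndarray, cfg: SegmentationConfig, label: str
) -> list[Segment]:
    n = len(member)
    w = cfg.window
    if n < w:
        return []
    csum = np.concatenate([[0], np.cumsum(member)])
    starts = np.arange(0, n - w + 1, cfg.step)
    frac = (csum[starts + w] - csum[starts]) / w
    hits = starts[frac >= cfg.fraction_min]
    if hits.size == 0:
        return []
    # union of hit windows -> covered intervals (1-based inclusive)
    covered: list[list[int]] = []
    for s in hits:
        lo, hi = int(s) + 1, int(s) + w
        if covered and lo <= covered[-1][1] + 1:
            covered[-1][1] = max(covered[-1][1], hi)
        else:
            covered.append([lo, hi])
    # merge across short gaps, but only when the merged stretch still
    # satisfies fraction_min (keeps the Segment invariant under merging)
    merged: list[list[int]] = [covered[0]]
    for lo, hi in covered[1:]:
        gap = lo - merged[-1][1] - 1
        if gap <= cfg.merge_gap and _subset_fraction(
            member, merged[-1][0], hi
        ) >= cfg.fraction_min:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    segments = []
    for lo, hi in merged:
        lo, hi = _refine_edges(member, lo, hi, cfg)
        if hi - lo + 1 < cfg.min_len:
            continue
        frac_seg = _subset_fraction(member, lo, hi)
        if frac_seg >= cfg.fraction_min:
            segments.append(Segment(label, lo, hi, frac_seg))
    return segments


def _refine_edges(
    member: np.ndarray, lo: int, hi: int, cfg: SegmentationConfig
) -> tuple[int, int]:
    """Pull segment boundaries onto the locally enriched stretch.

    Window blending lets candidate coverage bleed a few bases into the
    flanking background, so the boundary is re-localized as the
    maximal-scoring subsegment of the candidate, scoring member bases
    ``1 - fraction_min`` and non-members ``-fraction_min`` (so any stretch
    with positive score exceeds the threshold fraction).  Ties break toward
    the 5'-most subsegment."""
    scores = member[lo - 1 : hi] - cfg.fraction_min
    best_sum = -1.0
    best = (lo, lo - 1)
    run_sum = 0.0
    run_start = 0
    for i, sc in enumerate(scores):
        if run_sum <= 0:
            run_sum = 0.0
            run_start = i
        run_sum += sc
        if run_sum > best_sum + 1e-12:
            best_sum = run_sum
            best = (lo + run_start, lo + i)
    return best


def segment_repetition_regions(
    seq: str, cfg: SegmentationConfig | None = None
) -> list[Segment]:
    """Non-overlapping base-repetition-rich segments across all subsets.

    Candidates are computed per subset, then greedily retained in order of
    higher fraction, smaller subset, 5'-most start.  N counts against the
    subset fraction but is never a member base.
    """
    cfg = cfg or SegmentationConfig()
    seq = seq.upper()
    candidates: list[Segment] = []
    for label in cfg.subsets:
        bases = set(label.split("/"))
        member = np.array([c in bases for c in seq], dtype=float)
        candidates.extend(_candidate_segments(member, cfg, label))
    candidates.sort(key=lambda s: (-s.fraction, s.label.count("/"), s.start))
    kept: list[Segment] = []
    for cand in candidates:
        if all(cand.end < k.start or cand.start > k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda s: s.start)
    return kept
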