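"""Alignment-column conservation scoring and hot-spot calling.

Two independent per-column scores are used.  *Identity* is the modal
non-gap base count divided by the number of non-gap characters; *occupancy*
is the number of non-gap characters divided by the number of rows.  A column
is a conservation hot spot when it strictly exceeds both thresholds
(defaults: identity > 80%, occupancy > 84%).  Under the 84% occupancy rule a
59-row alignment needs at least 50 non-gap sequences in a column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .seqio import GAP, AlignmentMatrix, column_to_seq

BASES = ("A", "C", "G", "T", "N")


@dataclass
class ColumnProfile:
    col: int
    counts: dict[str, int]
    n_nongap: int
    modal_base: str | None
    identity_pct: float
    occupancy_pct: float


@dataclass
class HotspotConfig:
    """Strict thresholds: a hot-spot column must exceed both percentages."""

    identity_min: float = 80.0
    occupancy_min: float = 84.0

    def __post_init__(self) -> None:
        for name in ("identity_min", "occupancy_min"):
            val = getattr(self, name)
            if not 0 <= val <= 100:
                raise ValueError(f"{name} must lie in [0, 100], got {val}")


@dataclass
class HotspotSet:
    columns: list[int]
    runs: list[tuple[int, int]]
    projections: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.columns)


def profile_columns(aln: AlignmentMatrix) -> list[ColumnProfile]:
    """Per-column base counts with identity and occupancy percentages.

    All-gap columns get identity 0 and occupancy 0 and can never be hot
    spots.  When modal counts tie, the reported modal base is the
    alphabetically first one (display only; identity uses the tied count).
    """
    if aln.nrow == 0:
        raise ValueError("empty alignment")
    profiles = []
    for col in range(1, aln.ncol + 1):
        chars = aln.column(col)
        counts = {b: chars.count(b) for b in BASES}
        n_nongap = sum(counts.values())
        if n_nongap == 0:
            profiles.append(ColumnProfile(col, counts, 0, None, 0.0, 0.0))
            continue
        top = max(counts.values())
        modal = next(b for b in BASES if counts[b] == top)
        profiles.append(
            ColumnProfile(
                col=col,
                counts=counts,
                n_nongap=n_nongap,
                modal_base=modal,
                identity_pct=100.0 * top / n_nongap,
                occupancy_pct=100.0 * n_nongap / aln.nrow,
            )
        )
    return profiles


def min_occupancy_count(n_total: int, threshold_pct: float) -> int:
    """Smallest k with 100*k/n_total strictly greater than threshold_pct."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    k = int(threshold_pct * n_total // 100) + 1
    # integer floor can land one short of strictness at exact multiples
    while 100.0 * (k - 1) / n_total > threshold_pct:
        k -= 1
    return k


def _runs(columns: list[int]) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    for col in columns:
        if runs and col == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], col)
        else:
            runs.append((col, col))
    return runs


def call_hotspots(
    profiles: list[ColumnProfile],
    cfg: HotspotConfig | None = None,
    aln: AlignmentMatrix | None = None,
) -> HotspotSet:
    """Columns strictly exceeding both thresholds, their runs and projections.

    Projections map each maximal run of hot-spot columns onto 1-based
    sequence intervals per transcript, skipping gap columns; runs where a row
    is all gaps contribute no interval for that row.
    """
    cfg = cfg or HotspotConfig()
    columns = [
        p.col
        for p in profiles
        if p.identity_pct > cfg.identity_min and p.occupancy_pct > cfg.occupancy_min
    ]
    runs = _runs(columns)
    projections: dict[str, list[tuple[int, int]]] = {}
    if aln is not None:
        for row, (rid, _) in enumerate(aln.rows):
            intervals = []
            for lo, hi in runs:
                positions = [
                    p
                    for c in range(lo, hi + 1)
                    if (p := column_to_seq(aln, row, c)) is not None
                ]
                if positions:
                    intervals.append((min(positions), max(positions)))
            projections[rid] = intervals
    return HotspotSet(columns=columns, runs=runs, projections=projections)


def longest_hotspot_run(hs: HotspotSet) -> tuple[tuple[int, int] | None, int]:
    """Longest maximal run; ties broken toward the 5'-most run; empty -> 0."""
    best: tuple[int, int] | None = None
    best_len = 0
    for lo, hi in hs.runs:
        if hi - lo + 1 > best_len:
            best, best_len = (lo, hi), hi - lo + 1
    return best, best_len


def hotspots_to_bed(hs: HotspotSet) -> pd.DataFrame:
    """Per-transcript projected intervals as 0-based half-open BED rows."""
    rows = []
    for rid, intervals in hs.projections.items():
        for run_id, (start, end) in enumerate(intervals):
            rows.append(
                {"id": rid, "start": start - 1, "end": end, "run_id": run_id}
            )
    return pd.DataFrame(rows, columns=["id", "start", "end", "run_id"])


def hotspots_to_json(hs: HotspotSet) -> str:
    return json.dumps(
        {
            "columns": hs.columns,
            "runs": [list(r) for r in hs.runs],
            "projections": {
                rid: [list(iv) for iv in ivs] for rid, ivs in hs.projections.items()
            },
        },
        indent=2,
        sort_keys=True,
    )
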