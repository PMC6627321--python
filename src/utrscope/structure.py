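"""Dot-bracket secondary-structure parsing and hairpin-loop analysis.

The module analyzes structures supplied in Vienna (dot-bracket) format —
thermodynamic folding stays external.  A hairpin loop is a base pair (i, j)
enclosing only unpaired bases, with at least one base in the loop.  Hairpins
are assigned to 5'UTR sections by the midpoint of their closing pair; a loop
whose closing pair straddles the section boundary is additionally labelled
spanning but still counts with its midpoint's section in per-section
summaries (midpoint exactly on the boundary counts as before).

``maxpair_fold`` is a Nussinov-style base-pair-maximization folder kept as a
deterministic internal oracle so structure handling can be exercised without
any external prediction tool; it is not an energy model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

from .seqio import TranscriptRecord

_ENERGY_SUFFIX = re.compile(r"\s*\(\s*-?\d+(\.\d+)?\s*\)\s*$")

CANONICAL_PAIRS = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),  # wobble
}


class StructureError(ValueError):
    """Invalid dot-bracket string."""


@dataclass
class DotBracket:
    id: str
    seq: str
    struct: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.struct):
            raise StructureError(
                f"{self.id}: sequence length {len(self.seq)} != structure "
                f"length {len(self.struct)}"
            )
        bad = set(self.struct) - set("().")
        if bad:
            raise StructureError(f"{self.id}: invalid structure character {sorted(bad)[0]!r}")


def pair_table(struct: str) -> dict[int, int]:
    """1-based partner map of a dot-bracket string (both directions).

    Raises on unbalanced brackets; dots are simply absent from the map.
    """
    partners: dict[int, int] = {}
    stack: list[int] = []
    for pos, ch in enumerate(struct, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos}")
            i = stack.pop()
            partners[i] = pos
            partners[pos] = i
        elif ch != ".":
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return partners


@dataclass
class HairpinLoop:
    i: int  # 5' base of the closing pair
    j: int  # 3' base of the closing pair
    section: str = ""  # before / after / whole / spanning
    midpoint_section: str = ""

    @property
    def loop_len(self) -> int:
        return self.j - self.i - 1

    @property
    def midpoint(self) -> int:
        return (self.i + self.j) // 2


def enumerate_hairpins(db: DotBracket) -> list[HairpinLoop]:
    """All hairpin loops: pairs enclosing only unpaired bases, sorted by i."""
    partners = pair_table(db.struct)
    loops = []
    for i, j in partners.items():
        if i > j:
            continue
        if j - i - 1 < 1:
            continue
        if all(k not in partners for k in range(i + 1, j)):
            loops.append(HairpinLoop(i, j))
    loops.sort(key=lambda h: h.i)
    return loops


def count_hairpins_scan(struct: str) -> int:
    """Independent linear-scan hairpin count: ')' whose nearest bracket to
    the left is '(' with at least one dot in between (hairpin loops must
    enclose one or more unpaired bases)."""
    count = 0
    last_bracket = ""
    dots_since = 0
    for ch in struct:
        if ch == ".":
            dots_since += 1
        else:
            if ch == ")" and last_bracket == "(" and dots_since >= 1:
                count += 1
            last_bracket = ch
            dots_since = 0
    return count


def assign_sections(
    loops: list[HairpinLoop], rec: TranscriptRecord
) -> dict[str, int]:
    """Label each loop's section (in place) and return per-section counts.

    The counting section is the one containing the closing-pair midpoint
    floor((i+j)/2); spanning loops keep the 'spanning' label but count with
    their midpoint's section.
    """
    sections = rec.sections()
    counts = {name: 0 for name in sections}
    for loop in loops:
        mid_sec = rec.section_of(loop.midpoint)
        loop.midpoint_section = mid_sec
        start_sec = rec.section_of(loop.i)
        end_sec = rec.section_of(loop.j)
        loop.section = mid_sec if start_sec == end_sec else "spanning"
        counts[mid_sec] += 1
    return counts


# -- Vienna file dialect ----------------------------------------------------


def read_vienna(path) -> list[DotBracket]:
    """Read Vienna records: optional '>' header, sequence line, structure
    line (a trailing parenthesized energy annotation is ignored)."""
    entries: list[DotBracket] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    idx = 0
    n_anonymous = 0
    while idx < len(lines):
        if lines[idx].startswith(">"):
            name = lines[idx][1:].split()[0]
            idx += 1
        else:
            n_anonymous += 1
            name = f"structure_{n_anonymous}"
        if idx + 1 >= len(lines):
            raise StructureError(f"{path}: truncated record {name!r}")
        seq = lines[idx].strip().upper().replace("U", "T")
        struct = _ENERGY_SUFFIX.sub("", lines[idx + 1].strip())
        pair_table(struct)  # validates
        entries.append(DotBracket(name, seq, struct))
        idx += 2
    if not entries:
        raise StructureError(f"{path}: no structures found")
    return entries


def write_vienna(entries: list[DotBracket], path) -> None:
    with open(path, "w") as fh:
        for db in entries:
            fh.write(f">{db.id}\n{db.seq}\n{db.struct}\n")


# -- base-pair-maximization folder (internal oracle) ------------------------


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def maxpair_fold(seq: str, min_loop: int = 3) -> DotBracket:
    """Nussinov maximum base-pair folding over AU/GC/GU pairs (T read as U).

    Hairpin loops must contain at least ``min_loop`` bases.  The traceback is
    deterministic: at each interval the 5' base is paired with the smallest
    admissible partner before being left unpaired.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)
    if n < min_loop + 2:
        raise ValueError(f"sequence shorter than min_loop + 2 = {min_loop + 2}")

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:  # 0-based inclusive interval
        if j - i < min_loop + 1:
            return 0
        score = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(s[i], s[k]):
                score = max(score, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return score

    struct = ["."] * n

    def trace(i: int, j: int) -> None:
        while j - i >= min_loop + 1:
            target = best(i, j)
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(s[i], s[k]) and 1 + best(i + 1, k - 1) + best(k + 1, j) == target:
                    struct[i], struct[k] = "(", ")"
                    trace(i + 1, k - 1)
                    i = k + 1
                    paired = True
                    break
            if not paired:
                i += 1

    trace(0, n - 1)
    best.cache_clear()
    return DotBracket("maxpair", seq.upper(), "".join(struct))
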