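"""Genomic interval primitives shared across modules.

Coordinates are 0-based, half-open throughout (BED convention).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Optional


@dataclass(frozen=True)
class Interval:
    """A genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval", slack: int = 0) -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end + slack
            and other.start < self.end + slack
        )


@dataclass(frozen=True)
class Peak(Interval):
    """A scored interval with an optional summit (absolute coordinate)."""

    summit: Optional[int] = None

    @property
    def center(self) -> int:
        # peak "center" = summit when provided, else midpoint
        if self.summit is not None:
            return self.summit
        return (self.start + self.end) // 2


def merge_intervals(intervals: Iterable[Interval]) -> dict[str, list[tuple[int, int]]]:
    """Merge overlapping/adjacent intervals per chromosome.

    Returns ``{chrom: [(start, end), ...]}`` sorted and disjoint.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((cur_s, cur_e))
        merged[chrom] = out
    return merged


class RegionIndex:
    """Point/interval membership queries against a merged interval set."""

    def __init__(self, intervals: Iterable[Interval]):
        self._merged = merge_intervals(intervals)
        self._starts = {c: [s for s, _ in ivs] for c, ivs in self._merged.items()}
        self._ends = {c: [e for _, e in ivs] for c, ivs in self._merged.items()}

    def contains_point(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any region by >= 1 bp."""
        ends = self._ends.get(chrom)
        if not ends:
            return False
        # regions are sorted and disjoint: the only candidate is the first
        # region ending strictly after `start`
        i = bisect.bisect_right(ends, start)
        return i < len(ends) and self._starts[chrom][i] < end

    def total_length(self, chrom: Optional[str] = None) -> int:
        chroms = [chrom] if chrom is not None else list(self._merged)
        return sum(
            e - s for c in chroms for s, e in self._merged.get(c, [])
        )


def find_overlaps(
    intervals: list[Interval], chrom: str, start: int, end: int, slack: int = 0
) -> list[Interval]:
    """All intervals (not merged) overlapping [start, end) within ``slack``.

    Naive per-chromosome scan; adequate for the motif/feature set sizes used
    here, and trivially correct (it doubles as the oracle in tests).
    """
    return [
        iv
        for iv in intervals
        if iv.chrom == chrom and iv.start < end + slack and start < iv.end + slack
    ]
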