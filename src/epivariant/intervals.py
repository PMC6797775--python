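"""Genomic interval primitives shared by every pipeline stage.

Coordinates are 0-based half-open internally (BED convention); report
writers print 1-based inclusive, publication style. Strand never enters
interval algebra — it only matters when a transcript table is converted
to TSS points upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "merge_intervals",
    "interval_distance",
    "format_region_1based",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def format_region_1based(iv: GenomicInterval) -> str:
    """Render an interval the way reports print it: chrom:start-end, 1-based inclusive."""
    return f"{iv.chrom}:{iv.start + 1}-{iv.end}"


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals: sorted by (chrom, start), disjoint, touching runs merged.

    Touching intervals (end == next start) merge, matching maximal-region
    semantics used for promoter construction. IDs are dropped: a merged
    region no longer corresponds to a single input.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def interval_distance(iv: GenomicInterval, pos: int) -> int:
    """Distance in bp from a point to an interval; 0 if the point lies inside."""
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - iv.end + 1
    return 0


@dataclass
class CoverageTrack:
    """Per-chromosome step function: disjoint sorted intervals with values.

    Gaps have value 0. Backed by numpy arrays so interval sums are a pair
    of searchsorted calls plus a prefix-sum lookup.
    """

    _starts: Dict[str, np.ndarray] = field(default_factory=dict)
    _ends: Dict[str, np.ndarray] = field(default_factory=dict)
    _values: Dict[str, np.ndarray] = field(default_factory=dict)
    _cum: Dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        """Build from (chrom, start, end, value) records; overlaps are rejected."""
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if end <= start or start < 0:
                raise ValueError(f"bad coverage record {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        track = cls()
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
                raise ValueError(
                    f"overlapping coverage records on {chrom} near position {starts[i + 1]}"
                )
            track._starts[chrom] = starts
            track._ends[chrom] = ends
            track._values[chrom] = values
            # prefix sums of per-record mass (value * width) for O(log n) queries
            track._cum[chrom] = np.concatenate(
                [[0.0], np.cumsum(values * (ends - starts))]
            )
        return track

    @property
    def chroms(self) -> Sequence[str]:
        return list(self._starts)

    def sum_over(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end); 0 where nothing is recorded."""
        if end <= start:
            raise ValueError("query interval must be non-empty")
        if chrom not in self._starts:
            return 0.0
        starts, ends, values, cum = (
            self._starts[chrom],
            self._ends[chrom],
            self._values[chrom],
            self._cum[chrom],
        )
        # records fully inside the query, plus clipped partial records at both edges
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        total = float(cum[hi] - cum[lo])
        if starts[lo] < start:
            total -= float(values[lo]) * (start - starts[lo])
        if ends[hi - 1] > end:
            total -= float(values[hi - 1]) * (ends[hi - 1] - end)
        return total

    def sum_over_interval(self, iv: GenomicInterval) -> float:
        return self.sum_over(iv.chrom, iv.start, iv.end)
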