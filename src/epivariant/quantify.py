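"""Promoter-anchored normalization and per-peak coverage quantification.

The sequencing-depth model is promoter-anchored: for each sample, reads
falling inside a merged set of promoter windows (4 kbp around every TSS
by default) are tallied, the tally is divided by 1e7, and per-base
coverage is divided by the resulting factor. A peak's normalized coverage
q is the sum of normalized per-base coverage across its bases. Dividing by
the promoter tally makes q invariant to library size: scaling a sample's
raw coverage and its tally by the same constant leaves q unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import CoverageTrack, GenomicInterval, merge_intervals
from .io import AnnotationIndex, TssRecord

__all__ = [
    "PromoterSet",
    "NormalizationFactor",
    "build_promoter_set",
    "normalization_factor",
    "quantify_peaks",
    "mapq_fraction",
    "build_peak_matrix",
]

logger = logging.getLogger(__name__)

SCALE = 1e7  # promoter read tally divisor

LOW_MAPQ = 10  # reads below this MAPQ count toward the mappability-artifact fraction


@dataclass
class PromoterSet:
    """Merged promoter windows (disjoint, sorted) with the half-width used."""

    intervals: List[GenomicInterval]
    half_window: int

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        for iv in self.intervals:  # small sets only; bulk queries use numpy below
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return True
        return False


@dataclass(frozen=True)
class NormalizationFactor:
    """Per-sample depth factor s = promoter read tally / 1e7.

    The tally is a read count in practice, but any positive value is
    accepted so that rescaled or averaged tallies keep the factor exact.
    """

    sample_id: str
    tally: float

    def __post_init__(self) -> None:
        if self.tally <= 0:
            raise ValueError(
                f"empty promoter tally for sample {self.sample_id!r}: "
                "normalization undefined"
            )

    @property
    def s(self) -> float:
        return self.tally / SCALE


def build_promoter_set(
    tss_records: Sequence[TssRecord] | AnnotationIndex, half_window: int = 2000
) -> PromoterSet:
    """Windows of +/- half_window around every TSS, clipped at 0 and merged."""
    if isinstance(tss_records, AnnotationIndex):
        tss_records = tss_records.records
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    if not tss_records:
        raise ValueError("empty TSS table: promoter set (and normalization) undefined")
    windows = [
        GenomicInterval(r.chrom, max(0, r.pos - half_window), r.pos + half_window)
        for r in tss_records
    ]
    return PromoterSet(merge_intervals(windows), half_window)


def normalization_factor(
    source: int | Iterable[tuple[str, int]],
    promoter_set: PromoterSet | None = None,
    sample_id: str = "",
) -> NormalizationFactor:
    """Depth factor from a precomputed tally or from read 5' positions.

    A read counts toward the tally when its 5' mapped position (chrom, pos)
    lies inside the merged promoter set. Users with their own counting
    convention should pass the integer tally directly.
    """
    if isinstance(source, (int, float, np.integer, np.floating)):
        return NormalizationFactor(sample_id, float(source))
    if promoter_set is None:
        raise ValueError("promoter_set required when counting read positions")
    by_chrom: Dict[str, List[int]] = {}
    for chrom, pos in source:
        by_chrom.setdefault(chrom, []).append(pos)
    starts: Dict[str, np.ndarray] = {}
    ends: Dict[str, np.ndarray] = {}
    for iv in promoter_set.intervals:
        starts.setdefault(iv.chrom, [])
        ends.setdefault(iv.chrom, [])
    for iv in promoter_set.intervals:
        starts[iv.chrom].append(iv.start)
        ends[iv.chrom].append(iv.end)
    tally = 0
    for chrom, positions in by_chrom.items():
        if chrom not in starts:
            continue
        s = np.asarray(starts[chrom])
        e = np.asarray(ends[chrom])
        pos = np.asarray(positions)
        # promoter intervals are disjoint and sorted: a position is inside iff
        # the nearest interval starting at or before it has not yet ended
        idx = np.searchsorted(s, pos, side="right") - 1
        inside = (idx >= 0) & (pos < e[np.clip(idx, 0, None)])
        tally += int(inside.sum())
    return NormalizationFactor(sample_id, tally)


def quantify_peaks(
    coverage: CoverageTrack,
    peaks: Sequence[GenomicInterval],
    factor: NormalizationFactor,
) -> np.ndarray:
    """One sample's normalized-coverage column: q_i = (sum of raw per-base coverage) / s."""
    s = factor.s
    q = np.empty(len(peaks), dtype=np.float64)
    missing = set()
    for i, peak in enumerate(peaks):
        if peak.chrom not in coverage.chroms:
            missing.add(peak.chrom)
            q[i] = 0.0
        else:
            q[i] = coverage.sum_over_interval(peak) / s
    if missing:
        logger.warning(
            "sample %s: no coverage on chromosome(s) %s; affected peaks set to 0",
            factor.sample_id,
            ", ".join(sorted(missing)),
        )
    return q


def mapq_fraction(
    read_mapqs_by_peak: Mapping[str, Sequence[int]],
) -> pd.Series:
    """Per-peak fraction of reads with MAPQ < 10, pooled over all samples.

    Peaks with zero reads get NaN (missing); the mappability filter treats
    missing as not-excludable.
    """
    out = {}
    for peak_id, mapqs in read_mapqs_by_peak.items():
        arr = np.asarray(list(mapqs))
        if arr.size and (arr < 0).any():
            raise ValueError(f"negative MAPQ for peak {peak_id!r}")
        out[peak_id] = float((arr < LOW_MAPQ).sum() / arr.size) if arr.size else np.nan
    return pd.Series(out, dtype=float, name="low_mapq_fraction")


def build_peak_matrix(
    tracks: Mapping[str, CoverageTrack],
    peaks: Sequence[GenomicInterval],
    factors: Mapping[str, NormalizationFactor],
    sample_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the peaks x samples normalized-coverage matrix."""
    samples = list(sample_order) if sample_order is not None else list(tracks)
    missing = [s for s in samples if s not in tracks or s not in factors]
    if missing:
        raise ValueError(f"no coverage/factor for samples: {missing}")
    data = {s: quantify_peaks(tracks[s], peaks, factors[s]) for s in samples}
    index = [p.id if p.id is not None else f"peak_{i + 1}" for i, p in enumerate(peaks)]
    return pd.DataFrame(data, index=pd.Index(index, name="peak_id"), columns=samples)
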