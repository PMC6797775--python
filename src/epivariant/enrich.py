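"""Peak-to-gene annotation and one-tailed Fisher enrichment machinery.

Peaks link to a gene when any of the gene's TSSs lies within 2 kb of the
peak (distance 0 inside). Each peak falls in exactly one category:
protein_coding when at least one linked transcript is protein coding
(dominance rule), noncoding when linked only to non-coding transcripts,
unannotated when no TSS is near. Enrichment of a foreground peak or gene
set against a background uses the hypergeometric upper tail (one-tailed
Fisher exact test, enrichment direction), with Bonferroni or
Benjamini-Hochberg adjustment across a battery of tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .detect import DetectionThresholds
from .intervals import GenomicInterval, merge_intervals
from .io import AnnotationIndex, GeneSet, GwasVariant

__all__ = [
    "PeakAnnotation",
    "ContingencyResult",
    "RegionSet",
    "annotate_peaks",
    "enrichment_tail_p",
    "fisher_one_tailed",
    "bonferroni_adjust",
    "bh_adjust",
    "category_enrichment",
    "build_region_set",
    "peaks_overlapping",
    "region_overlap_test",
    "gene_overlap_test",
    "run_test_battery",
    "run_ora",
    "results_table",
]

logger = logging.getLogger(__name__)

CATEGORY_PROTEIN_CODING = "protein_coding"
CATEGORY_NONCODING = "noncoding"
CATEGORY_UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class PeakAnnotation:
    peak_id: str
    linked_genes: frozenset
    category: str


@dataclass
class ContingencyResult:
    """A 2x2 enrichment test: a, b = foreground in/out of category; c, d = rest."""

    test_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float  # NaN when 0/0
    p: float
    p_adjusted: float = float("nan")
    method: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def significant(self) -> bool:
        return bool(self.p_adjusted < 0.05)


@dataclass
class RegionSet:
    """Merged flanked regions around variants passing a p-value threshold."""

    name: str
    intervals: List[GenomicInterval]

    def __len__(self) -> int:
        return len(self.intervals)


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    tss_index: AnnotationIndex,
    gene_link_dist: int = 2000,
) -> List[PeakAnnotation]:
    """Link each peak to genes with a TSS strictly within gene_link_dist bp."""
    if len(tss_index) == 0:
        raise ValueError("empty TSS index")
    annotations = []
    for i, peak in enumerate(peaks):
        peak_id = peak.id if peak.id is not None else f"peak_{i + 1}"
        hits = tss_index.near_interval(peak, gene_link_dist)
        genes = frozenset(h.gene_id for h in hits)
        if not hits:
            category = CATEGORY_UNANNOTATED
        elif any(h.is_protein_coding for h in hits):
            category = CATEGORY_PROTEIN_CODING
        else:
            category = CATEGORY_NONCODING
        annotations.append(PeakAnnotation(peak_id, genes, category))
    return annotations


def enrichment_tail_p(a, N, K, n):
    """Upper-tail hypergeometric probability P(X >= a); accepts arrays."""
    return hypergeom.sf(np.asarray(a) - 1, N, K, n)


def fisher_one_tailed(a: int, b: int, c: int, d: int, test_name: str = "") -> ContingencyResult:
    """One-tailed Fisher exact test for enrichment: P(X >= a) given the margins.

    X is hypergeometric with population N = a+b+c+d, K = a+c category
    successes and n = a+b foreground draws. The odds ratio is (a*d)/(b*c),
    reported missing (NaN) for 0/0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    N, K, n = a + b + c + d, a + c, a + b
    p = float(enrichment_tail_p(a, N, K, n)) if N > 0 else 1.0
    p = min(p, 1.0)
    num, den = a * d, b * c
    odds = float("nan") if num == 0 and den == 0 else (math.inf if den == 0 else num / den)
    return ContingencyResult(test_name, a, b, c, d, odds, p)


def bonferroni_adjust(results: Sequence[ContingencyResult]) -> List[ContingencyResult]:
    m = len(results)
    for r in results:
        r.p_adjusted = min(1.0, m * r.p)
        r.method = "bonferroni"
    return list(results)


def bh_adjust(results: Sequence[ContingencyResult]) -> List[ContingencyResult]:
    if not results:
        return []
    _, q, _, _ = multipletests([r.p for r in results], method="fdr_bh")
    for r, qv in zip(results, q):
        r.p_adjusted = float(qv)
        r.method = "bh"
    return list(results)


def category_enrichment(
    annotations: Sequence[PeakAnnotation],
    altered_peak_ids: Iterable[str],
    categories: Sequence[str] | None = None,
    include_annotated_union: bool = True,
) -> List[ContingencyResult]:
    """Per-category enrichment of altered peaks, Bonferroni over the rows tested.

    Background is the full annotated peak catalog. The union row
    "annotated" (protein_coding + noncoding) is emitted alongside the
    per-category rows by default; the Bonferroni factor is the number of
    rows actually tested (logged).
    """
    altered = set(altered_peak_ids)
    if not altered:
        raise ValueError("altered peak set is empty")
    universe = {ann.peak_id for ann in annotations}
    stray = altered - universe
    if stray:
        raise ValueError(f"altered peaks missing from the catalog: {sorted(stray)[:5]}")
    if categories is None:
        categories = [CATEGORY_PROTEIN_CODING, CATEGORY_NONCODING, CATEGORY_UNANNOTATED]
    members: Dict[str, Set[str]] = {cat: set() for cat in categories}
    annotated_union: Set[str] = set()
    for ann in annotations:
        if ann.category in members:
            members[ann.category].add(ann.peak_id)
        if ann.category != CATEGORY_UNANNOTATED:
            annotated_union.add(ann.peak_id)
    rows: List[Tuple[str, Set[str]]] = []
    if include_annotated_union:
        rows.append(("annotated", annotated_union))
    rows.extend((cat, members[cat]) for cat in categories)
    results = []
    N = len(universe)
    for name, cat_set in rows:
        a = len(altered & cat_set)
        b = len(altered) - a
        c = len(cat_set) - a
        d = N - a - b - c
        results.append(fisher_one_tailed(a, b, c, d, test_name=name))
    logger.info("category enrichment: %d rows, Bonferroni m=%d", len(rows), len(rows))
    return bonferroni_adjust(results)


def build_region_set(
    variants: Sequence[GwasVariant],
    p_threshold: float,
    flank: int = 100_000,
    name: str = "regions",
) -> RegionSet:
    """Merged regions around variants with p < threshold, +/- flank bp each side."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    passing = [v for v in variants if v.pvalue < p_threshold]
    windows = [
        GenomicInterval(v.chrom, max(0, v.pos - flank), v.pos + flank + 1)
        for v in passing
    ]
    return RegionSet(name, merge_intervals(windows) if windows else [])


def peaks_overlapping(
    peaks: Sequence[GenomicInterval], regions: Sequence[GenomicInterval]
) -> Set[str]:
    """IDs of peaks sharing >= 1 base with any region (regions need not be disjoint)."""
    merged = merge_intervals(regions) if regions else []
    starts: Dict[str, np.ndarray] = {}
    ends: Dict[str, np.ndarray] = {}
    for iv in merged:
        starts.setdefault(iv.chrom, []).append(iv.start)
        ends.setdefault(iv.chrom, []).append(iv.end)
    starts = {c: np.asarray(v) for c, v in starts.items()}
    ends = {c: np.asarray(v) for c, v in ends.items()}
    hits: Set[str] = set()
    for i, peak in enumerate(peaks):
        if peak.chrom not in starts:
            continue
        s, e = starts[peak.chrom], ends[peak.chrom]
        # overlap iff some region starts before peak end and ends after peak start
        k = int(np.searchsorted(s, peak.end, side="left"))
        if k > 0 and e[k - 1] > peak.start:
            hits.add(peak.id if peak.id is not None else f"peak_{i + 1}")
    return hits


def region_overlap_test(
    peak_catalog: Sequence[GenomicInterval],
    altered_ids: Iterable[str],
    significant_regions: RegionSet,
    background_regions: RegionSet,
    test_name: str = "region_overlap",
) -> ContingencyResult:
    """Do altered peaks overlap the significant regions more than expected?

    The universe is restricted to catalog peaks overlapping the background
    regions (e.g. flanked windows around *all* variants the source study
    tested); within it, the 2x2 crosses altered/not with overlapping the
    significant regions or not.
    """
    universe = peaks_overlapping(peak_catalog, background_regions.intervals)
    if not universe:
        raise ValueError("no catalog peak overlaps the background regions")
    sig = peaks_overlapping(peak_catalog, significant_regions.intervals) & universe
    altered = set(altered_ids) & universe
    a = len(altered & sig)
    b = len(altered) - a
    c = len(sig) - a
    d = len(universe) - a - b - c
    return fisher_one_tailed(a, b, c, d, test_name=test_name)


def gene_overlap_test(
    altered_genes: Iterable[str],
    reported_genes: Iterable[str],
    background_genes: Iterable[str],
    test_name: str = "gene_overlap",
) -> ContingencyResult:
    """Fisher overlap of epigenetically altered genes with a reported gene list."""
    background = set(background_genes)
    if not background:
        raise ValueError("empty gene background")
    altered = set(altered_genes) & background
    reported = set(reported_genes)
    dropped = reported - background
    if dropped:
        logger.warning(
            "%d reported gene(s) absent from background dropped (e.g. %s)",
            len(dropped),
            sorted(dropped)[:3],
        )
        reported &= background
    a = len(altered & reported)
    b = len(altered) - a
    c = len(reported) - a
    d = len(background) - a - b - c
    return fisher_one_tailed(a, b, c, d, test_name=test_name)


def run_test_battery(results: Sequence[ContingencyResult]) -> List[ContingencyResult]:
    """BH-FDR across one dataset's battery (canonically six tests: up/down/all
    peaks for each of two case subgroups); significance at q < 0.05."""
    return bh_adjust(list(results))


def run_ora(
    gene_list: Iterable[str],
    gene_sets: Sequence[GeneSet],
    background_genes: Iterable[str],
) -> List[ContingencyResult]:
    """Over-representation analysis of a gene list against GMT sets.

    One Fisher test per set against the supplied background, BH-FDR across
    all sets, sorted by adjusted p then name.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    background = set(background_genes)
    outside = genes - background
    if outside:
        logger.warning(
            "%d query gene(s) outside background dropped", len(outside)
        )
        genes &= background
    results = []
    for gs in gene_sets:
        members = gs.genes & background
        a = len(genes & members)
        b = len(genes) - a
        c = len(members) - a
        d = len(background) - a - b - c
        results.append(fisher_one_tailed(a, b, c, d, test_name=gs.name))
    bh_adjust(results)
    results.sort(key=lambda r: (r.p_adjusted, r.p, r.test_name))
    return results


def results_table(results: Sequence[ContingencyResult]) -> pd.DataFrame:
    """Flatten results for the enrichment TSV writer."""
    return pd.DataFrame(
        [
            {
                "test_name": r.test_name,
                "a": r.a,
                "b": r.b,
                "c": r.c,
                "d": r.d,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "method": r.method,
                "significant_flag": r.significant,
            }
            for r in results
        ]
    )
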