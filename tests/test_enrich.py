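import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from epivariant.enrich import (
    ContingencyResult,
    annotate_peaks,
    bh_adjust,
    bonferroni_adjust,
    build_region_set,
    category_enrichment,
    fisher_one_tailed,
    gene_overlap_test,
    peaks_overlapping,
    region_overlap_test,
    run_ora,
    run_test_battery,
)
from epivariant.intervals import GenomicInterval
from epivariant.io import AnnotationIndex, GeneSet, GwasVariant, TssRecord


def tss(gene, pos, biotype="protein_coding", chrom="chr1"):
    return TssRecord(gene, f"T_{gene}_{pos}", biotype, chrom, pos, "+")


class TestAnnotatePeaks:
    def test_tss_inside_peak_links(self):
        index = AnnotationIndex([tss("G1", 1500)])
        [ann] = annotate_peaks([GenomicInterval("chr1", 1000, 2000, "p1")], index)
        assert ann.linked_genes == {"G1"}
        assert ann.category == "protein_coding"

    def test_distance_just_under_2kb_links(self):
        index = AnnotationIndex([tss("G1", 3500)])  # distance 1501 from [1000, 2000)
        [ann] = annotate_peaks([GenomicInterval("chr1", 1000, 2000, "p1")], index)
        assert ann.linked_genes == {"G1"}

    def test_distance_2kb_or_more_does_not_link(self):
        index = AnnotationIndex([tss("G1", 3999)])  # distance exactly 2000
        [ann] = annotate_peaks([GenomicInterval("chr1", 1000, 2000, "p1")], index)
        assert ann.category == "unannotated"

    def test_noncoding_only_category(self):
        index = AnnotationIndex([tss("G1", 1500, biotype="lincRNA")])
        [ann] = annotate_peaks([GenomicInterval("chr1", 1000, 2000, "p1")], index)
        assert ann.category == "noncoding"

    def test_protein_coding_dominates(self):
        index = AnnotationIndex([tss("G1", 1500, biotype="lincRNA"),
                                 tss("G2", 1600)])
        [ann] = annotate_peaks([GenomicInterval("chr1", 1000, 2000, "p1")], index)
        assert ann.category == "protein_coding"

    def test_categories_partition_catalog(self):
        rng = np.random.default_rng(1)
        peaks = [GenomicInterval("chr1", 10_000 * i, 10_000 * i + 1000, f"p{i}")
                 for i in range(50)]
        records = []
        for i in rng.choice(50, size=30, replace=False):
            biotype = "protein_coding" if i % 2 else "lincRNA"
            records.append(tss(f"G{i}", 10_000 * int(i) + 500, biotype=biotype))
        anns = annotate_peaks(peaks, AnnotationIndex(records))
        cats = [a.category for a in anns]
        assert len(cats) == 50
        assert sum(c == "protein_coding" for c in cats) + \
            sum(c == "noncoding" for c in cats) + \
            sum(c == "unannotated" for c in cats) == 50


class TestFisherOneTailed:
    def test_full_enumeration_example(self):
        # N=10, K=5, n=4: P(X >= 4) = C(5,4)C(5,0)/C(10,4) = 5/210
        r = fisher_one_tailed(4, 0, 1, 5)
        assert r.p == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        assert fisher_one_tailed(0, 10, 5, 85).p == pytest.approx(1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_tailed(-1, 2, 3, 4)

    def test_odds_ratio_conventions(self):
        assert fisher_one_tailed(1, 2, 4, 2).odds_ratio == pytest.approx(0.25)
        assert math.isnan(fisher_one_tailed(0, 3, 0, 4).odds_ratio)
        assert math.isinf(fisher_one_tailed(2, 3, 0, 6).odds_ratio)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_scipy_fisher_greater(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        mine = fisher_one_tailed(a, b, c, d).p
        _, ref = fisher_exact([[a, b], [c, d]], alternative="greater")
        assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)


class TestAdjustments:
    def test_bonferroni_exact(self):
        results = [fisher_one_tailed(4, 0, 1, 5) for _ in range(4)]
        bonferroni_adjust(results)
        for r in results:
            assert r.p_adjusted == pytest.approx(min(1.0, 4 * r.p))
            assert r.method == "bonferroni"

    def test_bh_ties(self):
        results = [ContingencyResult(f"t{i}", 1, 1, 1, 1, 1.0, 0.01)
                   for i in range(6)]
        run_test_battery(results)
        for r in results:
            assert r.p_adjusted == pytest.approx(0.01)
            assert r.significant

    def test_bh_matches_step_up_formula(self):
        rng = np.random.default_rng(3)
        ps = sorted(rng.uniform(0, 1, size=20))
        results = [ContingencyResult(f"t{i}", 1, 1, 1, 1, 1.0, p)
                   for i, p in enumerate(ps)]
        bh_adjust(results)
        m = len(ps)
        oracle = [p * m / (i + 1) for i, p in enumerate(ps)]
        for i in range(m - 2, -1, -1):
            oracle[i] = min(oracle[i], oracle[i + 1])
        oracle = [min(1.0, q) for q in oracle]
        for r, q in zip(results, oracle):
            assert r.p_adjusted == pytest.approx(q, rel=1e-12)

    def test_bh_qvalues_monotone_in_p_rank(self):
        rng = np.random.default_rng(8)
        ps = rng.uniform(0, 1, size=15)
        results = [ContingencyResult(f"t{i}", 1, 1, 1, 1, 1.0, p)
                   for i, p in enumerate(ps)]
        bh_adjust(results)
        ordered = sorted(results, key=lambda r: r.p)
        qs = [r.p_adjusted for r in ordered]
        assert qs == sorted(qs)


class TestCategoryEnrichment:
    def _fixture(self):
        peaks = [GenomicInterval("chr1", 10_000 * i, 10_000 * i + 1000, f"p{i}")
                 for i in range(40)]
        records = []
        for i in range(15):
            records.append(tss(f"G{i}", 10_000 * i + 500))
        for i in range(15, 25):
            records.append(tss(f"G{i}", 10_000 * i + 500, biotype="lincRNA"))
        return peaks, annotate_peaks(peaks, AnnotationIndex(records))

    def test_counts_and_composition(self):
        peaks, anns = self._fixture()
        altered = [f"p{i}" for i in range(0, 30, 3)]
        rows = category_enrichment(anns, altered)
        by_name = {r.test_name: r for r in rows}
        # compositional oracle: each row equals a direct Fisher call
        for name, members in [
            ("protein_coding", {f"p{i}" for i in range(15)}),
            ("noncoding", {f"p{i}" for i in range(15, 25)}),
            ("unannotated", {f"p{i}" for i in range(25, 40)}),
            ("annotated", {f"p{i}" for i in range(25)}),
        ]:
            a = len(set(altered) & members)
            b = len(altered) - a
            c = len(members) - a
            d = 40 - a - b - c
            direct = fisher_one_tailed(a, b, c, d)
            row = by_name[name]
            assert (row.a, row.b, row.c, row.d) == (a, b, c, d)
            assert row.p == pytest.approx(direct.p, rel=1e-12)
            assert row.p_adjusted == pytest.approx(min(1.0, len(rows) * direct.p))

    def test_all_peaks_altered_no_enrichment(self):
        peaks, anns = self._fixture()
        rows = category_enrichment(anns, [a.peak_id for a in anns])
        assert all(r.p == pytest.approx(1.0) for r in rows)

    def test_empty_altered_set_rejected(self):
        peaks, anns = self._fixture()
        with pytest.raises(ValueError, match="empty"):
            category_enrichment(anns, [])


class TestRegionSets:
    def test_nearby_variants_merge_into_one_region(self):
        variants = [GwasVariant("rs1", "chr1", 1_000_000, 1e-9),
                    GwasVariant("rs2", "chr1", 1_150_000, 1e-9)]
        rs = build_region_set(variants, 5e-8, flank=100_000)
        assert [(iv.start, iv.end) for iv in rs.intervals] == [(900_000, 1_250_001)]

    def test_no_passing_variants_empty(self):
        variants = [GwasVariant("rs1", "chr1", 100, 0.5)]
        assert len(build_region_set(variants, 5e-8)) == 0

    def test_suggestive_threshold_covers_significant_regions(self):
        rng = np.random.default_rng(4)
        variants = [GwasVariant(f"rs{i}", "chr1", int(pos), float(p))
                    for i, (pos, p) in enumerate(zip(
                        rng.integers(0, 10_000_000, 50),
                        10 ** rng.uniform(-12, 0, 50)))]
        strict = build_region_set(variants, 5e-8)
        loose = build_region_set(variants, 1e-6)
        for iv in strict.intervals:
            assert any(o.start <= iv.start and iv.end <= o.end
                       for o in loose.intervals)


class TestRegionOverlapTest:
    def _catalog(self):
        return [GenomicInterval("chr1", 100_000 * i, 100_000 * i + 2000, f"p{i}")
                for i in range(30)]

    def test_category_equal_universe_gives_p_one(self):
        peaks = self._catalog()
        variants = [GwasVariant(f"rs{i}", "chr1", 100_000 * i + 1000, 1e-9)
                    for i in range(10)]
        regions = build_region_set(variants, 5e-8, flank=500)
        res = region_overlap_test(peaks, [f"p{i}" for i in range(3)], regions, regions)
        assert res.p == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        peaks = self._catalog()
        sig = build_region_set([GwasVariant("rs1", "chr1", 100_000 * 5 + 1000, 1e-9)],
                               5e-8, flank=500, name="sig")
        bg_vars = [GwasVariant(f"rs{i}", "chr1", 100_000 * i + 1000, 1e-9)
                   for i in range(20)]
        bg = build_region_set(bg_vars, 1.0, flank=500, name="bg")
        res = region_overlap_test(peaks, ["p1", "p2"], sig, bg)
        assert res.a == 0
        assert res.p == pytest.approx(1.0)

    def test_counts_match_brute_force_recount(self):
        rng = np.random.default_rng(6)
        peaks = self._catalog()
        variants = [GwasVariant(f"rs{i}", "chr1", int(pos), float(p))
                    for i, (pos, p) in enumerate(zip(
                        rng.integers(0, 3_000_000, 40),
                        10 ** rng.uniform(-10, 0, 40)))]
        sig = build_region_set(variants, 5e-8, flank=5_000, name="sig")
        bg = build_region_set(variants, 1.0, flank=5_000, name="bg")
        altered = [f"p{i}" for i in rng.choice(30, size=8, replace=False)]
        res = region_overlap_test(peaks, altered, sig, bg)

        def overlaps_any(peak, regions):
            return any(peak.overlaps(r) for r in regions)

        universe = [p for p in peaks if overlaps_any(p, bg.intervals)]
        in_sig = {p.id for p in universe if overlaps_any(p, sig.intervals)}
        in_alt = set(altered) & {p.id for p in universe}
        a = len(in_alt & in_sig)
        assert (res.a, res.b, res.c, res.d) == (
            a, len(in_alt) - a, len(in_sig) - a,
            len(universe) - len(in_alt) - len(in_sig) + a)
        direct = fisher_one_tailed(res.a, res.b, res.c, res.d)
        assert res.p == pytest.approx(direct.p, rel=1e-12)

    def test_invariant_to_splitting_regions(self):
        peaks = self._catalog()
        whole = [GenomicInterval("chr1", 0, 1_000_000)]
        split = [GenomicInterval("chr1", 0, 300_000),
                 GenomicInterval("chr1", 300_000, 1_000_000)]
        from epivariant.enrich import RegionSet

        bg = RegionSet("bg", [GenomicInterval("chr1", 0, 3_000_000)])
        r1 = region_overlap_test(peaks, ["p1", "p2"], RegionSet("s", whole), bg)
        r2 = region_overlap_test(peaks, ["p1", "p2"], RegionSet("s", split), bg)
        assert (r1.a, r1.b, r1.c, r1.d, r1.p) == (r2.a, r2.b, r2.c, r2.d, r2.p)

    def test_empty_universe_rejected(self):
        peaks = self._catalog()
        from epivariant.enrich import RegionSet

        bg = RegionSet("bg", [GenomicInterval("chr2", 0, 1000)])
        with pytest.raises(ValueError, match="background"):
            region_overlap_test(peaks, ["p1"], bg, bg)


class TestGeneOverlap:
    def test_single_shared_gene(self):
        background = [f"G{i}" for i in range(100)]
        res = gene_overlap_test(["G0"], ["G0"], background)
        assert (res.a, res.b, res.c, res.d) == (1, 0, 0, 99)
        assert res.p == pytest.approx(1 / 100, rel=1e-12)

    def test_disjoint_lists(self):
        background = [f"G{i}" for i in range(50)]
        res = gene_overlap_test(["G0", "G1"], ["G10", "G11"], background)
        assert res.a == 0
        assert res.p == pytest.approx(1.0)

    def test_reported_gene_outside_background_dropped(self, caplog):
        import logging

        background = [f"G{i}" for i in range(10)]
        with caplog.at_level(logging.WARNING, logger="epivariant.enrich"):
            res = gene_overlap_test(["G0"], ["G0", "NOT_A_GENE"], background)
        assert res.c == 0
        assert any("dropped" in r.message for r in caplog.records)


class TestOra:
    def test_set_equal_to_list(self):
        background = [f"G{i}" for i in range(20)]
        sets = [GeneSet("hit", frozenset(background[:5]))]
        [res] = run_ora(background[:5], sets, background)
        assert res.p < 1e-3
        assert res.p_adjusted == pytest.approx(res.p)

    def test_disjoint_set(self):
        background = [f"G{i}" for i in range(20)]
        sets = [GeneSet("miss", frozenset(background[10:15]))]
        [res] = run_ora(background[:5], sets, background)
        assert res.p == pytest.approx(1.0)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="empty gene list"):
            run_ora([], [GeneSet("s", frozenset("AB"))], ["A", "B"])

    def test_matches_per_set_fisher_plus_bh_oracle(self):
        rng = np.random.default_rng(12)
        background = [f"G{i}" for i in range(200)]
        gene_list = list(rng.choice(background, size=30, replace=False))
        sets = [GeneSet(f"S{k}", frozenset(rng.choice(background, size=25,
                                                      replace=False)))
                for k in range(20)]
        results = run_ora(gene_list, sets, background)
        raw = {}
        for gs in sets:
            a = len(set(gene_list) & gs.genes)
            b = len(gene_list) - a
            c = len(gs.genes) - a
            d = 200 - a - b - c
            raw[gs.name] = fisher_one_tailed(a, b, c, d).p
        # BH step-up on the raw p-values
        items = sorted(raw.items(), key=lambda kv: kv[1])
        m = len(items)
        qs = [p * m / (i + 1) for i, (_, p) in enumerate(items)]
        for i in range(m - 2, -1, -1):
            qs[i] = min(qs[i], qs[i + 1])
        oracle_q = {name: min(1.0, q) for (name, _), q in zip(items, qs)}
        for r in results:
            assert r.p == pytest.approx(raw[r.test_name], rel=1e-12)
            assert r.p_adjusted == pytest.approx(oracle_q[r.test_name], rel=1e-9)
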