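"""Ratio-difference statistics, IBD segmentation and region intersection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibdkit import (IBDMapping, IBDSegment, SegmentationParams, allelic_ratio,
                    pair_site_informative, pairwise_segments, parse_pedigree,
                    ratio_diff, shared_allele_count, shared_regions,
                    summarize_regions)
from ibdkit.intervals import jaccard, merge_intervals


class TestAllelicRatio:
    @pytest.mark.parametrize("ad,dp,expected", [
        ((10, 10), 20, 0.5),
        ((20, 0), 20, 0.0),
        ((0, 18), 18, 1.0),
    ])
    def test_alt_fraction(self, mkcall, ad, dp, expected):
        assert allelic_ratio(mkcall((0, 1), ad, dp=dp)) == expected

    def test_zero_depth_rejected(self, mkcall):
        with pytest.raises(ValueError):
            allelic_ratio(mkcall((0, 1), (0, 0), dp=0))

    def test_multiallelic_rejected(self, mkcall):
        with pytest.raises(ValueError):
            allelic_ratio(mkcall((1, 2), (5, 5), dp=10))


class TestRatioDiff:
    def test_worked_example(self, mkcall):
        a = mkcall((0, 1), (15, 5), dp=20)
        b = mkcall((0, 1), (5, 15), dp=20)
        assert ratio_diff(a, b) == pytest.approx(0.5)

    @staticmethod
    def _call(ad, dp):
        from ibdkit import GenotypeCall

        return GenotypeCall(allele_indices=(0, 1),
                            ad=(max(0, dp - ad), min(ad, dp)), dp=dp, gq=45)

    @given(ad1=st.integers(0, 30), dp1=st.integers(1, 30),
           ad2=st.integers(0, 30), dp2=st.integers(1, 30))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, ad1, dp1, ad2, dp2):
        a = self._call(ad1, dp1)
        b = self._call(ad2, dp2)
        d = ratio_diff(a, b)
        assert 0.0 <= d <= 1.0
        assert d == ratio_diff(b, a)
        assert ratio_diff(a, a) == 0.0


class TestGenotypeComparisons:
    @pytest.mark.parametrize("gt1,gt2,informative", [
        ((0, 1), (0, 1), False),
        ((1, 0), (0, 1), False),   # unordered identity
        ((0, 0), (0, 1), True),
        ((0, 0), (1, 1), True),
        (None, (0, 1), False),
    ])
    def test_informative(self, gt1, gt2, informative):
        assert pair_site_informative(gt1, gt2) is informative

    @pytest.mark.parametrize("gt1,gt2,shared", [
        ((0, 0), (1, 1), 0),
        ((0, 0), (0, 1), 1),
        ((0, 1), (0, 1), 2),
        ((0, 0), (0, 0), 2),
        ((0, 1), (1, 1), 1),
    ])
    def test_shared_alleles_is_multiset_matching(self, gt1, gt2, shared):
        assert shared_allele_count(gt1, gt2) == shared
        assert shared_allele_count(gt2, gt1) == shared

    def test_missing_genotype_rejected(self):
        with pytest.raises(ValueError):
            shared_allele_count(None, (0, 1))


HET, HOMREF, HOMALT = (0, 1), (0, 0), (1, 1)
AD_HET, AD_REF, AD_ALT = (15, 15), (29, 1), (1, 29)


def _concordant_row(pos):
    # het vs hom-ref: shares an allele, ratio diff ~0.47
    return (pos, HET, AD_HET, HOMREF, AD_REF)


def _discordant_row(pos):
    # opposite homozygotes with corroborating reads, ratio diff ~0.97
    return (pos, HOMALT, AD_ALT, HOMREF, AD_REF)


def _identical_row(pos):
    return (pos, HET, AD_HET, HET, AD_HET)


PARAMS = SegmentationParams(min_sites=5, min_span_bp=100)


class TestPairwiseSegments:
    def test_uninterrupted_run_is_one_segment(self, mksites):
        sites = mksites([_concordant_row(1000 + 20_000 * i)
                         for i in range(100)])
        segs = pairwise_segments(sites, ("A", "B"), PARAMS)
        assert len(segs) == 1
        seg = segs[0]
        assert seg.n_informative_sites == 100
        assert (seg.start, seg.end) == (999, 1000 + 20_000 * 99)
        assert seg.min_shared_alleles == 1

    def test_discordant_run_beyond_tolerance_splits(self, mksites):
        rows = ([_concordant_row(1_000 + 1_000 * i) for i in range(50)]
                + [_discordant_row(60_000 + 100 * i) for i in range(3)]
                + [_concordant_row(70_000 + 1_000 * i) for i in range(50)])
        params = SegmentationParams(max_discordant_run=2, min_sites=5,
                                    min_span_bp=100)
        segs = pairwise_segments(mksites(rows), ("A", "B"), params)
        assert len(segs) == 2
        assert segs[0].end <= 60_000 and segs[1].start >= 69_000

    def test_tolerated_discordance_bridges(self, mksites):
        rows = ([_concordant_row(1_000 + 1_000 * i) for i in range(50)]
                + [_discordant_row(60_000), _discordant_row(60_100)]
                + [_concordant_row(70_000 + 1_000 * i) for i in range(50)])
        params = SegmentationParams(max_discordant_run=2, min_sites=5,
                                    min_span_bp=100)
        assert len(pairwise_segments(mksites(rows), ("A", "B"), params)) == 1

    def test_identical_sites_support_but_are_not_informative(self, mksites):
        sites = mksites([_identical_row(1_000 + 1_000 * i) for i in range(30)])
        segs = pairwise_segments(sites, ("A", "B"), PARAMS)
        assert len(segs) == 1
        assert segs[0].n_informative_sites == 0
        assert segs[0].n_supporting_sites == 30
        assert segs[0].min_shared_alleles == 2  # pure IBD2 support

    def test_genotype_miscall_rescued_by_reads(self, mksites):
        # apparent opposite homozygotes whose reads look heterozygous
        rows = [_concordant_row(1_000 + 1_000 * i) for i in range(20)]
        rows.insert(10, (10_500, HOMALT, AD_HET, HOMREF, AD_REF))
        assert len(pairwise_segments(mksites(rows), ("A", "B"), PARAMS)) == 1

    def test_unsorted_positions_rejected(self, mksites):
        sites = mksites([_concordant_row(5_000), _concordant_row(1_000)])
        with pytest.raises(ValueError, match="not sorted"):
            pairwise_segments(sites, ("A", "B"), PARAMS)

    def test_revisited_chromosome_rejected(self, mksites):
        sites = (mksites([_concordant_row(1_000)], chrom="1")
                 + mksites([_concordant_row(1_000)], chrom="2")
                 + mksites([_concordant_row(2_000)], chrom="1"))
        with pytest.raises(ValueError, match="revisited"):
            pairwise_segments(sites, ("A", "B"), PARAMS)

    def test_support_and_span_floors(self, mksites):
        sites = mksites([_concordant_row(1_000 + 1_000 * i) for i in range(4)])
        assert pairwise_segments(sites, ("A", "B"), PARAMS) == []
        tight = mksites([_concordant_row(1_000 + 10 * i) for i in range(10)])
        assert pairwise_segments(tight, ("A", "B"), PARAMS) == []


def _seg(chrom, start, end, pair):
    return IBDSegment(chrom=chrom, start=start, end=end, pair=pair,
                      min_shared_alleles=1, n_informative_sites=50,
                      n_supporting_sites=60, mean_ratio_diff=0.4)


THREE_AFFECTED = parse_pedigree(
    "F1 A 0 0 1 2\nF1 B 0 0 1 2\nF1 C 0 0 1 2")
PAIRS3 = [("A", "B"), ("A", "C"), ("B", "C")]

TWO_AFFECTED = parse_pedigree("F1 A 0 0 1 2\nF1 B 0 0 1 2")


class TestSharedRegions:
    def test_interval_intersection(self):
        segs = {("A", "B"): [_seg("1", 0, 10_000_000, ("A", "B"))]}
        ped = TWO_AFFECTED
        # single pair: regions equal that pair's segments
        regions = shared_regions(segs, ped)
        assert [(r.start, r.end) for r in regions] == [(0, 10_000_000)]

    def test_two_pair_overlap(self):
        segs = {p: [_seg("1", 0, 10_000_000, p)] for p in PAIRS3}
        segs[("B", "C")] = [_seg("1", 5_000_000, 15_000_000, ("B", "C"))]
        regions = shared_regions(segs, THREE_AFFECTED)
        assert [(r.start, r.end) for r in regions] == [(5_000_000, 10_000_000)]
        assert regions[0].supporting_pairs == tuple(PAIRS3)

    def test_empty_pair_list_gives_empty_result(self):
        segs = {p: [_seg("1", 0, 1_000_000, p)] for p in PAIRS3}
        segs[("A", "C")] = []
        assert shared_regions(segs, THREE_AFFECTED) == []

    def test_idempotent_on_identical_lists(self):
        segs = {p: [_seg("1", 100, 5_000, p), _seg("2", 0, 9_000, p)]
                for p in PAIRS3}
        regions = shared_regions(segs, THREE_AFFECTED)
        assert [(r.chrom, r.start, r.end) for r in regions] == \
            [("1", 100, 5_000), ("2", 0, 9_000)]

    def test_missing_pair_rejected(self):
        segs = {("A", "B"): [], ("A", "C"): []}
        with pytest.raises(KeyError):
            shared_regions(segs, THREE_AFFECTED)

    def test_matches_per_base_mask_oracle(self):
        rng = np.random.default_rng(17)
        span = 2_000
        for _ in range(20):
            segs = {}
            masks = []
            for p in PAIRS3:
                ivs = []
                mask = np.zeros(span, dtype=bool)
                for _ in range(rng.integers(0, 5)):
                    s = int(rng.integers(0, span - 1))
                    e = int(rng.integers(s + 1, span))
                    ivs.append(_seg("1", s, e, p))
                    mask[s:e] = True
                segs[p] = ivs
                masks.append(mask)
            regions = shared_regions(segs, THREE_AFFECTED)
            recovered = np.zeros(span, dtype=bool)
            for r in regions:
                recovered[r.start:r.end] = True
            assert np.array_equal(recovered, masks[0] & masks[1] & masks[2])


class TestSummarizeRegions:
    def test_counts_distinct_overlapping_genes(self):
        segs = {("A", "B"): [_seg("1", 0, 1_000, ("A", "B"))]}
        regions = shared_regions(segs, TWO_AFFECTED)
        genes = [("1", 100, 200, "G1"), ("1", 5_000, 6_000, "G2")]
        s = summarize_regions(regions, genes)
        assert (s.n_regions, s.total_bp, s.n_genes) == (1, 1_000, 1)

    def test_empty_regions(self):
        s = summarize_regions([], [("1", 0, 10, "G1")])
        assert (s.n_regions, s.total_bp, s.n_genes) == (0, 0, 0)

    def test_matches_brute_force_overlap(self):
        rng = np.random.default_rng(3)
        segs = {("A", "B"): [_seg("1", 10_000, 60_000, ("A", "B")),
                             _seg("1", 80_000, 90_000, ("A", "B"))]}
        regions = shared_regions(segs, TWO_AFFECTED)
        genes = [("1", int(s), int(s) + 3_000, f"G{i}")
                 for i, s in enumerate(rng.integers(0, 100_000, size=50))]
        expected = {n for c, s, e, n in genes
                    if any(s < r.end and r.start < e for r in regions)}
        assert summarize_regions(regions, genes).n_genes == len(expected)


class TestModelFit:
    def test_regions_contained_in_every_pair_segments(self, small_sim):
        res = IBDMapping(small_sim.records, small_sim.pedigree,
                         small_sim.sample_ids).fit()
        for region in res.regions:
            for pair, segs in res.segments_by_pair.items():
                assert any(s.chrom == region.chrom and s.start <= region.start
                           and region.end <= s.end for s in segs), \
                    (region, pair)

    def test_shared_span_monotone_in_segment_floors(self, small_sim):
        model = IBDMapping(small_sim.records, small_sim.pedigree,
                           small_sim.sample_ids)
        spans_sites = [
            sum(r.span for r in model.fit(
                SegmentationParams(min_sites=n)).regions)
            for n in (5, 25, 200, 2000)]
        spans_bp = [
            sum(r.span for r in model.fit(
                SegmentationParams(min_span_bp=n)).regions)
            for n in (1_000, 500_000, 2_000_000)]
        assert spans_sites == sorted(spans_sites, reverse=True)
        assert spans_bp == sorted(spans_bp, reverse=True)

    def test_recovery_against_planted_truth(self, small_sim):
        res = IBDMapping(small_sim.records, small_sim.pedigree,
                         small_sim.sample_ids).fit()
        j = jaccard(res.region_interval_map(), small_sim.truth.shared_regions)
        assert j >= 0.95

    def test_summary_mentions_thresholds(self, small_sim):
        res = IBDMapping(small_sim.records, small_sim.pedigree,
                         small_sim.sample_ids).fit()
        text = res.summary()
        assert "DP > 14" in text and "GQ > 30" in text
        assert "shared regions" in text
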