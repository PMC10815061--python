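"""SV matching rule, consensus clustering and inheritance/annotation filters."""

import numpy as np
import pytest

from ibdkit import (MergedSV, MergeParams, SVCall, annotate_and_filter_sv,
                    breakend_distances, caller_hard_filter,
                    dominant_model_filter, merge_callsets, mergeable,
                    parse_pedigree, reciprocal_overlap)


def sv(start, end, svtype="DEL", caller="callerA", chrom="1", gts=None,
       quality=None, flags=("PASS",)):
    return SVCall(chrom=chrom, start=start, end=end, svtype=svtype,
                  caller=caller, sample_genotypes=gts or {},
                  quality=quality, filter_flags=flags)


class TestReciprocalOverlap:
    def test_identical_is_one(self):
        assert reciprocal_overlap(sv(1000, 2000), sv(1000, 2000)) == 1.0

    def test_disjoint_is_zero(self):
        assert reciprocal_overlap(sv(0, 100), sv(500, 600)) == 0.0

    def test_worked_example(self):
        assert reciprocal_overlap(sv(1000, 2000), sv(1400, 2400)) == \
            pytest.approx(0.6)

    def test_cross_chromosome_is_zero_not_error(self):
        assert reciprocal_overlap(sv(0, 100), sv(0, 100, chrom="2")) == 0.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s1, s2 = rng.integers(0, 10_000, size=2)
            a = sv(int(s1), int(s1) + int(rng.integers(1, 5_000)))
            b = sv(int(s2), int(s2) + int(rng.integers(1, 5_000)))
            ro = reciprocal_overlap(a, b)
            assert 0.0 <= ro <= 1.0
            assert ro == reciprocal_overlap(b, a)


class TestBreakendDistances:
    @pytest.mark.parametrize("a,b,expected", [
        ((1000, 2000), (1000, 2000), (0, 0)),
        ((1000, 2000), (1400, 2400), (400, 400)),
        ((0, 5000), (3000, 5000), (3000, 0)),
    ])
    def test_pairs(self, a, b, expected):
        assert breakend_distances(sv(*a), sv(*b)) == expected

    def test_cross_chromosome_rejected(self):
        with pytest.raises(ValueError):
            breakend_distances(sv(0, 10), sv(0, 10, chrom="2"))


class TestMergeable:
    def test_worked_example_passes_default_rule(self):
        assert mergeable(sv(1000, 2000), sv(1400, 2400))

    def test_far_call_fails_both_criteria(self):
        assert not mergeable(sv(0, 10_000), sv(4_000, 20_000))

    def test_type_mismatch_blocked_unless_relaxed(self):
        a, b = sv(0, 5_000, "DEL"), sv(0, 5_000, "DUP")
        assert not mergeable(a, b)
        assert mergeable(a, b, MergeParams(require_same_type=False))

    def test_insertions_matched_by_breakend_distance_only(self):
        a = sv(10_000, 10_001, "INS")
        b = sv(10_400, 10_401, "INS")
        assert mergeable(a, b)
        assert not mergeable(a, sv(12_000, 12_001, "INS"))

    def test_symmetry(self):
        a, b = sv(1000, 2000), sv(1400, 2400)
        assert mergeable(a, b) == mergeable(b, a)


class TestCallerHardFilter:
    def test_required_flag(self):
        calls = [sv(0, 10, flags=("PASS",)), sv(20, 30, flags=("LowQual",))]
        kept = caller_hard_filter(calls, {"callerA": {"require_filter": "PASS"}})
        assert kept == [calls[0]]

    def test_min_quality(self):
        calls = [sv(0, 10, quality=3.0), sv(20, 30, quality=25.0)]
        kept = caller_hard_filter(calls, {"callerA": {"min_quality": 20}})
        assert kept == [calls[1]]

    def test_unknown_caller_passes_through(self, caplog):
        calls = [sv(0, 10, caller="novel")]
        with caplog.at_level("WARNING"):
            kept = caller_hard_filter(calls, {"callerA": {}})
        assert kept == calls
        assert "novel" in caplog.text


def _tenfold(caller, shift=0):
    return [sv(i * 100_000 + shift, i * 100_000 + 10_000 + shift,
               caller=caller) for i in range(10)]


class TestMergeCallsets:
    def test_three_identical_callsets(self):
        merged = merge_callsets([_tenfold(c) for c in "ABC"])
        assert len(merged) == 10
        assert all(m.n_callers == 3 for m in merged)

    def test_jittered_breakpoints_still_cluster(self):
        rng = np.random.default_rng(8)
        sets = []
        for caller in "ABC":
            shift = int(rng.integers(-200, 201))
            sets.append(_tenfold(caller, shift=shift))
        merged = merge_callsets(sets)
        assert len(merged) == 10
        assert all(m.n_callers == 3 for m in merged)

    def test_single_callset_is_identity(self):
        calls = _tenfold("A")
        merged = merge_callsets([calls])
        assert [(m.start, m.end) for m in merged] == \
            [(c.start, c.end) for c in calls]
        assert all(m.n_callers == 1 for m in merged)

    def test_strict_params_merge_only_exact_duplicates(self):
        a = [sv(0, 10_000, caller="A"), sv(50_000, 60_000, caller="A")]
        b = [sv(0, 10_000, caller="B"), sv(50_001, 60_000, caller="B")]
        merged = merge_callsets([a, b], MergeParams(
            min_reciprocal_overlap=1.0, max_breakend_distance_bp=0))
        assert sorted(m.n_callers for m in merged) == [1, 1, 2]

    def test_relaxed_params_merge_all_overlapping(self):
        a = [sv(0, 100_000, caller="A")]
        b = [sv(90_000, 190_000, caller="B")]
        params = MergeParams(min_reciprocal_overlap=0.0,
                             max_breakend_distance_bp=10**9)
        assert len(merge_callsets([a, b], params)) == 1

    def test_member_conservation(self):
        rng = np.random.default_rng(12)
        sets = []
        for caller in "ABC":
            sets.append([sv(int(s), int(s) + int(rng.integers(1_000, 20_000)),
                            caller=caller)
                         for s in rng.integers(0, 2_000_000, size=30)])
        merged = merge_callsets(sets)
        assert sum(len(m.members) for m in merged) == 90

    def test_median_consensus_coordinates(self):
        merged = merge_callsets([[sv(100, 10_000, caller="A")],
                                 [sv(200, 10_400, caller="B")],
                                 [sv(150, 10_100, caller="C")]])
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (150, 10_100)

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(21)
        params = MergeParams()
        calls = []
        for caller in "ABC":
            for s in rng.integers(0, 300_000, size=15):
                calls.append(sv(int(s), int(s) + int(rng.integers(5_000, 30_000)),
                                svtype=str(rng.choice(["DEL", "DUP"])),
                                caller=caller))
        merged = merge_callsets([calls], params)
        # brute-force transitive closure over the mergeable graph
        n = len(calls)
        adj = {i: [] for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                if mergeable(calls[i], calls[j], params):
                    adj[i].append(j)
                    adj[j].append(i)
        seen, components = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k])
            seen |= comp
            components.append(frozenset((calls[k].start, calls[k].end,
                                         calls[k].caller) for k in comp))
        got = {frozenset((m.start, m.end, m.caller) for m in c.members)
               for c in merged}
        assert got == set(components)


PED = parse_pedigree("""\
F1 II.8  0 0 1 2
F1 II.9  0 0 1 2
F1 II.10 0 0 2 1
F1 III.3 II.9 II.10 2 2
F1 III.7 II.9 II.10 1 2
""")
AFFECTED = ["II.8", "II.9", "III.3", "III.7"]


def _merged(gts):
    call = sv(0, 10_000, gts=gts)
    return MergedSV(chrom="1", start=0, end=10_000, svtype="DEL",
                    members=[call])


class TestDominantModelFilter:
    def test_fully_consistent_retained(self):
        gts = {s: "het" for s in AFFECTED} | {"II.10": "ref"}
        assert dominant_model_filter([_merged(gts)], PED)

    def test_one_noncarrier_affected_rejected(self):
        gts = {s: "het" for s in AFFECTED} | {"II.10": "ref",
                                              "III.7": "ref"}
        assert dominant_model_filter([_merged(gts)], PED) == []

    def test_carrier_unaffected_rejected(self):
        gts = {s: "het" for s in AFFECTED} | {"II.10": "het"}
        assert dominant_model_filter([_merged(gts)], PED) == []

    def test_missing_genotype_is_non_informative(self):
        gts = {s: "het" for s in AFFECTED} | {"II.10": "ref",
                                              "III.3": "missing"}
        assert dominant_model_filter([_merged(gts)], PED)


class TestAnnotateAndFilter:
    GENES = [("1", 5_000, 8_000, "WNT11"), ("1", 500_000, 550_000, "OTHER")]

    def test_phenotype_gene_in_ibd_region_retained(self):
        out = annotate_and_filter_sv([_merged({})], gene_intervals=self.GENES,
                                     phenotype_genes=["WNT11"],
                                     ibd_regions=[("1", 0, 20_000)])
        assert len(out) == 1
        assert out[0].annotations["genes"] == ["WNT11"]
        assert out[0].annotations["in_ibd_region"] is True

    def test_no_phenotype_gene_overlap_rejected(self):
        out = annotate_and_filter_sv([_merged({})], gene_intervals=self.GENES,
                                     phenotype_genes=["OTHER"])
        assert out == []

    def test_outside_ibd_regions_rejected(self):
        out = annotate_and_filter_sv([_merged({})], gene_intervals=self.GENES,
                                     phenotype_genes=["WNT11"],
                                     ibd_regions=[("1", 400_000, 600_000)])
        assert out == []

    def test_empty_phenotype_list_rejects_everything(self, caplog):
        with caplog.at_level("WARNING"):
            out = annotate_and_filter_sv([_merged({})],
                                         gene_intervals=self.GENES,
                                         phenotype_genes=[])
        assert out == []
        assert "empty phenotype-gene" in caplog.text

    def test_frequency_annotation(self):
        out = annotate_and_filter_sv(
            [_merged({})], gene_intervals=self.GENES,
            phenotype_genes=["WNT11"],
            freq_table=[("1", 0, 6_000, 0.01), ("1", 7_000, 9_000, 0.2)])
        assert out[0].annotations["max_population_frequency"] == 0.2
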