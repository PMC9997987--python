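import math
import random

import numpy as np
import pytest

from methcap.capture_eval import (
    conversion_report,
    filter_cov_records,
    intersect_with_regions,
    match_sites,
    paired_t_test,
    pearson_r,
    random_promoter_regions,
    region_mean_methylation,
    summarize_region_coverage,
)
from methcap.errors import ConfigurationError, DataError, UndefinedStatisticError
from methcap.io_formats import (
    CpGRecord,
    CytosineContextRecord,
    TargetRegion,
    percent_methylation,
)

from conftest import make_cov_record
from oracles import brute_region_mean


def cov(chrom, pos, m, u):
    return CpGRecord(chrom, pos, percent_methylation(m, u), m, u)


class TestCoverageSummary:
    def test_worked_example(self):
        track = {("chr1", 1): 10, ("chr1", 2): 10, ("chr1", 4): 20}
        region = TargetRegion("chr1", 0, 4, "r")
        (s,) = summarize_region_coverage(track, [region])
        assert s.mean_depth == pytest.approx(10.0)
        assert s.breadth == pytest.approx(0.75)
        assert s.min_depth == 0
        assert s.max_depth == 20

    def test_absent_region(self):
        (s,) = summarize_region_coverage({}, [TargetRegion("chr1", 0, 10, "r")])
        assert s.mean_depth == 0 and s.breadth == 0

    def test_order_preserved(self):
        regions = [TargetRegion("chr1", 0, 5, "a"), TargetRegion("chr1", 5, 10, "b")]
        out = summarize_region_coverage({}, regions)
        assert [s.region.name for s in out] == ["a", "b"]

    def test_empty_regions(self):
        assert summarize_region_coverage({("chr1", 1): 5}, []) == []


class TestFilterCov:
    def test_depth4_dropped(self):
        assert filter_cov_records([cov("chr1", 1, 3, 1)], min_depth=5) == []

    def test_depth5_retained_inclusive(self):
        assert len(filter_cov_records([cov("chr1", 1, 3, 2)], min_depth=5)) == 1

    def test_duplicate_equal_collapsed(self):
        records = [cov("chr1", 1, 5, 5), cov("chr1", 1, 5, 5)]
        assert len(filter_cov_records(records, min_depth=0)) == 1

    def test_duplicate_conflict_raises(self):
        records = [cov("chr1", 9, 5, 5), cov("chr1", 9, 6, 4)]
        with pytest.raises(DataError, match="chr1:9"):
            filter_cov_records(records, min_depth=0)


class TestIntersect:
    region = TargetRegion("chr1", 100, 200, "r")

    def test_first_base_retained(self):
        assert intersect_with_regions([cov("chr1", 101, 1, 1)], [self.region])

    def test_pos100_dropped(self):
        assert intersect_with_regions([cov("chr1", 100, 1, 1)], [self.region]) == []

    def test_end_base_retained_and_past_dropped(self):
        assert intersect_with_regions([cov("chr1", 200, 1, 1)], [self.region])
        assert intersect_with_regions([cov("chr1", 201, 1, 1)], [self.region]) == []

    def test_overlapping_regions_single_emission(self):
        regions = [self.region, TargetRegion("chr1", 150, 250, "r2")]
        out = intersect_with_regions([cov("chr1", 180, 1, 1)], regions)
        assert len(out) == 1

    def test_commutes_with_filter(self, rng: random.Random):
        regions = []
        for i in range(5):
            s = rng.randrange(0, 500)
            regions.append(TargetRegion("chr1", s, s + rng.randrange(10, 100), f"r{i}"))
        for _ in range(50):
            records = [make_cov_record(rng, pos=rng.randrange(1, 700)) for _ in range(40)]
            # dedup keys to satisfy unique-collapse equality on both routes
            records = list({(r.chrom, r.pos): r for r in records}.values())
            a = filter_cov_records(intersect_with_regions(records, regions), 5)
            b = intersect_with_regions(filter_cov_records(records, 5), regions)
            assert a == b


class TestMatchSites:
    def test_partial_overlap(self):
        a = [cov("chr1", 101, 1, 1), cov("chr1", 105, 2, 2)]
        b = [cov("chr1", 105, 3, 1), cov("chr1", 109, 0, 4)]
        m = match_sites(a, b)
        assert m.n == 1 and m.keys == (("chr1", 105),)
        assert m.percents_a == (50.0,) and m.percents_b == (75.0,)

    def test_disjoint(self):
        m = match_sites([cov("chr1", 1, 1, 1)], [cov("chr1", 2, 1, 1)])
        assert m.n == 0

    def test_identical(self):
        a = [cov("chr1", i, i, 10) for i in range(1, 8)]
        m = match_sites(a, list(a))
        assert m.n == len(a)
        assert m.percents_a == m.percents_b


class TestPearson:
    def test_perfect(self):
        m = match_sites(
            [cov("c", 1, 0, 10), cov("c", 2, 5, 5), cov("c", 3, 10, 0)],
            [cov("c", 1, 0, 10), cov("c", 2, 5, 5), cov("c", 3, 10, 0)],
        )
        assert pearson_r(m) == pytest.approx(1.0)

    def test_anti(self):
        a = [cov("c", 1, 0, 10), cov("c", 2, 5, 5), cov("c", 3, 10, 0)]
        b = [cov("c", 1, 10, 0), cov("c", 2, 5, 5), cov("c", 3, 0, 10)]
        assert pearson_r(match_sites(a, b)) == pytest.approx(-1.0)

    def test_worked_example(self):
        # pairs (0,10),(50,40),(100,100): sum-formula value 0.9819805...
        # (frozen from an independent scipy.stats.pearsonr computation)
        a = [cov("c", 1, 0, 10), cov("c", 2, 5, 5), cov("c", 3, 10, 0)]
        b = [cov("c", 1, 1, 9), cov("c", 2, 4, 6), cov("c", 3, 10, 0)]
        assert pearson_r(match_sites(a, b)) == pytest.approx(0.9819805060619655)

    def test_zero_variance_raises(self):
        a = [cov("c", 1, 5, 5), cov("c", 2, 5, 5)]
        b = [cov("c", 1, 1, 9), cov("c", 2, 9, 1)]
        with pytest.raises(UndefinedStatisticError):
            pearson_r(match_sites(a, b))

    def test_affine_invariance(self, rng):
        x = [rng.random() * 100 for _ in range(30)]
        a = [CpGRecord("c", i + 1, v, 0, 0) for i, v in enumerate(x)]
        b = [CpGRecord("c", i + 1, 0.5 * v + 3, 0, 0) for i, v in enumerate(x)]
        assert pearson_r(match_sites(a, b)) == pytest.approx(1.0)


class TestRegionMeans:
    def test_examples(self):
        region = TargetRegion("chr1", 0, 100, "r")
        records = [cov("chr1", 10, 0, 10), cov("chr1", 20, 10, 0)]
        assert region_mean_methylation(records, [region]) == {"r": pytest.approx(50.0)}
        assert region_mean_methylation([], [region]) == {}
        assert region_mean_methylation(
            [cov("chr1", 10, 3, 1)], [region]
        ) == {"r": pytest.approx(75.0)}

    def test_matches_brute_force(self, rng: random.Random):
        for _ in range(100):
            regions = []
            for i in range(4):
                s = rng.randrange(0, 800)
                regions.append(TargetRegion("chr1", s, s + rng.randrange(5, 120), f"r{i}"))
            records = [make_cov_record(rng, pos=rng.randrange(1, 1000)) for _ in range(50)]
            got = region_mean_methylation(records, regions)
            for region in regions:
                want = brute_region_mean(records, region)
                if want is None:
                    assert region.name not in got
                else:
                    assert got[region.name] == pytest.approx(want)


class TestPairedT:
    def test_identical_series(self):
        x = [float(i) for i in range(24)]
        t, dof, p = paired_t_test(x, x)
        assert (t, dof, p) == (0.0, 23, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        t, dof, p = paired_t_test([2, 2, 2, 2], [1, 1, 1, 1])
        assert math.isinf(t) and t > 0
        assert p == 0.0 and dof == 3

    def test_worked_example_zero_mean(self):
        t, dof, p = paired_t_test([1, 2, 3], [0, 2, 4])
        assert t == pytest.approx(0.0)
        assert dof == 2
        assert p == pytest.approx(1.0)

    def test_matches_scipy_on_random_data(self, rng):
        from scipy import stats
        x = [rng.random() * 100 for _ in range(15)]
        y = [rng.random() * 100 for _ in range(15)]
        t, dof, p = paired_t_test(x, y)
        ref = stats.ttest_rel(x, y)
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))
        assert dof == 14

    def test_too_short_raises(self):
        with pytest.raises(DataError):
            paired_t_test([1.0], [2.0])


def ctx(chrom, pos, m, u, context, tri="CNN"):
    return CytosineContextRecord(chrom, pos, "+", m, u, context, tri)


class TestConversionReport:
    def test_lambda_one_percent(self):
        records = [ctx("lambda", i + 1, 1 if i == 0 else 0, 0 if i == 0 else 1, "CHH", "CTT")
                   for i in range(100)]
        report = conversion_report(records, "lambda", "pUC19")
        assert report.lambda_error == pytest.approx(1.0)

    def test_puc19_retention(self):
        records = [ctx("pUC19", 1, 97, 3, "CpG", "CGA")]
        with pytest.warns(UserWarning):
            report = conversion_report(records, "lambda", "pUC19")
        assert report.puc19_retention == pytest.approx(97.0)

    def test_missing_lambda_warns(self):
        records = [ctx("chr1", 1, 1, 9, "CHG", "CAG")]
        with pytest.warns(UserWarning, match="lambda_error"):
            report = conversion_report(records, "lambda", "pUC19")
        assert report.lambda_error is None
        assert report.chg_level == pytest.approx(10.0)

    def test_controls_excluded_from_context_levels(self):
        records = [
            ctx("lambda", 1, 5, 5, "CHH", "CTT"),
            ctx("chr1", 1, 1, 99, "CHH", "CTT"),
            ctx("chr1", 2, 2, 98, "CHG", "CAG"),
        ]
        with pytest.warns(UserWarning):  # no pUC19 CpG calls
            report = conversion_report(records, "lambda", "pUC19")
        assert report.chh_level == pytest.approx(1.0)
        assert report.chg_level == pytest.approx(2.0)


class TestRandomPromoterRegions:
    def test_empty_promoters(self):
        out = random_promoter_regions({"chr1": 50000}, [], n_tracks=20, seed=1)
        assert out == []

    def test_promoter_inside_track_recovered(self):
        # track covers the whole single chromosome, so the intersection is
        # exactly the promoter interval
        prom = TargetRegion("chr1", 2000, 4500, "p")
        out = random_promoter_regions({"chr1": 10000}, [prom],
                                      n_tracks=5, track_len=10000, seed=1)
        assert len(out) == 1
        assert (out[0].chrom, out[0].start, out[0].end) == ("chr1", 2000, 4500)

    def test_no_eligible_chrom_raises(self):
        with pytest.raises(ConfigurationError):
            random_promoter_regions({"chr1": 500}, [], n_tracks=1, track_len=10000, seed=1)

    def test_partial_overlap_length(self, rng):
        # brute-force the intersection arithmetic over random placements
        for seed in range(20):
            prom = TargetRegion("chr1", 30000, 42000, "p")
            out = random_promoter_regions({"chr1": 100000}, [prom],
                                          n_tracks=30, track_len=10000, seed=seed)
            for region in out:
                assert region.start >= prom.start and region.end <= prom.end
                assert 0 < region.length <= 10000

    def test_deterministic(self):
        prom = TargetRegion("chr1", 5000, 9000, "p")
        a = random_promoter_regions({"chr1": 50000}, [prom], n_tracks=50, seed=9)
        b = random_promoter_regions({"chr1": 50000}, [prom], n_tracks=50, seed=9)
        assert a == b
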