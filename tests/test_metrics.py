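import numpy as np
import pytest

from modbench.aggregate import SiteProbTable, aggregate_sites, filter_by_coverage
from modbench.metrics import (
    MetricCurve,
    MetricPoint,
    cross_sample_concordance,
    default_threshold_grid,
    fdr_ratio,
    fdr_vs_ratio_curve,
    intermediate_band_fraction,
    per_read_fpr,
    per_site_fpr,
    per_site_recall,
    stoichiometry_correlation,
    sweep_thresholds,
)
from modbench.records import (
    GroundTruthSite,
    PerReadCall,
    SiteAggregate,
    SiteKey,
    ThresholdPolicy,
)
from conftest import make_call
from oracles import brute_per_read_fpr, brute_per_site_fpr, rank_then_pearson


def sk(pos, chrom="c", strand="+"):
    return SiteKey(chrom, pos, strand)


def agg(pos, nmod, cov, t=0.5):
    return SiteAggregate(site=sk(pos), mod_code="m6A", coverage=cov,
                         n_modified=nmod, threshold_used=t)


def truth(pos, level=0.5):
    return GroundTruthSite(site=sk(pos), level=level)


class TestRecall:
    def test_half_of_truth_recovered(self):
        recall, counts = per_site_recall({sk(1), sk(3)}, [truth(1), truth(2)])
        assert recall == 0.5
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)

    def test_perfect_prediction(self):
        recall, _ = per_site_recall({sk(1), sk(2)}, [truth(1), truth(2)])
        assert recall == 1.0

    def test_empty_truth_is_undefined_not_zero(self):
        recall, counts = per_site_recall({sk(1)}, [])
        assert recall is None
        assert counts.fp == 1

    def test_fn_split_between_no_prediction_and_below_cutoff(self):
        recall, counts = per_site_recall(
            {sk(1)}, [truth(1), truth(2), truth(3)], assessed_sites={sk(1), sk(2)}
        )
        assert counts.fn == 2
        assert counts.fn_no_prediction == 1  # site 3 never assessed

    def test_random_sets_match_set_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            pred = {sk(int(p)) for p in rng.integers(0, 100, size=rng.integers(1, 60))}
            truth_sites = [truth(int(p)) for p in
                           np.unique(rng.integers(0, 100, size=rng.integers(1, 60)))]
            recall, counts = per_site_recall(pred, truth_sites)
            ts = {t.site for t in truth_sites}
            assert recall == len(pred & ts) / len(ts)
            assert counts.tp + counts.fn == len(ts)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        a = {sk(i): v for i, v in enumerate([0.1, 0.2, 0.5, 0.9])}
        b = {s: v**2 for s, v in a.items()}
        rho, n = stoichiometry_correlation(a, b)
        assert rho == pytest.approx(1.0)
        assert n == 4

    def test_reverse_ranking_gives_minus_one(self):
        a = {sk(i): v for i, v in enumerate([0.1, 0.2, 0.5, 0.9])}
        b = {s: 1 - v for s, v in a.items()}
        rho, _ = stoichiometry_correlation(a, b)
        assert rho == pytest.approx(-1.0)

    def test_too_few_common_sites_is_undefined(self):
        a = {sk(0): 0.1, sk(1): 0.5}
        rho, n = stoichiometry_correlation(a, a)
        assert rho is None and n == 2

    def test_zero_variance_is_undefined(self):
        a = {sk(i): 0.3 for i in range(10)}
        b = {sk(i): i / 10 for i in range(10)}
        assert stoichiometry_correlation(a, b)[0] is None

    def test_matches_rank_then_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = 200
            x = np.round(rng.random(n), 1)  # heavy ties
            y = np.round(rng.random(n), 1)
            a = {sk(i): float(x[i]) for i in range(n)}
            b = {sk(i): float(y[i]) for i in range(n)}
            rho, _ = stoichiometry_correlation(a, b)
            oracle = rank_then_pearson(x, y)
            if oracle is None:
                assert rho is None
            else:
                assert rho == pytest.approx(oracle, abs=1e-12)

    def test_restrict_to_limits_common_sites(self):
        a = {sk(i): i / 10 for i in range(10)}
        b = {sk(i): (9 - i) / 10 for i in range(10)}
        rho, n = stoichiometry_correlation(a, b, restrict_to={sk(0), sk(1), sk(2)})
        assert n == 3
        assert rho == pytest.approx(-1.0)


class TestPerReadFpr:
    def test_half_above_threshold(self):
        calls = [make_call(prob=p, read_id=f"r{i}")
                 for i, p in enumerate([0.9, 0.2, 0.1, 0.7])]
        assert per_read_fpr(calls, ThresholdPolicy(0.61)) == 0.5

    def test_threshold_one_gives_zero(self):
        calls = [make_call(prob=p, read_id=f"r{i}") for i, p in enumerate([1.0, 0.5])]
        assert per_read_fpr(calls, ThresholdPolicy(1.0)) == 0.0

    def test_empty_input_is_undefined(self):
        assert per_read_fpr([], ThresholdPolicy(0.5)) is None

    def test_matches_counting_oracle_on_simulated_calls(self):
        rng = np.random.default_rng(8)
        probs = rng.random(10_000)
        calls = [make_call(prob=float(p), read_id=f"r{i}") for i, p in enumerate(probs)]
        for t in (0.0, 0.3, 0.61, 0.95):
            assert per_read_fpr(calls, ThresholdPolicy(t)) == brute_per_read_fpr(probs, t)


class TestPerSiteFpr:
    def test_fraction_of_sites_at_cutoff(self):
        aggs = [agg(i, n, 100) for i, n in enumerate([50, 5, 0, 20])]
        assert per_site_fpr(aggs, 0.1) == 0.5

    def test_unreachable_cutoff_gives_zero(self):
        aggs = [agg(i, n, 100) for i, n in enumerate([50, 99])]
        assert per_site_fpr(aggs, 1.0) == 0.0

    def test_empty_is_undefined(self):
        assert per_site_fpr([], 0.1) is None

    def test_candidate_denominator_option(self):
        aggs = [agg(0, 50, 100)]
        assert per_site_fpr(aggs, 0.1, n_candidate_sites=10) == pytest.approx(0.1)

    def test_random_table_matches_oracle(self):
        rng = np.random.default_rng(9)
        aggs = [agg(i, int(rng.integers(0, 31)), 30) for i in range(200)]
        for cutoff in (0.05, 0.1, 0.5):
            assert per_site_fpr(aggs, cutoff) == brute_per_site_fpr(
                [a.ratio_exact for a in aggs], cutoff
            )


class TestFdrRatio:
    def test_normalized_fraction_ratio(self):
        assert fdr_ratio(10, 100, 40, 200, cap=False) == pytest.approx(0.5)

    def test_cap_at_one(self):
        assert fdr_ratio(30, 100, 20, 100, cap=True) == 1.0

    def test_identical_samples_give_one(self):
        assert fdr_ratio(17, 220, 17, 220) == pytest.approx(1.0)

    def test_zero_wt_positives_is_undefined(self):
        assert fdr_ratio(5, 100, 0, 100) is None

    def test_zero_total_is_undefined(self):
        assert fdr_ratio(0, 0, 5, 100) is None

    def test_min_positive_guard(self):
        assert fdr_ratio(5, 100, 50, 100, min_positives=10) is None
        assert fdr_ratio(50, 100, 5, 100, min_positives=10) is None
        assert fdr_ratio(50, 100, 50, 100, min_positives=10) is not None


class TestSweep:
    def _dataset(self, seed=10, n_sites=30, cov=20):
        rng = np.random.default_rng(seed)
        wt, ivt, truth_sites = [], [], []
        for i in range(n_sites):
            modified = i % 3 == 0
            theta = 0.6 if modified else 0.0
            if modified:
                truth_sites.append(GroundTruthSite(site=sk(i, chrom="chr1"), level=theta))
            for j in range(cov):
                state = rng.random() < theta
                p_wt = rng.beta(8, 2) if state else rng.beta(2, 8)
                wt.append(make_call(pos=i, prob=float(p_wt), read_id=f"w{i}:{j}"))
                ivt.append(make_call(pos=i, prob=float(rng.beta(2, 8)), read_id=f"i{i}:{j}"))
        return wt, ivt, truth_sites

    def test_recall_and_fpr_non_increasing_across_grid(self):
        wt, ivt, tr = self._dataset()
        curve = sweep_thresholds(wt, ivt, tr, grid=[i / 20 for i in range(21)],
                                 min_coverage=1)
        recalls = [p.recall for p in curve]
        fprs = [p.fpr_read for p in curve]
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))
        assert all(a >= b for a, b in zip(fprs, fprs[1:]))
        assert curve.points[0].recall >= curve.points[-1].recall

    def test_everything_predicted_at_zero_threshold(self):
        wt, ivt, tr = self._dataset()
        curve = sweep_thresholds(wt, ivt, tr, grid=[0.0, 1.0], min_coverage=1)
        assert curve.points[0].recall == 1.0
        assert curve.points[0].fpr_read == 1.0  # continuous probs all > 0

    def test_points_match_independently_recomputed_statistics(self):
        wt, ivt, tr = self._dataset(seed=11)
        grid = [0.2, 0.5, 0.8]
        curve = sweep_thresholds(wt, ivt, tr, grid=grid, ratio_cutoff=0.1,
                                 min_coverage=1, min_positives=0)
        for point in curve:
            policy = ThresholdPolicy(point.t)
            wt_aggs = aggregate_sites(wt, policy)
            ivt_aggs = aggregate_sites(ivt, policy)
            predicted = {a.site for a in wt_aggs if a.ratio_at_least(0.1)}
            truth_sites = {t.site for t in tr}
            assert point.recall == len(predicted & truth_sites) / len(truth_sites)
            assert point.fpr_read == brute_per_read_fpr([c.prob for c in ivt], point.t)
            ivt_pos = sum(1 for a in ivt_aggs if a.ratio_at_least(0.1))
            assert point.fpr_site == ivt_pos / len(ivt_aggs)

    def test_grid_must_be_strictly_increasing(self):
        wt, ivt, tr = self._dataset()
        with pytest.raises(ValueError):
            sweep_thresholds(wt, ivt, tr, grid=[0.5, 0.5])

    def test_default_grid_contains_recommended_thresholds(self):
        grid = default_threshold_grid([0.033, 0.61])
        assert 0.033 in grid and 0.61 in grid
        assert len(grid) == 102  # 101 regular points + 0.033 (0.61 coincides)
        assert all(b > a for a, b in zip(grid, grid[1:]))


class TestFdrVsRatioCurve:
    def test_identical_universes_at_cutoff_zero_give_one(self):
        wt = [agg(i, i % 5, 10) for i in range(20)]
        ivt = [agg(i, (i + 1) % 3, 10) for i in range(20)]
        curve = fdr_vs_ratio_curve(wt, ivt, [0.0], min_positives=0)
        assert curve[0][1] == 1.0

    def test_clean_ivt_gives_zero(self):
        wt = [agg(i, 8, 10) for i in range(20)]
        ivt = [agg(i, 0, 10) for i in range(20)]
        curve = fdr_vs_ratio_curve(wt, ivt, [0.5], min_positives=0)
        assert curve[0][1] == 0.0

    def test_matches_pointwise_oracle(self):
        rng = np.random.default_rng(12)
        wt = [agg(i, int(rng.integers(0, 11)), 10) for i in range(50)]
        ivt = [agg(i, int(rng.integers(0, 4)), 10) for i in range(50)]
        from oracles import brute_fdr

        for cutoff, fdr in fdr_vs_ratio_curve(wt, ivt, [0.0, 0.1, 0.3], min_positives=0):
            wt_pos = sum(1 for a in wt if a.ratio_at_least(cutoff))
            ivt_pos = sum(1 for a in ivt if a.ratio_at_least(cutoff))
            assert fdr == brute_fdr(ivt_pos, 50, wt_pos, 50)


class TestConcordanceAndBand:
    def test_identical_samples(self):
        a = [agg(i, i % 7, 10) for i in range(30)]
        res = cross_sample_concordance(a, a)
        assert res.rho == pytest.approx(1.0)
        assert res.frac_a == res.frac_b == 1.0

    def test_disjoint_site_sets(self):
        a = [agg(i, 1, 10) for i in range(5)]
        b = [agg(i + 100, 1, 10) for i in range(5)]
        res = cross_sample_concordance(a, b)
        assert res.rho is None and res.n_common == 0

    def test_random_overlap_matches_set_arithmetic(self):
        rng = np.random.default_rng(13)
        a = [agg(i, int(rng.integers(0, 11)), 10) for i in range(40)]
        b = [agg(i, int(rng.integers(0, 11)), 10) for i in range(20, 60)]
        res = cross_sample_concordance(a, b)
        assert res.n_common == 20
        assert res.frac_a == 20 / 40 and res.frac_b == 20 / 40

    def test_band_all_intermediate(self):
        a = [agg(i, 2, 10) for i in range(10)]
        assert intermediate_band_fraction(a, a, 0.05, 0.40) == 1.0

    def test_band_all_zero(self):
        a = [agg(i, 0, 10) for i in range(10)]
        assert intermediate_band_fraction(a, a, 0.05, 0.40) == 0.0

    def test_band_counting_oracle(self):
        rng = np.random.default_rng(14)
        a = [agg(i, int(rng.integers(0, 11)), 10) for i in range(50)]
        b = [agg(i, int(rng.integers(0, 11)), 10) for i in range(50)]
        frac = intermediate_band_fraction(a, b, 0.05, 0.40)
        n = sum(
            1 for x, y in zip(a, b)
            if 0.05 <= x.ratio <= 0.40 and 0.05 <= y.ratio <= 0.40
        )
        assert frac == n / 50

    def test_no_common_sites_is_undefined(self):
        assert intermediate_band_fraction([], [], 0.05, 0.4) is None


class TestMetricCurveInvariants:
    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            MetricCurve([MetricPoint(t=0.5), MetricPoint(t=0.2)])
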