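"""Diagnostic-accuracy statistics: metrics, intervals, kappa, sample sizes."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from heatvalid.stats import (
    KappaResult,
    TwoByTwo,
    UndefinedKappaError,
    UndefinedMetricError,
    cohen_kappa,
    estimate_table_text,
    format_percent,
    metrics_from_table,
    sample_size_ppv,
    sample_size_sn_sp,
    wald_interval,
    wilson_cc_interval,
)


class TestTwoByTwo:
    def test_rejects_negative_and_empty(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 0, 0, 1)
        with pytest.raises(ValueError):
            TwoByTwo(0, 0, 0, 0)


class TestMetrics:
    def test_validation_study_table(self):
        m = metrics_from_table(TwoByTwo(1, 0, 3, 960))
        assert m["sensitivity"] == 0.25
        assert m["specificity"] == 1.0
        assert m["npv"] == 960 / 963
        assert m["ppv"] == 1.0

    @pytest.mark.parametrize("k,m", [(1, 1), (5, 200)])
    def test_perfect_classifier(self, k, m):
        assert all(v == 1.0 for v in metrics_from_table(TwoByTwo(k, 0, 0, m)).values())

    def test_enriched_sample_ppv_only(self):
        m = metrics_from_table(TwoByTwo(38, 24, 0, 0), metrics=("ppv",))
        assert m["ppv"] == pytest.approx(38 / 62)

    def test_zero_denominator_raises_naming_metric(self):
        with pytest.raises(UndefinedMetricError, match="npv"):
            metrics_from_table(TwoByTwo(38, 24, 0, 0), metrics=("npv",))

    def test_sensitivity_identity_on_integers(self):
        for tp, fn in [(1, 3), (7, 0), (0, 4), (13, 29)]:
            t = TwoByTwo(tp, 1, fn, 5)
            if tp + fn:
                sn = metrics_from_table(t, metrics=("sensitivity",))["sensitivity"]
                assert sn * (tp + fn) == pytest.approx(tp, abs=1e-12)


class TestWaldInterval:
    @pytest.mark.parametrize(
        "k,n,hw_pct",
        [
            (1, 4, "42.4%"),  # sensitivity 25.0 +/- 42.4
            (960, 963, "0.4%"),  # NPV 99.7 +/- 0.4
            (38, 62, "12.1%"),  # PPV 61.3 +/- 12.1
            (960, 960, "0.0%"),  # specificity 100.0 +/- 0.0
        ],
    )
    def test_published_half_widths(self, k, n, hw_pct):
        assert format_percent(wald_interval(k, n, 0.95).half_width) == hw_pct

    def test_degenerate_proportions_have_zero_width(self):
        for k, n in [(0, 17), (17, 17)]:
            est = wald_interval(k, n)
            assert est.half_width == 0.0
            assert est.lower == est.upper == est.p_hat

    def test_symmetric_before_clipping(self):
        est = wald_interval(30, 60)
        assert est.upper - est.p_hat == pytest.approx(est.p_hat - est.lower)

    def test_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(1, 4), (38, 62), (10, 30), (960, 963)]:
            est = wald_interval(k, n)
            lo, hi = proportion_confint(k, n, alpha=0.05, method="normal")
            assert est.lower == pytest.approx(max(0.0, lo), abs=1e-12)
            assert est.upper == pytest.approx(min(1.0, hi), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            wald_interval(5, 4)
        with pytest.raises(ValueError):
            wald_interval(1, 4, conf_level=1.2)


def bisect_wilson_cc(k, n, conf=0.95):
    """Independent oracle: root-find the continuity-corrected score equations."""
    z = norm.ppf((1 + conf) / 2)
    p = k / n

    def solve(f, a, b):
        fa = f(a)
        for _ in range(200):
            mid = (a + b) / 2
            fm = f(mid)
            if (fa < 0) == (fm < 0):
                a, fa = mid, fm
            else:
                b = mid
        return (a + b) / 2

    lower = (
        0.0
        if k == 0
        else solve(lambda q: (p - q - 1 / (2 * n)) - z * math.sqrt(q * (1 - q) / n), 0.0, p)
    )
    upper = (
        1.0
        if k == n
        else solve(lambda q: (q - p - 1 / (2 * n)) - z * math.sqrt(q * (1 - q) / n), p, 1.0)
    )
    return lower, upper


class TestWilsonCC:
    @pytest.mark.parametrize("k,n", [(0, 10), (1, 4), (38, 62), (4, 964), (960, 963)])
    def test_matches_bisection_oracle(self, k, n):
        est = wilson_cc_interval(k, n)
        lo, hi = bisect_wilson_cc(k, n)
        assert est.lower == pytest.approx(lo, abs=1e-6)
        assert est.upper == pytest.approx(hi, abs=1e-6)

    def test_boundary_conventions(self):
        assert wilson_cc_interval(0, 10).lower == 0.0
        assert wilson_cc_interval(10, 10).upper == 1.0

    @pytest.mark.parametrize("k,n", [(0, 5), (1, 4), (3, 7), (50, 50), (4, 964)])
    def test_contains_point_estimate(self, k, n):
        est = wilson_cc_interval(k, n)
        assert est.lower <= est.p_hat <= est.upper

    @pytest.mark.parametrize("maker", [wald_interval, wilson_cc_interval])
    def test_width_shrinks_with_confidence(self, maker):
        for k, n in [(1, 4), (5, 20), (38, 62)]:
            w95 = maker(k, n, 0.95)
            w80 = maker(k, n, 0.80)
            assert (w80.upper - w80.lower) <= (w95.upper - w95.lower)
            assert w95.lower <= w95.upper


class TestKappa:
    def test_perfect_agreement(self):
        pairs = [(True, True)] * 3 + [(False, False)] * 7
        res = cohen_kappa(pairs)
        assert res == KappaResult(n_pairs=10, p_o=1.0, p_e=res.p_e, kappa=1.0)

    def test_worked_agreement_table(self):
        pairs = [(True, True)] * 4 + [(True, False)] + [(False, True)] + [(False, False)] * 4
        res = cohen_kappa(pairs)
        assert res.p_o == pytest.approx(0.8)
        assert res.p_e == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.6)

    def test_flipping_an_agreeing_pair_lowers_kappa(self):
        base = [(True, True)] * 4 + [(False, False)] * 6
        worse = [(True, True)] * 3 + [(True, False)] + [(False, False)] * 6
        assert cohen_kappa(worse).kappa < cohen_kappa(base).kappa == 1.0

    def test_independent_raters_give_near_zero(self):
        rng = np.random.default_rng(12)
        n = 4000
        pairs = list(zip(rng.random(n) < 0.5, rng.random(n) < 0.5))
        # under independence SE(kappa) ~ 1/sqrt(n) for balanced margins
        assert abs(cohen_kappa(pairs).kappa) < 3 / math.sqrt(n)

    def test_constant_raters_undefined(self):
        with pytest.raises(UndefinedKappaError):
            cohen_kappa([(True, True)] * 5)

    def test_matches_sklearn_on_small_tables(self):
        from sklearn.metrics import cohen_kappa_score

        for a, b, c, d in itertools.product(range(4), repeat=4):
            n = a + b + c + d
            if n == 0 or a == n or d == n:
                continue
            pairs = (
                [(True, True)] * a + [(True, False)] * b + [(False, True)] * c + [(False, False)] * d
            )
            ours = cohen_kappa(pairs).kappa
            ra = [p[0] for p in pairs]
            rb = [p[1] for p in pairs]
            assert ours == pytest.approx(cohen_kappa_score(ra, rb), abs=1e-12)


class TestSampleSize:
    def test_ppv_branch_published_value(self):
        assert sample_size_ppv(0.80, 0.10, 0.95).n_required == 62

    @pytest.mark.parametrize(
        "ppv,d,expected", [(0.50, 0.10, 97), (0.80, 0.20, 16), (0.80, 0.05, 246)]
    )
    def test_ppv_branch_scaling(self, ppv, d, expected):
        assert sample_size_ppv(ppv, d, 0.95).n_required == expected

    def test_snsp_branch_components(self):
        plan = sample_size_sn_sp(0.40, 0.90, 0.10, 0.10, 0.95)
        assert plan.n_sn == 922
        assert plan.n_sp == 39
        assert plan.n_required == 922

    def test_prevalence_one_limit(self):
        z2 = norm.ppf(0.975) ** 2
        plan = sample_size_sn_sp(0.40, 0.90, 1 - 1e-12, 0.10, 0.95)
        assert plan.n_sn == math.ceil(z2 * 0.4 * 0.6 / 0.01)

    def test_symmetry(self):
        plan = sample_size_sn_sp(0.50, 0.50, 0.5, 0.10, 0.95)
        assert plan.n_sn == plan.n_sp

    def test_monotone_in_precision_and_confidence(self):
        n_coarse = sample_size_ppv(0.7, 0.2, 0.95).n_required
        n_fine = sample_size_ppv(0.7, 0.05, 0.95).n_required
        assert n_fine >= n_coarse
        assert (
            sample_size_ppv(0.7, 0.1, 0.99).n_required
            >= sample_size_ppv(0.7, 0.1, 0.95).n_required
            >= sample_size_ppv(0.7, 0.1, 0.80).n_required
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sample_size_ppv(0.0, 0.1)
        with pytest.raises(ValueError):
            sample_size_sn_sp(0.4, 0.9, 0.1, 0.0)


def test_estimate_table_text_reports_undefined():
    text = estimate_table_text(TwoByTwo(38, 24, 0, 0))
    assert "PPV = 38/62" in text
    assert "undefined" in text
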