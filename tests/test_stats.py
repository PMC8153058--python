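"""Group t-tests, the distance/button confusion model, and the
correlation suite."""

import numpy as np
import pytest
from scipy import stats as sps

from numdecode import (
    correlation_suite, distance_button_model, one_sample_t, paired_t_cohend,
)
from numdecode.decoding import ConfusionMatrix
from numdecode.stats import COMPARE_BUTTON_MAP


class TestOneSampleT:
    def test_values_at_reference_give_zero_t(self):
        res = one_sample_t([0.30, 0.20, 0.28, 0.22], mu0=0.25)
        assert res.t == pytest.approx(0.0)  # mean is exactly 0.25
        assert res.p_uncorrected == pytest.approx(1.0)
        assert res.cohen_d == pytest.approx(0.0)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        x = 0.25 + 0.05 * rng.standard_normal(39)
        res = one_sample_t(x, mu0=0.25)
        ref = sps.ttest_1samp(x, 0.25)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p_uncorrected == pytest.approx(ref.pvalue)
        assert res.df == 38

    def test_bonferroni_monotone_and_capped(self):
        x = [0.3, 0.31, 0.29, 0.33, 0.28]
        ps = [one_sample_t(x, m_comparisons=m).p_bonferroni
              for m in (1, 4, 8, 10_000)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))
        assert ps[-1] == 1.0
        res = one_sample_t(x, m_comparisons=8)
        assert res.p_bonferroni == pytest.approx(
            min(1.0, 8 * res.p_uncorrected))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            one_sample_t([0.25, 0.25, 0.25])

    def test_one_tailed_halves_p_on_the_observed_side(self):
        x = [0.30, 0.32, 0.29, 0.31]
        two = one_sample_t(x)
        one = one_sample_t(x, tails=1)
        assert one.p_uncorrected == pytest.approx(two.p_uncorrected / 2)


class TestPairedT:
    def test_hand_computed_example(self):
        # diffs {1, 2, 3}: mean 2, SD 1 -> t = 2 * sqrt(3), d = 2
        res = paired_t_cohend([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.cohen_d == pytest.approx(2.0)
        assert res.df == 2

    def test_antisymmetry(self):
        a = np.array([0.3, 0.4, 0.25, 0.5])
        b = np.array([0.2, 0.45, 0.3, 0.35])
        fwd = paired_t_cohend(a, b)
        rev = paired_t_cohend(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.cohen_d == pytest.approx(-rev.cohen_d)

    def test_symmetric_differences_give_zero_t(self):
        res = paired_t_cohend([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert res.t == pytest.approx(0.0)
        assert res.cohen_d == pytest.approx(0.0)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError):
            paired_t_cohend([1.0, 2.0], [1.0, 2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_cohend([1.0, 2.0], [1.0])


def confusion_from_rates(rate_fn, noise=0.0, rng=None):
    """4x4 confusion matrix whose off-diagonal rates follow rate_fn."""
    labels = np.array([2, 4, 6, 8])
    counts = np.zeros((4, 4))
    for i, tgt in enumerate(labels):
        off = {}
        for j, pred in enumerate(labels):
            if pred == tgt:
                continue
            r = rate_fn(tgt, pred)
            if rng is not None and noise > 0:
                r = max(r + noise * rng.standard_normal(), 0.001)
            off[j] = r
        total_off = sum(off.values())
        for j, r in off.items():
            counts[i, j] = 1000 * r
        counts[i, i] = 1000 * max(1 - total_off, 0.01)
    return ConfusionMatrix(labels=labels, counts=counts)


class TestDistanceButtonModel:
    def test_recovers_pure_distance_structure(self):
        rng = np.random.default_rng(5)
        confusions = {
            f"sub-{i:02d}": confusion_from_rates(
                lambda t, p: 0.25 - 0.04 * abs(t - p),
                noise=0.005, rng=rng)
            for i in range(39)
        }
        res = distance_button_model(confusions)
        assert res.df == 38
        assert res.distance_t < 0 and res.distance_p < 0.001
        assert abs(res.button_t) < 2

    def test_recovers_pure_button_structure(self):
        rng = np.random.default_rng(6)
        confusions = {
            f"sub-{i:02d}": confusion_from_rates(
                lambda t, p: 0.05 + 0.15 * (
                    COMPARE_BUTTON_MAP[t] == COMPARE_BUTTON_MAP[p]),
                noise=0.005, rng=rng)
            for i in range(20)
        }
        res = distance_button_model(confusions)
        assert res.button_t > 0 and res.button_p < 0.001
        assert res.distance_p > 0.05

    def test_uniform_confusions_show_no_structure(self):
        rng = np.random.default_rng(7)
        null_ts = []
        for rep in range(20):
            confusions = {
                f"sub-{i:02d}": confusion_from_rates(
                    lambda t, p: 0.2, noise=0.02, rng=rng)
                for i in range(15)
            }
            res = distance_button_model(confusions)
            null_ts.append((abs(res.distance_t) < 2.5,
                            abs(res.button_t) < 2.5))
        frac_ok = np.mean([a and b for a, b in null_ts])
        assert frac_ok >= 0.8

    def test_too_few_participants_rejected(self):
        confusions = {"sub-00": confusion_from_rates(lambda t, p: 0.2)}
        with pytest.raises(ValueError):
            distance_button_model(confusions)


class TestCorrelationSuite:
    def test_perfect_monotone_association(self):
        x = np.arange(10, dtype=float)
        y = x**3 + 5
        rep = correlation_suite(x, y)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.kendall_tau == pytest.approx(1.0)

    def test_sign_reversal_swaps_one_sided_factors(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(39)
        y = -0.4 * x + 0.8 * rng.standard_normal(39)
        a = correlation_suite(x, y)
        b = correlation_suite(-x, y)
        assert a.bf_minus0 == pytest.approx(b.bf_plus0, rel=1e-8)
        assert a.bf10 == pytest.approx(b.bf10, rel=1e-8)

    def test_one_sided_p_smaller_in_observed_direction(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(39)
        y = -0.5 * x + 0.7 * rng.standard_normal(39)
        rep = correlation_suite(x, y, alternative="negative")
        assert rep.pearson_r < 0
        assert rep.p_one_pearson == pytest.approx(rep.p_two_pearson / 2)

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.standard_normal(39)
            y = rng.standard_normal(39)
            if correlation_suite(x, y).p_two_pearson < 0.05:
                hits += 1
        # binomial 99.9% band around 0.05 at 300 replicates
        assert 0.012 <= hits / n_rep <= 0.092

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlation_suite(np.ones(10), np.arange(10.0))

    def test_report_is_self_consistent(self, small_cohort):
        cov = small_cohort.covariates
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        rep = correlation_suite(x, y)
        assert rep.bf01 == pytest.approx(1 / rep.bf10)
        assert rep.n == 10
        assert -1 <= rep.pearson_r <= 1
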