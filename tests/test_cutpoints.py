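"""Cut-point estimators against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adatier.cutpoints import (
    CONFIRMATORY_LINEAR,
    NONPARAMETRIC_P95,
    PARAMETRIC_LOG,
    CutPointParams,
    CutPointResult,
    assess_normality,
    confirmatory_cutpoint,
    percent_inhibition,
    percentile,
    remove_iqr_outliers,
    screening_cutpoint_inhibited,
    screening_cutpoint_untreated,
)


# --- brute-force oracles -----------------------------------------------------

def oracle_percentile(values, p):
    """Sort and interpolate at position 1 + p(n-1), from first principles."""
    x = sorted(float(v) for v in values)
    pos = 1 + p * (len(x) - 1)
    k = int(np.floor(pos))
    frac = pos - k
    if k >= len(x):
        return x[-1]
    lo = x[k - 1]
    hi = x[k] if k < len(x) else x[-1]
    return lo + frac * (hi - lo)


def oracle_fence(values, fence=1.5):
    x = np.asarray(values, float)
    q1 = oracle_percentile(x, 0.25)
    q3 = oracle_percentile(x, 0.75)
    iqr = q3 - q1
    keep = [v for v in x if q1 - fence * iqr <= v <= q3 + fence * iqr]
    removed = [v for v in x if not (q1 - fence * iqr <= v <= q3 + fence * iqr)]
    return keep, removed


class TestPercentile:
    def test_worked_examples(self):
        assert percentile(range(1, 101), 0.95) == pytest.approx(95.05)
        assert percentile([0.0, 1.0], 0.95) == pytest.approx(0.95)
        assert percentile([7.0] * 12, 0.95) == 7.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=3, max_size=200),
        p=st.sampled_from([0.05, 0.25, 0.5, 0.75, 0.95]),
    )
    def test_matches_brute_force_oracle(self, values, p):
        assert percentile(values, p) == pytest.approx(oracle_percentile(values, p), abs=1e-9)


class TestOutlierRemoval:
    def test_worked_example(self):
        retained, removed = remove_iqr_outliers([1, 2, 3, 4, 100])
        assert list(removed) == [100.0]
        assert sorted(retained) == [1.0, 2.0, 3.0, 4.0]

    def test_constant_data_nothing_removed(self):
        retained, removed = remove_iqr_outliers([5.0] * 8)
        assert len(retained) == 8 and len(removed) == 0

    def test_tight_symmetric_data_identity(self):
        x = np.linspace(0.0, 1.0, 20)
        retained, removed = remove_iqr_outliers(x)
        assert len(removed) == 0

    def test_needs_four_values(self):
        with pytest.raises(ValueError):
            remove_iqr_outliers([1.0, 2.0, 3.0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-50, max_value=50), min_size=4, max_size=120))
    def test_matches_brute_force_oracle(self, values):
        retained, removed = remove_iqr_outliers(values)
        keep, drop = oracle_fence(values)
        assert sorted(retained) == pytest.approx(sorted(keep))
        assert sorted(removed) == pytest.approx(sorted(drop))


class TestNormality:
    def test_normal_draws_pass_at_expected_rate(self):
        """p > 0.10 in ~90% of normal samples (uniform p under the null)."""
        rng = np.random.default_rng(11)
        passed = sum(assess_normality(rng.normal(size=48)) > 0.10 for _ in range(1000))
        assert 0.85 <= passed / 1000 <= 0.95

    def test_lognormal_fails_reliably(self):
        rng = np.random.default_rng(12)
        failed = sum(
            assess_normality(rng.lognormal(0.0, 1.0, 48)) < 0.10 for _ in range(400)
        )
        assert failed / 400 > 0.90

    def test_constant_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            assess_normality([1.0] * 10)


class TestScreeningUntreated:
    def test_degenerate_constant_input(self):
        r = screening_cutpoint_untreated([0.5] * 12)
        assert r.cut_point == pytest.approx(0.5)
        assert r.method == PARAMETRIC_LOG

    def test_closed_form_limit_without_trimming(self):
        """With the fence disabled, the estimator converges on
        exp(mu + 1.645 sigma) of the log-normal population."""
        rng = np.random.default_rng(42)
        vals = rng.lognormal(0.0, 0.5, 4000)
        r = screening_cutpoint_untreated(vals, CutPointParams(outlier_fence=100.0))
        assert r.method == PARAMETRIC_LOG
        assert r.cut_point == pytest.approx(np.exp(1.645 * 0.5), rel=0.03)

    def test_closed_form_limit_with_default_fence(self):
        """The default fence trims ~0.7% of each tail of a normal sample,
        shrinking the SD slightly; the limit is still within a few percent
        of exp(mu + 1.645 sigma)."""
        rng = np.random.default_rng(42)
        vals = rng.lognormal(0.0, 0.5, 4000)
        r = screening_cutpoint_untreated(vals)
        assert r.cut_point == pytest.approx(np.exp(1.645 * 0.5), rel=0.06)

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            screening_cutpoint_untreated([0.5] * 11 + [-0.1])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            screening_cutpoint_untreated([0.5] * 9)

    def test_small_training_set_warns(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning, match="48"):
            screening_cutpoint_untreated(rng.lognormal(0, 0.3, 20))

    def test_fallback_when_logs_are_not_normal(self):
        """Bimodal data defeat the log transform; the estimator records the
        failed Shapiro gate and falls back to the 95th percentile."""
        rng = np.random.default_rng(13)
        vals = np.concatenate([rng.lognormal(-1.5, 0.1, 30), rng.lognormal(1.5, 0.1, 18)])
        r = screening_cutpoint_untreated(vals)
        assert r.method == NONPARAMETRIC_P95
        assert r.shapiro_p_transformed <= 0.10
        assert "fell back" in r.notes


class TestScreeningInhibited:
    def test_integers_1_to_100(self):
        r = screening_cutpoint_inhibited(list(range(1, 101)))
        assert r.cut_point == pytest.approx(95.05)
        assert r.method == NONPARAMETRIC_P95
        assert r.n_outliers_removed == 0

    def test_constant_input(self):
        r = screening_cutpoint_inhibited([0.42] * 15)
        assert r.cut_point == pytest.approx(0.42)

    def test_outlier_removed_before_percentile(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 3 + [100.0]
        r = screening_cutpoint_inhibited(vals)
        assert r.n_outliers_removed == 1
        assert r.cut_point == pytest.approx(percentile([1.0, 2.0, 3.0, 4.0] * 3, 0.95))


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [0.5, 3.0, 17.0])
    def test_both_screening_estimators_scale(self, c):
        rng = np.random.default_rng(21)
        vals = rng.lognormal(-1.5, 0.35, 48)
        for fn in (screening_cutpoint_untreated, screening_cutpoint_inhibited):
            base = fn(vals).cut_point
            scaled = fn(c * vals).cut_point
            assert scaled == pytest.approx(c * base, rel=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(22)
        vals = rng.lognormal(-1.5, 0.35, 48)
        perm = rng.permutation(vals)
        assert screening_cutpoint_untreated(vals).cut_point == pytest.approx(
            screening_cutpoint_untreated(perm).cut_point
        )
        assert screening_cutpoint_inhibited(vals).cut_point == pytest.approx(
            screening_cutpoint_inhibited(perm).cut_point
        )


class TestPercentInhibition:
    def test_worked_examples(self):
        assert percent_inhibition(1.0, 0.253) == pytest.approx(74.7)
        assert percent_inhibition(1.0, 1.0) == 0.0
        assert percent_inhibition(1.0, 1.2) == pytest.approx(-20.0)

    def test_untreated_must_be_positive(self):
        with pytest.raises(ValueError):
            percent_inhibition(0.0, 0.5)


class TestConfirmatory:
    def test_degenerate_constant(self):
        r = confirmatory_cutpoint([10.0] * 12)
        assert r.cut_point == pytest.approx(10.0)
        assert r.method == CONFIRMATORY_LINEAR

    def test_outlier_removed_before_mean_sd(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 3 + [100.0]
        r = confirmatory_cutpoint(vals)
        assert r.n_outliers_removed == 1
        kept = np.array([1.0, 2.0, 3.0, 4.0] * 3)
        assert r.cut_point == pytest.approx(kept.mean() + 1.645 * kept.std(ddof=1))

    def test_monte_carlo_matches_closed_form(self):
        """Normal inhibitions (mu=30, sigma=20, n=48): the mean estimated cut
        sits near 30 + 1.645 x 20 = 62.9, a little below because the fence
        trims extreme tails."""
        rng = np.random.default_rng(7)
        cuts = [
            confirmatory_cutpoint(rng.normal(30, 20, 48)).cut_point for _ in range(1000)
        ]
        assert np.mean(cuts) == pytest.approx(62.9, abs=2.5)


def test_result_invariants():
    with pytest.raises(ValueError):
        CutPointResult(cut_point=float("nan"), method=PARAMETRIC_LOG, n_input=10, n_outliers_removed=0)
    with pytest.raises(ValueError):
        CutPointResult(cut_point=1.0, method=PARAMETRIC_LOG, n_input=5, n_outliers_removed=5)
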