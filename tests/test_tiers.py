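"""Screen -> confirm -> titer cascade and isotype summaries."""

import numpy as np
import pytest

from adatier import pipeline
from adatier.cutpoints import (
    CONFIRMATORY_LINEAR,
    NONPARAMETRIC_P95,
    PARAMETRIC_LOG,
    CutPointResult,
)
from adatier.plates import BlankSummary, SampleResult
from adatier.simulate import SimulationConfig
from adatier.tiers import (
    DonorOutcome,
    MethodMismatchError,
    TiterSeries,
    classify_donor,
    confirm,
    determine_titer,
    screen,
    summarize_isotypes,
)


def sample(mean_od, donor="D1", antigen="SaCas9", condition="untreated"):
    return SampleResult(
        donor_id=donor, antigen=antigen, condition=condition,
        serum_dilution=20, mean_od=mean_od, sd_od=0.0, n_replicates=3,
    )


def screening_cut(value, method=PARAMETRIC_LOG):
    return CutPointResult(cut_point=value, method=method, n_input=48, n_outliers_removed=0)


def confirmatory_cut(value):
    return CutPointResult(cut_point=value, method=CONFIRMATORY_LINEAR, n_input=48, n_outliers_removed=0)


class TestScreen:
    def test_above_cut_is_positive(self):
        assert screen(sample(1.10), screening_cut(1.012))

    def test_tie_is_negative(self):
        assert not screen(sample(1.012), screening_cut(1.012))

    def test_below_cut_is_negative(self):
        assert not screen(sample(0.2), screening_cut(0.5129, NONPARAMETRIC_P95))

    def test_confirmatory_cut_rejected(self):
        with pytest.raises(MethodMismatchError):
            screen(sample(1.0), confirmatory_cut(71.61))


class TestConfirm:
    def test_above_cut_confirms(self):
        pi, ok = confirm(sample(1.0), sample(0.2, condition="inhibited"), confirmatory_cut(71.61))
        assert pi == pytest.approx(80.0)
        assert ok

    def test_tie_does_not_confirm(self):
        pi, ok = confirm(
            sample(1.0), sample(1.0 - 0.7161, condition="inhibited"), confirmatory_cut(71.61)
        )
        assert pi == pytest.approx(71.61)
        assert not ok

    def test_enhancement_does_not_confirm(self):
        pi, ok = confirm(sample(1.0), sample(1.05, condition="inhibited"), confirmatory_cut(71.61))
        assert pi == pytest.approx(-5.0)
        assert not ok

    def test_screening_cut_rejected(self):
        with pytest.raises(MethodMismatchError):
            confirm(sample(1.0), sample(0.2, condition="inhibited"), screening_cut(1.0))

    def test_mismatched_pair_rejected(self):
        with pytest.raises(ValueError, match="do not match"):
            confirm(sample(1.0, donor="D1"), sample(0.2, donor="D2", condition="inhibited"),
                    confirmatory_cut(71.61))

    def test_screen_positive_without_pair_names_donor(self):
        with pytest.raises(ValueError, match="D7"):
            classify_donor(sample(1.5, donor="D7"), None, screening_cut(1.0), confirmatory_cut(71.61))


class TestTiter:
    BLANK = BlankSummary("T1", 0.05, 0.01, 4)  # threshold 0.07

    def test_worked_example(self):
        series = TiterSeries([4, 16, 64, 256, 1024], [2.0, 1.2, 0.4, 0.09, 0.06], self.BLANK)
        assert determine_titer(series) == 256

    def test_all_below_threshold_is_none(self):
        series = TiterSeries([4, 16, 64], [0.06, 0.05, 0.04], self.BLANK)
        assert determine_titer(series) is None

    def test_exactly_at_threshold_excluded(self):
        series = TiterSeries([4, 16, 64], [2.0, 0.07, 0.01], self.BLANK)
        assert determine_titer(series) == 4

    def test_titer_non_increasing_in_threshold(self):
        rng = np.random.default_rng(5)
        dilutions = [4, 16, 64, 256, 1024]
        for _ in range(50):
            ods = np.sort(rng.uniform(0.0, 2.0, 5))[::-1]
            titers = []
            for sd in [0.0, 0.05, 0.2, 0.5]:
                series = TiterSeries(dilutions, list(ods), BlankSummary("T", 0.05, sd, 4))
                t = determine_titer(series)
                titers.append(0 if t is None else t)
            assert all(b <= a for a, b in zip(titers, titers[1:]))

    def test_series_invariants(self):
        with pytest.raises(ValueError, match="increasing"):
            TiterSeries([4, 4, 16], [1.0, 0.5, 0.2], self.BLANK)
        with pytest.raises(ValueError, match="length"):
            TiterSeries([4, 16], [1.0], self.BLANK)
        with pytest.raises(ValueError, match="empty"):
            TiterSeries([], [], self.BLANK)


class TestIsotypes:
    def outcome(self, donor, isotype):
        return DonorOutcome(
            donor_id=donor, antigen="SaCas9", screen_od=1.0, screen_positive=True,
            percent_inhibition=80.0, confirmed_positive=True, isotype=isotype,
        )

    def test_even_three_way_split_reports_igg4_zero(self):
        outcomes = [self.outcome("D1", "IgG1"), self.outcome("D2", "IgG2"), self.outcome("D3", "IgG3")]
        summary = summarize_isotypes(outcomes)
        assert summary["IgG1"] == pytest.approx(33.3, abs=0.05)
        assert summary["IgG2"] == pytest.approx(33.3, abs=0.05)
        assert summary["IgG3"] == pytest.approx(33.3, abs=0.05)
        assert summary["IgG4"] == 0.0

    def test_all_one_isotype(self):
        outcomes = [self.outcome(f"D{i}", "IgG1") for i in range(5)]
        assert summarize_isotypes(outcomes) == {"IgG1": 100.0, "IgG2": 0.0, "IgG3": 0.0, "IgG4": 0.0}

    def test_no_calls_warns_and_is_empty(self):
        with pytest.warns(UserWarning, match="no isotyped"):
            assert summarize_isotypes([]) == {}


class TestOutcomeInvariants:
    def test_confirmation_requires_screen_positive(self):
        with pytest.raises(ValueError):
            DonorOutcome("D1", "SaCas9", 0.2, False, confirmed_positive=True)

    def test_titer_requires_confirmation(self):
        with pytest.raises(ValueError):
            DonorOutcome("D1", "SaCas9", 1.2, True, percent_inhibition=80.0,
                         confirmed_positive=False, titer=64)


class TestCascade:
    def test_raising_od_never_unscreens(self):
        """Monotonicity of the strict-greater screening rule."""
        cut = screening_cut(0.5)
        conf = confirmatory_cut(20.0)
        rng = np.random.default_rng(9)
        for _ in range(100):
            od = float(rng.uniform(0.0, 1.5))
            bump = float(rng.uniform(0.0, 1.0))
            lo = classify_donor(sample(od), sample(od * 0.1, condition="inhibited"), cut, conf)
            hi = classify_donor(sample(od + bump), sample(od * 0.1, condition="inhibited"), cut, conf)
            assert hi.screen_positive >= lo.screen_positive

    def test_noise_free_end_to_end_classification(self):
        """Without noise, every seropositive donor above the screening cut
        whose inhibition fraction clears the confirmatory cut is confirmed,
        and no seronegative is (their 5% nonspecific inhibition sits far
        below the confirmatory cut)."""
        config = SimulationConfig(
            n_donors=60, prevalence_sa=0.2, prevalence_sp=0.0,
            noise_cv=0.0, blank_sd=0.0, seed=31,
        )
        result = pipeline.run_study(config, titrate=False)
        truth = {d.donor_id: d.seropositive_sa for d in result.donors}
        for o in result.outcomes["with_inhibition"]:
            if o.antigen != "SaCas9":
                continue
            if truth[o.donor_id]:
                assert o.screen_positive
                assert o.percent_inhibition == pytest.approx(74.7, abs=1e-6)
                assert o.confirmed_positive
            else:
                assert not bool(o.confirmed_positive)
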