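"""4PL fitting, quantitation limits, and the minimum-required-dilution rule."""

import numpy as np
import pytest

from adatier import plates
from adatier.curve import CurveQC, FourPLParams, determine_loq, determine_mrd, fit_4pl
from adatier.plates import SampleResult
from adatier.simulate import SimulationConfig, generate_standard_series


TRUE = FourPLParams(lower_asymptote=0.02, upper_asymptote=2.1, ec50=40.0, hill_slope=1.2)


def standards_from(params, concs, cv=0.0):
    return [
        SampleResult(
            donor_id=None, antigen="SaCas9", condition="standard", serum_dilution=1,
            mean_od=float(params(c)), sd_od=cv * float(params(c)), n_replicates=3,
            spiked_conc=float(c),
        )
        for c in concs
    ]


class TestFourPL:
    def test_evaluation_monotone_for_positive_slope(self):
        c = np.logspace(-2, 4, 60)
        od = TRUE(c)
        assert (np.diff(od) > 0).all()
        assert TRUE(0.0) == pytest.approx(TRUE.lower_asymptote)

    def test_inverse_round_trips(self):
        c = np.logspace(-1, 3, 9)
        np.testing.assert_allclose(TRUE.inverse(TRUE(c)), c, rtol=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FourPLParams(1.0, 0.5, 10.0, 1.0)
        with pytest.raises(ValueError):
            FourPLParams(0.0, 2.0, -1.0, 1.0)


class TestFit:
    def test_noise_free_exact_recovery(self):
        concs = 3000.0 / 4.0 ** np.arange(7)
        params, qc = fit_4pl(standards_from(TRUE, concs))
        assert params.ec50 == pytest.approx(TRUE.ec50, rel=1e-6)
        assert params.hill_slope == pytest.approx(TRUE.hill_slope, rel=1e-6)
        assert params.upper_asymptote == pytest.approx(TRUE.upper_asymptote, rel=1e-6)
        assert qc.residual_rms == pytest.approx(0.0, abs=1e-8)
        # clean data: every point recovers, so LLOQ is the lowest standard
        assert qc.lloq == pytest.approx(concs.min())
        assert qc.uloq == pytest.approx(concs.max())

    def test_too_few_concentrations_rejected(self):
        concs = [1.0, 10.0, 100.0]
        with pytest.raises(ValueError, match="5 distinct"):
            fit_4pl(standards_from(TRUE, concs))

    def test_noisy_ec50_recovery_over_seeds(self):
        """5% CV, 7x3 design: EC50 recovers within 15% for >=90% of seeds."""
        cfg = SimulationConfig(noise_cv=0.05)
        errs = []
        for s in range(100):
            rng = np.random.default_rng(100 + s)
            frame = generate_standard_series(cfg, 3000, 4, 7, rng=rng)
            corrected = plates.blank_correct(frame)
            standards = [
                x for x in plates.aggregate_replicates(corrected) if x.condition == "standard"
            ]
            params, _ = fit_4pl(standards)
            errs.append(abs(params.ec50 - cfg.fourpl.ec50) / cfg.fourpl.ec50)
        errs = np.asarray(errs)
        assert errs.mean() < 0.15
        assert np.quantile(errs, 0.90) < 0.15


class TestLoq:
    @pytest.mark.parametrize("top,expected", [(3000.0, 0.73), (1000.0, 0.24)])
    def test_clean_series_sensitivity_is_lowest_point(self, top, expected):
        """Noise-free 7-point 4-fold series: the LLOQ is the bottom standard."""
        concs = top / 4.0 ** np.arange(7)
        _, qc = fit_4pl(standards_from(TRUE, concs))
        assert round(qc.lloq, 2) == expected

    def test_corrupted_lowest_point_moves_lloq_up(self):
        concs = 3000.0 / 4.0 ** np.arange(7)
        standards = standards_from(TRUE, concs)
        params, _ = fit_4pl(standards)
        # re-measure the lowest standard at 50% recovery
        low = standards[-1] if standards[-1].spiked_conc == concs.min() else standards[0]
        bad_od = float(TRUE(concs.min() * 0.5))
        corrupted = [
            SampleResult(
                donor_id=None, antigen="SaCas9", condition="standard", serum_dilution=1,
                mean_od=bad_od, sd_od=0.0, n_replicates=3, spiked_conc=float(concs.min()),
            )
            if s.spiked_conc == concs.min()
            else s
            for s in standards
        ]
        qc = determine_loq(corrupted, params)
        assert qc.lloq == pytest.approx(sorted(concs)[1])

    def test_nothing_qualifies_flags_undefined(self):
        concs = 3000.0 / 4.0 ** np.arange(7)
        standards = [
            SampleResult(
                donor_id=None, antigen="SaCas9", condition="standard", serum_dilution=1,
                mean_od=float(TRUE(c)), sd_od=float(TRUE(c)) * 0.5,  # 50% CV everywhere
                n_replicates=3, spiked_conc=float(c),
            )
            for c in concs
        ]
        params, _ = fit_4pl(standards_from(TRUE, concs))
        with pytest.warns(UserWarning, match="LLOQ undefined"):
            qc = determine_loq(standards, params)
        assert qc.lloq is None and not qc.qualified

    def test_loq_bracket_every_qualifying_standard(self):
        concs = 3000.0 / 4.0 ** np.arange(7)
        standards = standards_from(TRUE, concs)
        params, qc = fit_4pl(standards)
        back = params.inverse(np.array([s.mean_od for s in standards]))
        nominal = np.array([s.spiked_conc for s in standards])
        ok = (back / nominal >= 0.8) & (back / nominal <= 1.2)
        assert nominal[ok].min() >= qc.lloq and nominal[ok].max() <= qc.uloq


def qc_with_range(dr):
    return CurveQC(lloq=1.0, uloq=100.0, dynamic_range_od=dr, residual_rms=0.0)


class TestMrd:
    RETENTIONS = {5: 0.55, 10: 0.71, 20: 0.83, 30: 0.90}

    def test_smallest_qualifying_dilution(self):
        serum = {d: qc_with_range(r) for d, r in self.RETENTIONS.items()}
        result = determine_mrd(serum, qc_with_range(1.0))
        assert result.mrd == 20
        assert result.monotone

    def test_no_dilution_qualifies(self):
        serum = {d: qc_with_range(r * 0.5) for d, r in self.RETENTIONS.items()}
        result = determine_mrd(serum, qc_with_range(1.0))
        assert result.mrd is None and result.note

    def test_zero_retention_accepts_smallest_dilution(self):
        serum = {d: qc_with_range(r) for d, r in self.RETENTIONS.items()}
        assert determine_mrd(serum, qc_with_range(1.0), retention=0.0).mrd == 5

    def test_scale_invariance(self):
        serum = {d: qc_with_range(r) for d, r in self.RETENTIONS.items()}
        base = determine_mrd(serum, qc_with_range(1.0))
        scaled = determine_mrd(
            {d: qc_with_range(3.7 * r) for d, r in self.RETENTIONS.items()},
            qc_with_range(3.7),
        )
        assert scaled.mrd == base.mrd
        for d in self.RETENTIONS:
            assert scaled.retention_by_dilution[d] == pytest.approx(
                base.retention_by_dilution[d]
            )

    def test_non_monotone_warns_but_returns_smallest(self):
        serum = {5: qc_with_range(0.85), 10: qc_with_range(0.75), 20: qc_with_range(0.9)}
        with pytest.warns(UserWarning, match="monotone"):
            result = determine_mrd(serum, qc_with_range(1.0))
        assert result.mrd == 5 and not result.monotone

    def test_needs_two_dilutions(self):
        with pytest.raises(ValueError):
            determine_mrd({20: qc_with_range(0.9)}, qc_with_range(1.0))
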