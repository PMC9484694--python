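import numpy as np
import pytest
from scipy.stats import skewnorm

from rippms import chem, synth
from rippms.ms_io import QQQ, QTOF, Chromatogram, SignalTable
from rippms.quant import (
    PeakCriteria,
    assess_peak,
    ecc,
    eic,
    fit_skewed_gaussian,
    fraction_from_areas,
    fraction_modified,
)

GRID = np.arange(1.0, 6.0, 0.005)


class TestEic:
    def test_window_inclusion(self):
        table = SignalTable.from_records([
            (1.0, 999.7, 10.0), (1.0, 1000.3, 20.0), (1.0, 1000.6, 40.0),
            (2.0, 500.0, 99.0),
        ])
        trace = eic(table, 1000.0, 0.5)
        np.testing.assert_allclose(trace.rt, [1.0, 2.0])
        np.testing.assert_allclose(trace.intensity, [30.0, 0.0])

    @pytest.mark.parametrize("instrument,z,expected", [
        (QQQ, 4, 0.5),    # ±2/x Da
        (QTOF, 2, 0.5),   # ±1/x Da
    ])
    def test_instrument_halfwidth(self, instrument, z, expected):
        assert instrument.eic_halfwidth(z) == pytest.approx(expected)

    def test_rejects_nonpositive_halfwidth(self):
        table = SignalTable.from_records([(1.0, 1000.0, 1.0)])
        with pytest.raises(ValueError):
            eic(table, 1000.0, 0.0)


class TestEcc:
    def test_pointwise_sum_identity(self, two_state_run, dehydration):
        _, table, _ = two_state_run
        states = chem.enumerate_states(synth.DEFAULT_FUSION_PEPTIDE,
                                       [dehydration])
        for state in states:
            chrom, per_charge = ecc(table, state, QQQ)
            total = sum(t.intensity for t in per_charge.values())
            np.testing.assert_array_equal(chrom.intensity, total)

    def test_apex_matches_injected_elution(self, two_state_run, dehydration):
        spec, table, truth = two_state_run
        states = chem.enumerate_states(synth.DEFAULT_FUSION_PEPTIDE,
                                       [dehydration])
        modified = next(s for s in states if s.label == "modified")
        chrom, _ = ecc(table, modified, QQQ)
        apex_rt = chrom.rt[np.argmax(chrom.intensity)]
        sp = next(s for s in spec.species if s.state.label == "modified")
        apex, width, skew = sp.elution
        true_apex = GRID[np.argmax(
            skewnorm.pdf(GRID, skew, loc=apex, scale=width))]
        assert abs(apex_rt - true_apex) <= QQQ.scan_interval / 60.0 + 1e-9

    def test_empty_table_all_zero(self, dehydration):
        table = SignalTable.from_records(
            [(t, 1999.9, 1.0) for t in GRID[:10]])
        state = chem.enumerate_states("W" * 60, [])[0]
        chrom, per_charge = ecc(table, state, QQQ)
        assert chrom.intensity.max() == 0.0


class TestFit:
    def test_parameter_recovery_within_one_percent(self):
        y = 100.0 * skewnorm.pdf(GRID, 1.0, loc=3.0, scale=0.1)
        fit = fit_skewed_gaussian(Chromatogram(GRID, y))
        assert fit.converged
        assert fit.area == pytest.approx(100.0, rel=0.01)
        assert fit.rt == pytest.approx(3.0, rel=0.01)
        assert fit.width == pytest.approx(0.1, rel=0.01)
        assert fit.skew == pytest.approx(1.0, rel=0.01)
        assert fit.baseline == pytest.approx(0.0, abs=1e-3)

    def test_flat_zero_not_converged(self):
        fit = fit_skewed_gaussian(Chromatogram(GRID, np.zeros_like(GRID)))
        assert not fit.converged and fit.area == 0.0

    def test_symmetric_peak_fits_zero_skew(self):
        y = 50.0 * skewnorm.pdf(GRID, 0.0, loc=3.0, scale=0.12)
        fit = fit_skewed_gaussian(Chromatogram(GRID, y))
        assert abs(fit.skew) < 0.05

    def test_needs_eight_points(self):
        with pytest.raises(ValueError):
            fit_skewed_gaussian(Chromatogram(GRID[:5], np.ones(5)))


def synthetic_ecc(charges, skew=1.0, width=0.08, apex=3.0,
                  second_peak=None):
    """Hand-built ECC + per-charge EICs on the standard grid.

    ``second_peak`` = (rt, height fraction of main apex) adds a
    contaminating symmetric peak to the compound trace.
    """
    profile = skewnorm.pdf(GRID, skew, loc=apex, scale=width)
    weights = np.ones(len(charges)) / len(charges)
    per_charge = {
        z: Chromatogram(GRID, 1e6 * w * profile, kind="EIC")
        for z, w in zip(charges, weights)
    }
    total = 1e6 * profile
    if second_peak is not None:
        rt2, frac = second_peak
        total = total + frac * total.max() * np.exp(
            -0.5 * ((GRID - rt2) / width) ** 2)
    return Chromatogram(GRID, total, kind="ECC"), per_charge


class TestAssessPeak:
    def assess(self, charges, **kw):
        chrom, per_charge = synthetic_ecc(charges, **kw)
        fit = fit_skewed_gaussian(chrom)
        return assess_peak(fit, chrom, per_charge)

    def test_clean_twelve_charge_peak_is_valid(self):
        result = self.assess(range(5, 17))
        assert result.valid and result.reasons == ()
        assert result.n_charge_states == 12
        assert result.n_consecutive == 12

    def test_too_few_charge_states(self):
        result = self.assess(range(5, 13))  # 8 states: "greater than eight" fails
        assert not result.valid
        assert result.reasons == ("charge_states",)

    def test_too_few_consecutive(self):
        result = self.assess([4, 6, 8, 10, 12, 14, 16, 18, 20])
        assert not result.valid
        assert result.reasons == ("consecutive",)

    def test_second_large_peak(self):
        result = self.assess(range(5, 17), second_peak=(5.0, 0.9))
        assert not result.valid
        assert "large_peaks" in result.reasons
        assert result.n_large_peaks == 1

    def test_small_peaks_tolerated_up_to_two(self):
        chrom, per_charge = synthetic_ecc(range(5, 17))
        extra = (0.5 * chrom.intensity.max()
                 * np.exp(-0.5 * ((GRID - 4.5) / 0.08) ** 2)
                 + 0.5 * chrom.intensity.max()
                 * np.exp(-0.5 * ((GRID - 5.3) / 0.08) ** 2))
        contaminated = Chromatogram(GRID, chrom.intensity + extra, kind="ECC")
        fit = fit_skewed_gaussian(chrom)
        result = assess_peak(fit, contaminated, per_charge)
        assert result.n_small_peaks == 2
        assert "small_peaks" not in result.reasons

    def test_excessive_skew(self):
        result = self.assess(range(5, 17), skew=2.0)
        assert not result.valid
        assert "skew" in result.reasons

    def test_excessive_width(self):
        result = self.assess(range(5, 17), width=0.3)
        assert not result.valid
        assert "width" in result.reasons


class TestFractionFromAreas:
    def test_modified_over_total(self):
        areas = [("unmodified", 25.0), ("modified", 75.0)]
        assert fraction_from_areas(areas) == pytest.approx(0.75)

    def test_partial_excluded_by_default(self):
        areas = [("unmodified", 20.0), ("partial", 30.0), ("modified", 50.0)]
        assert fraction_from_areas(areas) == pytest.approx(0.50)

    def test_partial_counted_when_requested(self):
        areas = [("unmodified", 20.0), ("partial", 30.0), ("modified", 50.0)]
        assert fraction_from_areas(areas, ("partial", "modified")) \
            == pytest.approx(0.80)

    def test_zero_total_undefined(self):
        assert fraction_from_areas([]) is None


class TestFractionModifiedPipeline:
    def test_recovers_injected_fraction(self, two_state_run, dehydration):
        _, table, truth = two_state_run
        result = fraction_modified(table, synth.DEFAULT_FUSION_PEPTIDE,
                                   [dehydration], QQQ)
        assert result.detected
        assert result.fraction_modified == pytest.approx(
            truth["fraction_modified"], abs=0.05)

    def test_area_conservation_noiseless(self, dehydration):
        spec = synth.standard_two_state_run(0.5, seed=9, noise=(0.0, 0.0))
        table, truth = synth.simulate_run(spec)
        result = fraction_modified(table, synth.DEFAULT_FUSION_PEPTIDE,
                                   [dehydration], QQQ)
        for state, fit, assessment in result.per_state:
            if fit is None:
                continue
            injected = next(s["abundance"] for s in truth["species"]
                            if s["label"] == state.label)
            assert fit.area == pytest.approx(injected, rel=0.05)

    def test_undetected_when_no_signal(self, dehydration):
        table = SignalTable.from_records(
            [(t, 600.0, 2000.0) for t in GRID[:50]])
        result = fraction_modified(table, synth.DEFAULT_FUSION_PEPTIDE,
                                   [dehydration], QQQ)
        assert not result.detected
        assert result.fraction_modified is None

    def test_monotone_in_modified_abundance(self, dehydration):
        estimates = []
        for f in (0.2, 0.4, 0.6, 0.8):
            spec = synth.standard_two_state_run(f, seed=11)
            table, _ = synth.simulate_run(spec)
            result = fraction_modified(table, synth.DEFAULT_FUSION_PEPTIDE,
                                       [dehydration], QQQ)
            estimates.append(result.fraction_modified)
        assert all(b > a for a, b in zip(estimates, estimates[1:]))

    def test_report_frame(self, two_state_run, dehydration):
        _, table, _ = two_state_run
        result = fraction_modified(table, synth.DEFAULT_FUSION_PEPTIDE,
                                   [dehydration], QQQ)
        frame = result.to_frame()
        assert set(frame["label"]) == {"unmodified", "modified"}
        assert (frame["valid"]).all()
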