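"""FRAP correction, normalization, fitting, immobile fraction."""

import numpy as np
import pytest

from pcpquant import frap as fr
from pcpquant import synthetic as sim
from pcpquant.frap import FRAPTrace, NormalizedTrace


def _trace(times, bleach, reference, background, n_prebleach=3):
    return FRAPTrace(np.asarray(times, float), np.asarray(bleach, float),
                     np.asarray(reference, float),
                     np.asarray(background, float), n_prebleach)


class TestCorrection:
    def test_hand_computed_correction(self):
        """bleach 110, bg 10, ref 190, pre-bleach ref mean (bg-sub) 200."""
        t = [-15.0, -10.0, -5.0, 0.0]
        trace = _trace(t, [210, 210, 210, 110], [210, 210, 210, 190],
                       [10, 10, 10, 10])
        corrected = fr.correct_trace(trace)
        assert corrected[-1] == pytest.approx(100.0 / (180.0 / 200.0))

    def test_constant_reference_is_unit_factor(self):
        t = np.arange(-3, 10, 1.0)
        bleach = 100.0 + 5.0 * np.arange(t.size)
        trace = _trace(t, bleach, np.full(t.size, 300.0),
                       np.full(t.size, 20.0))
        np.testing.assert_allclose(fr.correct_trace(trace), bleach - 20.0)

    def test_generator_acquisition_bleach_removed(self):
        """Corrected series is proportional to the bleach-free model."""
        p = sim.FRAPSimParams(mobile_fraction=0.5, rate_k=0.03,
                              acquisition_bleach_rate=0.002, noise_sd=0.0)
        traces, _ = sim.make_frap_traces(p)
        tr = fr.traces_from_table(traces)[0]
        corrected = fr.correct_trace(tr)
        t_post = tr.times[tr.n_prebleach:]
        model = sim.frap_recovery_model(t_post, p.bleach_depth,
                                        p.mobile_fraction, p.rate_k)
        ratio = corrected[tr.n_prebleach:] / model
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)
        # pre-bleach frames sit at the same scale as the model's unit level
        np.testing.assert_allclose(corrected[:tr.n_prebleach],
                                   ratio[0], rtol=1e-9)

    def test_nonpositive_reference_names_frame(self):
        trace = _trace([-10, -5, 0, 5], [100] * 4, [50, 50, 10, 50],
                       [10, 10, 10, 10], n_prebleach=2)
        with pytest.raises(ValueError, match="frame 2"):
            fr.correct_trace(trace)


class TestNormalization:
    def test_hand_computed_normalization(self):
        """pre {100,102,98}, F_bleach 20, later point 60 -> 0.5."""
        corrected = np.array([100.0, 102.0, 98.0, 20.0, 60.0])
        norm = fr.normalize_trace(corrected, n_prebleach=3)
        assert norm.value[0] == 0.0
        assert norm.value[1] == pytest.approx((60.0 - 20.0) / (100.0 - 20.0))

    def test_endpoints_of_the_scale(self):
        corrected = np.array([100.0, 100.0, 100.0, 30.0, 30.0, 100.0])
        norm = fr.normalize_trace(corrected, n_prebleach=3)
        assert norm.value[0] == 0.0   # F_t = F_bleach
        assert norm.value[-1] == 1.0  # F_t = F_ini

    def test_time_rebased_to_first_postbleach(self):
        corrected = np.array([100.0, 100.0, 100.0, 20.0, 40.0, 60.0])
        times = np.array([-15.9, -10.9, -5.9, 0.0, 5.0, 10.0])
        norm = fr.normalize_trace(corrected, 3, times=times)
        np.testing.assert_allclose(norm.t, [0.0, 5.0, 10.0])

    def test_no_bleach_depth_raises(self):
        with pytest.raises(ValueError, match="bleach depth"):
            fr.normalize_trace(np.full(10, 100.0), n_prebleach=3)

    def test_affine_invariance(self):
        """Consistent affine rescaling of all ROIs leaves the output unchanged."""
        p = sim.FRAPSimParams(mobile_fraction=0.7, noise_sd=0.0)
        traces, _ = sim.make_frap_traces(p)
        tr = fr.traces_from_table(traces)[0]
        norm1 = fr.normalize_trace(fr.correct_trace(tr), 3, times=tr.times)
        tr2 = FRAPTrace(tr.times, 3.0 * tr.bleach_roi + 40.0,
                        3.0 * tr.reference_roi + 40.0,
                        3.0 * tr.background_roi + 40.0, 3)
        norm2 = fr.normalize_trace(fr.correct_trace(tr2), 3, times=tr2.times)
        np.testing.assert_allclose(norm2.value, norm1.value, atol=1e-9)


class TestImmobileFraction:
    @pytest.mark.parametrize("y0, plateau, expected", [
        (0.0, 1.0, 0.0),
        (0.1, 0.1, 1.0),
        (0.0, 0.58, 0.42),
    ])
    def test_formula(self, y0, plateau, expected):
        value, flag = fr.immobile_fraction(y0, plateau)
        assert value == pytest.approx(expected)
        assert flag == "ok"

    def test_monotone_decreasing_in_plateau(self):
        values = [fr.immobile_fraction(0.1, p)[0] for p in (0.2, 0.5, 0.9)]
        assert values[0] > values[1] > values[2]

    def test_out_of_range_clipped_with_flag(self):
        value, flag = fr.immobile_fraction(0.0, 1.2)
        assert value == 0.0 and flag == "clipped"

    def test_y0_at_one_undefined(self):
        with pytest.raises(ValueError):
            fr.immobile_fraction(1.0, 1.0)


class TestFitting:
    def test_noiseless_round_trip_to_1e6(self):
        t = 5.0 * np.arange(60)
        y = fr.one_phase_association(t, 0.05, 0.60, 0.03)
        fit = fr.fit_recovery(NormalizedTrace(t=t, value=y))
        assert fit.Y0 == pytest.approx(0.05, abs=1e-6)
        assert fit.Plateau == pytest.approx(0.60, abs=1e-6)
        assert fit.k == pytest.approx(0.03, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_constant_series_immobile(self):
        t = 5.0 * np.arange(20)
        fit = fr.fit_recovery(NormalizedTrace(t=t, value=np.full(20, 0.3)))
        assert fit.Plateau == fit.Y0 == pytest.approx(0.3)
        assert np.isnan(fit.k)
        assert fit.immobile_fraction == 1.0

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fr.fit_recovery(NormalizedTrace(t=np.arange(4.0),
                                            value=np.zeros(4)))

    def test_noisy_ensemble_recovers_immobile_fraction(self):
        """50 traces, mobile 0.6, sigma 0.02: mean immobile within 0.05 of 0.4."""
        p = sim.FRAPSimParams(mobile_fraction=0.6, rate_k=0.02,
                              noise_sd=0.02 * 1000.0, n_traces=50, seed=17)
        traces, _ = sim.make_frap_traces(p)
        fits = [fr.process_trace(tr)[1] for tr in fr.traces_from_table(traces)]
        imms = [f.immobile_fraction for f in fits]
        assert abs(np.mean(imms) - 0.4) < 0.05

    def test_uncorrected_fits_overestimate_immobile_fraction(self):
        """Acquisition bleaching inflates the apparent immobile fraction."""
        p = sim.FRAPSimParams(mobile_fraction=0.7, rate_k=0.03,
                              acquisition_bleach_rate=0.002, noise_sd=0.0)
        traces, _ = sim.make_frap_traces(p)
        tr = fr.traces_from_table(traces)[0]
        corrected_fit = fr.process_trace(tr)[1]
        raw = tr.bleach_roi - tr.background_roi  # skip reference correction
        raw_fit = fr.fit_recovery(
            fr.normalize_trace(raw, tr.n_prebleach, times=tr.times))
        assert raw_fit.immobile_fraction > corrected_fit.immobile_fraction


class TestConditionSummary:
    def test_identical_traces_zero_sd(self):
        t = 5.0 * np.arange(30)
        y = fr.one_phase_association(t, 0.1, 0.7, 0.02)
        norm = NormalizedTrace(t=t, value=y)
        s = fr.summarize_frap([norm, NormalizedTrace(t=t, value=y.copy())])
        np.testing.assert_allclose(s.sd, 0.0, atol=1e-15)
        assert s.pooled_fit.Plateau == pytest.approx(0.7, abs=1e-6)

    def test_averaged_fit_equals_single_fit_for_identical_traces(self):
        t = 5.0 * np.arange(30)
        y = fr.one_phase_association(t, 0.0, 0.6, 0.05)
        norm = NormalizedTrace(t=t, value=y)
        single = fr.fit_recovery(norm)
        pooled = fr.summarize_frap([norm, norm]).pooled_fit
        assert pooled.Plateau == pytest.approx(single.Plateau, abs=1e-9)
        assert pooled.k == pytest.approx(single.k, abs=1e-9)

    def test_averaged_trace_recovers_immobile_fraction(self):
        p = sim.FRAPSimParams(mobile_fraction=0.7, rate_k=0.02,
                              noise_sd=0.02 * 1000.0, n_traces=30, seed=23)
        traces, _ = sim.make_frap_traces(p)
        norms = [fr.process_trace(tr)[0] for tr in fr.traces_from_table(traces)]
        s = fr.summarize_frap(norms)
        assert abs(s.pooled_fit.immobile_fraction - 0.3) < 0.05

    def test_mismatched_grids_rejected(self):
        a = NormalizedTrace(t=np.arange(10.0), value=np.zeros(10))
        b = NormalizedTrace(t=np.arange(10.0) * 2, value=np.zeros(10))
        with pytest.raises(ValueError, match="time grids"):
            fr.summarize_frap([a, b])
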