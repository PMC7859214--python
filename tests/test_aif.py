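"""AIF construction: subtraction, pixel selection, windowing, fitting."""

import numpy as np
import pytest

from vertperf import (
    DynamicSeries,
    InvalidParameterError,
    NoBolusError,
    ROIMask,
    aif_snr,
    blood_to_plasma,
    build_aif,
    extract_roi_curve,
    first_pass_window,
    normalize_population,
    select_sa_pixel,
    subtract_baseline_series,
)
from vertperf.aif import FirstPassFit, first_pass_model, fit_first_pass


def _series(signal, n_baseline=5):
    times = (np.arange(signal.shape[0]) + 0.5) * 2.0
    return DynamicSeries(signal=signal, times=times, n_baseline=n_baseline)


class TestSubtraction:
    def test_constant_series_subtracts_to_zero(self):
        s = _series(np.full((10, 3, 3), 7.0))
        out = subtract_baseline_series(s)
        np.testing.assert_array_equal(out.signal, 0.0)

    def test_single_pixel_bump_survives_exactly(self):
        sig = np.full((10, 3, 3), 2.0)
        sig[7, 1, 2] += 5.0
        out = subtract_baseline_series(_series(sig))
        assert out.signal[7, 1, 2] == pytest.approx(5.0)
        out.signal[7, 1, 2] = 0.0
        np.testing.assert_allclose(out.signal, 0.0, atol=1e-12)

    def test_phantom_artery_pixels_brightest_in_roi(self, noisy_bundle):
        sub = subtract_baseline_series(noisy_bundle.dynamic)
        roi = noisy_bundle.masks["sa_roi"].mask
        peaks = sub.signal.max(axis=0)
        truth = noisy_bundle.masks["sa_pixels"].mask
        # the two true artery pixels out-peak everything else in the ROI
        assert peaks[truth].min() > peaks[roi & ~truth].max()


class TestPixelSelection:
    def test_single_pixel_roi_forced_choice(self):
        mask = np.zeros((4, 4), bool)
        mask[2, 3] = True
        sig = np.random.default_rng(0).normal(size=(6, 4, 4))
        assert select_sa_pixel(_series(sig), ROIMask(mask)) == (2, 3)

    def test_tie_breaks_to_lowest_row_major_index(self):
        sig = np.zeros((6, 4, 4))
        sig[3, 1, 2] = 5.0
        sig[3, 2, 1] = 5.0
        mask = np.ones((4, 4), bool)
        picked = select_sa_pixel(_series(sig), ROIMask(mask))
        # exhaustive scan oracle
        peaks = sig.max(axis=0)
        best = max(
            ((r, c) for r in range(4) for c in range(4)),
            key=lambda rc: (peaks[rc], (-rc[0], -rc[1])),
        )
        assert picked == best == (1, 2)

    def test_phantom_selection_inside_truth_set(self, noisy_bundle):
        sub = subtract_baseline_series(noisy_bundle.dynamic)
        r, c = select_sa_pixel(sub, noisy_bundle.masks["sa_roi"])
        assert noisy_bundle.masks["sa_pixels"].mask[r, c]

    def test_invariant_to_constant_image_offset(self, noisy_bundle):
        dyn = noisy_bundle.dynamic
        offset = np.random.default_rng(1).normal(size=dyn.signal.shape[1:])
        shifted = DynamicSeries(signal=dyn.signal + offset, times=dyn.times,
                                n_baseline=dyn.n_baseline)
        roi = noisy_bundle.masks["sa_roi"]
        assert (select_sa_pixel(subtract_baseline_series(dyn), roi)
                == select_sa_pixel(subtract_baseline_series(shifted), roi))


class TestROICurve:
    def test_uniform_roi_equals_single_pixel(self):
        curve = np.linspace(0, 3, 8)
        arr = np.tile(curve[:, None, None], (1, 3, 3))
        out = extract_roi_curve(arr, ROIMask(np.ones((3, 3), bool)))
        np.testing.assert_allclose(out, curve)

    def test_two_pixel_mean(self):
        arr = np.zeros((5, 1, 2))
        c1, c2 = np.arange(5.0), np.arange(5.0) ** 2
        arr[:, 0, 0], arr[:, 0, 1] = c1, c2
        out = extract_roi_curve(arr, ROIMask(np.ones((1, 2), bool)))
        np.testing.assert_allclose(out, (c1 + c2) / 2)

    def test_phantom_aorta_curve_matches_generator(self, noiseless_analysis,
                                                   noiseless_bundle):
        curve = extract_roi_curve(noiseless_analysis.conc,
                                  noiseless_bundle.masks["aorta"])
        np.testing.assert_allclose(
            curve, noiseless_bundle.truth_curves["aorta_cb"], atol=1e-6)


class TestFirstPassWindow:
    def test_default_rule_peak_plus_three(self):
        curve = np.concatenate([np.zeros(8), [1, 3, 5, 4, 2, 1.5, 1.2, 1.1,
                                              1.0, 0.9, 0.8, 0.7]])
        w = first_pass_window(curve, 5)
        assert w[0] == 0 and w[-1] == 10 + 3

    def test_recirculation_bump_excluded(self):
        base = np.concatenate([np.zeros(8), [1, 3, 5, 4, 2.5, 1.8, 1.5],
                               1.4 * np.ones(15)])
        bump = base.copy()
        bump[20:25] += [0.5, 1.5, 2.0, 1.5, 0.5]  # second pass at +10 frames
        w = first_pass_window(bump, 5)
        assert w[-1] <= 13  # peak at 10, default +3; bump untouched
        assert 21 not in w

    def test_phantom_window_at_most_four_past_peak(self, noiseless_bundle):
        curve = noiseless_bundle.truth_curves["aorta_cb"]
        w = first_pass_window(curve, 5)
        assert w[-1] - int(np.argmax(curve)) <= 4

    def test_no_bolus_raises_with_diagnostic(self):
        rng = np.random.default_rng(0)
        flat = rng.normal(10.0, 0.1, 40)
        with pytest.raises(NoBolusError, match="baseline"):
            first_pass_window(flat, 5)


TRUE_FIT = dict(a_gauss=40.0, t_center=60.0, sigma=6.0, alpha_exp=1.2,
                beta_exp=0.002, s_sig=0.7, tau_sig=52.0)


class TestFirstPassFit:
    def _curve(self, times):
        return first_pass_model(times, **TRUE_FIT)

    def test_noiseless_recovery_of_all_parameters(self):
        times = (np.arange(120) + 0.5) * 2.0
        curve = self._curve(times)
        fit = fit_first_pass(curve, np.arange(120), times)
        for name, truth in TRUE_FIT.items():
            assert getattr(fit, name) == pytest.approx(truth, rel=0.01), name
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-6)

    def test_monte_carlo_peak_recovery_at_snr_40(self):
        times = (np.arange(60) + 0.5) * 2.0
        clean = self._curve(times)
        true_peak = clean.max()
        window = first_pass_window(clean, 5)
        rng = np.random.default_rng(2024)
        ok = 0
        n = 200
        for _ in range(n):
            noisy = clean + rng.normal(0, true_peak / 40.0, clean.shape)
            try:
                fit = fit_first_pass(noisy, window, times)
            except Exception:
                continue
            if abs(fit(times).max() - true_peak) / true_peak < 0.05:
                ok += 1
        assert ok >= 0.95 * n

    def test_fit_ignores_frames_outside_window(self):
        times = (np.arange(80) + 0.5) * 2.0
        curve = self._curve(times)
        window = first_pass_window(curve, 5)
        fit_a = fit_first_pass(curve, window, times)
        perturbed = curve.copy()
        perturbed[window[-1] + 1:] += 17.0  # garbage past the window
        fit_b = fit_first_pass(perturbed, window, times)
        assert fit_a.as_dict() == fit_b.as_dict()

    def test_phantom_fit_below_raw_at_second_pass(self, noiseless_analysis,
                                                  noiseless_bundle):
        aif = noiseless_analysis.aifs["aortic"]
        raw = aif.raw
        # around the recirculation bump the fitted first pass is below raw
        spec = noiseless_bundle.spec
        i = int((spec.bolus_center + spec.recirc_lag) / spec.frame_interval)
        assert np.all(aif.cb[i - 2: i + 3] < raw[i - 2: i + 3])


class TestPlasmaAndSNR:
    def test_hematocrit_scaling_example(self):
        cb = np.array([0.0, 5.8, 2.0])
        cp = blood_to_plasma(cb, 0.42)
        assert cp[1] == pytest.approx(10.0)

    def test_zero_hct_identity_and_default(self):
        cb = np.array([1.0, 2.0])
        np.testing.assert_array_equal(blood_to_plasma(cb, 0.0), cb)
        # default hematocrit is 0.42
        assert blood_to_plasma(np.array([5.8])) == pytest.approx([10.0])

    def test_invalid_hct_raises(self):
        with pytest.raises(InvalidParameterError):
            blood_to_plasma(np.ones(3), 1.0)

    def test_cp_cb_ratio_constant(self, noiseless_analysis):
        aif = noiseless_analysis.aifs["aortic"]
        sel = aif.cb > 1e-6
        np.testing.assert_allclose(aif.cp[sel] / aif.cb[sel], 1 / 0.58,
                                   rtol=1e-12)

    def test_snr_arithmetic(self):
        curve = np.concatenate([[0.1, -0.1, 0.1, -0.1, 0.1] , [2.0]])
        assert aif_snr(curve, 5) == pytest.approx(2.0 / np.std(curve[:5]))

    def test_constant_baseline_flagged_infinite(self):
        with pytest.warns(RuntimeWarning):
            assert np.isinf(aif_snr(np.array([1.0, 1, 1, 1, 1, 3]), 5))

    def test_phantom_aortic_snr_exceeds_segmental(self, noisy_analysis):
        assert (noisy_analysis.aifs["aortic"].snr
                > noisy_analysis.aifs["segmental"].snr)


class TestNormalization:
    def test_output_peak_is_population_value(self, noiseless_analysis):
        pop = normalize_population(noiseless_analysis.aifs["aortic"])
        assert pop.peak == pytest.approx(6.0, rel=1e-12)
        assert pop.kind == "population"

    def test_idempotent_at_same_target(self, noiseless_analysis):
        pop = normalize_population(noiseless_analysis.aifs["aortic"], 6.0)
        again = normalize_population(pop, 6.0)
        np.testing.assert_allclose(again.cb, pop.cb, rtol=1e-12)

    def test_argmax_frame_unchanged(self, noiseless_analysis):
        aif = noiseless_analysis.aifs["aortic"]
        pop = normalize_population(aif, 6.0)
        assert np.argmax(pop.cb) == np.argmax(aif.cb)

    def test_curve_already_at_target_unchanged(self, times):
        fit = FirstPassFit(30.0, 60.0, 5.0, 0.5, 0.001, 0.7, 55.0)
        cb = fit(times)
        from vertperf.aif import AIFCurve

        aif = AIFCurve(cb=cb * (6.0 / cb.max()), times=times)
        out = normalize_population(aif, 6.0)
        np.testing.assert_allclose(out.cb, aif.cb, rtol=1e-12)

    def test_zero_peak_rejected(self, times):
        from vertperf.aif import AIFCurve

        with pytest.raises(InvalidParameterError):
            normalize_population(AIFCurve(cb=np.zeros_like(times),
                                          times=times))


class TestBuildAIF:
    def test_early_bolus_inside_baseline_rejected(self):
        times = (np.arange(60) + 0.5) * 2.0
        curve = first_pass_model(times, 30.0, 8.0, 2.0, 0.3, 0.0, 1.0, 5.0)
        with pytest.raises(NoBolusError):
            build_aif(curve, times, n_baseline=5)
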