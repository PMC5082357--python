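"""Parameter recovery by Levenberg–Marquardt fitting, the single-beat
shortening pipeline, template matching and the semi-automatic multi-beat
loop with its stop and discard rules."""

import numpy as np
import pytest

from ewavekit import (
    AutofitOptions,
    DetectionSettings,
    DopplerStrip,
    PDFModel,
    PDFParameters,
    autofit_sequence,
    build_start_template,
    detect_envelope,
    fit_pdf,
    fit_with_shortening,
    locate_start,
    model_velocity,
    peak_characteristics,
    synth_strip,
    synth_trace,
)
from ewavekit.envelope import VelocityTrace
from ewavekit.errors import FitError, NoMatchError
from ewavekit.synthetic import ArtifactSpec

from conftest import plain_settings, random_underdamped, strip_spec


def rel_err(result, truth: PDFParameters) -> np.ndarray:
    return np.abs(np.array(result.params.as_tuple())
                  / np.array(truth.as_tuple()) - 1.0)


class TestFitPdf:
    @pytest.mark.parametrize("fixture", ["worked_example_a", "worked_example_b"])
    def test_noise_free_recovery_within_half_percent(self, fixture, request):
        truth = request.getfixturevalue(fixture)
        res = fit_pdf(synth_trace(truth, dt=0.001))
        assert res.converged
        assert rel_err(res, truth).max() < 0.005

    def test_undamped_boundary_recovery(self):
        truth = PDFParameters(c=0.0, k=100.0, x0=10.0)
        res = fit_pdf(synth_trace(truth, dt=0.001))
        assert res.params.c <= 0.1
        assert res.params.k == pytest.approx(100.0, rel=0.005)
        assert res.params.x0 == pytest.approx(10.0, rel=0.005)

    def test_random_underdamped_recovery(self, rng):
        for truth in random_underdamped(rng, 50):
            res = fit_pdf(synth_trace(truth, dt=0.002))
            assert rel_err(res, truth).max() < 0.005, truth

    def test_noisy_recovery_mean_error(self, worked_example_a):
        errs = [rel_err(fit_pdf(synth_trace(worked_example_a, dt=0.002,
                                            noise_sd=3.0, seed=s)),
                        worked_example_a)
                for s in range(50)]
        mae = np.mean(errs, axis=0)
        assert mae[1] < 0.05      # stiffness k
        assert np.all(mae < 0.07)

    def test_residual_tiny_on_own_model_data(self, worked_example_a):
        res = fit_pdf(synth_trace(worked_example_a, dt=0.001))
        vmax = peak_characteristics(worked_example_a)[1]
        assert res.residual_norm <= 1e-6 * vmax

    def test_invariant_to_uniform_time_shift(self, worked_example_a):
        trace = synth_trace(worked_example_a, dt=0.002)
        shifted = VelocityTrace(times=trace.times + 0.37,
                                velocities=trace.velocities,
                                accepted=trace.accepted)
        a = fit_pdf(trace).params
        b = fit_pdf(shifted).params
        assert b.c == pytest.approx(a.c, rel=1e-6, abs=1e-8)
        assert b.k == pytest.approx(a.k, rel=1e-6)
        assert b.x0 == pytest.approx(a.x0, rel=1e-6)

    def test_too_few_samples_rejected(self):
        t = np.array([0.0, 0.01, 0.02, 0.03])
        with pytest.raises(FitError):
            PDFModel(VelocityTrace(times=t, velocities=t * 100,
                                   accepted=np.ones_like(t, bool)))

    def test_triad_method_skips_optimizer(self, worked_example_a):
        res = PDFModel(synth_trace(worked_example_a, dt=0.002)).fit(
            init=worked_example_a, method="triad")
        assert res.method == "triad"
        assert res.nfev == 0
        assert res.params == worked_example_a


class TestResultsObject:
    def test_summary_and_diagnostics(self, worked_example_a):
        res = fit_pdf(synth_trace(worked_example_a, dt=0.002, noise_sd=2.0, seed=1))
        text = res.summary()
        for token in ("c", "k", "x0", "KFEI", "converged"):
            assert token in text
        assert set(res.bse) == {"c", "k", "x0"}
        assert all(np.isfinite(v) and v > 0 for v in res.bse.values())
        assert res.nobs == len(res.fittedvalues) == len(res.resid)

    def test_from_dataframe_constructor(self, worked_example_a):
        import pandas as pd

        trace = synth_trace(worked_example_a, dt=0.002)
        df = pd.DataFrame({"time_s": trace.times, "velocity_cm_s": trace.velocities})
        res = PDFModel.from_dataframe(df).fit()
        assert rel_err(res, worked_example_a).max() < 0.005

    def test_predict_matches_model(self, worked_example_a):
        res = fit_pdf(synth_trace(worked_example_a, dt=0.001))
        t = np.linspace(0, 0.3, 7)
        np.testing.assert_allclose(res.predict(t),
                                   model_velocity(res.params, t))


class TestShorteningPipeline:
    def test_flags_off_equals_detect_plus_fit(self, worked_example_a):
        strip, truth = synth_strip(strip_spec(worked_example_a, seed=11))
        settings = plain_settings(truth.duration_s)
        direct = fit_pdf(detect_envelope(strip, settings))
        piped = fit_with_shortening(strip, settings)
        assert piped.params == direct.params
        assert piped.stages == ["detect_envelope", "fit_pdf"]

    def test_zero_tail_alone_near_neutral_on_clean_strip(self, worked_example_a):
        # zeroing the last two samples barely moves a clean fit (the wave is
        # essentially at the baseline there anyway)
        strip, truth = synth_strip(strip_spec(worked_example_a, seed=12))
        off = fit_with_shortening(strip, plain_settings(truth.duration_s))
        zt = fit_with_shortening(strip, DetectionSettings(
            t_start=0.0, t_end=truth.duration_s, tangent_shorten=False))
        rel = np.abs(np.array(zt.params.as_tuple())
                     / np.array(off.params.as_tuple()) - 1.0)
        assert rel.max() < 0.02

    def test_tangent_pulls_edec_toward_clinical_line_on_clean_strip(
            self, worked_example_a):
        # the clinical tangent line meets the baseline before the model's
        # exponential tail, so enabling both corrections shortens the fitted
        # deceleration time on a clean strip — a bounded, directional shift
        strip, truth = synth_strip(strip_spec(worked_example_a, seed=12))
        off = fit_with_shortening(strip, plain_settings(truth.duration_s))
        on = fit_with_shortening(strip, DetectionSettings(
            t_start=0.0, t_end=truth.duration_s))
        assert on.indices.edec < off.indices.edec
        rel = np.abs(np.array(on.params.as_tuple())
                     / np.array(off.params.as_tuple()) - 1.0)
        assert rel.max() < 0.20

    def test_artifacts_shortening_reduces_edec_error(self, worked_example_a):
        from ewavekit.model import derived_indices

        spec = strip_spec(worked_example_a, seed=3, headroom_cm_s=40.0,
                          artifact=ArtifactSpec(probability=0.6))
        strip, truth = synth_strip(spec)
        edec_true = derived_indices(worked_example_a).edec
        off = fit_with_shortening(strip, plain_settings(truth.duration_s))
        on = fit_with_shortening(strip, DetectionSettings(
            t_start=0.0, t_end=truth.duration_s))
        assert abs(on.indices.edec - edec_true) < abs(off.indices.edec - edec_true)


class TestTemplateMatching:
    def test_self_localization_is_exact(self, worked_example_a):
        strip, truth = synth_strip(strip_spec(worked_example_a, seed=9))
        fit = fit_with_shortening(strip, plain_settings(truth.duration_s))
        template = build_start_template(strip, fit)
        assert locate_start(template, strip) == pytest.approx(0.0, abs=1e-12)

    def test_translation_equivariance(self, worked_example_a):
        strip, truth = synth_strip(strip_spec(worked_example_a, seed=9))
        fit = fit_with_shortening(strip, plain_settings(truth.duration_s))
        template = build_start_template(strip, fit)
        shifted = DopplerStrip(np.roll(strip.pixels, 10, axis=1),
                               strip.dt_per_col, strip.dv_per_row,
                               strip.baseline_row)
        assert locate_start(template, shifted) == pytest.approx(
            10 * strip.dt_per_col)

    def test_clipped_template_flagged(self, worked_example_a):
        strip, truth = synth_strip(strip_spec(worked_example_a, seed=9))
        fit = fit_with_shortening(strip, plain_settings(truth.duration_s))
        # onset at column 0 clips the left half of the patch
        template = build_start_template(strip, fit, half_width=10)
        assert template.clipped
        assert template.col_start == 0
        # an interior onset is not clipped
        rolled = DopplerStrip(np.roll(strip.pixels, 40, axis=1),
                              strip.dt_per_col, strip.dv_per_row,
                              strip.baseline_row)
        t_on = locate_start(template, rolled)
        trace = detect_envelope(rolled, DetectionSettings(
            t_start=t_on, t_end=t_on + 0.40, zero_tail=False,
            tangent_shorten=False))
        interior = build_start_template(rolled, fit_pdf(trace), half_width=10)
        assert not interior.clipped

    def test_pure_noise_raises_no_match(self, worked_example_a, rng):
        strip, truth = synth_strip(strip_spec(worked_example_a, seed=9))
        fit = fit_with_shortening(strip, plain_settings(truth.duration_s))
        template = build_start_template(strip, fit)
        noise = DopplerStrip(rng.integers(0, 255, (160, 320)).astype(np.uint8),
                             strip.dt_per_col, strip.dv_per_row, 150)
        with pytest.raises(NoMatchError):
            locate_start(template, noise, floor=0.6)


class TestAutofit:
    def _beats(self, params_list, seed0=0, **kw):
        return [synth_strip(strip_spec(p, seed=seed0 + i, **kw))[0]
                for i, p in enumerate(params_list)]

    def test_identical_beats_all_accepted(self, worked_example_a):
        beats = self._beats([worked_example_a] * 5)
        settings = plain_settings(0.40)
        seed_fit = fit_with_shortening(beats[0], settings)
        report = autofit_sequence(beats, seed_fit,
                                  AutofitOptions(detection=settings))
        assert len(report.fits) == 5
        assert report.discarded == []

    def test_forty_percent_deviation_discards(self, worked_example_a):
        params = [worked_example_a] * 3 + [PDFParameters(17.3, 220.0, 11.4)]
        beats = self._beats(params, headroom_cm_s=40.0)
        settings = plain_settings(0.40)
        seed_fit = fit_with_shortening(beats[0], settings)
        report = autofit_sequence(beats, seed_fit,
                                  AutofitOptions(detection=settings))
        # |220 - 135| / 135 = 0.63 > 0.40 -> the 4th beat is discarded
        assert [i for i, _ in report.discarded] == [3]
        assert report.discarded[0][1] == "parameter-deviation"
        assert len(report.fits) == 3

    def test_smooth_load_drift_tracked(self, worked_example_a):
        params = [PDFParameters(17.3, 135.0, 11.4 * 1.05**i) for i in range(6)]
        beats = self._beats(params, headroom_cm_s=40.0)
        settings = plain_settings(0.40)
        seed_fit = fit_with_shortening(beats[0], settings)
        report = autofit_sequence(beats, seed_fit,
                                  AutofitOptions(detection=settings))
        assert report.discarded == []
        devs = [d for d in report.deviations[1:]]
        assert all(d <= 0.40 for d in devs)

    def test_partition_property(self, worked_example_a, rng):
        params = [worked_example_a] * 3 + [PDFParameters(17.3, 220.0, 11.4)]
        beats = self._beats(params, headroom_cm_s=40.0)
        noise = DopplerStrip(rng.integers(0, 30, (160, 320)).astype(np.uint8),
                             beats[0].dt_per_col, beats[0].dv_per_row, 150)
        beats.append(noise)  # unmatched beat
        settings = plain_settings(0.40)
        seed_fit = fit_with_shortening(beats[0], settings)
        report = autofit_sequence(beats, seed_fit,
                                  AutofitOptions(detection=settings))
        assert len(report.fits) + len(report.discarded) == len(beats)
        reasons = dict(report.discarded)
        assert reasons[4] == "no-template-match"

    def test_stop_rules_bound_detection_window(self, worked_example_a):
        # the detected window never extends past 1/3 cycle, and ends once
        # velocity drops below 35% of the wave's peak
        beats = self._beats([worked_example_a] * 2)
        settings = plain_settings(0.40)
        seed_fit = fit_with_shortening(beats[0], settings)
        options = AutofitOptions(detection=settings, cycle_length_s=0.8)
        report = autofit_sequence(beats, seed_fit, options)
        trace = report.fits[1].trace
        assert trace.times[-1] <= 0.8 / 3.0 + 1e-9
        v = trace.accepted_velocities
        i_peak = int(np.argmax(v))
        below = v[i_peak:] < 0.35 * v[i_peak]
        # at most the single stop sample sits below the 35% floor
        assert below.sum() <= 1
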