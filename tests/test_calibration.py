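"""V-log(I) fitting, the equivalent-intensity transform, and S(λ)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ergspectra import (CalibrationError, DegenerateFitError, ERGSession,
                        FitError, ValidationError, average_sensitivities,
                        equivalent_log_intensity, fit_vlogi,
                        sensitivity_spectrum, simulate_study)
from ergspectra.calibration import VLogICurve
from ergspectra.simulate import default_truth
from ergspectra.templates import OpsinTemplate, template_sensitivity


def _white_session(x, v, i_min=1e12, adaptation="dark"):
    """Build a session whose white ladder realises the given (x, V) points."""
    intensities = i_min * 10.0 ** np.asarray(x, dtype=float)
    return ERGSession("t01", "female", adaptation,
                      white_before=[(float(i), float(a))
                                    for i, a in zip(intensities, v)])


class TestVLogIFit:
    def test_exact_line_recovered(self):
        curve = fit_vlogi(_white_session([0, 1, 2, 3], [0, 2, 4, 6]))
        assert curve.slope == pytest.approx(2.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.x_range == (0.0, pytest.approx(3.0))

    def test_before_and_after_series_averaged_per_intensity(self):
        s = _white_session([0, 1, 2], [1, 3, 5])
        s.white_after = [(i, a + 2.0) for (i, _), a in
                         zip(s.white_before, [1, 3, 5])]
        curve = fit_vlogi(s)
        # fit runs on the averaged ladder [2, 4, 6]
        assert curve.slope == pytest.approx(2.0, abs=1e-12)
        assert curve.intercept == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_closed_form_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 3.9, 8)
        v = np.abs(2.1 * x + 0.4 + rng.normal(0, 0.3, 8))
        curve = fit_vlogi(_white_session(x, v))
        slope_ref, intercept_ref = np.polyfit(x, v, 1)
        assert curve.slope == pytest.approx(slope_ref, abs=1e-10)
        assert curve.intercept == pytest.approx(intercept_ref, abs=1e-10)

    def test_single_intensity_is_a_fit_error(self):
        with pytest.raises(FitError):
            fit_vlogi(_white_session([0], [1]))

    def test_flat_response_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_vlogi(_white_session([0, 1, 2], [3, 3, 3]))


class TestEquivalentIntensity:
    curve = VLogICurve(slope=2.0, intercept=0.0, x_offset=12.0,
                       r_squared=1.0, x_range=(0.0, 3.0), n_points=8)

    def test_amplitude_at_intercept_maps_to_zero(self):
        c = VLogICurve(slope=1.5, intercept=0.7, x_offset=12.0,
                       r_squared=1.0, x_range=(0.0, 3.0), n_points=8)
        assert equivalent_log_intensity(c, 0.7) == pytest.approx(0.0)

    def test_simple_inversion(self):
        assert equivalent_log_intensity(self.curve, 5.0) == pytest.approx(2.5)

    def test_extrapolation_flagged_not_rejected(self):
        x, flags = equivalent_log_intensity(self.curve, [1.0, 9.0],
                                            return_flags=True)
        assert list(flags) == [False, True]
        assert x[1] == pytest.approx(4.5)

    def test_nonpositive_slope_rejected(self):
        bad = VLogICurve(slope=-1.0, intercept=0.0, x_offset=12.0,
                         r_squared=0.5, x_range=(0.0, 3.0), n_points=8)
        with pytest.raises(CalibrationError):
            equivalent_log_intensity(bad, 1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 3.0))
    def test_forward_then_inverse_is_identity(self, x):
        assert equivalent_log_intensity(
            self.curve, self.curve.predict(x)) == pytest.approx(x, abs=1e-12)


class TestSensitivitySpectrum:
    def _mono_session(self, amplitudes, wavelengths=(400.0, 500.0)):
        s = _white_session([0, 1, 2, 3], [0, 2, 4, 6])
        s.mono_responses = [(1, float(w), float(a))
                            for w, a in zip(wavelengths, amplitudes)]
        return s

    def test_one_decade_below_maximum_gives_a_tenth(self):
        # amplitudes chosen so x_eq = [2, 3]
        spec = sensitivity_spectrum(self._mono_session([4.0, 6.0]))
        assert list(spec.values) == [pytest.approx(0.1), pytest.approx(1.0)]

    def test_constant_responses_give_unit_sensitivity_with_tie_flag(self):
        with pytest.warns(UserWarning, match="tie"):
            spec = sensitivity_spectrum(self._mono_session([4.0, 4.0]))
        assert np.allclose(spec.values, 1.0)
        assert spec.peak_tied

    def test_all_zero_mono_responses_rejected(self):
        with pytest.raises(ValidationError, match="zero"):
            sensitivity_spectrum(self._mono_session([0.0, 0.0]))

    def test_zero_noise_single_receptor_recovers_template_ratio(
            self, protocol):
        truth = default_truth(
            noise_sd=0.0, n_per_sex=1,
            receptors=(default_truth().receptors[1],),   # LW only
            ki={"LW": {"dark": 1.0, "dim_green": 1.0, "bright_green": 1.0}},
            reference_map={"LW": "dark"})
        session = next(s for s in simulate_study(protocol, truth)
                       if s.adaptation_label == "dark")
        spec = sensitivity_spectrum(session)
        r = template_sensitivity(OpsinTemplate(lambda_max=527.0),
                                 spec.wavelengths)
        assert np.allclose(spec.values, r / r.max(), atol=1e-8)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(scale=st.floats(0.2, 5.0), shift=st.floats(0.0, 3.0))
    def test_affine_amplitude_rescaling_cancels(self, protocol, scale, shift):
        """Rescaling every amplitude V -> scale*V + shift and refitting the
        calibration leaves S(λ) unchanged: the transform cancels a and b."""
        session = next(s for s in simulate_study(
            protocol, default_truth(n_per_sex=1, seed=4))
            if s.adaptation_label == "dark")
        ref = sensitivity_spectrum(session)
        scaled = ERGSession(
            session.individual_id, session.sex, session.adaptation_label,
            white_before=[(i, scale * a + shift)
                          for i, a in session.white_before],
            white_after=[(i, scale * a + shift)
                         for i, a in session.white_after],
            mono_responses=[(r, w, scale * a + shift)
                            for r, w, a in session.mono_responses])
        assert np.allclose(sensitivity_spectrum(scaled).values, ref.values,
                           atol=1e-9)


class TestAveraging:
    def _curve(self, values, label="dark"):
        from ergspectra import SpectralSensitivity
        return SpectralSensitivity(wavelengths=np.array([400.0, 500.0]),
                                   values=np.asarray(values, dtype=float),
                                   adaptation_label=label)

    def test_single_curve_average_is_itself_with_zero_sd(self):
        avg = average_sensitivities([self._curve([0.2, 1.0])], "pooled")
        assert np.allclose(avg.values, [0.2, 1.0])
        assert np.allclose(avg.sd, 0.0)
        assert avg.n == 1

    def test_two_curve_mean_and_sd(self):
        avg = average_sensitivities(
            [self._curve([0.2, 1.0]), self._curve([0.4, 1.0])], "pooled")
        assert np.allclose(avg.values, [0.3, 1.0])
        assert avg.sd[0] == pytest.approx(np.sqrt(2) * 0.1, rel=1e-9)
        assert avg.sd[1] == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            average_sensitivities([], "pooled")

    def test_mismatched_grids_rejected(self):
        from ergspectra import SpectralSensitivity
        a = self._curve([0.2, 1.0])
        b = SpectralSensitivity(wavelengths=np.array([410.0, 500.0]),
                                values=np.array([0.2, 1.0]),
                                adaptation_label="dark")
        with pytest.raises(ValidationError):
            average_sensitivities([a, b], "pooled")

    @pytest.mark.parametrize("seed", [0, 1, 6])
    def test_cohort_mean_tracks_its_large_sample_expectation(
            self, seed, cohort_mean_oracle):
        """A 20-individual average behaves like one more draw from the
        sampling distribution of cohort means: its worst per-wavelength
        standardised deviation stays within the envelope observed over 100
        independent oracle cohorts.  (The reference is the expectation of
        the *measured* curve — per-wavelength S is skewed at this noise
        level, so a normal-theory CLT band would be miscalibrated.)"""
        from ergspectra import AdaptationState, StimulusProtocol
        proto = StimulusProtocol(adaptation_states=(AdaptationState("dark"),))
        group_means = cohort_mean_oracle
        mu = group_means.mean(axis=0)
        sigma = group_means.std(axis=0, ddof=1)
        envelope = np.max(np.abs(group_means - mu) / sigma, axis=1).max()

        curves = [sensitivity_spectrum(s) for s in
                  simulate_study(proto, default_truth(seed=seed))]
        avg = average_sensitivities(curves, "pooled")
        m_test = np.max(np.abs(avg.values - mu) / sigma)
        assert m_test <= envelope


@pytest.fixture(scope="module")
def cohort_mean_oracle():
    """100 independent 20-individual cohort means of dark-adapted S(λ)."""
    from ergspectra import AdaptationState, StimulusProtocol
    proto = StimulusProtocol(adaptation_states=(AdaptationState("dark"),))
    values = []
    for block in range(10):
        truth = default_truth(n_per_sex=100, seed=90_000 + block)
        values += [sensitivity_spectrum(s).values
                   for s in simulate_study(proto, truth)]
    values = np.asarray(values)                      # 2000 individuals
    return values.reshape(100, 20, -1).mean(axis=1)  # 100 cohorts of 20
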