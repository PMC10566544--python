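"""Schedule simulation, analytic emission integrals, phantom rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vchopper import (
    AcquisitionConfig,
    DecayModel,
    build_schedule,
    emission_integral,
    render_phantom_video,
    simulate_frame_intensities,
    two_shape_phantom,
)
from vchopper.errors import InvalidConfigError
from vchopper.simulate import NoiseModel, PhantomRegion, PhantomSpec

from .oracles import emission_integral_quad, gated_delays_bruteforce


class TestBuildSchedule:
    def test_frame_and_pulse_counts(self):
        config = AcquisitionConfig(50, 0.4, 30, 0.02, +1, 1 / 350)
        schedule = build_schedule(config, 30.0)
        assert schedule.n_frames == 900
        assert schedule.n_pulses == 1500

    def test_short_duration_counts(self):
        config = AcquisitionConfig(50, 0.4, 30, 0.02, -1, 1 / 350)
        schedule = build_schedule(config, 1.0)
        assert schedule.n_frames in (29, 30)

    def test_frame_spacing_is_actual_period(self):
        config = AcquisitionConfig(50, 0.4, 30, 0.02, -1, 1 / 350)
        starts = build_schedule(config, 5.0).frame_starts_s
        assert np.allclose(np.diff(starts), 1 / 29.98, atol=1e-12)

    def test_subframe_duration_rejected(self):
        config = AcquisitionConfig(50, 0.4, 30, 0.0, -1, 1 / 350)
        with pytest.raises(InvalidConfigError):
            build_schedule(config, 0.01)


class TestEmissionIntegral:
    def test_window_inside_decay_closed_form(self):
        config = AcquisitionConfig(50, 0.4, 30, 0.0, -1, 1 / 350)
        schedule = build_schedule(config, 1.0)
        tau, amp, s = 500e-6, 2.0, 1 / 350
        d = 1e-3  # delay after the off edge at 8 ms
        window = (0.008 + d, 0.008 + d + s)
        expected = amp * tau * (np.exp(-d / tau) - np.exp(-(d + s) / tau))
        value = emission_integral(DecayModel(tau, amp), schedule, window)
        assert value == pytest.approx(expected, rel=1e-12)

    def test_dead_window_collects_nothing(self):
        config = AcquisitionConfig(50, 0.4, 30, 0.0, -1, 1 / 350)
        schedule = build_schedule(config, 1.0)
        value = emission_integral(DecayModel(1e-9), schedule, (0.0199, 0.01999))
        assert value == pytest.approx(0.0, abs=1e-15)

    def test_window_ratio_is_exponential(self):
        config = AcquisitionConfig(50, 0.4, 30, 0.0, -1, 1 / 350)
        schedule = build_schedule(config, 1.0)
        tau, s, delta = 400e-6, 1 / 350, 150e-6
        decay = DecayModel(tau)
        a = emission_integral(decay, schedule, (0.0085, 0.0085 + s))
        b = emission_integral(decay, schedule, (0.0085 + delta, 0.0085 + delta + s))
        assert b / a == pytest.approx(np.exp(-delta / tau), rel=1e-10)

    @given(
        start=st.floats(0.0, 0.08),
        length=st.floats(1e-4, 0.05),
        tau=st.floats(5e-5, 5e-3),
        rise=st.sampled_from(["instantaneous", "exponential"]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_numeric_quadrature(self, start, length, tau, rise):
        config = AcquisitionConfig(50, 0.4, 30, 0.0, -1, 1 / 350)
        schedule = build_schedule(config, 1.0)
        value = emission_integral(
            DecayModel(tau, 1.3), schedule, (start, start + length), rise_model=rise
        )
        oracle = emission_integral_quad(
            (start, start + length), 50, 0.4, tau, 1.3, rise
        )
        assert value == pytest.approx(oracle, rel=1e-8, abs=1e-15)

    def test_gated_intensity_monotone_in_delay(self):
        config = AcquisitionConfig(50, 0.4, 30, 0.0, -1, 1 / 350)
        schedule = build_schedule(config, 1.0)
        decay = DecayModel(300e-6)
        delays = np.linspace(0, 0.009, 40)
        values = [
            emission_integral(decay, schedule, (0.008 + d, 0.008 + d + 1 / 350))
            for d in delays
        ]
        assert np.all(np.diff(values) < 0)


class TestFrameIntensities:
    def make(self, sign, sigma=0.02):
        return AcquisitionConfig(50, 0.4, 30, sigma, sign, 1 / 350)

    def _gated_means(self, config, duration=6.0):
        """Gated intensities of a single exposure phase class (successive
        gated frames alternate between phase classes, so the within-class
        subsequence is the one that traces the decay monotonically)."""
        schedule = build_schedule(config, duration)
        intensities = simulate_frame_intensities(schedule, DecayModel(250e-6))
        gated = np.array([k for k, _ in gated_delays_bruteforce(config, duration)])
        same_class = gated % 3 == gated[0] % 3
        return intensities[gated[same_class]], intensities.max()

    def test_zero_drift_gated_intensities_constant(self):
        values, plateau = self._gated_means(self.make(-1, sigma=0.0))
        assert np.ptp(values) <= 1e-12 * plateau

    def test_negative_drift_decreasing(self):
        """Gate drifting away from the pulses scans the decay high to low."""
        values, _ = self._gated_means(self.make(-1))
        values = values[:80]
        assert values[0] > values[-1]
        assert np.all(np.diff(values) < 0)

    def test_positive_drift_increasing(self):
        values, _ = self._gated_means(self.make(+1))
        values = values[:80]
        assert values[-1] > values[0]
        assert np.all(np.diff(values) > 0)

    def test_gated_subsequence_is_exponential(self):
        """Log gated intensity vs brute-force delay is affine with slope
        -1/tau."""
        config = self.make(-1)
        tau = 250e-6
        schedule = build_schedule(config, 18.0)
        intensities = simulate_frame_intensities(schedule, DecayModel(tau))
        pairs = gated_delays_bruteforce(config, 18.0)
        idx = np.array([k for k, _ in pairs])
        delays = np.array([d for _, d in pairs])
        logs = np.log(intensities[idx])
        slope, intercept = np.polyfit(delays, logs, 1)
        pred = slope * delays + intercept
        r2 = 1 - np.sum((logs - pred) ** 2) / np.sum((logs - logs.mean()) ** 2)
        assert r2 > 0.999999
        assert slope == pytest.approx(-1 / tau, rel=1e-6)


class TestRenderPhantomVideo:
    def test_truth_labels_match_bruteforce_overlap(self, micro_config):
        spec = two_shape_phantom(shape=(16, 16), noise=None, rng_seed=0)
        stack = render_phantom_video(spec, micro_config, 5.0)
        gated = {k for k, _ in gated_delays_bruteforce(micro_config, 5.0)}
        expected = np.array(
            [0 if k in gated else 1 for k in range(stack.n_frames)], dtype=np.int8
        )
        assert np.array_equal(stack.truth_labels, expected)

    def test_truth_delays_match_bruteforce(self, micro_config):
        spec = two_shape_phantom(shape=(8, 8), noise=None, rng_seed=0)
        stack = render_phantom_video(spec, micro_config, 5.0)
        for k, delay in gated_delays_bruteforce(micro_config, 5.0):
            assert stack.truth_delay_s[k] == pytest.approx(delay, abs=1e-12)

    def test_dark_phantom_is_all_zero(self, micro_config):
        spec = PhantomSpec(
            image_shape=(8, 8),
            regions=[PhantomRegion(np.ones((8, 8), bool), DecayModel(1e-4, 0.0))],
            autofluorescence_level=0.0,
            noise=None,
        )
        stack = render_phantom_video(spec, micro_config, 2.0)
        assert stack.frames.max() == 0

    def test_same_seed_is_bit_identical(self, micro_config):
        spec = two_shape_phantom(shape=(16, 16), noise=NoiseModel(), rng_seed=7)
        a = render_phantom_video(spec, micro_config, 3.0)
        b = render_phantom_video(spec, micro_config, 3.0)
        assert np.array_equal(a.frames, b.frames)

    def test_overlapping_regions_rejected(self):
        mask = np.ones((8, 8), bool)
        with pytest.raises(InvalidConfigError):
            PhantomSpec(
                image_shape=(8, 8),
                regions=[
                    PhantomRegion(mask, DecayModel(1e-4)),
                    PhantomRegion(mask, DecayModel(2e-4)),
                ],
            )

    def test_rolling_shutter_skews_row_labels(self, micro_config):
        """With a large row skew, some frames have rows on both sides of the
        off edge; the conservative label marks them source-on."""
        spec_plain = two_shape_phantom(shape=(16, 16), noise=None, rng_seed=0)
        spec_skew = two_shape_phantom(
            shape=(16, 16), noise=None, rng_seed=0, ers_row_skew_s=2e-4
        )
        plain = render_phantom_video(spec_plain, micro_config, 5.0)
        skew = render_phantom_video(spec_skew, micro_config, 5.0)
        assert skew.truth_labels.sum() > plain.truth_labels.sum()
        # skewed labels are a superset: no frame flips from on to gated
        assert np.all(skew.truth_labels >= plain.truth_labels)
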