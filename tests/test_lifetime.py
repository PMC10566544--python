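"""Decay fitting, lifetime-image reconstruction, and ROI statistics."""

import numpy as np
import pytest

from vchopper import (
    assemble_virtual_sequence,
    fit_decay,
    reconstruct_lifetime_image,
    roi_decay_curve,
    roi_stats,
    threshold_classifier,
)
from vchopper.errors import InsufficientSamplesError, InvalidConfigError
from vchopper.extract import VirtualDecaySequence
from vchopper.lifetime import LifetimeImage


def make_trace(tau, n=30, span_factor=8.0, amp=100.0, background=0.0):
    t = np.linspace(0.0, span_factor * tau, n)
    return amp * np.exp(-t / tau) + background, t


class TestFitDecay:
    def test_exponential_ratio_points(self):
        tau0 = 2.5e-4
        t = np.array([0.0, tau0, 2 * tau0])
        y = 100.0 * np.exp(-t / tau0)
        fit = fit_decay(y, t, method="loglinear", dark_value=0.0)
        assert fit.ok
        assert fit.model.lifetime_s == pytest.approx(tau0, rel=1e-9)

    @pytest.mark.parametrize(
        "method, kwargs",
        [("loglinear", {"dark_value": 0.0}), ("nls", {})],
    )
    def test_noise_free_trace_recovered_to_fraction_of_percent(self, method, kwargs):
        tau = 512.3e-6
        y, t = make_trace(tau)
        fit = fit_decay(y, t, method=method, **kwargs)
        assert fit.ok
        assert fit.model.lifetime_s == pytest.approx(tau, rel=1e-3)
        assert fit.r_squared > 0.9999

    def test_constant_trace_is_marked_failed(self):
        y = np.full(20, 55.0)
        t = np.linspace(0, 1e-3, 20)
        fit = fit_decay(y, t)
        assert not fit.ok
        assert fit.model is None

    def test_rising_trace_is_marked_failed(self):
        t = np.linspace(0, 1e-3, 20)
        fit = fit_decay(np.exp(t / 1e-4), t)
        assert not fit.ok

    def test_methods_agree_on_clean_data(self):
        y, t = make_trace(3.3e-4, n=40)
        log_fit = fit_decay(y, t, method="loglinear")
        nls_fit = fit_decay(y, t, method="nls")
        assert log_fit.model.lifetime_s == pytest.approx(
            nls_fit.model.lifetime_s, rel=0.01
        )

    def test_nls_recovers_background(self):
        y, t = make_trace(2e-4, background=7.0)
        fit = fit_decay(y, t, method="nls")
        assert fit.model.background == pytest.approx(7.0, rel=0.05)
        assert fit.model.lifetime_s == pytest.approx(2e-4, rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientSamplesError):
            fit_decay(np.array([2.0, 1.0]), np.array([0.0, 1.0]))

    def test_non_increasing_delays_rejected(self):
        with pytest.raises(InvalidConfigError):
            fit_decay(np.ones(4), np.array([0.0, 1.0, 1.0, 2.0]))


def _sequence_from(stack, config):
    labels = threshold_classifier(stack)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assemble_virtual_sequence(stack, labels, config)


class TestReconstructLifetimeImage:
    def test_two_region_medians_match_truth(self, micro_config, two_shape_clean):
        spec, stack = two_shape_clean
        seq = _sequence_from(stack, micro_config)
        image = reconstruct_lifetime_image(seq, method="loglinear")
        for region in spec.regions:
            valid = region.mask & image.mask
            median = np.median(image.tau_map[valid])
            assert median == pytest.approx(region.decay.lifetime_s, rel=0.01)

    def test_three_region_medians_ordered(self, subhundred_config, three_region_clean):
        spec, stack = three_region_clean
        seq = _sequence_from(stack, subhundred_config)
        image = reconstruct_lifetime_image(seq, method="loglinear")
        medians = [
            np.median(image.tau_map[r.mask & image.mask]) for r in spec.regions
        ]
        truths = [r.decay.lifetime_s for r in spec.regions]
        assert np.argsort(medians).tolist() == np.argsort(truths).tolist()
        for median, truth in zip(medians, truths):
            assert median == pytest.approx(truth, rel=0.01)

    def test_scale_equivariance(self, micro_config, two_shape_clean):
        """Multiplying all intensities by a constant leaves tau unchanged."""
        _, stack = two_shape_clean
        seq = _sequence_from(stack, micro_config)
        scaled = VirtualDecaySequence(
            frames=seq.frames * 37.0,
            delay_s=seq.delay_s,
            source_indices=seq.source_indices,
            direction=seq.direction,
            geometry=seq.geometry,
        )
        base = reconstruct_lifetime_image(seq, method="loglinear")
        big = reconstruct_lifetime_image(scaled, method="loglinear")
        both = base.mask & big.mask
        assert both.sum() > 0.9 * base.mask.sum()
        assert np.allclose(base.tau_map[both], big.tau_map[both], rtol=1e-6)

    def test_dark_sequence_fully_masked_with_warning(self):
        seq = VirtualDecaySequence(
            frames=np.zeros((10, 6, 6)),
            delay_s=np.linspace(0, 1e-3, 10),
            source_indices=np.arange(10),
            direction="away",
        )
        with pytest.warns(UserWarning, match="all pixels masked"):
            image = reconstruct_lifetime_image(seq)
        assert not image.mask.any()


class TestRoiDecayCurve:
    def test_single_region_roi_recovers_lifetime(self, micro_config, two_shape_clean):
        spec, stack = two_shape_clean
        seq = _sequence_from(stack, micro_config)
        _, fit = roi_decay_curve(seq, spec.regions[0].mask)
        assert fit.ok
        assert fit.model.lifetime_s == pytest.approx(
            spec.regions[0].decay.lifetime_s, rel=1e-3
        )

    def test_background_roi_fails_to_fit(self, micro_config, two_shape_clean):
        spec, stack = two_shape_clean
        seq = _sequence_from(stack, micro_config)
        background = ~(spec.regions[0].mask | spec.regions[1].mask)
        _, fit = roi_decay_curve(seq, background)
        assert not fit.ok

    def test_mixed_roi_lifetime_between_components(
        self, micro_config, two_shape_clean
    ):
        """A single-exponential fit of a two-component mean decay lands
        strictly between the component lifetimes (checked against a
        brute-force fit of the analytic mixture)."""
        from scipy.optimize import curve_fit

        spec, stack = two_shape_clean
        seq = _sequence_from(stack, micro_config)
        union = spec.regions[0].mask | spec.regions[1].mask
        curve, fit = roi_decay_curve(seq, union)
        tau_short = spec.regions[0].decay.lifetime_s
        tau_long = spec.regions[1].decay.lifetime_s
        assert tau_short < fit.model.lifetime_s < tau_long

        # oracle: fit the analytic two-exponential mixture the same way;
        # a gated frame integrates the decay over the exposure, so each
        # component's weight carries the tau * (1 - exp(-s/tau)) factor
        shutter = micro_config.shutter_s
        weights = [
            r.mask.sum() * r.decay.lifetime_s
            * (1 - np.exp(-shutter / r.decay.lifetime_s))
            for r in spec.regions
        ]
        t = seq.delay_s
        mix = (
            weights[0] * np.exp(-t / tau_short) + weights[1] * np.exp(-t / tau_long)
        ) / sum(weights)

        def model(tt, a, tau, b):
            return a * np.exp(-tt / tau) + b

        oracle_tau = curve_fit(model, t, mix, p0=[1.0, 3e-4, 0.0], maxfev=5000)[0][1]
        assert fit.model.lifetime_s == pytest.approx(oracle_tau, rel=0.05)

    def test_empty_roi_rejected(self, micro_config, two_shape_clean):
        _, stack = two_shape_clean
        seq = _sequence_from(stack, micro_config)
        with pytest.raises(InvalidConfigError):
            roi_decay_curve(seq, np.zeros(seq.frames.shape[1:], dtype=bool))


class TestRoiStats:
    @staticmethod
    def _image_from_taus(taus):
        taus = np.asarray(taus, dtype=float)
        shape = taus.shape
        return LifetimeImage(
            tau_map=taus,
            amplitude_map=np.ones(shape),
            background_map=np.zeros(shape),
            fit_quality_map=np.ones(shape),
            mask=np.ones(shape, dtype=bool),
        )

    def test_uniform_roi_has_zero_spread(self):
        image = self._image_from_taus(np.full((4, 4), 2e-4))
        stats = roi_stats(image, np.ones((4, 4), bool))
        assert stats.sd_tau_s == 0.0
        assert stats.cv == 0.0
        assert stats.pixel_count == 16

    def test_two_point_sample_statistics(self):
        image = self._image_from_taus(np.array([[100e-6, 200e-6]]))
        stats = roi_stats(image, np.ones((1, 2), bool))
        assert stats.mean_tau_s == pytest.approx(150e-6)
        assert stats.sd_tau_s == pytest.approx(70.71e-6, rel=1e-3)
        assert stats.cv == pytest.approx(0.4714, rel=1e-3)

    def test_noisy_phantom_cv_is_narrow(self, micro_config, two_shape_noisy):
        """At the default noise preset the per-pixel lifetime histogram of a
        uniform region stays narrow (CV at the ten-percent level)."""
        spec, stack = two_shape_noisy
        seq = _sequence_from(stack, micro_config)
        image = reconstruct_lifetime_image(seq, method="nls")
        stats = roi_stats(image, spec.regions[0].mask)
        assert stats.cv <= 0.10
        assert stats.pixel_count > 0.5 * spec.regions[0].mask.sum()

    def test_empty_roi_rejected(self):
        image = self._image_from_taus(np.full((2, 2), 1e-4))
        with pytest.raises(InvalidConfigError):
            roi_stats(image, np.zeros((2, 2), bool))
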