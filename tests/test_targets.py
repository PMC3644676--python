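"""Stimulus synthesis: rendering, centering, difficulty screens, scheduling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctlearn.config import TargetConfig
from ctlearn.targets import (
    GenerationError, SegmentCoefficients, TargetSegment, build_schedule,
    center_and_zero, center_midline, render_segment, sample_random_segment,
    screen_random, zero_endpoints,
)


def coeffs(b0=0.0, **kw):
    a = [0.0] * 6
    b = [0.0] * 6
    for key, val in kw.items():
        idx = int(key[1]) - 1
        (a if key[0] == "a" else b)[idx] = val
    return SegmentCoefficients(b0=b0, a=tuple(a), b=tuple(b))


class TestRenderSegment:
    def test_zero_coefficients_render_flat(self):
        seg = render_segment(coeffs())
        assert seg.samples.shape == (500,)
        assert np.all(seg.samples == 0)

    def test_single_sine_is_closed_form(self):
        seg = render_segment(coeffs(a1=1.0))
        x = np.linspace(0, 2 * np.pi, 500)
        np.testing.assert_allclose(seg.samples, np.sin(x), atol=1e-12)
        assert seg.rom == pytest.approx(2.0, rel=1e-4)
        assert abs(seg.samples[0]) < 1e-12 and abs(seg.samples[-1]) < 1e-12

    def test_cosine_with_offset(self):
        seg = render_segment(coeffs(b0=-1.0, b1=1.0))
        x = np.linspace(0, 2 * np.pi, 500)
        np.testing.assert_allclose(seg.samples, np.cos(x) - 1.0, atol=1e-12)
        assert seg.samples.min() == pytest.approx(-2.0, abs=1e-3)

    def test_sample_count_follows_rate_and_duration(self):
        seg = render_segment(coeffs(a1=1.0), duration_s=4.0, sample_rate=25.0)
        assert seg.samples.size == 100

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(ValueError):
            SegmentCoefficients(b0=np.nan, a=(0,) * 6, b=(0,) * 6)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=12, max_size=12))
    def test_one_period_endpoints_match(self, cs):
        """f(0) == f(2*pi) for any coefficient draw (one full period)."""
        seg = render_segment(SegmentCoefficients(0.0, tuple(cs[:6]), tuple(cs[6:])))
        assert seg.samples[0] == pytest.approx(seg.samples[-1], abs=1e-9)


class TestCenterAndZero:
    def test_offset_cosine_is_centered(self):
        seg = center_midline(render_segment(coeffs(b0=-1.0, b1=1.0)))
        s = seg.samples
        # offset (max+min)/2 removed: min/max at +/-1
        assert (s.max() + s.min()) / 2 == pytest.approx(0.0, abs=1e-9)
        assert s.max() == pytest.approx(1.0, abs=1e-3)
        assert s.min() == pytest.approx(-1.0, abs=1e-3)

    def test_full_adjustment_zeroes_endpoints(self):
        seg = center_and_zero(render_segment(coeffs(b0=-1.0, b1=1.0)))
        assert seg.samples[0] == pytest.approx(0.0, abs=1e-12)
        assert seg.samples[-1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_sine_is_fixed_point(self):
        seg = render_segment(coeffs(a1=1.0))
        out = center_and_zero(seg)
        np.testing.assert_allclose(out.samples, seg.samples, atol=1e-12)

    def test_unequal_endpoints_ramped_to_zero(self):
        raw = np.sin(np.linspace(0, 2 * np.pi, 100)) + np.linspace(0.4, -0.2, 100)
        seg = TargetSegment("random", coeffs(a1=1.0), raw, 10.0, 10.0)
        out = zero_endpoints(seg)
        assert out.samples[0] == pytest.approx(0.0, abs=1e-12)
        assert out.samples[-1] == pytest.approx(0.0, abs=1e-12)

    def test_idempotent_on_periodic_segments(self, repeated):
        again = center_and_zero(repeated)
        np.testing.assert_allclose(again.samples, repeated.samples, atol=1e-9)

    def test_rom_preserved_for_periodic_segments(self):
        seg = render_segment(coeffs(a1=3.0, b2=2.0, b0=5.0))
        out = center_and_zero(seg)
        assert out.rom == pytest.approx(seg.rom, rel=1e-9)

    def test_constant_segment_rejected(self):
        seg = render_segment(coeffs(b0=3.0))
        with pytest.raises(ValueError, match="constant"):
            center_and_zero(seg)


class TestScreenRandom:
    def test_self_copy_passes_all_screens(self, repeated):
        rep = screen_random(repeated, repeated)
        assert rep.rom_ok and rep.velocity_ok and rep.slope_ok
        assert rep.passed

    def test_rom_ten_percent_off_fails(self, repeated):
        inflated = TargetSegment("random", repeated.coefficients,
                                 repeated.samples * 1.10,
                                 repeated.duration_s, repeated.sample_rate)
        rep = screen_random(inflated, repeated)
        assert not rep.rom_ok

    def test_half_amplitude_fails_velocity_floor(self, repeated):
        half = TargetSegment("random", repeated.coefficients,
                             repeated.samples * 0.5,
                             repeated.duration_s, repeated.sample_rate)
        rep = screen_random(half, repeated, velocity_floor_frac=0.8)
        assert not rep.velocity_ok
        assert rep.mean_abs_velocity == pytest.approx(
            0.5 * repeated.mean_abs_velocity)

    def test_slope_screen_checks_both_junction_orders(self, repeated):
        # time reversal negates the junction slopes -> slope screen must fail
        flipped = TargetSegment("random", repeated.coefficients,
                                -repeated.samples,
                                repeated.duration_s, repeated.sample_rate)
        assert not screen_random(flipped, repeated).slope_ok

    def test_mismatched_rates_rejected(self, repeated):
        other = render_segment(coeffs(a1=1.0), duration_s=5.0)
        with pytest.raises(ValueError):
            screen_random(other, repeated)


class TestSampleRandomSegment:
    def test_deterministic_under_seed(self, repeated, target_cfg):
        s1 = sample_random_segment(np.random.default_rng(42), repeated, target_cfg)
        s2 = sample_random_segment(np.random.default_rng(42), repeated, target_cfg)
        np.testing.assert_array_equal(s1.samples, s2.samples)

    def test_accepted_segments_pass_reaudit(self, repeated, target_cfg, rng):
        """Every accepted draw re-passes the screens it was accepted under."""
        for _ in range(25):
            seg = sample_random_segment(rng, repeated, target_cfg)
            rep = screen_random(seg, repeated, target_cfg.rom_tolerance,
                                target_cfg.velocity_floor_frac,
                                target_cfg.slope_tolerance)
            assert rep.passed
            assert np.abs(seg.samples).max() <= target_cfg.amplitude_limit_deg
            assert np.abs(seg.coefficients.as_array()[1:]).max() <= \
                target_cfg.coefficient_range

    def test_segment_endpoints_cross_zero(self, repeated, target_cfg, rng):
        seg = sample_random_segment(rng, repeated, target_cfg)
        assert seg.samples[0] == pytest.approx(0.0, abs=1e-9)
        assert seg.samples[-1] == pytest.approx(0.0, abs=1e-9)

    def test_exhausted_attempts_report_failure_counts(self, repeated):
        cfg = TargetConfig(rom_tolerance=1e-9, max_attempts=5)
        with pytest.raises(GenerationError) as err:
            sample_random_segment(np.random.default_rng(0), repeated, cfg)
        assert sum(err.value.failure_counts.values()) > 0

    def test_disabled_screens_accept_first_candidate(self, repeated):
        cfg = TargetConfig(rom_tolerance=1.0, velocity_floor_frac=0.0,
                           slope_tolerance=100.0, max_attempts=25)
        seg = sample_random_segment(np.random.default_rng(0), repeated, cfg)
        assert seg.kind == "random"


class TestBuildSchedule:
    def test_ten_trial_block_counterbalanced(self, target_cfg):
        trials = build_schedule(10, np.random.default_rng(0), target_cfg)
        first = [t.order_flag for t in trials]
        assert first.count("repeated-first") == 5
        assert first.count("random-first") == 5

    def test_five_days_of_fifty_trials(self, target_cfg):
        trials = build_schedule(50, np.random.default_rng(1), target_cfg, n_days=5)
        assert len(trials) == 250
        for day in range(1, 6):
            day_flags = [t.order_flag for t in trials if t.day == day]
            assert day_flags.count("repeated-first") == 25

    def test_empty_schedule(self, target_cfg):
        assert build_schedule(0, np.random.default_rng(0), target_cfg) == []

    def test_odd_block_size_rejected(self, target_cfg):
        with pytest.raises(ValueError):
            build_schedule(9, np.random.default_rng(0), target_cfg,
                           trials_per_block=9)

    def test_repeated_segment_bitwise_identical_across_trials(self, target_cfg):
        trials = build_schedule(10, np.random.default_rng(2), target_cfg, n_days=2)
        ref = trials[0].repeated.samples
        for t in trials:
            assert t.repeated.samples is ref  # the very same object
            np.testing.assert_array_equal(t.repeated.samples, ref)

    def test_every_trial_has_one_of_each_kind(self, target_cfg):
        trials = build_schedule(4, np.random.default_rng(3), target_cfg,
                                trials_per_block=4)
        for t in trials:
            kinds = sorted(s.kind for s in t.segments)
            assert kinds == ["random", "repeated"]
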