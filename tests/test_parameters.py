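"""Step/stride timing, pendulum step length, double-integration excursion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneegait.errors import DomainError, InputError, InsufficientDataError
from kneegait.events import InitialContactSeries
from kneegait.parameters import (
    GaitOptions,
    PendulumConfig,
    step_length,
    step_times,
    stride_length,
    stride_times,
    summarize_gait,
    vertical_excursion,
    walking_speed,
)
from kneegait.simulate import WalkSimulationSpec
from tests.conftest import recover_summary

FS = 32.0
G = 9.80665


class TestTiming:
    def test_step_times_direct_differencing(self):
        np.testing.assert_allclose(step_times(np.array([0.0, 0.5, 1.1])), [0.5, 0.6])

    def test_uniform_contacts_give_uniform_step_times(self):
        t = np.arange(12) * 0.53
        np.testing.assert_allclose(step_times(t), 0.53, atol=1e-12)

    def test_single_contact_gives_empty(self):
        assert step_times(np.array([0.4])).size == 0

    def test_stride_times_example(self):
        np.testing.assert_allclose(stride_times(np.array([0.0, 0.5, 1.1])), [1.1])

    def test_stride_equals_sum_of_adjacent_steps_exactly(self):
        rng = np.random.default_rng(3)
        t = np.cumsum(rng.uniform(0.4, 0.8, 20))
        st_ = step_times(t)
        np.testing.assert_array_equal(stride_times(t), st_[:-1] + st_[1:])

    def test_stride_times_at_cohort_scale(self):
        np.testing.assert_allclose(
            stride_times(np.array([0.0, 0.57, 1.13, 1.70])), [1.13, 1.13], atol=1e-12
        )

    def test_too_few_contacts_empty(self):
        assert stride_times(np.array([0.0, 0.5])).size == 0


class TestVerticalExcursion:
    def test_zero_segment_gives_zero(self):
        assert vertical_excursion(np.zeros(20), FS) == 0.0

    def test_sinusoid_recovers_peak_to_peak_displacement(self):
        # a(t) = -A w^2 sin(w t) integrates to displacement A sin(w t):
        # excursion 2A, within 5% at 32 Hz for a 1 Hz component, A = 5 mm
        A, f = 0.005, 1.0
        w = 2 * np.pi * f
        t = np.arange(int(FS / f) + 1) / FS
        seg = -A * w**2 * np.sin(w * t) / G  # in g
        assert vertical_excursion(seg, FS) == pytest.approx(2 * A, rel=0.05)

    def test_constant_bias_annihilated_by_drift_correction(self):
        seg = np.full(int(0.5 * FS), 0.01)  # 0.01 g over a 0.5 s step
        assert vertical_excursion(seg, FS) < 1e-4  # < 0.1 mm

    def test_short_segment_rejected(self):
        with pytest.raises(InputError):
            vertical_excursion(np.zeros(3), FS)


class TestStepLength:
    def test_closed_form_value(self):
        # Wp = 0.34, KG = 4, D = 0.01: 4 * 2 * sqrt(0.0068 - 0.0001)
        assert step_length(0.01) == pytest.approx(0.654829, abs=1e-6)

    @pytest.mark.parametrize("d", [0.0, 0.68])
    def test_boundaries_give_exact_zero(self, d):
        assert step_length(d, PendulumConfig(Wp=0.34, KG=4.0)) == 0.0

    def test_monotone_increasing_below_sensor_height(self):
        cfg = PendulumConfig()
        grid = np.linspace(1e-6, cfg.Wp, 500)
        vals = [step_length(d, cfg) for d in grid]
        assert np.all(np.diff(vals) > 0)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            step_length(-0.001)
        with pytest.raises(DomainError):
            step_length(0.7)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0.0, 0.3), st.floats(0.5, 8.0))
    def test_doubling_kg_doubles_length(self, d, kg):
        base = step_length(d, PendulumConfig(Wp=0.34, KG=kg))
        assert step_length(d, PendulumConfig(Wp=0.34, KG=2 * kg)) == pytest.approx(2 * base, rel=1e-12)


class TestStrideLengthAndSpeed:
    def test_stride_doubles_step(self):
        assert stride_length(0.35) == 0.70
        assert stride_length(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            stride_length(-0.1)

    def test_walking_speed_division(self):
        assert walking_speed(0.6, 0.5) == pytest.approx(1.2)
        assert walking_speed(0.35, 0.57) == pytest.approx(0.6140, abs=1e-4)
        assert walking_speed(0.0, 0.5) == 0.0

    def test_zero_step_time_rejected(self):
        with pytest.raises(DomainError):
            walking_speed(0.6, 0.0)


class TestSummarizeGait:
    def test_uniform_walk_recovers_timing(self):
        spec = WalkSimulationSpec(n_steps=30, step_time_mean=0.55, step_time_sd=0.0,
                                  D_mean=0.008, D_sd=0.0, noise_sd=0.0, seed=2)
        truth, summary, _, _ = recover_summary(spec)
        assert summary.avg_step_time == pytest.approx(0.55, abs=1 / FS)
        assert summary.avg_stride_time == pytest.approx(1.10, abs=2 / FS)

    def test_stride_length_identity_exact(self):
        spec = WalkSimulationSpec(seed=4, noise_sd=0.0)
        _, summary, _, _ = recover_summary(spec)
        assert summary.avg_stride_length == 2.0 * summary.avg_step_length

    def test_two_contacts_insufficient(self):
        ics = InitialContactSeries(ic_indices=np.array([10, 28]), sampling_rate=FS)
        with pytest.raises(InsufficientDataError):
            summarize_gait(ics, np.zeros(64), FS)

    def test_parameter_recovery_grid(self):
        # noise-free walks: step time within one sample period, step length
        # within 5% of the pendulum formula at the true excursion
        for T in (0.45, 0.55, 0.7):
            for D in (0.002, 0.008, 0.015):
                spec = WalkSimulationSpec(n_steps=30, step_time_mean=T, step_time_sd=0.0,
                                          D_mean=D, D_sd=0.0, noise_sd=0.0, seed=0)
                truth, summary, _, _ = recover_summary(spec)
                assert summary.avg_step_time == pytest.approx(T, abs=1 / FS)
                assert summary.avg_step_length == pytest.approx(
                    truth.summary.avg_step_length, rel=0.05
                )

    def test_kg_scaling_doubles_lengths_and_speed(self):
        from kneegait.parameters import summarize_gait as sg
        from tests.conftest import detect_walk

        spec = WalkSimulationSpec(seed=5, noise_sd=0.0)
        rec, _, corrected, ics = detect_walk(spec)
        s1, _ = sg(ics, corrected.vertical, FS, PendulumConfig(KG=4.0))
        s2, _ = sg(ics, corrected.vertical, FS, PendulumConfig(KG=8.0))
        assert s2.avg_step_length == pytest.approx(2 * s1.avg_step_length, rel=1e-12)
        assert s2.walking_speed == pytest.approx(2 * s1.walking_speed, rel=1e-12)
        assert s2.avg_step_time == s1.avg_step_time

    def test_combined_summary_is_side_mean(self):
        from kneegait.parameters import GaitSummary, combine_summaries

        left = GaitSummary(0.5, 1.0, 0.3, 0.6, 0.6, 10, side="left", subject_id="s")
        right = GaitSummary(0.6, 1.2, 0.4, 0.8, 0.7, 12, side="right", subject_id="s")
        c = combine_summaries(left, right)
        assert c.side == "combined"
        assert c.avg_step_time == pytest.approx(0.55)
        assert c.avg_step_length == pytest.approx(0.35)
        assert c.avg_stride_length == pytest.approx(0.70)
        assert c.n_steps == 22
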