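"""Two-pass sinusoid fitting and the residual-threshold exclusion mask."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculearn import (
    DegenerateFitError,
    FitParams,
    SinusoidFit,
    VelocityTrace,
    build_exclusion_mask,
    fit_sinusoid,
    measure_test,
    measure_velocity,
)
from oculearn.conditioning import condition
from conftest import make_clean_trace
from oracles import bruteforce_mask

RATE = 1000.0


def vtrace(v, rate=RATE):
    return VelocityTrace(np.asarray(v, dtype=float), rate)


def zero_fit(frequency=1.0):
    """A null fit, so mask construction sees the velocity as its residual."""
    return SinusoidFit(frequency, 0.0, 0.0, 0.0, 0.0, 0)


class TestFitSinusoid:
    def test_recovers_exact_coefficients(self):
        t = np.arange(45000) / RATE
        v = 3 * np.sin(2 * np.pi * t) + 4 * np.cos(2 * np.pi * t) + 2
        fit = fit_sinusoid(vtrace(v), None, 1.0)
        assert fit.amplitude == pytest.approx(5.0, abs=1e-9)
        assert fit.offset == pytest.approx(2.0, abs=1e-9)
        assert fit.phase == pytest.approx(np.arctan2(4, 3), abs=1e-9)

    def test_zero_signal_gives_zero_fit(self):
        fit = fit_sinusoid(vtrace(np.zeros(5000)), None, 1.0)
        assert fit.amplitude == 0.0 and fit.offset == 0.0

    def test_amplitude_estimator_precision_under_white_noise(self, rng):
        t = np.arange(45000) / RATE
        v = 10 * np.sin(2 * np.pi * t) + rng.normal(0, 1, t.size)
        fit = fit_sinusoid(vtrace(v), None, 1.0)
        # OLS amplitude sd = sqrt(2/n) ~ 0.0067 deg/s here
        assert fit.amplitude == pytest.approx(10.0, abs=0.1)

    def test_respects_mask(self):
        t = np.arange(10000) / RATE
        v = 2 * np.sin(2 * np.pi * t)
        v[:3000] = 99.0
        mask = np.ones(v.size, bool)
        mask[:3000] = False
        fit = fit_sinusoid(vtrace(v), mask, 1.0)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.n_used == 7000

    def test_degenerate_when_span_below_one_cycle(self):
        mask = np.zeros(45000, bool)
        mask[:800] = True  # 0.8 s < 1 cycle at 1 Hz
        with pytest.raises(DegenerateFitError):
            fit_sinusoid(vtrace(np.ones(45000)), mask, 1.0)
        with pytest.raises(DegenerateFitError):
            fit_sinusoid(vtrace(np.ones(2)), None, 1.0)


class TestExclusionMask:
    def test_matching_sinusoid_excludes_nothing(self):
        t = np.arange(45000) / RATE
        v = 8 * np.sin(2 * np.pi * t)
        fit = fit_sinusoid(vtrace(v), None, 1.0)
        mask = build_exclusion_mask(vtrace(v), fit)
        assert mask.excluded_fraction == 0.0
        assert mask.segments == [(0, 45000)]

    def test_single_pulse_excluded_with_padding(self):
        """100 ms pulse + 50 ms pads = exactly 200 excluded samples."""
        v = np.zeros(45000)
        v[10000:10100] = 200.0
        mask = build_exclusion_mask(vtrace(v), zero_fit())
        retained = mask.retained
        assert (~retained).sum() == 200
        assert not retained[9950:10150].any()
        assert np.array_equal(
            retained, bruteforce_mask(v, RATE)
        )

    def test_short_retained_gap_between_pulses_removed(self):
        """Two pulses whose dilated regions leave a sub-10 ms island."""
        v = np.zeros(5000)
        v[1000:1050] = 100.0
        # gap after padding: 50 ms pad + 8 ms island + 50 ms pad
        v[1158:1200] = -100.0
        mask = build_exclusion_mask(vtrace(v), zero_fit())
        assert np.array_equal(mask.retained, bruteforce_mask(v, RATE))
        assert not mask.retained[1100:1108].any()

    def test_exact_threshold_value_is_retained(self):
        v = np.zeros(3000)
        v[1500] = 31.0  # equality: not "more than" the threshold
        mask = build_exclusion_mask(vtrace(v), zero_fit())
        assert mask.excluded_fraction == 0.0
        v[1500] = np.nextafter(31.0, 100.0)
        mask = build_exclusion_mask(vtrace(v), zero_fit())
        assert not mask.retained[1500]

    def test_boundary_pulse_padding_clips_at_trace_edges(self):
        v = np.zeros(2000)
        v[:20] = 100.0
        v[-20:] = -100.0
        mask = build_exclusion_mask(vtrace(v), zero_fit())
        assert np.array_equal(mask.retained, bruteforce_mask(v, RATE))
        assert not mask.retained[:70].any() and not mask.retained[-70:].any()

    @pytest.mark.parametrize("applies", ["retained", "excluded"])
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_mask_equals_bruteforce_oracle_on_random_traces(self, seed, applies):
        rng = np.random.default_rng(seed)
        rate = float(rng.choice([250.0, 500.0, 1000.0]))
        n = int(rng.integers(200, 1500))
        v = rng.normal(0, 15, n)
        for _ in range(rng.integers(0, 6)):
            i = int(rng.integers(0, n))
            w = int(rng.integers(1, 120))
            v[i : i + w] += rng.choice([-1, 1]) * rng.uniform(20, 300)
        v[rng.integers(0, n, 5)] = 31.0  # exact-threshold values
        mask = build_exclusion_mask(
            vtrace(v, rate), zero_fit(), min_segment_applies=applies
        )
        oracle = bruteforce_mask(v, rate, min_segment_applies=applies)
        assert np.array_equal(mask.retained, oracle)

    def test_threshold_and_pad_monotonicity(self, rng):
        v = rng.normal(0, 25, 8000)
        fracs = [
            build_exclusion_mask(vtrace(v), zero_fit(), threshold_degps=th).excluded_fraction
            for th in [10.0, 20.0, 31.0, 50.0, 100.0]
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        fracs = [
            build_exclusion_mask(vtrace(v), zero_fit(), pad_s=p).excluded_fraction
            for p in [0.0, 0.02, 0.05, 0.10]
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestMeasureTest:
    def test_parameter_recovery_with_noise(self):
        tr = make_clean_trace(gain=0.8, noise_sd=1.0, seed=3)
        m = measure_test(tr)
        assert m.valid
        assert m.amplitude == pytest.approx(8.0, rel=0.01)
        assert m.gain == pytest.approx(0.8, rel=0.01)

    def test_gain_is_amplitude_over_stimulus_peak(self):
        tr = make_clean_trace(gain=1.0)
        m = measure_test(tr)
        assert m.gain == pytest.approx(m.amplitude / 10.0, abs=1e-12)

    def test_majority_artifact_trace_is_rejected(self):
        t = np.arange(45000) / RATE
        v = 8 * np.sin(2 * np.pi * t)
        # alternating pulses covering >45% after padding
        for j in range(120):
            s = j * 375 + 100
            v[s : s + 125] += 100.0 * (-1) ** j
        m = measure_velocity(vtrace(v), 1.0, 10.0)
        assert not m.valid
        assert m.reason == "excluded_fraction"
        assert m.amplitude is None

    def test_two_pass_fit_reduces_saccade_bias(self):
        """The refit on desaccaded data should nearly always be closer to
        the programmed amplitude than the first-pass fit."""
        from oculearn import StimulusSpec, TrueState, sample_saccade_train, synthesize_eye_trace

        wins = 0
        n_sims = 40
        for i in range(n_sims):
            sac = sample_saccade_train(45.0, 1.0, seed=5000 + i)
            tr = synthesize_eye_trace(
                StimulusSpec(1.0, 10.0),
                TrueState(0.8, 0.0, 2.0),
                sac,
                45.0,
                RATE,
                seed=6000 + i,
            )
            vel = condition(tr)
            pass1 = fit_sinusoid(vel, None, 1.0)
            m = measure_test(tr)
            assert m.valid
            if abs(m.amplitude - 8.0) <= abs(pass1.amplitude - 8.0):
                wins += 1
        assert wins >= 0.95 * n_sims

    def test_third_pass_would_barely_change_amplitude(self):
        """Exactly two passes are performed; a hypothetical third pass
        moves the amplitude by under 0.5% on a standard synthetic trace."""
        from oculearn import StimulusSpec, TrueState, sample_saccade_train, synthesize_eye_trace

        sac = sample_saccade_train(45.0, 1.0, seed=11)
        tr = synthesize_eye_trace(
            StimulusSpec(1.0, 10.0), TrueState(0.8, 0.0, 2.0), sac, 45.0, RATE, seed=12
        )
        m = measure_test(tr)
        vel = condition(tr)
        fit2 = fit_sinusoid(vel, None, 1.0)
        mask1 = build_exclusion_mask(vel, fit2)
        fit_b = fit_sinusoid(vel, mask1.retained, 1.0)
        mask2 = build_exclusion_mask(vel, fit_b)
        fit_c = fit_sinusoid(vel, mask2.retained, 1.0)
        assert abs(fit_c.amplitude - m.amplitude) / m.amplitude < 0.005

    def test_missing_frequency_metadata_raises(self):
        from oculearn import EyeTrace, InvalidArgumentError

        tr = EyeTrace(np.zeros(5000), RATE)
        with pytest.raises(InvalidArgumentError):
            measure_test(tr)

    def test_excluded_fraction_counting_modes(self):
        """The default fraction counts pads and short-segment removals; the
        alternative counts only the threshold crossings themselves."""
        t = np.arange(45000) / RATE
        v = 8 * np.sin(2 * np.pi * t)
        v[10000:10100] += 200.0
        default = measure_velocity(vtrace(v), 1.0, 10.0)
        narrow = measure_velocity(
            vtrace(v), 1.0, 10.0, FitParams(excluded_fraction_counts="threshold_only")
        )
        assert default.excluded_fraction == pytest.approx(200 / 45000)
        assert narrow.excluded_fraction == pytest.approx(100 / 45000)

    def test_threshold_zero_rejects_everything(self):
        tr = make_clean_trace(gain=0.8, noise_sd=2.0, seed=1)
        params = FitParams(threshold_degps=0.0)
        vel = condition(tr)
        m = measure_velocity(vel, 1.0, 10.0, params)
        assert not m.valid and m.excluded_fraction == 1.0
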