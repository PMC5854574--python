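"""Fractional-interval rates, filtering, and 50-Hz kinematics."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from tracklag.preprocess import (
    RateSeries,
    behavior_to_50hz,
    error_magnitude_normalized,
    lowpass_rate,
    mean_subtract,
    rate_from_spikes,
)
from tracklag.simulate import BehaviorTrial, SpikeTrain
from tracklag.task import Condition


def _series(rate, stage="raw"):
    rate = np.asarray(rate, dtype=float)
    return RateSeries(np.arange(len(rate)) * 20.0 + 10.0, rate, stage)


class TestFractionalIntervalRate:
    def test_single_isi_reads_reciprocal(self):
        """Spikes at 0 and 100 ms: every bin inside (0, 100) reads 10 sp/s."""
        rs = rate_from_spikes(SpikeTrain(np.array([0.0, 100.0])), 200.0)
        np.testing.assert_allclose(rs.rate[:5], 10.0)
        np.testing.assert_allclose(rs.rate[5:], 0.0)

    def test_partial_overlap_is_time_weighted(self):
        """Spikes at 10, 30, 50 ms: bin [20, 40) averages the two 50-Hz
        ISIs over their 10-ms shares, reading 50 spikes/s."""
        rs = rate_from_spikes(SpikeTrain(np.array([10.0, 30.0, 50.0])), 100.0)
        assert rs.rate[1] == pytest.approx(50.0)

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_integral_conserves_isi_count(self, seed):
        """Σ rate·Δt over all bins equals the number of whole interspike
        intervals, exactly."""
        rng = np.random.default_rng(seed)
        st = np.unique(np.sort(rng.uniform(0.0, 5000.0, 300)).round())
        st = st[np.concatenate(([True], np.diff(st) > 0))]
        rs = rate_from_spikes(SpikeTrain(st), 5000.0)
        total = rs.rate.sum() * 0.02
        assert total == pytest.approx(len(st) - 1, abs=1e-9)

    @given(
        st.lists(
            st.integers(min_value=0, max_value=4999), min_size=2, max_size=150, unique=True
        )
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_conservation_and_nonnegativity_property(self, times):
        """For any spike train, the binned rate is non-negative and its
        time-integral equals the interspike-interval count."""
        st_arr = np.sort(np.array(times, dtype=float))
        rs = rate_from_spikes(SpikeTrain(st_arr), 5000.0)
        assert np.all(rs.rate >= 0.0)
        assert rs.rate.sum() * 0.02 == pytest.approx(len(st_arr) - 1, abs=1e-8)

    def test_fewer_than_two_spikes_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            rs = rate_from_spikes(SpikeTrain(np.array([50.0])), 200.0)
        assert not rs.rate.any()


class TestLowpass:
    def test_dc_gain_unity(self):
        rs = lowpass_rate(_series(np.full(400, 7.0)))
        np.testing.assert_allclose(rs.rate, 7.0, rtol=1e-9)
        assert rs.stage == "filtered"

    @pytest.mark.parametrize("freq,rel,min_att", [(3.0, 0.02, None), (10.0, 0.10, 10.0)])
    def test_gain_matches_analytic_zero_phase_response(self, freq, rel, min_att):
        """Forward-backward filtering realizes |H|² of the single-pass
        second-order 3-Hz Butterworth design."""
        n = 2000
        t = np.arange(n) / 50.0
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_rate(_series(x)).rate
        measured = np.abs(y[500:1500]).max()
        b, a = signal.butter(2, 3.0, fs=50.0)
        _, h = signal.freqz(b, a, worN=[freq], fs=50.0)
        expected = np.abs(h[0]) ** 2
        assert measured == pytest.approx(expected, rel=rel)
        if min_att is not None:
            assert measured < 1.0 / min_att

    def test_short_series_passes_through(self):
        with pytest.warns(UserWarning):
            rs = lowpass_rate(_series(np.arange(5.0)))
        np.testing.assert_array_equal(rs.rate, np.arange(5.0))


class TestMeanSubtract:
    def test_zero_mean_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50.0, 5.0, 300)
        a = mean_subtract(_series(x, "filtered"))
        b = mean_subtract(_series(x + 11.3, "filtered"))
        assert abs(a.rate.mean()) < 1e-9
        np.testing.assert_allclose(a.rate, b.rate, atol=1e-9)

    def test_stage_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            mean_subtract(_series(np.zeros(10), "raw"))
        with pytest.raises(ValueError):
            lowpass_rate(_series(np.zeros(100), "filtered"))


def _line_trial(v=(3.0, -4.0), n=400, delay_ms=0, cond="baseline"):
    t = np.arange(n) / 200.0
    hand = np.outer(t, v)
    d = delay_ms // 5
    cursor = np.vstack([np.tile(hand[0], (d, 1)), hand[: n - d]]) if d else hand
    return BehaviorTrial(
        t_ms=t * 1000.0,
        target_xy=hand.copy(),
        hand_xy=hand,
        cursor_xy=cursor,
        visible=np.ones(n, bool),
        condition=Condition.from_label(cond),
    )


class TestBehaviorTo50Hz:
    def test_constant_velocity_recovered(self):
        kin = behavior_to_50hz(_line_trial(), 1.25)
        np.testing.assert_allclose(kin.VX[1:-1], 3.0, atol=1e-9)
        np.testing.assert_allclose(kin.VY[1:-1], -4.0, atol=1e-9)

    def test_cursor_on_target_gives_zero_error(self):
        kin = behavior_to_50hz(_line_trial(), 1.25)
        assert not kin.XE.any() and not kin.YE.any()
        assert kin.inside_target.all()

    def test_delay_offset_along_motion_direction(self):
        """Straight-line hand at 4 cm/s with a 200-ms cursor delay leaves
        a 0.8-cm error component opposite the motion direction."""
        kin = behavior_to_50hz(_line_trial(v=(4.0, 0.0), delay_ms=200, cond="delay200"), 1.25)
        interior = slice(10, -1)
        np.testing.assert_allclose(kin.XE[interior], -0.8, atol=1e-9)
        np.testing.assert_allclose(kin.YE[interior], 0.0, atol=1e-9)

    def test_grid_alignment_with_rate_series(self):
        trial = _line_trial()
        kin = behavior_to_50hz(trial, 1.25)
        rs = rate_from_spikes(SpikeTrain(np.array([1.0, 500.0, 900.0])), trial.duration_ms)
        assert len(kin) == len(rs.rate)
        np.testing.assert_array_equal(kin.t_ms, rs.t_ms)


class TestErrorNormalization:
    def _blocks(self, scale=2.0):
        base = [behavior_to_50hz(_line_trial(v=(4.0, 0.0), delay_ms=100, cond="delay100"), 1.25)]
        manip = [
            behavior_to_50hz(_line_trial(v=(4.0 * scale, 0.0), delay_ms=100, cond="delay100"), 1.25)
        ]
        return {"baseline": base, "manipulation": manip}

    def test_baseline_self_normalizes_to_one(self):
        norm = error_magnitude_normalized(self._blocks())
        assert norm["baseline"].mean() == pytest.approx(1.0)

    def test_larger_errors_normalize_above_one(self):
        norm = error_magnitude_normalized(self._blocks(scale=2.0))
        assert norm["manipulation"].mean() > 1.0

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            error_magnitude_normalized({"baseline": [], "manipulation": []})
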