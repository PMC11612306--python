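"""Burst segmentation, cumulative traces, and the CDF fit."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

from _oracles import brute_force_bursts, grid_fit_tau
from tcpalm import (
    TAU_PER_WIDTH,
    BurstRejected,
    TcpalmConfig,
    TemporalBurst,
    burst_statistics,
    cumulative_trace,
    fit_cumulative_cdf,
    segment_temporal_bursts,
)


def _burst(frames):
    frames = np.asarray(frames, dtype=np.int64)
    return TemporalBurst(0, int(frames[0]), int(frames[-1]), frames, len(frames))


class TestSegmentation:
    def test_empty_input(self):
        assert segment_temporal_bursts([], 100) == []

    def test_gap_above_cutoff_splits(self):
        bursts = segment_temporal_bursts([0, 50, 151, 200], 100)
        assert [b.detection_frames.tolist() for b in bursts] == [[0, 50], [151, 200]]
        assert bursts[0].first_frame == 0 and bursts[1].last_frame == 200

    def test_gap_equal_to_cutoff_merges(self):
        assert len(segment_temporal_bursts([0, 100], 100)) == 1

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            segment_temporal_bursts([5, 3], 100)

    def test_concatenation_restores_input(self, rng):
        frames = np.sort(rng.integers(0, 5000, size=200))
        bursts = segment_temporal_bursts(frames, 42)
        restored = np.concatenate([b.detection_frames for b in bursts])
        np.testing.assert_array_equal(restored, frames)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        frames=st.lists(st.integers(0, 3000), min_size=0, max_size=60),
        cutoff=st.integers(1, 200),
    )
    def test_matches_brute_force_splitter(self, frames, cutoff):
        frames = sorted(frames)
        ours = [b.detection_frames.tolist() for b in segment_temporal_bursts(frames, cutoff)]
        assert ours == brute_force_bursts(frames, cutoff)

    def test_burst_count_non_increasing_in_cutoff(self, rng):
        for _ in range(50):
            frames = np.sort(rng.integers(0, 2000, size=rng.integers(1, 80)))
            counts = [
                len(segment_temporal_bursts(frames, c)) for c in range(1, 300, 7)
            ]
            assert counts == sorted(counts, reverse=True)


class TestCumulativeTrace:
    def test_single_detection(self):
        t, y = cumulative_trace(_burst([5]), 0.01)
        assert t.tolist() == [0.05] and y.tolist() == [1]

    def test_consecutive_frames(self):
        t, y = cumulative_trace(_burst([0, 1, 2]), 0.01)
        np.testing.assert_allclose(t, [0.0, 0.01, 0.02])
        assert y.tolist() == [1, 2, 3]

    def test_conservation_and_monotonicity(self, rng):
        frames = np.sort(rng.integers(0, 1000, size=150))
        t, y = cumulative_trace(_burst(frames), 0.01)
        assert y[-1] == 150
        assert (np.diff(y) > 0).all() and (np.diff(t) > 0).all()


class TestCdfFit:
    def test_insufficient_detections_is_typed_outcome(self):
        trace = cumulative_trace(_burst([1, 2, 3]), 0.01)
        out = fit_cumulative_cdf(trace, min_burst_detections=10)
        assert isinstance(out, BurstRejected)
        assert out.reason == "insufficient detections"

    def test_single_frame_step_is_degenerate_sigmoid(self):
        trace = cumulative_trace(_burst([7] * 25), 0.01)
        fit = fit_cumulative_cdf(trace, 10)
        assert fit.width_s == 0.0
        assert fit.tau_s == pytest.approx(0.0)
        assert fit.r_squared >= 0.98

    def test_tau_closed_form_from_width(self):
        # 10-90% rise of a Gaussian CDF with unit width
        assert TAU_PER_WIDTH == pytest.approx(2.5631, abs=1e-4)
        t = np.linspace(0.0, 20.0, 400)
        y = 100.0 * ndtr((t - 10.0) / 1.0)
        fit = fit_cumulative_cdf((t, y), 10)
        assert fit.tau_s == pytest.approx(2.5631, rel=0.01)

    @pytest.mark.parametrize("amp,t0,w", [(150.0, 30.0, 2.0), (500.0, 8.0, 0.5)])
    def test_noiseless_sigmoid_parameters_recovered(self, amp, t0, w):
        t = np.linspace(t0 - 6 * w, t0 + 6 * w, 300)
        y = amp * ndtr((t - t0) / w)
        fit = fit_cumulative_cdf((t, y), 10)
        assert fit.amplitude == pytest.approx(amp, rel=0.01)
        assert fit.t0_s == pytest.approx(t0, rel=0.01)
        assert fit.width_s == pytest.approx(w, rel=0.01)
        assert fit.r_squared > 0.999

    def test_linear_ramp_agrees_with_grid_oracle(self):
        # 200 uniformly spaced detections over 8 s
        t = np.linspace(10.0, 18.0, 200)
        y = np.arange(1, 201, dtype=float)
        fit = fit_cumulative_cdf((t, y), 10)
        tau_oracle = grid_fit_tau(t, y)
        assert fit.tau_s == pytest.approx(tau_oracle, rel=0.15)

    def test_tau_scales_with_time(self, rng):
        frames = np.sort(rng.integers(0, 800, size=120))
        t, y = cumulative_trace(_burst(frames), 0.01)
        fit1 = fit_cumulative_cdf((t, y), 10)
        fit3 = fit_cumulative_cdf((3.0 * t, y), 10)
        assert fit3.tau_s == pytest.approx(3.0 * fit1.tau_s, rel=1e-3)


def test_burst_statistics():
    assert burst_statistics([]) == (0, 0)
    bursts = [_burst([0, 1, 2]), _burst([500 + i for i in range(7)])]
    assert burst_statistics(bursts) == (2, 10)
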