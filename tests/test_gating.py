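"""The gating ledger: R² gate, burst-count normalization, frequency
filter, live/fixed rule, and the provenance bookkeeping."""
import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import prune_low_frequency_bins
from tcpalm import (
    CdfFit,
    FilterConfig,
    apply_all_gates,
    classify_live_fixed,
    frequency_filter,
    gate_by_r2,
    subsample_bursts,
)


def _fit(tau, r2):
    return CdfFit(100.0, 5.0, tau / 2.5631, 0.0, r2, tau)


class TestR2Gate:
    def test_threshold_is_inclusive(self):
        fits = [_fit(5.0, 0.98), _fit(5.0, 0.97), _fit(5.0, 0.99)]
        kept = gate_by_r2(fits, 0.98)
        assert [f.r_squared for f in kept] == [0.98, 0.99]

    def test_lowering_threshold_never_drops_more(self, rng):
        for _ in range(30):
            fits = [_fit(1.0, r) for r in rng.uniform(0.5, 1.0, size=40)]
            n_strict = len(gate_by_r2(fits, 0.98))
            n_loose = len(gate_by_r2(fits, 0.90))
            assert n_loose >= n_strict


class TestSubsample:
    def test_subsamples_to_target(self, rng):
        taus = rng.uniform(0, 20, 3000)
        out = subsample_bursts(taus, 2500, seed=0)
        assert out.size == 2500
        assert set(out.tolist()) <= set(taus.tolist())

    def test_small_input_kept_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="tcpalm.gating"):
            out = subsample_bursts(np.arange(100.0), 2500, seed=0)
        assert out.size == 100
        assert "below the normalization target" in caplog.text

    def test_deterministic_and_order_preserving(self, rng):
        taus = rng.uniform(0, 20, 500)
        a = subsample_bursts(taus, 200, seed=7)
        b = subsample_bursts(taus, 200, seed=7)
        np.testing.assert_array_equal(a, b)
        pos = [taus.tolist().index(v) for v in a]
        assert pos == sorted(pos)


class TestFrequencyFilter:
    def test_documented_bin_counts_example(self):
        # bins with counts [10, 50, 8, 2]; 20% of max = 10 -> keep 10 and 50
        values = np.concatenate(
            [np.full(10, 0.5), np.full(50, 2.5), np.full(8, 4.5), np.full(2, 6.5)]
        )
        out = frequency_filter(values, bin_width_s=2.0, freq_fraction=0.2)
        assert out.size == 60
        assert set(np.floor(out / 2.0)) == {0.0, 1.0}

    def test_single_bin_input_fully_retained(self):
        out = frequency_filter([1.0, 1.2, 1.4], 2.0, 0.2)
        assert out.size == 3

    def test_empty_input(self):
        assert frequency_filter([], 2.0, 0.2).size == 0

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        values=st.lists(st.floats(0.0, 60.0), min_size=1, max_size=120),
        width=st.sampled_from([0.5, 1.0, 2.0, 5.0]),
    )
    def test_matches_histogram_prune_oracle(self, values, width):
        ours = frequency_filter(values, width, 0.2)
        oracle = prune_low_frequency_bins(values, width, 0.2)
        np.testing.assert_array_equal(np.sort(ours), np.sort(oracle))

    def test_modal_bin_never_removed(self, rng):
        for _ in range(50):
            values = rng.exponential(8.0, size=rng.integers(1, 400))
            out = frequency_filter(values, 2.0, 0.2)
            bins = np.floor(values / 2.0)
            uniq, counts = np.unique(bins, return_counts=True)
            modal = uniq[np.argmax(counts)]
            assert np.sum(np.floor(out / 2.0) == modal) == counts.max()


class TestLiveFixedRule:
    @pytest.mark.parametrize(
        "tau,expected",
        [(5.86, "live_like"), (25.0, "fixed_like"), (20.0, "fixed_like"),
         (19.999, "live_like"), (0.0, "live_like")],
    )
    def test_20s_boundary_is_strict(self, tau, expected):
        assert classify_live_fixed(tau, 20.0) == expected

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            classify_live_fixed(-0.1)


class TestApplyAllGates:
    def test_empty_input(self):
        out = apply_all_gates([], FilterConfig(), "empty")
        assert out.n == 0
        assert out.provenance["n_input"] == 0
        assert sum(
            v for k, v in out.provenance.items() if k.startswith("dropped")
        ) == 0

    def test_provenance_sums_to_input(self, rng):
        fits = [
            _fit(t, r)
            for t, r in zip(rng.exponential(8, 400), rng.uniform(0.9, 1.0, 400))
        ]
        out = apply_all_gates(fits, FilterConfig(n_bursts_norm=200), "x")
        p = out.provenance
        dropped = (
            p["dropped_r2"]
            + p["dropped_subsample"]
            + p["dropped_frequency"]
            + p["dropped_class"]
        )
        assert dropped + p["n_retained"] == p["n_input"] == 400
        assert p["n_retained"] == out.n
        assert (out.tau_values_s < 20.0).all()  # live_like kept by default

    def test_idempotent(self, rng):
        fits = [
            _fit(t, r)
            for t, r in zip(rng.exponential(8, 300), rng.uniform(0.9, 1.0, 300))
        ]
        cfg = FilterConfig(n_bursts_norm=250)
        once = apply_all_gates(fits, cfg, "x")
        refit = [_fit(t, 1.0) for t in once.tau_values_s]
        twice = apply_all_gates(refit, cfg, "x")
        np.testing.assert_array_equal(once.tau_values_s, twice.tau_values_s)
        assert twice.provenance["n_retained"] == twice.provenance["n_input"]

    def test_keep_class_none_retains_both_classes(self):
        fits = [_fit(5.0, 1.0), _fit(30.0, 1.0), _fit(6.0, 1.0), _fit(31.0, 1.0)]
        cfg = FilterConfig(hist_bin_width_s=50.0)  # one bin: frequency gate inert
        out = apply_all_gates(fits, cfg, "x", keep_class=None)
        assert out.n == 4
        assert out.provenance["n_live_like"] == 2
        assert out.provenance["n_fixed_like"] == 2


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(r2_min=0.0)
    with pytest.raises(ValueError):
        FilterConfig(freq_fraction=1.0)
    with pytest.raises(ValueError):
        FilterConfig(hist_bin_width_s=0.0)
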