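"""Simulator contracts: determinism, ground truth, ON-window confinement,
background statistics, and the live/fixed temporal contrast."""
import numpy as np
import pandas as pd
import pytest

from tcpalm import (
    AcquisitionParams,
    ClusterSpec,
    PhotophysicsParams,
    live_cluster_specs,
    simulate_fixed_cell,
    simulate_live_cell,
)


def test_default_acquisition_covers_100_seconds(acq):
    assert acq.n_frames == 10_000
    assert acq.frame_time_s == 0.01
    assert acq.duration_s == pytest.approx(100.0)


def test_no_clusters_no_background_gives_empty_table(acq, phot):
    table = simulate_live_cell(acq, phot, [], background_rate_hz=0.0, seed=0)
    assert len(table) == 0
    assert list(table.columns) == [
        "frame",
        "x_nm",
        "y_nm",
        "uncertainty_nm",
        "truth_cluster_id",
    ]


def test_cluster_detections_confined_to_on_window(acq, phot, single_cluster_spec):
    table = simulate_live_cell(acq, phot, [single_cluster_spec], 0.0, seed=3)
    times = table["frame"].to_numpy() * acq.frame_time_s
    assert times.min() >= 20.0
    assert times.max() <= 28.0
    assert (table["truth_cluster_id"] == 0).all()


def test_background_count_matches_poisson_expectation(acq, phot):
    # lambda = 50 Hz * 100 s = 5000; a fixed seed stays within 3*sqrt(lambda)
    table = simulate_live_cell(acq, phot, [], background_rate_hz=50.0, seed=42)
    lam = 5000.0
    assert abs(len(table) - lam) < 3 * np.sqrt(lam)
    assert (table["truth_cluster_id"] == -1).all()


@pytest.mark.parametrize(
    "center,t_on,lifetime",
    [((20_000.0, 5000.0), 10.0, 5.0), ((5000.0, 5000.0), 98.0, 5.0)],
)
def test_invalid_cluster_error_names_the_cluster(acq, phot, center, t_on, lifetime):
    bad = ClusterSpec(center, 60.0, t_on, lifetime, 10)
    with pytest.raises(ValueError, match="cluster 1"):
        simulate_live_cell(
            acq,
            phot,
            [ClusterSpec((5000.0, 5000.0), 60.0, 0.0, 5.0, 10), bad],
            0.0,
            seed=0,
        )


def test_simulation_is_deterministic_under_seed(acq, phot, single_cluster_spec):
    a = simulate_live_cell(acq, phot, [single_cluster_spec], 20.0, seed=9)
    b = simulate_live_cell(acq, phot, [single_cluster_spec], 20.0, seed=9)
    pd.testing.assert_frame_equal(a, b)
    c = simulate_live_cell(acq, phot, [single_cluster_spec], 20.0, seed=10)
    assert not a.equals(c)


def test_table_invariants_hold(live_table, acq):
    table, specs = live_table
    assert (table["frame"] >= 0).all() and (table["frame"] < acq.n_frames).all()
    for col in ("x_nm", "y_nm"):
        assert (table[col] >= 0).all() and (table[col] <= acq.field_size_nm).all()
    key = table[["frame", "x_nm", "y_nm"]].to_numpy()
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    assert (order == np.arange(len(table))).all(), "rows sorted by frame, x, y"
    assert set(np.unique(table["truth_cluster_id"])) <= set(range(len(specs))) | {-1}


def test_fixed_cell_empty_and_immobile_cases(phot):
    acq = AcquisitionParams(localization_sigma_nm=0.0)
    assert len(simulate_fixed_cell(acq, phot, 0, seed=0)) == 0
    one = simulate_fixed_cell(acq, phot, 1, seed=5)
    assert one["x_nm"].nunique() == 1 and one["y_nm"].nunique() == 1


def test_fixed_cell_traces_span_most_of_the_acquisition(acq, phot):
    table = simulate_fixed_cell(acq, phot, n_molecules=200, seed=2)
    spans = table.groupby("truth_cluster_id")["frame"].agg(
        lambda f: (f.max() - f.min()) * acq.frame_time_s
    )
    assert (spans > 0.5 * acq.duration_s).mean() >= 0.90


def test_live_sites_have_shorter_time_spans_than_fixed_sites(acq, phot):
    live_medians, fixed_medians = [], []
    for seed in range(3):
        specs = live_cluster_specs(acq, seed=seed)
        live = simulate_live_cell(acq, phot, specs, 0.0, seed=seed)
        span = live.groupby("truth_cluster_id")["frame"].agg(np.ptp)
        live_medians.append(span.median() * acq.frame_time_s)
        fixed = simulate_fixed_cell(acq, phot, 50, seed=seed)
        span = fixed.groupby("truth_cluster_id")["frame"].agg(np.ptp)
        fixed_medians.append(span.median() * acq.frame_time_s)
    assert max(live_medians) < min(fixed_medians)


def test_parameter_validation():
    with pytest.raises(ValueError):
        AcquisitionParams(n_frames=0)
    with pytest.raises(ValueError):
        PhotophysicsParams(mean_dark_frames=0.0)
    with pytest.raises(ValueError):
        ClusterSpec((0.0, 0.0), radius_nm=-1.0, t_on_s=0.0, lifetime_s=1.0, n_molecules=1)
    with pytest.raises(ValueError):
        simulate_fixed_cell(AcquisitionParams(), PhotophysicsParams(), -1, seed=0)
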