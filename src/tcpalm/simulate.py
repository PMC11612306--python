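"""Synthetic single-molecule localization data with known ground truth.

Generates localization tables (one row per detection: frame, x, y) that
emulate two acquisition regimes used to calibrate time-correlated PALM
(tcPALM) analysis of RNA Pol II clustering:

* **live-cell** fields, where transient clusters recruit photoconvertible
  Dendra2-tagged molecules during a finite ON-window (the ground-truth
  cluster lifetime) on top of a uniform background of spurious detections;
* **fixed-cell** controls, where immobile emitters blink for the whole
  acquisition so that any apparent temporal structure is pure
  single-molecule photophysics.

Positions are drawn directly in the localization domain (no camera/PSF
rendering): a molecule sits at its cluster centre plus an isotropic
Gaussian offset of scale ``radius_nm``, and every detection adds an
independent Gaussian localization error.  Blinking is modelled as an
alternating renewal process with geometric (memoryless) ON and OFF
durations in frames.

Every simulated detection carries a ``truth_cluster_id`` column (-1 for
background) that real data files do not have; downstream readers tolerate
its absence.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionParams",
    "PhotophysicsParams",
    "ClusterSpec",
    "simulate_live_cell",
    "simulate_fixed_cell",
    "live_cluster_specs",
    "DEFAULT_LIVE_N_CLUSTERS",
    "DEFAULT_FIXED_N_MOLECULES",
    "write_ground_truth",
]

#: default number of transient clusters in the live-cell preset
DEFAULT_LIVE_N_CLUSTERS = 10
#: default number of immobile emitters in the fixed-cell preset
DEFAULT_FIXED_N_MOLECULES = 200

_TABLE_COLUMNS = ["frame", "x_nm", "y_nm", "uncertainty_nm", "truth_cluster_id"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera acquisition geometry and timing.

    Defaults reproduce a 100-s acquisition: 10,000 frames at 10 ms
    exposure, over a 15-µm square nuclear field.
    """

    n_frames: int = 10_000
    frame_time_s: float = 0.01
    field_size_nm: float = 15_000.0
    localization_sigma_nm: float = 15.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.frame_time_s <= 0:
            raise ValueError(f"frame_time_s must be > 0, got {self.frame_time_s}")
        if self.field_size_nm <= 0:
            raise ValueError(f"field_size_nm must be > 0, got {self.field_size_nm}")
        if self.localization_sigma_nm < 0:
            raise ValueError("localization_sigma_nm must be >= 0")

    @property
    def duration_s(self) -> float:
        """Total acquisition time in seconds (n_frames x frame_time_s)."""
        return self.n_frames * self.frame_time_s


@dataclass(frozen=True)
class PhotophysicsParams:
    """Dendra2-like blinking model (geometric ON/OFF durations in frames).

    ``mean_burst_frames`` and ``mean_dark_frames`` set the alternating
    fluorescent/dark durations; ``bursts_per_molecule_mean`` is the mean
    number of re-activations before irreversible bleaching (live mode
    only — fixed-cell emitters blink for the whole acquisition);
    ``detection_rate_hz`` converts to a per-frame detection probability
    for an ON molecule, ``min(1, detection_rate_hz * frame_time_s)``.

    Defaults keep dark gaps far below the 100-frame blinking cutoff, so a
    persistent emitter produces a single temporal burst.
    """

    mean_burst_frames: float = 1.0
    mean_dark_frames: float = 12.0
    bursts_per_molecule_mean: float = 3.0
    detection_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "mean_burst_frames",
            "mean_dark_frames",
            "bursts_per_molecule_mean",
            "detection_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    def detection_prob(self, frame_time_s: float) -> float:
        return min(1.0, self.detection_rate_hz * frame_time_s)


@dataclass(frozen=True)
class ClusterSpec:
    """Ground truth for one transient cluster.

    ``lifetime_s`` is the ON-window duration, i.e. the true correlation
    time the tcPALM fit should recover; ``radius_nm`` is the Gaussian
    scale of member-molecule positions around the centre.
    """

    center_xy_nm: tuple[float, float]
    radius_nm: float
    t_on_s: float
    lifetime_s: float
    n_molecules: int

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be > 0")
        if self.lifetime_s <= 0:
            raise ValueError("lifetime_s must be > 0")
        if self.t_on_s < 0:
            raise ValueError("t_on_s must be >= 0")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")


def _validate_cluster(spec: ClusterSpec, acq: AcquisitionParams, index: int) -> None:
    cx, cy = spec.center_xy_nm
    if not (0.0 <= cx <= acq.field_size_nm and 0.0 <= cy <= acq.field_size_nm):
        raise ValueError(
            f"cluster {index}: center {spec.center_xy_nm} outside field "
            f"[0, {acq.field_size_nm}] nm"
        )
    if spec.t_on_s + spec.lifetime_s > acq.duration_s + 1e-9:
        raise ValueError(
            f"cluster {index}: ON-window [{spec.t_on_s}, "
            f"{spec.t_on_s + spec.lifetime_s}] s exceeds acquisition "
            f"duration {acq.duration_s} s"
        )


def _geometric(rng: np.random.Generator, mean: float, size=None):
    # geometric on {1, 2, ...} with the given mean (p = 1/mean)
    return rng.geometric(min(1.0, 1.0 / mean), size=size)


def _blink_frames_bleaching(
    rng: np.random.Generator, phot: PhotophysicsParams, start_frame: int
) -> np.ndarray:
    """ON-frames of one molecule from activation until bleaching."""
    n_bursts = int(_geometric(rng, phot.bursts_per_molecule_mean))
    frames: list[int] = []
    f = start_frame
    for b in range(n_bursts):
        length = int(_geometric(rng, phot.mean_burst_frames))
        frames.extend(range(f, f + length))
        f += length + int(_geometric(rng, phot.mean_dark_frames))
    return np.asarray(frames, dtype=np.int64)


def _blink_frames_renewal(
    rng: np.random.Generator, phot: PhotophysicsParams, n_frames: int
) -> np.ndarray:
    """ON-frames of an alternating ON/OFF renewal process over the whole
    acquisition (vectorised; no bleaching)."""
    cycle = phot.mean_burst_frames + phot.mean_dark_frames
    frames: list[np.ndarray] = []
    f = int(_geometric(rng, phot.mean_dark_frames))  # initial dark delay
    while f < n_frames:
        n_cyc = max(16, int(1.5 * (n_frames - f) / cycle) + 8)
        bursts = _geometric(rng, phot.mean_burst_frames, n_cyc).astype(np.int64)
        darks = _geometric(rng, phot.mean_dark_frames, n_cyc).astype(np.int64)
        starts = f + np.concatenate(([0], np.cumsum(bursts + darks)[:-1]))
        # expand each burst [start, start+len) into individual frames
        total = int(bursts.sum())
        offsets = np.arange(total) - np.repeat(
            np.concatenate(([0], np.cumsum(bursts)[:-1])), bursts
        )
        frames.append(np.repeat(starts, bursts) + offsets)
        f = int(starts[-1] + bursts[-1] + darks[-1])
    out = np.concatenate(frames) if frames else np.empty(0, dtype=np.int64)
    return out[out < n_frames]


def _localize(
    rng: np.random.Generator,
    acq: AcquisitionParams,
    base_xy: np.ndarray,
    n: int,
) -> np.ndarray:
    xy = base_xy + rng.normal(0.0, acq.localization_sigma_nm, size=(n, 2))
    return np.clip(xy, 0.0, acq.field_size_nm)


def _finalize_table(parts: list[pd.DataFrame]) -> pd.DataFrame:
    if parts:
        table = pd.concat(parts, ignore_index=True)
    else:
        table = pd.DataFrame(
            {
                "frame": pd.Series(dtype=np.int64),
                "x_nm": pd.Series(dtype=float),
                "y_nm": pd.Series(dtype=float),
                "uncertainty_nm": pd.Series(dtype=float),
                "truth_cluster_id": pd.Series(dtype=np.int64),
            }
        )
    order = np.lexsort(
        (table["y_nm"].to_numpy(), table["x_nm"].to_numpy(), table["frame"].to_numpy())
    )
    return table.iloc[order].reset_index(drop=True)


def simulate_live_cell(
    acq: AcquisitionParams,
    phot: PhotophysicsParams,
    clusters: Sequence[ClusterSpec],
    background_rate_hz: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a live-cell localization table with transient clusters.

    Each cluster recruits ``n_molecules`` emitters at times uniform over
    its ON-window; every emitter blinks per ``phot`` until bleaching, and
    its detections are truncated at the window end so all detection times
    of cluster *k* fall inside ``[t_on_s, t_on_s + lifetime_s]``.
    Background detections (``truth_cluster_id = -1``) are uniform in
    space and time with total expectation
    ``background_rate_hz * duration``.

    Returns a DataFrame sorted by (frame, x, y) with columns
    frame / x_nm / y_nm / uncertainty_nm / truth_cluster_id; identical
    inputs and seed give identical tables.
    """
    if background_rate_hz < 0:
        raise ValueError("background_rate_hz must be >= 0")
    for i, spec in enumerate(clusters):
        _validate_cluster(spec, acq, i)

    rng = np.random.default_rng(seed)
    p_det = phot.detection_prob(acq.frame_time_s)
    parts: list[pd.DataFrame] = []

    for k, spec in enumerate(clusters):
        # detection times must lie within the ON-window
        f_lo = int(np.ceil(spec.t_on_s / acq.frame_time_s))
        f_hi = int(np.floor((spec.t_on_s + spec.lifetime_s) / acq.frame_time_s))
        f_hi = min(f_hi, acq.n_frames - 1)
        recruit_t = rng.uniform(
            spec.t_on_s, spec.t_on_s + spec.lifetime_s, size=spec.n_molecules
        )
        center = np.asarray(spec.center_xy_nm, dtype=float)
        frames_k: list[np.ndarray] = []
        xy_k: list[np.ndarray] = []
        for t0 in recruit_t:
            start = max(f_lo, int(np.ceil(t0 / acq.frame_time_s)))
            on = _blink_frames_bleaching(rng, phot, start)
            on = on[on <= f_hi]
            if p_det < 1.0 and on.size:
                on = on[rng.random(on.size) < p_det]
            if not on.size:
                continue
            mol_xy = center + rng.normal(0.0, spec.radius_nm, size=2)
            frames_k.append(on)
            xy_k.append(_localize(rng, acq, mol_xy, on.size))
        if frames_k:
            fr = np.concatenate(frames_k)
            xy = np.concatenate(xy_k)
            parts.append(
                pd.DataFrame(
                    {
                        "frame": fr,
                        "x_nm": xy[:, 0],
                        "y_nm": xy[:, 1],
                        "uncertainty_nm": acq.localization_sigma_nm,
                        "truth_cluster_id": np.int64(k),
                    }
                )
            )

    n_bg = rng.poisson(background_rate_hz * acq.duration_s)
    if n_bg > 0:
        parts.append(
            pd.DataFrame(
                {
                    "frame": rng.integers(0, acq.n_frames, size=n_bg),
                    "x_nm": rng.uniform(0, acq.field_size_nm, size=n_bg),
                    "y_nm": rng.uniform(0, acq.field_size_nm, size=n_bg),
                    "uncertainty_nm": acq.localization_sigma_nm,
                    "truth_cluster_id": np.int64(-1),
                }
            )
        )
    return _finalize_table(parts)


def simulate_fixed_cell(
    acq: AcquisitionParams,
    phot: PhotophysicsParams,
    n_molecules: int = DEFAULT_FIXED_N_MOLECULES,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a fixed-cell control: immobile emitters, photophysics only.

    Emitters are placed uniformly over the field and blink as an
    alternating ON/OFF renewal process for the entire acquisition (no
    bleaching, no ON-window), so their detection traces span most of the
    100 s and their apparent correlation times are long.  Each emitter is
    its own truth cluster (ids 0..n_molecules-1).
    """
    if n_molecules < 0:
        raise ValueError(f"n_molecules must be >= 0, got {n_molecules}")
    rng = np.random.default_rng(seed)
    p_det = phot.detection_prob(acq.frame_time_s)
    parts: list[pd.DataFrame] = []
    for k in range(n_molecules):
        pos = rng.uniform(0, acq.field_size_nm, size=2)
        on = _blink_frames_renewal(rng, phot, acq.n_frames)
        if p_det < 1.0 and on.size:
            on = on[rng.random(on.size) < p_det]
        if not on.size:
            continue
        xy = _localize(rng, acq, pos, on.size)
        parts.append(
            pd.DataFrame(
                {
                    "frame": on,
                    "x_nm": xy[:, 0],
                    "y_nm": xy[:, 1],
                    "uncertainty_nm": acq.localization_sigma_nm,
                    "truth_cluster_id": np.int64(k),
                }
            )
        )
    return _finalize_table(parts)


def live_cluster_specs(
    acq: AcquisitionParams,
    seed: int = 0,
    n_clusters: int = DEFAULT_LIVE_N_CLUSTERS,
    radius_nm: float = 60.0,
    lifetime_range_s: tuple[float, float] = (4.0, 12.0),
    n_molecules: int = 80,
    min_separation_nm: float = 2_000.0,
    edge_margin_nm: float = 1_000.0,
) -> list[ClusterSpec]:
    """Draw the default live-cell preset: transient clusters with random
    centres (rejection-sampled to a minimum pairwise separation), lifetimes
    uniform over ``lifetime_range_s`` and ON-starts uniform over the
    feasible range.  Lifetimes of 4-12 s place fitted correlation times in
    the 5-10 s regime typical of small RNA Pol II clusters."""
    lo, hi = lifetime_range_s
    if not (0 < lo <= hi <= acq.duration_s):
        raise ValueError(f"lifetime_range_s {lifetime_range_s} infeasible")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_clusters:
        c = rng.uniform(edge_margin_nm, acq.field_size_nm - edge_margin_nm, size=2)
        if all(np.linalg.norm(c - o) >= min_separation_nm for o in centers):
            centers.append(c)
        tries += 1
        if tries > 100_000:
            raise RuntimeError("could not place clusters at requested separation")
    specs = []
    for c in centers:
        lifetime = float(rng.uniform(lo, hi))
        t_on = float(rng.uniform(0.0, acq.duration_s - lifetime))
        specs.append(
            ClusterSpec(
                center_xy_nm=(float(c[0]), float(c[1])),
                radius_nm=radius_nm,
                t_on_s=t_on,
                lifetime_s=lifetime,
                n_molecules=n_molecules,
            )
        )
    return specs


def write_ground_truth(
    path: str | Path,
    acq: AcquisitionParams,
    phot: PhotophysicsParams,
    seed: int,
    clusters: Sequence[ClusterSpec] | None = None,
    table: pd.DataFrame | None = None,
) -> None:
    """Write the simulation ground truth as a JSON sidecar (cluster specs,
    per-cluster emitted detection counts, parameters, seed)."""
    payload: dict = {
        "seed": int(seed),
        "acquisition": asdict(acq),
        "photophysics": asdict(phot),
    }
    if clusters is not None:
        payload["clusters"] = [asdict(c) for c in clusters]
    if table is not None and "truth_cluster_id" in table.columns:
        counts = table["truth_cluster_id"].value_counts().sort_index()
        payload["detections_per_cluster"] = {
            str(int(k)): int(v) for k, v in counts.items()
        }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
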