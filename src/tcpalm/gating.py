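"""Gating of raw correlation times before condition comparison.

Raw per-burst correlation times are filtered by a fixed ledger of gates
before any statistics are computed:

1. **R² gate** — keep fits with R² >= 0.98 (inclusive); poorer fits are
   dominated by photophysics rather than clustering.
2. **Burst-count normalization** — conditions are compared at a common
   number of bursts (2500) by seeded uniform subsampling, so that
   detection-efficiency differences between acquisitions do not bias the
   lifetime distributions.
3. **Frequency filter** — correlation times falling in histogram bins
   whose frequency is below 20% of the modal bin are removed, pruning
   sparse photophysical tails.
4. **Live/fixed rule** — fixed-cell controls show correlation times of
   20 s and above; live-cell clustering is identified by tau < 20 s
   (strict), values at or above are classified fixed-like.

Every gate records how many values it dropped (the provenance ledger),
and dropped + retained always equals the input count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .temporal import CdfFit

__all__ = [
    "FilterConfig",
    "LifetimeSet",
    "gate_by_r2",
    "subsample_bursts",
    "frequency_filter",
    "classify_live_fixed",
    "apply_all_gates",
]

logger = logging.getLogger(__name__)

LiveFixed = Literal["live_like", "fixed_like"]


@dataclass(frozen=True)
class FilterConfig:
    r2_min: float = 0.98
    n_bursts_norm: int = 2500
    freq_fraction: float = 0.20
    live_tau_max_s: float = 20.0
    hist_bin_width_s: float = 2.0
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r2_min <= 1):
            raise ValueError("r2_min must be in (0, 1]")
        if self.n_bursts_norm < 1:
            raise ValueError("n_bursts_norm must be >= 1")
        if not (0 < self.freq_fraction < 1):
            raise ValueError("freq_fraction must be in (0, 1)")
        if self.live_tau_max_s <= 0:
            raise ValueError("live_tau_max_s must be > 0")
        if self.hist_bin_width_s <= 0:
            raise ValueError("hist_bin_width_s must be > 0")


@dataclass
class LifetimeSet:
    """Gated correlation times of one condition plus the drop ledger."""

    condition_label: str
    tau_values_s: np.ndarray
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return int(self.tau_values_s.size)


def gate_by_r2(fits: Sequence[CdfFit], r2_min: float = 0.98) -> list[CdfFit]:
    """Keep fits with R² >= r2_min (inclusive); order preserved."""
    if not (0 < r2_min <= 1):
        raise ValueError("r2_min must be in (0, 1]")
    return [f for f in fits if f.r_squared >= r2_min]


def subsample_bursts(
    taus: Sequence[float], n_target: int, seed: int = 0
) -> np.ndarray:
    """Subsample to ``n_target`` values without replacement (seeded).

    If fewer values than the target are available, all are retained and
    a warning is logged (bursts cannot be invented).  The output keeps
    the original relative order.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    arr = np.asarray(taus, dtype=float)
    if arr.size <= n_target:
        if arr.size < n_target:
            logger.warning(
                "only %d bursts available, below the normalization target %d; "
                "keeping all",
                arr.size,
                n_target,
            )
        return arr.copy()
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(arr.size, size=n_target, replace=False))
    return arr[keep]


def frequency_filter(
    taus: Sequence[float],
    bin_width_s: float = 2.0,
    freq_fraction: float = 0.20,
) -> np.ndarray:
    """Remove values in under-populated histogram bins.

    Values are binned into [k*w, (k+1)*w); values whose bin count is
    strictly below ``freq_fraction`` times the modal bin count are
    removed.  The modal bin is always retained.  Order is preserved.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be > 0")
    arr = np.asarray(taus, dtype=float)
    if arr.size == 0:
        return arr.copy()
    bins = np.floor(arr / bin_width_s).astype(np.int64)
    uniq, inverse, counts = np.unique(bins, return_inverse=True, return_counts=True)
    threshold = freq_fraction * counts.max()
    return arr[counts[inverse] >= threshold]


def classify_live_fixed(tau_s: float, live_tau_max_s: float = 20.0) -> LiveFixed:
    """Classify a correlation time: live-like iff tau < live_tau_max_s."""
    if tau_s < 0:
        raise ValueError(f"tau_s must be >= 0, got {tau_s}")
    return "live_like" if tau_s < live_tau_max_s else "fixed_like"


def apply_all_gates(
    fits: Sequence[CdfFit],
    cfg: FilterConfig | None = None,
    condition_label: str = "",
    keep_class: LiveFixed | None = "live_like",
) -> LifetimeSet:
    """Apply the full gate ledger: R² -> subsample -> frequency -> live/fixed.

    ``keep_class`` selects which live/fixed class survives the final
    gate ('live_like' for live-cell data); ``None`` disables that gate
    (the classification counts are still recorded).  Deterministic under
    a fixed ``subsample_seed``.
    """
    cfg = cfg or FilterConfig()
    n_input = len(fits)
    kept_fits = gate_by_r2(fits, cfg.r2_min)
    taus = np.asarray([f.tau_s for f in kept_fits], dtype=float)
    n_r2 = taus.size

    taus = subsample_bursts(taus, cfg.n_bursts_norm, cfg.subsample_seed)
    n_sub = taus.size

    taus = frequency_filter(taus, cfg.hist_bin_width_s, cfg.freq_fraction)
    n_freq = taus.size

    n_live = int(np.sum(taus < cfg.live_tau_max_s))
    n_fixed = int(taus.size - n_live)
    if keep_class == "live_like":
        taus = taus[taus < cfg.live_tau_max_s]
    elif keep_class == "fixed_like":
        taus = taus[taus >= cfg.live_tau_max_s]

    provenance = {
        "n_input": n_input,
        "dropped_r2": n_input - n_r2,
        "dropped_subsample": n_r2 - n_sub,
        "dropped_frequency": n_sub - n_freq,
        "dropped_class": n_freq - int(taus.size),
        "n_retained": int(taus.size),
        "n_live_like": n_live,
        "n_fixed_like": n_fixed,
    }
    return LifetimeSet(condition_label, taus, provenance)
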