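"""Per-condition lifetime summaries and between-condition comparison.

Conditions are summarized by median ± MAD and mean ± SEM (both reported,
always labelled — a bare "±" is ambiguous), and compared with the
unpaired two-sided Wilcoxon rank(-sum) / Mann-Whitney U test: exact
enumeration for small tie-free samples (n1 + n2 <= 20), normal
approximation with tie and continuity correction otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .gating import LifetimeSet

__all__ = [
    "NoDataError",
    "ConditionSummary",
    "ComparisonResult",
    "summarize_lifetimes",
    "wilcoxon_rank_test",
    "cumulative_distribution",
]


class NoDataError(ValueError):
    """Raised when a summary is requested for an empty lifetime set."""


@dataclass(frozen=True)
class ConditionSummary:
    condition_label: str
    n_clusters: int
    median_tau_s: float
    mad_s: float  # median absolute deviation (median-centred dispersion)
    mean_tau_s: float
    sem_s: float


@dataclass(frozen=True)
class ComparisonResult:
    label_a: str
    label_b: str
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    n1: int
    n2: int


def _values(data: LifetimeSet | Sequence[float]) -> np.ndarray:
    if isinstance(data, LifetimeSet):
        return np.asarray(data.tau_values_s, dtype=float)
    return np.asarray(data, dtype=float)


def summarize_lifetimes(lifetime_set: LifetimeSet | Sequence[float]) -> ConditionSummary:
    """Summarize a gated lifetime set (median±MAD and mean±SEM)."""
    tau = _values(lifetime_set)
    if tau.size == 0:
        raise NoDataError("no data: cannot summarize an empty lifetime set")
    label = (
        lifetime_set.condition_label if isinstance(lifetime_set, LifetimeSet) else ""
    )
    sem = float(np.std(tau, ddof=1) / np.sqrt(tau.size)) if tau.size > 1 else 0.0
    return ConditionSummary(
        condition_label=label,
        n_clusters=int(tau.size),
        median_tau_s=float(np.median(tau)),
        mad_s=float(sps.median_abs_deviation(tau)),
        mean_tau_s=float(tau.mean()),
        sem_s=sem,
    )


def wilcoxon_rank_test(
    a: LifetimeSet | Sequence[float],
    b: LifetimeSet | Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Unpaired two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when n1 + n2 <= 20 and there are no
    ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    xa, xb = _values(a), _values(b)
    if xa.size == 0 or xb.size == 0:
        raise NoDataError("no data: both samples must be non-empty")
    if isinstance(a, LifetimeSet) and a.condition_label:
        label_a = a.condition_label
    if isinstance(b, LifetimeSet) and b.condition_label:
        label_b = b.condition_label
    pooled = np.concatenate([xa, xb])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(xa.size),
        n2=int(xb.size),
    )


def cumulative_distribution(
    lifetime_set: LifetimeSet | Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of a lifetime set.

    Returns (tau_s, fraction): unique sorted values and the fraction of
    lifetimes <= each value (right-continuous; last fraction is 1).
    """
    tau = _values(lifetime_set)
    if tau.size == 0:
        raise NoDataError("no data: cannot compute the ECDF of an empty set")
    values, counts = np.unique(tau, return_counts=True)
    return values, np.cumsum(counts) / tau.size
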