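"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths (and libraries) they check:
burst splitting by explicit accumulation, the cumulative-CDF fit by
exhaustive grid search, and the rank test by enumeration of rank
assignments.
"""
from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.special import ndtr

TAU_PER_WIDTH = 2 * 1.28155
BASELINE_MAX_FRACTION = 0.25


def brute_force_bursts(frames, cutoff):
    """Split a sorted frame list into runs with gaps <= cutoff by direct
    accumulation (independent of the vectorised implementation)."""
    out, current = [], []
    for f in frames:
        if current and f - current[-1] > cutoff:
            out.append(current)
            current = []
        current.append(int(f))
    if current:
        out.append(current)
    return out


def grid_fit_tau(times, counts, n_grid=140):
    """Dense-grid least squares for the sigmoid-plus-background trace model.

    Exhaustive search over (t0, w) with the amplitude and background
    slope solved linearly under the same constraints as the fitted
    model: A in [0, 2N], b in [0, 0.25*N/span], t0 within the burst,
    w in [1e-3, 10] x span.  Returns the correlation time 2*1.28155*w of
    the lowest-SSE grid point.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    span = t[-1] - t[0]
    n = y[-1]
    if span == 0.0:
        return 0.0
    b_max = BASELINE_MAX_FRACTION * n / span
    lin = t - t[0]
    ws = np.geomspace(1e-3 * span, 10.0 * span, n_grid)
    best_sse, best_tau = np.inf, 0.0
    for t0 in np.linspace(t[0], t[-1], n_grid):
        phi_all = ndtr((t[None, :] - t0) / ws[:, None])
        for i, w in enumerate(ws):
            phi = phi_all[i]
            design = np.column_stack([phi, lin])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            a, b = float(coef[0]), float(coef[1])
            a = min(max(a, 0.0), 2.0 * n)
            b = min(max(b, 0.0), b_max)
            if b in (0.0, b_max):  # re-solve A on the clamped boundary
                denom = max(float(phi @ phi), 1e-300)
                a = min(max(float(phi @ (y - b * lin)) / denom, 0.0), 2.0 * n)
            sse = float(np.sum((a * phi + b * lin - y) ** 2))
            if sse < best_sse:
                best_sse, best_tau = sse, TAU_PER_WIDTH * w
    return best_tau


def enumerate_rank_test_p(a, b):
    """Exact two-sided Mann-Whitney p-value by enumerating every
    assignment of the pooled ranks to the first sample (tie-free data).

    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))) under the uniform
    null over all C(n1+n2, n1) rank assignments.
    """
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1, n = len(a), len(a) + len(b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2
    n_le = n_ge = 0
    for subset in combinations(range(1, n + 1), n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        n_le += u <= u_obs
        n_ge += u >= u_obs
    total = comb(n, n1)
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def prune_low_frequency_bins(values, bin_width, fraction):
    """Reference histogram-and-prune: np.histogram over [0, max] with
    fixed-width bins, drop values in bins strictly below fraction*max."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return values.copy()
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    which = np.minimum(np.searchsorted(edges, values, side="right") - 1, n_bins - 1)
    return values[counts[which] >= fraction * counts.max()]
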