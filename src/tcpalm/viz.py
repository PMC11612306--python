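"""Optional plots: lifetime frequency histogram and ECDF (SVG-friendly)."""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .gating import LifetimeSet
from .stats import cumulative_distribution


def plot_lifetime_histogram(
    sets: Sequence[LifetimeSet], bin_width_s: float = 2.0, ax=None
):
    """Frequency histogram of gated lifetimes, one series per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hi = max((s.tau_values_s.max() for s in sets if s.n), default=bin_width_s)
    edges = np.arange(0, hi + 2 * bin_width_s, bin_width_s)
    for s in sets:
        ax.hist(
            s.tau_values_s, bins=edges, alpha=0.5, label=f"{s.condition_label} (n={s.n})"
        )
    ax.set_xlabel("lifetime τ (s)")
    ax.set_ylabel("frequency")
    ax.legend()
    return ax


def plot_lifetime_ecdf(sets: Sequence[LifetimeSet], ax=None):
    """Normalized cumulative distribution of gated lifetimes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in sets:
        tau, frac = cumulative_distribution(s)
        ax.step(tau, frac, where="post", label=f"{s.condition_label} (n={s.n})")
    ax.set_xlabel("lifetime τ (s)")
    ax.set_ylabel("cumulative fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax
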