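"""Figure-style summaries: raw + smoothed profile with the cluster bar.

Plots are a convenience view of numbers that already live in the TSV/JSON
reports; nothing downstream depends on them.  matplotlib is imported lazily
so the core pipeline has no plotting dependency.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datamodel import ClusterCall, FrequencyProfile

__all__ = ["plot_tf_profile"]


def plot_tf_profile(
    profile: FrequencyProfile,
    calls: Sequence[ClusterCall] = (),
    ax=None,
):
    """Bar plot of the raw per-rank frequency, the smoothed curve, and one
    horizontal bar per positive-cell cluster (dashed where the border
    coverage is fractional).  Returns the matplotlib axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ranks = np.arange(1, profile.L_max + 1)
    ax.bar(ranks, profile.f, color="0.8", width=0.9, label="raw frequency")
    if profile.f_smooth is not None:
        ax.plot(ranks, profile.f_smooth, color="C0", lw=2, label="smoothed")
    for call in calls:
        if not call.coverage:
            continue
        y = -0.06
        core = call.core_span
        if core is not None:
            ax.hlines(y, core[0], core[1], colors="C2", lw=4)
        for r, cov in call.coverage.items():
            if cov < 1.0:  # fractional border: dashed stub
                ax.hlines(y, r - 0.4, r + 0.4, colors="C2", lw=4, linestyles=(0, (1, 1)))
    ax.set_xlabel("rank (1 = furthest from NB, oldest)")
    ax.set_ylabel("frequency")
    ax.set_ylim(-0.12, 1.05)
    ax.set_title(profile.tf)
    ax.legend(loc="upper right", frameon=False, fontsize=8)
    return ax
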