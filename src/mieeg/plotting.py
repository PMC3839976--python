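"""Optional map figures (requires the ``plot`` extra / matplotlib).

Scalp-style renderings of the condition-difference tables: coherence
subject-count maps as lines between electrode positions (thickness and
color encode the count), and per-channel power-difference curves laid
out by electrode position.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .montage import POSITIONS_2D


def plot_coherence_counts(counts: pd.DataFrame, freq_hz: float, ax=None):
    """Draw one frequency bin of a subject-count map on a schematic scalp.

    ``counts`` comes from ``cohstats.subject_significance_counts``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    sel = counts[np.isclose(counts.freq_hz, freq_hz)]
    vmax = max(int(sel.n_significant.max()), 1)
    cmap = plt.get_cmap("viridis")
    chans = sorted(set(sel.channel_a) | set(sel.channel_b))
    for _, row in sel.iterrows():
        if row.n_significant == 0:
            continue
        xa, ya = POSITIONS_2D[row.channel_a]
        xb, yb = POSITIONS_2D[row.channel_b]
        frac = row.n_significant / vmax
        ax.plot([xa, xb], [ya, yb], color=cmap(frac),
                linewidth=0.5 + 3.0 * frac, alpha=0.8, zorder=1)
    for ch in chans:
        x, y = POSITIONS_2D[ch]
        ax.scatter([x], [y], s=60, color="white", edgecolor="black",
                   zorder=2)
        ax.annotate(ch, (x, y), ha="center", va="center", fontsize=5,
                    zorder=3)
    ax.add_patch(plt.Circle((0, 0), 1.15, fill=False, color="gray"))
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_title(f"{freq_hz:.2f} Hz (max {vmax} subjects)", fontsize=8)
    return ax


def plot_power_difference(pooled: pd.DataFrame, group: str, fig=None):
    """Per-channel rest-minus-imagery curves arranged by scalp position.

    ``pooled`` comes from ``cohstats.cohort_power_difference``; thick
    line = group mean, thin lines = mean +- SD.
    """
    import matplotlib.pyplot as plt

    sel = pooled[pooled.group == group]
    if fig is None:
        fig = plt.figure(figsize=(7, 7))
    span = max(float((sel.mean_diff.abs() + sel.sd_diff.fillna(0)).max()),
               1e-9)
    for ch, cdf in sel.groupby("channel"):
        x, y = POSITIONS_2D[ch]
        ax = fig.add_axes([(x + 1.4) / 3.2, (y + 1.4) / 3.2, 0.16, 0.10])
        cdf = cdf.sort_values("freq_hz")
        ax.plot(cdf.freq_hz, cdf.mean_diff, lw=1.5, color="black")
        sd = cdf.sd_diff.fillna(0)
        ax.plot(cdf.freq_hz, cdf.mean_diff + sd, lw=0.5, color="gray")
        ax.plot(cdf.freq_hz, cdf.mean_diff - sd, lw=0.5, color="gray")
        ax.axhline(0, lw=0.3, color="blue")
        ax.set_ylim(-span, span)
        ax.set_title(ch, fontsize=6, pad=1)
        ax.tick_params(labelsize=4, length=1)
    return fig
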