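"""Overlay plots of empirical vs theoretical track-length distributions."""

from __future__ import annotations

import numpy as np

from .inference import TrackSet

__all__ = ["plot_track_length_overlay"]


def plot_track_length_overlay(
    tracks: TrackSet,
    distributions: dict,
    bins: int = 60,
    max_length: float | None = None,
    ax=None,
    log_y: bool = True,
):
    """Histogram the observed track lengths per ancestry and overlay the
    theoretical mixture-exponential densities.

    ``distributions`` maps ancestry label -> TrackLengthDistribution.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for lab, dist in distributions.items():
        ls = tracks.lengths_of(lab)
        if ls.size == 0:
            continue
        hi = max_length or float(np.quantile(ls, 0.995))
        edges = np.linspace(tracks.threshold, hi, bins + 1)
        ax.hist(
            ls, bins=edges, density=True, alpha=0.35,
            label=f"ancestry {lab} (n={ls.size})",
        )
        grid = np.linspace(max(edges[0], 1e-4), hi, 400)
        # renormalize the theoretical density to the plotted window so the
        # overlay is comparable to the density-normalized histogram
        mass = dist.sf(edges[0]) - dist.sf(hi)
        ax.plot(grid, dist.pdf(grid) / mass, lw=1.5)
    ax.set_xlabel("track length (Morgan)")
    ax.set_ylabel("density")
    if log_y:
        ax.set_yscale("log")
    ax.legend(fontsize=8)
    return ax
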