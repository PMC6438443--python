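"""Optional matplotlib heatmaps for mean-field surfaces.

Kept out of the core import path: matplotlib is only required when a
plot is actually requested.
"""

from __future__ import annotations

import numpy as np

from .meanfields import MeanFieldSurface, SignificanceSurface

__all__ = ["plot_surface"]


def plot_surface(
    surface: MeanFieldSurface,
    path: str | None = None,
    significance: SignificanceSurface | None = None,
    phase_surface: MeanFieldSurface | None = None,
    ax=None,
):
    """Heatmap of a mean-field magnitude surface (time vs log timescale).

    If ``significance`` is given (with ``phase_surface`` holding the
    matching phasor mean field when the plotted surface is a WMF),
    contours are drawn at each threshold level.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    years = surface.years if surface.years is not None else np.arange(surface.values.shape[0])
    mesh = ax.pcolormesh(years, surface.timescales, surface.magnitude.T, shading="nearest")
    ax.set_yscale("log")
    ax.set_xlabel("year")
    ax.set_ylabel("timescale (years)")
    ax.set_title(surface.kind.upper())
    plt.colorbar(mesh, ax=ax)
    if significance is not None:
        contour_surface = phase_surface if phase_surface is not None else surface
        styles = [":", "-.", "--", "-"]
        for level, threshold, style in zip(
            significance.levels, significance.thresholds, styles
        ):
            ax.contour(
                years,
                contour_surface.timescales,
                contour_surface.magnitude.T,
                levels=[threshold],
                colors="k",
                linestyles=style,
                linewidths=0.8,
            )
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
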