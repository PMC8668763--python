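"""Projection-only visualisation of occupied niche space.

Plots each year's community on the first two trait-space axes, with its 2-D
convex hull drawn inside the pool ("overarching") hull. This is a *projection*
of the multidimensional space used for the metrics — an illustration, not the
geometry the numbers are computed in.
"""

from __future__ import annotations

import numpy as np

from .core_data import CommunityMatrix
from .trait_space import TraitSpace

__all__ = ["plot_yearly_hulls"]


def plot_yearly_hulls(
    space: TraitSpace,
    comm: CommunityMatrix,
    years: list[int] | None = None,
    ncols: int = 6,
    out_path=None,
):
    """Small-multiple scatter of yearly communities over the pool hull (2-D).

    Point areas scale with relative abundance within the year. Returns the
    matplotlib figure; saves to ``out_path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.spatial import ConvexHull

    years = comm.years if years is None else years
    pool_pts = space.coords[:, :2]
    pool_hull = ConvexHull(pool_pts)
    nrows = int(np.ceil(len(years) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 2.2 * nrows),
                             sharex=True, sharey=True, squeeze=False)
    for ax in axes.flat:
        ax.set_axis_off()
    for ax, year in zip(axes.flat, years):
        ax.set_axis_on()
        for simplex in pool_hull.simplices:
            ax.plot(pool_pts[simplex, 0], pool_pts[simplex, 1], color="0.8", lw=0.8)
        present = [t for t in comm.present(year) if t in space.taxa]
        pts = space.subset(present)[:, :2]
        a = comm.abundance.loc[year, present].to_numpy(dtype=float)
        w = a / a.max()
        if len(present) >= 3:
            try:
                hull = ConvexHull(pts)
                for simplex in hull.simplices:
                    ax.plot(pts[simplex, 0], pts[simplex, 1], color="C0", lw=1.0)
            except Exception:
                pass
        ax.scatter(pts[:, 0], pts[:, 1], s=4 + 40 * w, alpha=0.6, color="C0", lw=0)
        ax.set_title(str(year), fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.suptitle("Occupied niche space, first two trait-space axes (projection only)",
                 fontsize=10)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
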