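"""Plot helpers for label fields and Voronoi diagrams."""

from __future__ import annotations

import numpy as np

from .geometry import LabelField
from .voronoi import VoronoiDiagram2D

__all__ = ["plot_label_field", "plot_voronoi_2d", "plot_region_hulls"]


def plot_label_field(labels: LabelField, ax=None, cmap: str = "tab20", **imshow_kw):
    """Show a 2D label field in world coordinates (interface in black)."""
    import matplotlib.pyplot as plt
    from matplotlib import colors

    if labels.dim != 2:
        raise ValueError("plot_label_field draws 2D fields; take a slice first")
    if ax is None:
        _, ax = plt.subplots()
    n = max(labels.n_labels, 1)
    base = plt.get_cmap(cmap)
    table = np.vstack(
        [
            [0, 0, 0, 1],  # interface
            [1, 1, 1, 1],  # unreached
            [base(i % base.N) for i in range(n)],
        ]
    )
    cm = colors.ListedColormap(table)
    org = labels.origin
    span = np.asarray(labels.grid.shape) * labels.resolution
    ax.imshow(
        labels.grid.T,  # axis 0 = world x
        origin="lower",
        extent=[org[0], org[0] + span[0], org[1], org[1] + span[1]],
        cmap=cm,
        vmin=-1.5,
        vmax=n + 0.5,
        interpolation="nearest",
        **imshow_kw,
    )
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax


def plot_voronoi_2d(diagram: VoronoiDiagram2D, ax=None, **line_kw):
    """Draw clipped Voronoi polygons and their seeds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    line_kw.setdefault("color", "k")
    line_kw.setdefault("lw", 1.0)
    for poly in diagram.polygons:
        if len(poly):
            closed = np.vstack([poly, poly[:1]])
            ax.plot(closed[:, 0], closed[:, 1], **line_kw)
    ax.plot(diagram.seeds[:, 0], diagram.seeds[:, 1], "o", color="C3", ms=4)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax


def plot_region_hulls(hulls: dict, ax=None):
    """Render 3D region hulls as translucent triangle collections."""
    import matplotlib.pyplot as plt
    from mpl_toolkits.mplot3d.art3d import Poly3DCollection

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    for k, hull in sorted(hulls.items()):
        if hull.degenerate:
            continue
        tris = hull.vertices[hull.simplices]
        ax.add_collection3d(
            Poly3DCollection(tris, alpha=0.3, facecolor=f"C{k % 10}", edgecolor="k",
                             linewidths=0.2)
        )
    return ax
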