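"""Plain matplotlib exports of unit polygons and clade-labelled sites."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

from .core import Site, UnitPartition

__all__ = ["plot_units"]


def plot_units(partition: UnitPartition | None, sites: Sequence[Site] = (),
               ax=None):
    """Draw unit polygon boundaries and sites coloured by clade."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    if partition is not None:
        for uid in partition.unit_ids:
            geom = partition.units[uid]
            polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
            for poly in polys:
                x, y = poly.exterior.xy
                ax.plot(x, y, color="0.4", lw=0.8)
            c = geom.representative_point()
            ax.annotate(uid, (c.x, c.y), fontsize=8, color="0.3",
                        ha="center", va="center")
    clades = sorted({s.clade for s in sites if s.clade})
    cmap = plt.get_cmap("tab10")
    for k, clade in enumerate(clades):
        xs = [s.lon for s in sites if s.clade == clade]
        ys = [s.lat for s in sites if s.clade == clade]
        ax.scatter(xs, ys, s=12, color=cmap(k % 10), label=clade)
    if clades:
        ax.legend(title="clade", fontsize=8, loc="best")
    ax.set_xlabel("longitude (°)")
    ax.set_ylabel("latitude (°)")
    ax.set_aspect("equal", adjustable="datalim")
    return ax
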