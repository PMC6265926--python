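"""Choropleth rendering of posterior district effects.

Draws a disease-mapping-style figure: posterior mean spatial effects on
a diverging colour scale centred at zero, labelled with district codes.
Geometry comes from a GeoJSON feature collection carrying a region-id
property; when no geometry is available a lattice heat-grid is drawn
instead so that synthetic lattice runs still produce a map figure.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import PatchCollection
from matplotlib.patches import Polygon as MplPolygon

__all__ = ["render_map", "render_lattice"]


def _polygons(geometry: dict):
    gtype = geometry["type"]
    if gtype == "Polygon":
        yield geometry["coordinates"][0]
    elif gtype == "MultiPolygon":
        for poly in geometry["coordinates"]:
            yield poly[0]
    else:
        raise ValueError(f"unsupported geometry type {gtype!r}")


def render_map(
    effects: pd.DataFrame,
    geojson_path: str | Path,
    out_path: str | Path,
    id_property: str = "district",
) -> None:
    """Choropleth of ``effects`` (columns: district, mean) over GeoJSON."""
    gj = json.loads(Path(geojson_path).read_text())
    values = dict(zip(effects["district"].astype(int), effects["mean"]))
    vmax = max(abs(v) for v in values.values()) or 1.0
    cmap = plt.get_cmap("RdBu_r")
    norm = plt.Normalize(-vmax, vmax)

    fig, ax = plt.subplots(figsize=(8, 7))
    patches, colors, labels = [], [], []
    for feat in gj["features"]:
        rid = int(feat["properties"][id_property])
        if rid not in values:
            raise ValueError(f"no posterior effect for region {rid}")
        for ring in _polygons(feat["geometry"]):
            arr = np.asarray(ring, dtype=float)
            patches.append(MplPolygon(arr, closed=True))
            colors.append(values[rid])
            labels.append((arr[:, 0].mean(), arr[:, 1].mean(), rid))
    pc = PatchCollection(patches, cmap=cmap, norm=norm, edgecolor="black", lw=0.5)
    pc.set_array(np.asarray(colors))
    ax.add_collection(pc)
    for x, y, rid in labels:
        ax.text(x, y, str(rid), ha="center", va="center", fontsize=7)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.colorbar(pc, ax=ax, shrink=0.7, label="posterior mean spatial effect")
    ax.set_title("Structured spatial effects (posterior means)")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_lattice(
    effects: pd.DataFrame, rows: int, cols: int, out_path: str | Path
) -> None:
    """Heat-grid analogue of the choropleth for lattice district maps.

    Region ids are assumed row-major 1..rows*cols, the lattice builder's
    convention.
    """
    values = dict(zip(effects["district"].astype(int), effects["mean"]))
    grid = np.full((rows, cols), np.nan)
    for rid, v in values.items():
        r, c = divmod(rid - 1, cols)
        grid[r, c] = v
    vmax = np.nanmax(np.abs(grid)) or 1.0
    fig, ax = plt.subplots(figsize=(1.2 * cols, 1.2 * rows))
    im = ax.imshow(grid, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    for rid in values:
        r, c = divmod(rid - 1, cols)
        ax.text(c, r, str(rid), ha="center", va="center", fontsize=8)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8, label="posterior mean spatial effect")
    ax.set_title("Structured spatial effects (posterior means)")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)
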