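"""Static figure export: embeddings/scatters with closed polygon overlays."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless
import matplotlib.pyplot as plt
import numpy as np

from .core_data import CellDataset
from .errors import FeatureLookupError
from .geometry import AxesContext, PolygonSet
from .selection import scatter_coordinates


def _resolve_coords(ds: CellDataset, axes: AxesContext) -> np.ndarray:
    if axes.kind == "embedding":
        return ds.get_embedding(axes.embedding_name)
    return scatter_coordinates(ds, axes)


def _resolve_colors(ds: CellDataset, color_by: str | None):
    """Color by a gene's raw expression or by a categorical annotation."""
    if color_by is None:
        return None, False
    if color_by in ds.annotations.columns:
        labels = ds.annotations[color_by].astype(str)
        cats = sorted(labels.unique())
        lut = {c: i for i, c in enumerate(cats)}
        return labels.map(lut).to_numpy(), True
    if color_by in ds.gene_ids:
        return ds.feature_values(color_by, layer="raw"), False
    raise FeatureLookupError(
        f"color_by {color_by!r} is neither an annotation column nor a gene"
    )


def render_overlay(
    ds: CellDataset,
    axes: AxesContext,
    polys: PolygonSet | None,
    color_by: str | None,
    out,
    point_size: float = 4.0,
) -> Path:
    """Scatter all cells under the axes context, draw closed polygons, save PNG.

    A sidecar ``<out>.polygons.json`` records the plotted polygon coordinates
    (identical to the session JSON) for provenance.
    """
    out = Path(out)
    coords = _resolve_coords(ds, axes)
    colors, categorical = _resolve_colors(ds, color_by)

    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        coords[:, 0],
        coords[:, 1],
        c=colors if colors is not None else "grey",
        cmap="tab10" if categorical else "viridis",
        s=point_size,
        linewidths=0,
    )
    if colors is not None and not categorical:
        fig.colorbar(sc, ax=ax, label=color_by)
    if polys is not None:
        for poly in polys.polygons:
            v = np.vstack([poly.vertices, poly.vertices[:1]])
            ax.plot(v[:, 0], v[:, 1], lw=1.5)
            ax.annotate(poly.name, poly.vertices.mean(axis=0))
    if axes.kind == "embedding":
        ax.set_xlabel(f"{axes.embedding_name} 1")
        ax.set_ylabel(f"{axes.embedding_name} 2")
    else:
        ax.set_xlabel(f"{axes.x_feature} ({axes.x_scale})")
        ax.set_ylabel(f"{axes.y_feature} ({axes.y_scale})")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)

    if polys is not None:
        sidecar = out.with_suffix(out.suffix + ".polygons.json")
        with open(sidecar, "w") as fh:
            json.dump(polys.to_json_dict(), fh, indent=1)
    return out
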