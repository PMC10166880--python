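"""Apply polygon gates to a dataset and manage the resulting annotations.

Gates enter programmatically (vertex lists or session JSON) rather than by
mouse capture; applying a set writes one label per cell into an annotation
column, stores the polygon set in the dataset's session store under the same
key, and returns a :class:`SelectionResult` bundling labels with the full
cells-by-polygons boolean membership matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import CellDataset
from .errors import AxesContextError, DomainError, FeatureLookupError
from .geometry import (
    AxesContext,
    PolygonSet,
    labels_from_membership,
    membership_matrix,
)

logger = logging.getLogger(__name__)

#: pseudo-count used to place zero counts on log10 axes (half a count)
DEFAULT_ZERO_PSEUDO = 0.5


@dataclass
class SelectionResult:
    """Outcome of applying one polygon set: labels + membership + provenance."""

    key: str
    labels: list[str]
    membership: np.ndarray  # n_cells x n_polygons, bool
    polygon_set: PolygonSet


def _write_result(
    ds: CellDataset, key: str, labels: list[str], polys: PolygonSet
) -> None:
    if key in ds.annotations.columns:
        logger.info("overwriting existing annotation column %r", key)
    ds.annotations[key] = labels
    ds.polygon_store[key] = polys


def select_on_embedding(
    ds: CellDataset,
    embedding_name: str,
    polys: PolygonSet,
    key: str,
    outside_label: str = "rest",
) -> SelectionResult:
    """Gate cells on a named 2-D embedding and annotate the dataset in place."""
    coords = ds.get_embedding(embedding_name)
    if polys.axes.kind != "embedding":
        raise AxesContextError(
            f"polygon set drawn on {polys.axes.kind!r} axes cannot be applied "
            f"to embedding {embedding_name!r}"
        )
    if polys.axes.embedding_name != embedding_name:
        raise AxesContextError(
            f"polygon set bound to embedding {polys.axes.embedding_name!r}, "
            f"requested {embedding_name!r}"
        )
    m = membership_matrix(coords, polys)
    labels = labels_from_membership(m, polys.names, outside_label)
    _write_result(ds, key, labels, polys)
    return SelectionResult(key=key, labels=labels, membership=m, polygon_set=polys)


def scatter_coordinates(
    ds: CellDataset,
    axes: AxesContext,
    zero_pseudo: float = DEFAULT_ZERO_PSEUDO,
) -> np.ndarray:
    """Per-cell (x, y) display coordinates for a feature-vs-feature scatter.

    log10-scaled axes transform the values; zeros are placed at
    ``log10(zero_pseudo)`` (half a count by default) so they stay gateable.
    """
    cols = []
    for feature, scale in (
        (axes.x_feature, axes.x_scale),
        (axes.y_feature, axes.y_scale),
    ):
        vals = ds.feature_values(feature, layer=axes.layer)
        if scale == "log10":
            if (vals < 0).any():
                raise DomainError(
                    f"feature {feature!r} has negative values; log10 axis invalid"
                )
            vals = np.where(vals > 0, vals, zero_pseudo)
            vals = np.log10(vals)
        cols.append(vals)
    return np.column_stack(cols)


def select_on_scatter(
    ds: CellDataset,
    polys: PolygonSet,
    key: str,
    outside_label: str = "rest",
    zero_pseudo: float = DEFAULT_ZERO_PSEUDO,
) -> SelectionResult:
    """Gate cells on a feature-vs-feature scatter defined by the set's axes.

    Polygons are interpreted in the *displayed* coordinate system: with a
    log10 axis the polygon vertices are log10-transformed values.
    """
    if polys.axes.kind != "scatter":
        raise AxesContextError(
            f"polygon set drawn on {polys.axes.kind!r} axes cannot be applied to a scatter"
        )
    pts = scatter_coordinates(ds, polys.axes, zero_pseudo=zero_pseudo)
    m = membership_matrix(pts, polys)
    labels = labels_from_membership(m, polys.names, outside_label)
    _write_result(ds, key, labels, polys)
    return SelectionResult(key=key, labels=labels, membership=m, polygon_set=polys)


def apply_session(
    ds: CellDataset, polys: PolygonSet, key: str, outside_label: str = "rest"
) -> SelectionResult:
    """Dispatch a polygon set to the embedding or scatter path based on its axes."""
    if polys.axes.kind == "embedding":
        return select_on_embedding(ds, polys.axes.embedding_name, polys, key, outside_label)
    return select_on_scatter(ds, polys, key, outside_label)


def rename_labels(ds: CellDataset, key: str, mapping: dict[str, str]) -> CellDataset:
    """Replace selection labels (e.g. default integer names) with custom names.

    Composite comma-joined labels are renamed as whole strings.  Every mapping
    source must be a label currently present; a mapping that merges distinct
    groups into one target is allowed but warned about.
    """
    if key not in ds.annotations.columns:
        raise FeatureLookupError(f"unknown annotation key {key!r}")
    labels = ds.annotations[key].astype(str)
    present = set(labels)
    unknown = set(mapping) - present
    if unknown:
        raise FeatureLookupError(
            f"labels {sorted(unknown)} not present under {key!r}; "
            f"valid labels: {sorted(present)}"
        )
    targets = list(mapping.values())
    merged = set(targets) & (present - set(mapping))
    if len(targets) != len(set(targets)) or merged:
        warnings.warn(
            f"rename under {key!r} merges distinct groups into one label",
            stacklevel=2,
        )
    ds.annotations[key] = labels.map(lambda s: mapping.get(s, s)).to_numpy()
    return ds


def save_session(ds: CellDataset, key: str, path) -> None:
    """Persist the polygon set stored under an annotation key as session JSON."""
    try:
        polys = ds.polygon_store[key]
    except KeyError:
        raise FeatureLookupError(f"no polygon session stored under key {key!r}") from None
    polys.save(path)


def load_session(path) -> PolygonSet:
    """Load a polygon session from JSON; vertices reproduce exactly as written."""
    return PolygonSet.load(path)
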