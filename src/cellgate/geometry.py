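"""Polygon gates and point-in-polygon membership.

A gate is an ordered list of vertices, implicitly closed, drawn in some axes
context (a named 2-D embedding, or a feature-vs-feature scatter with linear or
log10 axes).  Membership uses the even-odd (crossing-number) rule, so
self-intersecting hand-drawn polygons are legal and resolved by crossing
parity.  Points on an edge or vertex count as inside: gates are closed sets,
as in flow cytometry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

#: distance below which a point is considered to lie on a polygon edge
BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class AxesContext:
    """Where a polygon lives: which plot, which features, which axis scales."""

    kind: str  # "embedding" | "scatter"
    embedding_name: str | None = None
    x_feature: str | None = None
    y_feature: str | None = None
    layer: str = "raw"  # layer for scatter features: "raw" | "normalized"
    x_scale: str = "linear"  # "linear" | "log10"
    y_scale: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in ("embedding", "scatter"):
            raise ValidationError(f"axes kind must be embedding/scatter, got {self.kind!r}")
        if self.kind == "embedding" and not self.embedding_name:
            raise ValidationError("embedding axes require embedding_name")
        if self.kind == "scatter" and not (self.x_feature and self.y_feature):
            raise ValidationError("scatter axes require x_feature and y_feature")
        for s in (self.x_scale, self.y_scale):
            if s not in ("linear", "log10"):
                raise ValidationError(f"axis scale must be linear/log10, got {s!r}")

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "x_scale": self.x_scale, "y_scale": self.y_scale}
        if self.kind == "embedding":
            d["embedding_name"] = self.embedding_name
        else:
            d.update(
                x_feature=self.x_feature, y_feature=self.y_feature, layer=self.layer
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AxesContext":
        return cls(
            kind=d["kind"],
            embedding_name=d.get("embedding_name"),
            x_feature=d.get("x_feature"),
            y_feature=d.get("y_feature"),
            layer=d.get("layer", "raw"),
            x_scale=d.get("x_scale", "linear"),
            y_scale=d.get("y_scale", "linear"),
        )


@dataclass(frozen=True)
class Polygon:
    """Named, implicitly-closed polygon with >= 3 finite vertices.

    Default names are decimal integers (as strings) assigned in drawing
    order.  Convexity and non-self-intersection are not required.
    """

    name: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValidationError(f"polygon {self.name!r}: vertices must be (k, 2)")
        if v.shape[0] < 3:
            raise ValidationError(
                f"polygon {self.name!r}: at least 3 vertices required, got {v.shape[0]}"
            )
        if not np.isfinite(v).all():
            raise ValidationError(f"polygon {self.name!r}: non-finite vertex coordinates")
        object.__setattr__(self, "vertices", v)
        if abs(_signed_area(v)) == 0.0:
            warnings.warn(
                f"polygon {self.name!r} has zero area; it matches only boundary points",
                stacklevel=2,
            )

    def translated(self, dx: float, dy: float) -> "Polygon":
        return Polygon(self.name, self.vertices + np.array([dx, dy]))

    def scaled(self, s: float) -> "Polygon":
        return Polygon(self.name, self.vertices * s)


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class PolygonSet:
    """Ordered collection of uniquely-named polygons bound to one axes context."""

    axes: AxesContext
    polygons: list[Polygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.polygons]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate polygon names in set: {names}")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.polygons]

    def __len__(self) -> int:
        return len(self.polygons)

    @classmethod
    def from_vertex_lists(
        cls,
        axes: AxesContext,
        vertex_lists: Iterable[Sequence],
        names: Sequence[str] | None = None,
    ) -> "PolygonSet":
        """Build a set from bare vertex lists; unnamed polygons get "0", "1", ..."""
        vertex_lists = list(vertex_lists)
        if names is None:
            names = [str(i) for i in range(len(vertex_lists))]
        polys = [Polygon(str(n), np.asarray(v, float)) for n, v in zip(names, vertex_lists)]
        return cls(axes=axes, polygons=polys)

    # ------------------------------------------------------------------ JSON
    def to_json_dict(self) -> dict:
        return {
            "axes": self.axes.to_dict(),
            "polygons": [
                {"name": p.name, "vertices": p.vertices.tolist()} for p in self.polygons
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PolygonSet":
        try:
            axes = AxesContext.from_dict(d["axes"])
            polys = [
                Polygon(str(p["name"]), np.asarray(p["vertices"], float))
                for p in d["polygons"]
            ]
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed polygon-session schema: {exc}") from exc
        return cls(axes=axes, polygons=polys)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "PolygonSet":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}: malformed JSON ({exc})") from exc
        return cls.from_json_dict(d)


# -------------------------------------------------------------- membership
def _on_boundary(points: np.ndarray, v: np.ndarray, tol: float) -> np.ndarray:
    """True where a point lies within ``tol`` of some polygon edge."""
    a = v
    b = np.roll(v, -1, axis=0)
    ab = b - a  # (k, 2)
    seg_len2 = np.einsum("ij,ij->i", ab, ab)  # (k,)
    # vector from each edge start to each point: (n, k, 2)
    ap = points[:, None, :] - a[None, :, :]
    t = np.einsum("nkj,kj->nk", ap, ab)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(seg_len2 > 0, t / seg_len2, 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * ab[None, :, :]
    d2 = np.einsum("nkj->nk", (points[:, None, :] - closest) ** 2)
    return (d2 <= tol * tol).any(axis=1)


def points_in_polygon(
    points: np.ndarray, poly: Polygon, tol: float = BOUNDARY_TOL
) -> np.ndarray:
    """Vectorized even-odd test; boundary points (within ``tol``) are inside."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != 2:
        raise ValidationError("points must be (n, 2)")
    if not np.isfinite(points).all():
        raise ValidationError("points contain non-finite coordinates")
    v = poly.vertices
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for j in range(len(v)):
        # half-open vertical rule avoids double-counting shared vertices
        crosses = (y1[j] > y) != (y2[j] > y)
        if not crosses.any():
            continue
        x_int = x1[j] + (y - y1[j]) * (x2[j] - x1[j]) / (y2[j] - y1[j])
        inside ^= crosses & (x < x_int)
    inside |= _on_boundary(points, v, tol)
    return inside


def point_in_polygon(p: Sequence[float], poly: Polygon, tol: float = BOUNDARY_TOL) -> bool:
    """Even-odd membership of a single point (boundary-inclusive)."""
    return bool(points_in_polygon(np.asarray(p, float)[None, :], poly, tol=tol)[0])


def membership_matrix(points: np.ndarray, polys: PolygonSet) -> np.ndarray:
    """Boolean ``n x k`` matrix: entry (i, j) iff point i is inside polygon j."""
    if len(polys) == 0:
        raise ValidationError("polygon set is empty: nothing to select")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    return np.column_stack([points_in_polygon(points, p) for p in polys.polygons])


def labels_from_membership(
    membership: np.ndarray, names: Sequence[str], outside_label: str = "rest"
) -> list[str]:
    """Comma-join the names of all polygons containing each cell.

    Join order follows polygon drawing order.  Cells inside no polygon get
    ``outside_label`` (default ``"rest"``).
    """
    names = list(names)
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate polygon names: {names}")
    membership = np.asarray(membership, dtype=bool)
    if membership.shape[1] != len(names):
        raise ValidationError("membership columns must match number of names")
    arr = np.array(names, dtype=object)
    return [
        ",".join(arr[row]) if row.any() else outside_label for row in membership
    ]
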