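"""Synthetic single-cell datasets with the structure polygon gating assumes.

The generator emulates the statistical shape of droplet scRNA-seq with
optional antibody-capture features: cells fall into clusters, each cluster is
a Gaussian blob in a 2-D embedding, marker genes are elevated by a fold
factor in designated clusters, UMI counts are negative-binomial (overdispersed
relative to Poisson, as real UMI data are) with independent dropout, and
antibody-capture counts are log-normal so they span orders of magnitude, the
regime where log-axis gating matters.

Ground-truth cluster labels are stored in the ``"true_cluster"`` annotation,
so gate recovery, enrichment and mixture fits can all be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import chi2

from .core_data import CellDataset
from .errors import ValidationError
from .geometry import Polygon

TRUTH_KEY = "true_cluster"


@dataclass
class MarkerSpec:
    """One marker gene elevated ``fold``-fold in a set of clusters."""

    gene: str
    clusters: frozenset[int]
    fold: float

    def __post_init__(self) -> None:
        self.clusters = frozenset(int(c) for c in self.clusters)
        if self.fold <= 1:
            raise ValidationError(f"marker {self.gene!r}: fold must be > 1")


@dataclass
class CaptureSpec:
    """Antibody-capture-like feature: log-normal counts, cluster-specific location.

    ``log10_loc`` maps cluster index -> location of log10(counts); clusters
    not listed use ``baseline_log10``.  sigma is the log10-scale spread.
    """

    feature: str
    log10_loc: dict[int, float]
    baseline_log10: float = 0.3
    sigma: float = 0.35


@dataclass
class SimSpec:
    """Parameters of one simulated dataset; defaults give a typical small run."""

    n_cells: int = 2000
    n_genes: int = 100
    n_clusters: int = 3
    cluster_weights: np.ndarray | None = None  # uniform if None
    embedding_centers: np.ndarray | None = None  # circle of radius 10 if None
    embedding_sd: float = 1.0
    marker_table: list[MarkerSpec] = field(default_factory=list)
    baseline_mean: float = 2.0
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.1
    capture_features: list[CaptureSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_cells < 1 or self.n_genes < 1:
            raise ValidationError("n_cells, n_genes, n_clusters must be positive")
        if self.cluster_weights is None:
            self.cluster_weights = np.full(self.n_clusters, 1.0 / self.n_clusters)
        self.cluster_weights = np.asarray(self.cluster_weights, dtype=float)
        if len(self.cluster_weights) != self.n_clusters:
            raise ValidationError("cluster_weights length must equal n_clusters")
        if abs(self.cluster_weights.sum() - 1.0) > 1e-9 or (self.cluster_weights < 0).any():
            raise ValidationError("cluster_weights must be a probability simplex")
        if self.embedding_centers is None:
            ang = 2 * np.pi * np.arange(self.n_clusters) / max(self.n_clusters, 1)
            self.embedding_centers = 10.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        self.embedding_centers = np.asarray(self.embedding_centers, dtype=float)
        if self.embedding_centers.shape != (self.n_clusters, 2):
            raise ValidationError("embedding_centers must be n_clusters x 2")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.nb_dispersion <= 0 or self.embedding_sd <= 0 or self.baseline_mean <= 0:
            raise ValidationError("dispersion, embedding_sd, baseline_mean must be > 0")
        for m in self.marker_table:
            if m.clusters and max(m.clusters) >= self.n_clusters:
                raise ValidationError(f"marker {m.gene!r} references unknown cluster")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance mean + mean^2/dispersion."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate(spec: SimSpec) -> CellDataset:
    """Draw one dataset from the spec; deterministic per ``spec.seed``.

    Gene ids are ``gene000``... with marker names substituted; capture
    features are appended after the genes.  The embedding is stored under
    ``"umap"`` and true cluster labels under ``"true_cluster"``.
    """
    rng = np.random.default_rng(spec.seed)
    clusters = rng.choice(spec.n_clusters, size=spec.n_cells, p=spec.cluster_weights)
    coords = spec.embedding_centers[clusters] + rng.normal(
        0.0, spec.embedding_sd, size=(spec.n_cells, 2)
    )

    gene_ids = [f"gene{i:03d}" for i in range(spec.n_genes)]
    marker_idx: dict[str, int] = {}
    for i, m in enumerate(spec.marker_table):
        if i >= spec.n_genes:
            raise ValidationError("more markers than genes")
        gene_ids[i] = m.gene
        marker_idx[m.gene] = i

    means = np.full((spec.n_cells, spec.n_genes), spec.baseline_mean)
    for m in spec.marker_table:
        in_cluster = np.isin(clusters, list(m.clusters))
        means[in_cluster, marker_idx[m.gene]] *= m.fold
    counts = _nb_draw(rng, means, spec.nb_dispersion)
    if spec.dropout_rate > 0:
        keep = rng.random(counts.shape) >= spec.dropout_rate
        counts = counts * keep

    if spec.capture_features:
        cap_cols = []
        for cap in spec.capture_features:
            loc = np.array(
                [cap.log10_loc.get(int(c), cap.baseline_log10) for c in clusters]
            )
            vals = 10.0 ** rng.normal(loc, cap.sigma)
            cap_cols.append(np.round(vals).astype(np.int64))
        counts = np.column_stack([counts] + cap_cols)
        gene_ids = gene_ids + [cap.feature for cap in spec.capture_features]

    ds = CellDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=[f"cell{i:05d}" for i in range(spec.n_cells)],
        gene_ids=gene_ids,
    )
    ds.annotations[TRUTH_KEY] = [str(int(c)) for c in clusters]
    ds.attach_embedding("umap", coords)
    return ds


def reference_polygon(
    spec: SimSpec, cluster: int, q: float = 0.95, n_vertices: int = 16, name: str | None = None
) -> Polygon:
    """Convex polygon covering probability ``q`` of a cluster's embedding Gaussian.

    A regular ``n_vertices``-gon circumscribing the circle of radius
    ``sd * sqrt(chi2.ppf(q, 2))`` around the cluster center, so the enclosed
    probability is (slightly above) ``q`` and expected membership is known
    analytically.
    """
    if not (0 < q < 1):
        raise ValidationError("q must be in (0, 1)")
    center = spec.embedding_centers[cluster]
    r = spec.embedding_sd * float(np.sqrt(chi2.ppf(q, df=2)))
    # circumscribe so the inscribed circle has radius r
    r_out = r / np.cos(np.pi / n_vertices)
    ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
    verts = center + r_out * np.column_stack([np.cos(ang), np.sin(ang)])
    return Polygon(name if name is not None else str(cluster), verts)


def straddling_marker_dataset(
    seed: int,
    n_cells: int = 2000,
    n_genes: int = 60,
    zone_fold: float = 40.0,
    zone_radius: float = 1.5,
    marker: str = "MARKER",
) -> tuple[CellDataset, Polygon]:
    """Two block clusters with a marker whose high zone straddles them both.

    Two Gaussian blobs sit side by side; the marker gene is elevated not in
    either cluster but in the disc of radius ``zone_radius`` around the
    midpoint between the cluster centers, so block-cluster membership is a
    poor proxy for marker expression.  Returns the dataset (truth labels in
    ``"true_cluster"``, zone membership in ``"in_zone"``) and a tight
    polygon gate around the zone.
    """
    centers = np.array([[-2.0, 0.0], [2.0, 0.0]])
    spec = SimSpec(
        n_cells=n_cells,
        n_genes=n_genes,
        n_clusters=2,
        embedding_centers=centers,
        embedding_sd=1.2,
        baseline_mean=2.0,
        nb_dispersion=2.0,
        dropout_rate=0.1,
        seed=seed,
    )
    ds = simulate(spec)
    gene_ids = list(ds.gene_ids)
    gene_ids[0] = marker
    ds.gene_ids = gene_ids

    rng = np.random.default_rng(seed + 1)
    coords = ds.get_embedding("umap")
    in_zone = np.sum(coords**2, axis=1) <= zone_radius**2
    counts = ds.counts.tolil()
    boosted = _nb_draw(
        rng, np.full(int(in_zone.sum()), spec.baseline_mean * zone_fold), spec.nb_dispersion
    )
    boosted = boosted * (rng.random(len(boosted)) >= spec.dropout_rate)
    counts[np.flatnonzero(in_zone), 0] = boosted[:, None]
    ds.counts = sp.csr_matrix(counts)
    ds.annotations["in_zone"] = np.where(in_zone, "zone", "rest")

    ang = 2 * np.pi * np.arange(16) / 16
    r = zone_radius / np.cos(np.pi / 16)
    gate = Polygon("zone", r * np.column_stack([np.cos(ang), np.sin(ang)]))
    return ds, gate
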