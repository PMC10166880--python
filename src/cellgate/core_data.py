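"""Self-contained single-cell dataset container and plain-text I/O.

The central object is :class:`CellDataset`: a cells-by-genes matrix of raw UMI
counts, aligned cell/gene identifiers, per-cell annotation columns, named 2-D
embeddings and a store of polygon gating sessions.  Cell order is the canonical
index everywhere — matrices, annotations and embeddings align positionally;
``cell_id`` is used only when joining against files.

Counts are held sparse (CSR) internally, but all contracts are value-level:
readers accept Matrix Market triplets or dense CSV and produce the same object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    DimensionalityError,
    FeatureLookupError,
    FormatError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .geometry import PolygonSet

logger = logging.getLogger(__name__)


def _as_int_csr(matrix, source: str = "<matrix>") -> sp.csr_matrix:
    """Coerce to an integer CSR matrix, rejecting negative or fractional entries."""
    m = sp.csr_matrix(matrix)
    data = np.asarray(m.data, dtype=np.float64)
    if data.size and not np.isfinite(data).all():
        raise ValidationError(f"{source}: matrix contains non-finite entries")
    if data.size and (data < 0).any():
        raise ValidationError(f"{source}: matrix contains negative entries")
    if data.size and np.any(data != np.round(data)):
        raise ValidationError(f"{source}: matrix contains non-integer entries")
    out = m.astype(np.int64)
    out.eliminate_zeros()
    return out


@dataclass
class CellDataset:
    """Cells-by-genes UMI count matrix with annotations, embeddings and gate sessions.

    Parameters
    ----------
    counts
        ``n_cells x n_genes`` non-negative integer matrix of raw UMI counts.
    cell_ids, gene_ids
        Unique string identifiers; lengths fix the matrix dimensions.
    normalized
        Optional same-shape non-negative real matrix.  When absent and
        requested, computed lazily: counts scaled per cell to the median
        total count, then ``log1p``.
    annotations
        Per-cell columns (labels, cluster assignments, ...).
    embeddings
        Name -> ``n_cells x 2`` finite coordinate matrix (UMAP, t-SNE, PCA...).
    polygon_store
        Annotation key -> the :class:`~cellgate.geometry.PolygonSet` that
        produced it, kept so gates can be re-plotted or re-applied.
    """

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    normalized: sp.csr_matrix | None = None
    annotations: pd.DataFrame | None = None
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    polygon_store: dict[str, "PolygonSet"] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = _as_int_csr(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=pd.RangeIndex(self.n_cells))
        self.validate()

    # ------------------------------------------------------------------ basics
    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise FeatureLookupError(f"unknown gene/feature {gene!r}") from None

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any broken container invariant."""
        if self.counts.shape != (self.n_cells, self.n_genes):
            raise ValidationError(
                f"counts shape {self.counts.shape} != "
                f"({self.n_cells} cells, {self.n_genes} genes)"
            )
        if len(set(self.cell_ids)) != self.n_cells:
            raise ValidationError("cell_ids contain duplicates")
        if len(set(self.gene_ids)) != self.n_genes:
            raise ValidationError("gene_ids contain duplicates")
        if self.normalized is not None:
            if self.normalized.shape != self.counts.shape:
                raise ValidationError("normalized layer shape differs from counts")
            if self.normalized.data.size and (self.normalized.data < 0).any():
                raise ValidationError("normalized layer has negative entries")
        if len(self.annotations) != self.n_cells:
            raise ValidationError(
                f"annotations have {len(self.annotations)} rows for "
                f"{self.n_cells} cells"
            )
        for name, coords in self.embeddings.items():
            _check_embedding(coords, self.n_cells, name)

    # ----------------------------------------------------------------- layers
    def get_layer(self, layer: str = "raw") -> sp.csr_matrix:
        """Return the requested expression layer, computing ``normalized`` on demand."""
        if layer == "raw":
            return self.counts
        if layer == "normalized":
            if self.normalized is None:
                self.normalized = median_normalize(self.counts)
            return self.normalized
        raise FeatureLookupError(f"unknown layer {layer!r} (use 'raw' or 'normalized')")

    def feature_values(self, gene: str, layer: str = "raw") -> np.ndarray:
        """Dense per-cell vector of one gene's values in the given layer."""
        j = self.gene_index(gene)
        return np.asarray(self.get_layer(layer)[:, j].todense()).ravel()

    # ------------------------------------------------------------- embeddings
    def attach_embedding(self, name: str, coords: np.ndarray) -> "CellDataset":
        """Register a named 2-D embedding; rejects anything not exactly 2 columns."""
        coords = np.asarray(coords, dtype=float)
        _check_embedding(coords, self.n_cells, name)
        self.embeddings[name] = coords
        return self

    def get_embedding(self, name: str) -> np.ndarray:
        try:
            return self.embeddings[name]
        except KeyError:
            raise FeatureLookupError(
                f"unknown embedding {name!r}; have {sorted(self.embeddings)}"
            ) from None

    # --------------------------------------------------------------- subsets
    def subset(self, mask: np.ndarray) -> "CellDataset":
        """New dataset containing only cells where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_cells,):
            raise ValidationError("subset mask length must equal n_cells")
        idx = np.flatnonzero(mask)
        return CellDataset(
            counts=self.counts[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            normalized=None if self.normalized is None else self.normalized[idx],
            annotations=self.annotations.iloc[idx].reset_index(drop=True),
            embeddings={k: v[idx] for k, v in self.embeddings.items()},
            polygon_store=dict(self.polygon_store),
        )


def _check_embedding(coords: np.ndarray, n_cells: int, name: str) -> None:
    coords = np.asarray(coords)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise DimensionalityError(
            f"embedding {name!r}: embeddings limited to 2 dimensions, "
            f"got shape {coords.shape}"
        )
    if coords.shape[0] != n_cells:
        raise ValidationError(
            f"embedding {name!r} has {coords.shape[0]} rows for {n_cells} cells"
        )
    if not np.isfinite(coords).all():
        raise ValidationError(f"embedding {name!r} contains non-finite values")


def median_normalize(counts: sp.spmatrix) -> sp.csr_matrix:
    """Per-cell scaling to the median total count, then log1p.

    The standard library-size normalization for UMI data: each cell's counts
    are divided by its total and multiplied by the median total over cells,
    then log1p-transformed.  Cells with zero total are left at zero.
    """
    counts = sp.csr_matrix(counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    target = float(np.median(totals[totals > 0])) if (totals > 0).any() else 1.0
    scale = np.divide(target, totals, out=np.zeros_like(totals), where=totals > 0)
    out = sp.diags(scale) @ counts
    out.data = np.log1p(out.data)
    return sp.csr_matrix(out)


# ---------------------------------------------------------------------- files
def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def read_mtx_dataset(
    matrix_path,
    barcodes_path,
    features_path,
    orientation: str = "cells-by-genes",
) -> CellDataset:
    """Read a Matrix Market matrix plus barcode/feature TSVs into a dataset.

    ``orientation`` must be stated explicitly because both conventions exist
    in the wild (CellRanger writes genes-by-cells); genes-by-cells input is
    transposed so the returned counts are always cells-by-genes.  Feature
    lines may carry 2-3 tab-separated fields; the first is the gene id.
    """
    if orientation not in ("cells-by-genes", "genes-by-cells"):
        raise ValueError(f"orientation must be cells-by-genes or genes-by-cells, got {orientation!r}")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:
        raise FormatError(f"{matrix_path}: not a readable Matrix Market file ({exc})") from exc
    barcodes = [line.split("\t")[0] for line in _read_lines(barcodes_path)]
    features = [line.split("\t")[0] for line in _read_lines(features_path)]

    n_rows, n_cols = mat.shape
    if orientation == "cells-by-genes":
        exp_rows, exp_cols = len(barcodes), len(features)
    else:
        exp_rows, exp_cols = len(features), len(barcodes)
    if n_rows != exp_rows:
        bad = barcodes_path if orientation == "cells-by-genes" else features_path
        raise FormatError(
            f"{bad}: {exp_rows} entries but matrix declares {n_rows} rows"
        )
    if n_cols != exp_cols:
        bad = features_path if orientation == "cells-by-genes" else barcodes_path
        raise FormatError(
            f"{bad}: {exp_cols} entries but matrix declares {n_cols} columns"
        )
    counts = _as_int_csr(mat, source=str(matrix_path))
    if orientation == "genes-by-cells":
        counts = sp.csr_matrix(counts.T)
    return CellDataset(counts=counts, cell_ids=barcodes, gene_ids=features)


def write_mtx_dataset(ds: CellDataset, out_dir) -> None:
    """Write matrix.mtx (cells-by-genes, integer) + barcodes.tsv + features.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(ds.counts), field="integer")
    (out / "barcodes.tsv").write_text("".join(c + "\n" for c in ds.cell_ids))
    (out / "features.tsv").write_text("".join(g + "\n" for g in ds.gene_ids))


def read_dense_csv(path) -> CellDataset:
    """Dense CSV matrix: first column cell_id, header row gene_ids."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return CellDataset(
        counts=_as_int_csr(df.to_numpy(), source=str(path)),
        cell_ids=[str(c) for c in df.index],
        gene_ids=[str(g) for g in df.columns],
    )


def write_dense_csv(ds: CellDataset, path) -> None:
    df = pd.DataFrame(
        ds.counts.toarray(), index=ds.cell_ids, columns=ds.gene_ids
    )
    df.index.name = "cell_id"
    df.to_csv(path, float_format="%.17g")


def write_dataset_dir(ds: CellDataset, out_dir) -> None:
    """Persist a dataset as a directory of plain-text files.

    Layout: matrix.mtx + barcodes.tsv + features.tsv, annotations.csv (if any
    columns), and one embedding_<name>.csv per embedding.
    """
    out = Path(out_dir)
    write_mtx_dataset(ds, out)
    if len(ds.annotations.columns):
        write_annotations(ds, out / "annotations.csv")
    for name in ds.embeddings:
        write_embedding_csv(ds, out / f"embedding_{name}.csv", name)


def read_dataset_dir(in_dir) -> CellDataset:
    """Read a dataset directory written by :func:`write_dataset_dir`."""
    d = Path(in_dir)
    ds = read_mtx_dataset(
        d / "matrix.mtx", d / "barcodes.tsv", d / "features.tsv", "cells-by-genes"
    )
    if (d / "annotations.csv").exists():
        read_annotations(ds, d / "annotations.csv")
    for f in sorted(d.glob("embedding_*.csv")):
        read_embedding_csv(ds, f, f.stem[len("embedding_") :])
    return ds


def write_annotations(ds: CellDataset, path, columns: list[str] | None = None) -> None:
    """Write annotation columns to CSV keyed by cell_id (header-only if none)."""
    df = ds.annotations if columns is None else ds.annotations[list(columns)]
    out = df.copy()
    out.insert(0, "cell_id", ds.cell_ids)
    out.to_csv(path, index=False, float_format="%.17g")


def read_annotations(ds: CellDataset, path) -> CellDataset:
    """Read annotation columns from CSV, joining on cell_id.

    Every cell_id in the file must exist in the dataset; rows are re-ordered
    to the dataset's canonical cell order.  Existing columns with the same
    names are overwritten.
    """
    df = pd.read_csv(path, dtype={"cell_id": str}, float_precision="round_trip")
    if "cell_id" not in df.columns:
        raise FormatError(f"{path}: missing required 'cell_id' column")
    unknown = set(df["cell_id"]) - set(ds.cell_ids)
    if unknown:
        raise FeatureLookupError(
            f"{path}: cell_ids not present in dataset: {sorted(unknown)[:5]}"
        )
    df = df.set_index("cell_id").reindex(ds.cell_ids)
    for col in df.columns:
        ds.annotations[col] = df[col].to_numpy()
    return ds


def read_embedding_csv(ds: CellDataset, path, name: str) -> CellDataset:
    """Embedding CSV with columns cell_id, dim1, dim2; joined on cell_id."""
    df = pd.read_csv(path, dtype={"cell_id": str}, float_precision="round_trip")
    for col in ("cell_id", "dim1", "dim2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    unknown = set(df["cell_id"]) - set(ds.cell_ids)
    if unknown:
        raise FeatureLookupError(
            f"{path}: cell_ids not present in dataset: {sorted(unknown)[:5]}"
        )
    df = df.set_index("cell_id").reindex(ds.cell_ids)
    if df[["dim1", "dim2"]].isna().any().any():
        raise ValidationError(f"{path}: embedding missing for some cells")
    return ds.attach_embedding(name, df[["dim1", "dim2"]].to_numpy(dtype=float))


def write_embedding_csv(ds: CellDataset, path, name: str) -> None:
    coords = ds.get_embedding(name)
    pd.DataFrame(
        {"cell_id": ds.cell_ids, "dim1": coords[:, 0], "dim2": coords[:, 1]}
    ).to_csv(path, index=False, float_format="%.17g")
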