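"""Per-region read-outs over any categorical cell annotation.

Three read-outs — percentage of cells, percentage of cells expressing a gene,
and transcripts per million (TPM) of a gene — plus the fold-enrichment
statistic, computable on polygon-gate regions, cluster assignments or any
other categorical annotation.

Under the assumption that one UMI represents one detected mRNA transcript,

    TPM(region, gene) = UMIs of gene in region / total UMIs in region * 1e6
    Enrichment(region, gene) = TPM(region, gene) / TPM(all other cells, gene)

Both always use raw UMI counts, never a normalized layer.  Composite
comma-joined labels ("CCR7,SELL") are atomic strings for these statistics;
use :func:`label_contains` to pool polygon members across composite labels.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import CellDataset
from .errors import FeatureLookupError, ValidationError


def _labels(ds: CellDataset, key: str) -> pd.Series:
    if key not in ds.annotations.columns:
        raise FeatureLookupError(f"unknown annotation key {key!r}")
    if ds.n_cells == 0:
        raise ValidationError("dataset has no cells")
    return ds.annotations[key].astype(str)


def label_mask(ds: CellDataset, key: str, label: str) -> np.ndarray:
    """Boolean mask of cells whose label equals ``label`` exactly."""
    return (_labels(ds, key) == label).to_numpy()


def label_contains(ds: CellDataset, key: str, polygon_name: str) -> np.ndarray:
    """Mask of cells whose (possibly composite) label includes a polygon name.

    "CCR7,SELL" cells pool with "CCR7" cells under ``polygon_name="CCR7"``.
    """
    return (
        _labels(ds, key)
        .map(lambda s: polygon_name in s.split(","))
        .to_numpy(dtype=bool)
    )


def pct_cells(ds: CellDataset, key: str) -> dict[str, float]:
    """Percentage of all cells carrying each distinct label (sums to 100)."""
    counts = _labels(ds, key).value_counts(sort=False)
    return {lab: 100.0 * n / ds.n_cells for lab, n in counts.items()}


def pct_expressing(
    ds: CellDataset, key: str, gene: str, threshold: int = 1
) -> dict[str, float]:
    """Per label: percentage of its cells with raw count >= ``threshold``."""
    j = ds.gene_index(gene)
    expr = np.asarray(ds.counts[:, j].todense()).ravel() >= threshold
    labels = _labels(ds, key)
    out: dict[str, float] = {}
    for lab, idx in labels.groupby(labels, sort=False).groups.items():
        sel = expr[np.asarray(idx)]
        out[lab] = 100.0 * sel.sum() / len(sel)
    return out


def tpm(ds: CellDataset, cells: np.ndarray | Sequence[int], gene: str) -> float:
    """Transcripts per million of a gene within a set of cells (raw counts).

    ``cells`` is a boolean mask or integer index array.  Returns NaN with a
    warning if the region's total UMI count is zero.
    """
    cells = np.asarray(cells)
    if cells.dtype == bool:
        cells = np.flatnonzero(cells)
    if len(cells) == 0:
        raise ValidationError("region is empty")
    j = ds.gene_index(gene)
    sub = ds.counts[cells]
    total = sub.sum()
    if total == 0:
        warnings.warn("region has zero total UMIs; TPM undefined", stacklevel=2)
        return float("nan")
    gene_sum = sub[:, j].sum()
    return float(gene_sum) / float(total) * 1e6


def tpm_all_genes(ds: CellDataset, cells: np.ndarray) -> np.ndarray:
    """TPM vector over all genes for one region (sums to 1e6 when total > 0)."""
    cells = np.asarray(cells)
    if cells.dtype == bool:
        cells = np.flatnonzero(cells)
    if len(cells) == 0:
        raise ValidationError("region is empty")
    sums = np.asarray(ds.counts[cells].sum(axis=0)).ravel().astype(float)
    total = sums.sum()
    if total == 0:
        warnings.warn("region has zero total UMIs; TPM undefined", stacklevel=2)
        return np.full(ds.n_genes, np.nan)
    return sums / total * 1e6


def _enrichment_from_masks(
    ds: CellDataset, inside: np.ndarray, gene: str
) -> float:
    outside = ~inside
    if not inside.any() or not outside.any():
        raise ValidationError(
            "enrichment requires both the region and its complement to be non-empty"
        )
    t_in = tpm(ds, inside, gene)
    t_out = tpm(ds, outside, gene)
    if np.isnan(t_in) or np.isnan(t_out):
        return float("nan")
    if t_out == 0.0:
        if t_in == 0.0:
            return float("nan")
        warnings.warn(
            f"gene {gene!r} absent outside the region; enrichment is infinite",
            stacklevel=3,
        )
        return float("inf")
    return t_in / t_out


def enrichment(ds: CellDataset, key: str, label: str, gene: str) -> float:
    """Fold enrichment: TPM inside the labelled region over TPM of all other cells.

    The complement is every cell NOT carrying the label; composite comma
    labels match string-exactly.
    """
    return _enrichment_from_masks(ds, label_mask(ds, key, label), gene)


def combined_enrichment(
    ds: CellDataset, key: str, labels: Iterable[str], gene: str
) -> float:
    """Enrichment of the pooled cell set of several labels vs. all remaining cells."""
    labels = list(labels)
    lab = _labels(ds, key)
    inside = lab.isin(labels).to_numpy()
    return _enrichment_from_masks(ds, inside, gene)


def region_stats(
    ds: CellDataset,
    key: str,
    genes: Sequence[str] = (),
    threshold: int = 1,
) -> pd.DataFrame:
    """Full per-region table: n_cells, pct_cells, and per-gene read-outs.

    Rows are keyed by region label (in order of first appearance); per-gene
    columns are ``pct_expressing_<g>``, ``tpm_<g>`` and ``enrichment_<g>``.
    Percentages are not rounded; format at print time.
    """
    labels = _labels(ds, key)
    order = list(dict.fromkeys(labels))
    pct = pct_cells(ds, key)
    rows: dict[str, dict] = {
        lab: {"n_cells": int((labels == lab).sum()), "pct_cells": pct[lab]}
        for lab in order
    }
    for g in genes:
        pe = pct_expressing(ds, key, g, threshold=threshold)
        for lab in order:
            mask = (labels == lab).to_numpy()
            rows[lab][f"pct_expressing_{g}"] = pe[lab]
            rows[lab][f"tpm_{g}"] = tpm(ds, mask, g)
            rows[lab][f"enrichment_{g}"] = (
                _enrichment_from_masks(ds, mask, g) if mask.any() and not mask.all()
                else float("nan")
            )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region"
    return df
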