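"""Gaussian mixture grouping of cells on two marker-gene axes.

Cells are divided into K groups by a full-covariance Gaussian mixture fitted
with expectation-maximization, initialized from a k-means partition (k-means++
seeding, Lloyd iterations).  The feature space is the normalized expression of
two marker genes by default, matching how such groupings are run on
single-cell data; raw counts are available via the ``layer`` flag.

Both the EM loop and the k-means initializer are implemented here; component
labels are ordered by descending mixture weight so fits are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core_data import CellDataset
from .errors import ValidationError

_LOG2PI = np.log(2.0 * np.pi)


# ------------------------------------------------------------------ k-means
def kmeans_init(
    points: np.ndarray, K: int, seed: int, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray]:
    """k-means++ seeding followed by Lloyd iterations to an assignment fixpoint.

    Returns (centers ``K x d``, assignments ``n``).  Deterministic given
    ``seed``.  Clusters that empty out are re-seeded at the point farthest
    from its center, so degenerate inputs (e.g. all points identical) still
    converge with duplicate centers rather than crashing.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < K:
        raise ValidationError(f"need at least K={K} points, got {n}")
    rng = np.random.default_rng(seed)

    # k-means++ seeding
    centers = np.empty((K, points.shape[1]))
    centers[0] = points[rng.integers(n)]
    d2 = np.sum((points - centers[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total == 0:
            centers[k] = points[rng.integers(n)]
        else:
            centers[k] = points[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((points - centers[k]) ** 2, axis=1))

    assign = np.full(n, -1)
    for _ in range(max_iter):
        dists = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = dists.argmin(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for k in range(K):
            mask = assign == k
            if mask.any():
                centers[k] = points[mask].mean(axis=0)
            else:
                centers[k] = points[dists.min(axis=1).argmax()]
    return centers, assign


# ---------------------------------------------------------------------- GMM
@dataclass
class MixtureModel:
    """Fitted K-component full-covariance Gaussian mixture in 2-D."""

    K: int
    weights: np.ndarray  # (K,), sums to 1
    means: np.ndarray  # (K, 2)
    covariances: np.ndarray  # (K, 2, 2), symmetric positive-definite
    responsibilities: np.ndarray  # (n, K), rows sum to 1
    loglik_trace: list[float] = field(default_factory=list)
    features: tuple[str, str] | None = None

    @property
    def assignments(self) -> np.ndarray:
        """Hard component index per cell: argmax responsibility."""
        return self.responsibilities.argmax(axis=1)


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (d * _LOG2PI + logdet + maha)


def _m_step(
    X: np.ndarray, resp: np.ndarray, reg: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = X.shape
    nk = resp.sum(axis=0) + 10.0 * np.finfo(float).eps
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    covs = np.empty((resp.shape[1], d, d))
    for k in range(resp.shape[1]):
        diff = X - means[k]
        covs[k] = (resp[:, k, None] * diff).T @ diff / nk[k]
        covs[k].flat[:: d + 1] += reg
    return weights, means, covs


def fit_gmm(
    ds: CellDataset,
    gene_x: str,
    gene_y: str,
    K: int,
    seed: int,
    layer: str = "normalized",
    tol: float = 1e-6,
    max_iter: int = 200,
    reg: float = 1e-6,
) -> MixtureModel:
    """Fit a K-component Gaussian mixture to two marker genes' expression.

    EM starts from one-hot responsibilities of a :func:`kmeans_init`
    partition and stops when the relative change in mean log-likelihood
    drops below ``tol`` or after ``max_iter`` iterations.  ``reg`` is added
    to covariance diagonals so components collapsing on few points stay
    positive-definite.
    """
    X = np.column_stack(
        [ds.feature_values(gene_x, layer=layer), ds.feature_values(gene_y, layer=layer)]
    )
    model = fit_gmm_points(X, K, seed, tol=tol, max_iter=max_iter, reg=reg)
    model.features = (gene_x, gene_y)
    return model


def fit_gmm_points(
    X: np.ndarray,
    K: int,
    seed: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    reg: float = 1e-6,
) -> MixtureModel:
    """EM fit on a bare ``n x d`` point array (the computational core)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n < K:
        raise ValidationError(f"need at least K={K} points, got {n}")
    _, assign = kmeans_init(X, K, seed)
    resp = np.zeros((n, K))
    resp[np.arange(n), assign] = 1.0

    trace: list[float] = []
    weights = means = covs = None
    prev = -np.inf
    for _ in range(max_iter):
        weights, means, covs = _m_step(X, resp, reg)
        log_prob = np.empty((n, K))
        for k in range(K):
            try:
                log_prob[:, k] = np.log(weights[k]) + _log_gauss(X, means[k], covs[k])
            except np.linalg.LinAlgError as exc:
                raise ValidationError(
                    f"component {k}: singular covariance despite regularization"
                ) from exc
        norm = logsumexp(log_prob, axis=1)
        loglik = float(norm.mean())
        trace.append(loglik)
        resp = np.exp(log_prob - norm[:, None])
        if np.isfinite(prev) and abs(loglik - prev) < tol * max(abs(prev), 1.0):
            break
        prev = loglik
    weights, means, covs = _m_step(X, resp, reg)

    # order components by descending weight for reproducibility
    order = np.argsort(-weights, kind="stable")
    return MixtureModel(
        K=K,
        weights=weights[order],
        means=means[order],
        covariances=covs[order],
        responsibilities=resp[:, order],
        loglik_trace=trace,
    )


def assign_groups(model: MixtureModel, ds: CellDataset, key: str) -> CellDataset:
    """Write the hard component assignment as a string annotation column.

    The result is a categorical annotation usable by the region statistics
    exactly like a polygon selection.
    """
    if model.responsibilities.shape[0] != ds.n_cells:
        raise ValidationError(
            f"model fitted on {model.responsibilities.shape[0]} cells, "
            f"dataset has {ds.n_cells}"
        )
    ds.annotations[key] = [str(int(a)) for a in model.assignments]
    return ds
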