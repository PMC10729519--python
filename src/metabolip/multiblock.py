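"""Per-block PCA, Hotelling T² confidence ellipses, and SUM-PCA fusion.

SUM-PCA is low-level multiblock data fusion: each autoscaled block is
weighted so that all blocks contribute equal total variance (default weight
1/sqrt(p_b) for a block with p_b autoscaled variables), the weighted blocks
are concatenated column-wise, and an ordinary PCA of the fused matrix gives
the "super scores" T_sup summarising all blocks jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

BlockWeighting = Literal["none", "sqrt_p", "sqrt_eig1"]


@dataclass
class PCAModel:
    loadings: np.ndarray          # variables x components, orthonormal columns
    scores: np.ndarray            # samples x components (U * S)
    eigenvalues: np.ndarray       # variance per component, descending
    n_components: int
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def project(self, X_new: np.ndarray) -> np.ndarray:
        """Scores of new samples (applies stored center/scale if present)."""
        Z = np.asarray(X_new, dtype=float)
        if self.center is not None:
            Z = Z - self.center
        if self.scale is not None:
            Z = Z / self.scale
        return Z @ self.loadings


@dataclass
class SumPCAModel:
    block_ids: list
    block_weights: dict
    block_slices: dict
    super_scores: np.ndarray      # T_sup: samples x components
    super_loadings: np.ndarray
    eigenvalues: np.ndarray
    n_components: int


@dataclass
class HotellingEllipse:
    """95% (by default) Hotelling T² confidence ellipse of a 2-D score cloud."""

    center: np.ndarray
    semi_axes: np.ndarray         # descending
    angle: float                  # orientation of the major axis, radians
    t2_crit: float
    cov: np.ndarray = field(repr=False, default=None)

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(points) - self.center
        return np.einsum("ij,jk,ik->i", d, np.linalg.inv(self.cov), d)

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.mahalanobis_sq(points) <= self.t2_crit


def _sign_fix(loadings: np.ndarray, scores: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    # deterministic sign: largest-|.| element of each loading column positive
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs, scores * signs


def fit_pca(X: np.ndarray, n_components: int | None = None,
            center: np.ndarray | None = None,
            scale: np.ndarray | None = None) -> PCAModel:
    """PCA by SVD of an already autoscaled matrix.

    Scores are U*S, eigenvalues S²/(n-1) in descending order.  A
    deterministic sign convention makes each loading column's
    largest-magnitude element positive.  ``n_components`` beyond the matrix
    rank is truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max(initial=0.0) * max(n, p) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if n_components is None:
        n_components = rank
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; "
                      "truncated", stacklevel=2)
        n_components = rank
    if n_components > min(n - 1, p):
        n_components = min(n - 1, p)
    k = n_components
    loadings, scores = _sign_fix(Vt[:k].T, U[:, :k] * S[:k])
    return PCAModel(loadings=loadings, scores=scores,
                    eigenvalues=S[:k] ** 2 / (n - 1), n_components=k,
                    center=center, scale=scale)


def block_weight(X: np.ndarray, weighting: BlockWeighting) -> float:
    if weighting == "none":
        return 1.0
    if weighting == "sqrt_p":
        return 1.0 / np.sqrt(X.shape[1])
    if weighting == "sqrt_eig1":
        s1 = np.linalg.svd(X, compute_uv=False)[0]
        return 1.0 / np.sqrt(s1 ** 2 / (X.shape[0] - 1))
    raise ValueError(f"unknown block weighting {weighting!r}")


def sum_pca(blocks: Sequence[np.ndarray], n_components: int | None = None,
            block_ids: Sequence[str] | None = None,
            weighting: BlockWeighting = "sqrt_p") -> SumPCAModel:
    """Fuse autoscaled blocks sharing sample order and PCA the result.

    With the default 1/sqrt(p_b) weighting every autoscaled block enters
    with total sum of squares p_b*(n-1)/p_b = (n-1) — i.e. equal across
    blocks — so no block dominates merely by having more variables.
    """
    blocks = [np.asarray(b, dtype=float) for b in blocks]
    if not blocks:
        raise ValueError("no blocks given")
    n = blocks[0].shape[0]
    for i, b in enumerate(blocks):
        if b.shape[0] != n:
            raise ValueError(
                f"block {i} has {b.shape[0]} samples, expected {n}; "
                "blocks must share identical sample order")
    if block_ids is None:
        block_ids = [f"block{i}" for i in range(len(blocks))]
    weights = {bid: block_weight(b, weighting)
               for bid, b in zip(block_ids, blocks)}
    fused = np.hstack([b * weights[bid] for bid, b in zip(block_ids, blocks)])
    slices, start = {}, 0
    for bid, b in zip(block_ids, blocks):
        slices[bid] = slice(start, start + b.shape[1])
        start += b.shape[1]
    pca = fit_pca(fused, n_components)
    return SumPCAModel(block_ids=list(block_ids), block_weights=weights,
                       block_slices=slices, super_scores=pca.scores,
                       super_loadings=pca.loadings,
                       eigenvalues=pca.eigenvalues,
                       n_components=pca.n_components)


def hotelling_t2_crit(n: int, alpha: float = 0.05) -> float:
    """Critical T² for a 2-D score cloud: 2(n-1)/(n-2) * F(1-alpha; 2, n-2)."""
    if n < 4:
        raise ValueError("need at least 4 samples")
    return 2 * (n - 1) / (n - 2) * stats.f.ppf(1 - alpha, 2, n - 2)


def hotelling_ellipse(scores: np.ndarray, alpha: float = 0.05
                      ) -> HotellingEllipse:
    """Hotelling T² confidence ellipse for a samples x 2 score matrix."""
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("scores must be samples x 2")
    n = S.shape[0]
    t2 = hotelling_t2_crit(n, alpha)
    center = S.mean(axis=0)
    cov = np.cov(S, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov) < 2:
        raise np.linalg.LinAlgError("singular score covariance")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi_axes = np.sqrt(evals * t2)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return HotellingEllipse(center=center, semi_axes=semi_axes, angle=angle,
                            t2_crit=t2, cov=cov)
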