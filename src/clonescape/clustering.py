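"""DAPC-style genetic structure: k-means on PCA scores with a BIC scan,
then discriminant axes and membership probabilities.

This is the model-free alternative to Bayesian admixture inference for
dominant markers: no Hardy-Weinberg assumption, applicable to polyploids.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans

from .genotypes import BinaryMatrix

__all__ = ["ClusterScan", "DAPCResult", "pca_scores", "n_pcs_for_variance", "kmeans_bic_scan", "dapc_fit"]


def _as_complete_array(bm: BinaryMatrix | np.ndarray) -> np.ndarray:
    """Binary values with missing entries replaced by the column mean.

    Mean imputation is the standard dominant-marker practice before PCA: it
    leaves the column centroid unchanged and adds no between-group signal.
    """
    X = bm.values if isinstance(bm, BinaryMatrix) else np.asarray(bm, dtype=float)
    X = X.astype(float).copy()
    if np.isnan(X).any():
        mean = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X[idx] = mean[idx[1]]
    return X


def pca_scores(bm: BinaryMatrix | np.ndarray, n_pcs: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores of the (mean-imputed) binary matrix.

    Returns (scores, variance_fraction); ``n_pcs=None`` keeps every
    component.
    """
    X = _as_complete_array(bm)
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else var
    scores = U * S
    if n_pcs is not None:
        if n_pcs > scores.shape[1]:
            raise ValueError(f"n_pcs={n_pcs} exceeds available components {scores.shape[1]}")
        scores = scores[:, :n_pcs]
    return scores, frac


def n_pcs_for_variance(bm: BinaryMatrix | np.ndarray, threshold: float = 0.9) -> int:
    """Smallest number of components whose cumulative variance fraction
    reaches ``threshold`` — a helper for choosing the retained PCs."""
    _, frac = pca_scores(bm)
    cum = np.cumsum(frac)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


@dataclass
class ClusterScan:
    """BIC scan over candidate numbers of k-means clusters."""

    k_values: list[int]
    bic: np.ndarray
    chosen_k: int
    assignments: np.ndarray          # labels in 1..chosen_k for the chosen k
    labels_per_k: dict[int, np.ndarray]
    n_pcs: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "BIC": self.bic})


def kmeans_bic_scan(
    bm: BinaryMatrix | np.ndarray,
    k_max: int = 20,
    n_pcs: int | None = None,
    seed: int | None = None,
    n_starts: int = 10,
    forced_k: int | None = None,
) -> ClusterScan:
    """Scan k = 1..k_max with k-means on PCA-reduced genotypes.

    BIC(k) = n * ln(WSS_k / n) + k * ln(n), with WSS the total within-cluster
    sum of squares over the retained scores; the chosen k minimizes BIC (ties
    go to the smaller k).  A ``forced_k`` overrides the argmin for the
    reported assignment while the full scan is still returned — useful when
    BIC declines monotonically and an external criterion fixes k.
    """
    scores, frac = pca_scores(bm)
    n = scores.shape[0]
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be smaller than the number of rows ({n})")
    if n_pcs is not None:
        if n_pcs > scores.shape[1]:
            raise ValueError(f"n_pcs={n_pcs} exceeds available components")
        scores = scores[:, :n_pcs]
    used_pcs = scores.shape[1]
    rng = np.random.default_rng(seed)
    bic = np.empty(k_max)
    labels_per_k: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            wss = float(((scores - scores.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                n_init=n_starts,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(scores)
            wss = float(km.inertia_)
            labels = km.labels_
        wss = max(wss, 1e-300)  # guard log of an exact-fit scan
        bic[k - 1] = n * np.log(wss / n) + k * np.log(n)
        labels_per_k[k] = labels + 1
    chosen = forced_k if forced_k is not None else int(np.argmin(bic)) + 1
    if not 1 <= chosen <= k_max:
        raise ValueError(f"forced_k={forced_k} outside scanned range 1..{k_max}")
    return ClusterScan(
        k_values=list(range(1, k_max + 1)),
        bic=bic,
        chosen_k=chosen,
        assignments=labels_per_k[chosen],
        labels_per_k=labels_per_k,
        n_pcs=used_pcs,
    )


@dataclass
class DAPCResult:
    """Discriminant analysis of principal components."""

    n_pcs: int
    n_da: int
    discriminant_axes: np.ndarray    # (n_pcs x n_da), in PC space
    da_scores: np.ndarray            # (n x n_da)
    membership: np.ndarray           # (n x K), rows sum to 1
    groups: list

    def membership_frame(self, ids: list[str] | None = None) -> pd.DataFrame:
        idx = ids if ids is not None else list(range(self.membership.shape[0]))
        return pd.DataFrame(self.membership, index=idx, columns=[str(g) for g in self.groups])


def dapc_fit(
    bm: BinaryMatrix | np.ndarray,
    groups: np.ndarray | list,
    n_pcs: int,
    n_da: int | None = None,
) -> DAPCResult:
    """Fit discriminant axes on retained PCA scores and derive membership
    probabilities.

    Axes solve the generalized eigenproblem Sb v = lambda Sw v (between vs
    pooled within-group covariance of the retained scores).  Membership is a
    softmax over negative half squared Mahalanobis distances to the group
    centroids in discriminant space, using the pooled within-group
    covariance there.
    """
    groups = np.asarray(groups)
    uniq = list(dict.fromkeys(groups.tolist()))
    K = len(uniq)
    if K < 2:
        raise ValueError("DAPC needs at least 2 groups")
    if n_da is None:
        n_da = min(n_pcs, K - 1)
    if n_da > min(n_pcs, K - 1):
        raise ValueError(f"n_da={n_da} exceeds min(n_pcs, K-1) = {min(n_pcs, K - 1)}")
    scores, _ = pca_scores(bm, n_pcs=n_pcs)
    n = scores.shape[0]
    grand = scores.mean(axis=0)
    Sw = np.zeros((n_pcs, n_pcs))
    Sb = np.zeros((n_pcs, n_pcs))
    centroids = {}
    for g in uniq:
        Xg = scores[groups == g]
        mu = Xg.mean(axis=0)
        centroids[g] = mu
        dev = Xg - mu
        Sw += dev.T @ dev
        db = (mu - grand)[:, None]
        Sb += len(Xg) * (db @ db.T)
    if n - K <= 0 or np.linalg.cond(Sw / max(n - K, 1)) > 1e10:
        raise ValueError("singular within-group covariance; retain fewer principal components")
    Sw /= n - K
    Sb /= max(K - 1, 1)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][:n_da]
    W = evecs[:, order]
    da = scores @ W
    cent_da = np.array([centroids[g] @ W for g in uniq])
    Cw = np.zeros((n_da, n_da))
    for gi, g in enumerate(uniq):
        dev = da[groups == g] - cent_da[gi]
        Cw += dev.T @ dev
    Cw /= n - K
    Cw += np.eye(n_da) * 1e-10 * max(np.trace(Cw) / n_da, 1.0)
    Cinv = np.linalg.inv(Cw)
    d2 = np.empty((n, K))
    for gi in range(K):
        dev = da - cent_da[gi]
        d2[:, gi] = np.einsum("ij,jk,ik->i", dev, Cinv, dev)
    logw = -0.5 * d2
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    membership = w / w.sum(axis=1, keepdims=True)
    return DAPCResult(
        n_pcs=n_pcs,
        n_da=n_da,
        discriminant_axes=W,
        da_scores=da,
        membership=membership,
        groups=uniq,
    )
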