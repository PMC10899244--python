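"""Mahalanobis-distance cluster-quality statistics: L-ratio and isolation distance.

For a cluster C of N_c spikes in a d-dimensional feature space, the
squared Mahalanobis distance of spike i from C is

    MD2_i = (x_i - mu_C)' Sigma_C^{-1} (x_i - mu_C)

with mu_C, Sigma_C the mean and unbiased covariance of C's own members.
"Noise spikes" for C are all other spikes detected on the same channel
(members of other clusters plus unassigned spikes).

L-ratio:  L(C) = sum over i not in C of [1 - CDF_chi2,df(MD2_i)],
          L_ratio = L(C) / N_c.
An L-ratio below 0.05 indicates good separation and isolation.

Isolation distance: the MD2 value of the N_c-th closest noise spike;
undefined (reported as a flag, not an error) when fewer than N_c noise
spikes exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ClusterQuality",
    "mahalanobis_sq",
    "l_ratio",
    "isolation_distance",
    "quality_report",
]


@dataclass(frozen=True)
class ClusterQuality:
    """Per-cluster quality numbers; ``isolation_distance`` is None when undefined."""

    cluster_id: int
    n_c: int
    L: float
    l_ratio: float
    isolation_distance: float | None
    df: int


def _cluster_moments(
    features: np.ndarray, labels: np.ndarray, cluster_id: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    member = labels == cluster_id
    n_c, d = int(member.sum()), features.shape[1]
    if n_c <= d:
        raise ValueError(
            f"cluster {cluster_id}: {n_c} spikes <= {d} dimensions; "
            "covariance not estimable"
        )
    mu = features[member].mean(axis=0)
    cov = np.cov(features[member], rowvar=False, ddof=1)
    # ridge only for near-degenerate fixtures; off the path for real data
    if np.linalg.cond(cov) > 1e12:
        cov = cov + np.eye(d) * (1e-9 * np.trace(cov) / d)
    if not np.isfinite(np.linalg.cond(cov)) or np.linalg.cond(cov) > 1e15:
        raise np.linalg.LinAlgError(
            f"cluster {cluster_id}: covariance singular after regularization"
        )
    return member, mu, cov


def mahalanobis_sq(
    features: np.ndarray, labels: np.ndarray, cluster_id: int
) -> np.ndarray:
    """Squared Mahalanobis distance of *every* spike from cluster ``cluster_id``.

    Returns one value per row of ``features`` (members and non-members).
    Requires N_c > d so the cluster covariance is estimable.
    """
    member, mu, cov = _cluster_moments(features, labels, cluster_id)
    diff = np.asarray(features, dtype=np.float64) - mu
    sol = np.linalg.solve(cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


def l_ratio(
    features: np.ndarray,
    labels: np.ndarray,
    cluster_id: int,
    df: int | None = None,
) -> tuple[float, float]:
    """L(C) and L-ratio of one cluster.

    ``df`` defaults to the feature dimension.  Returns ``(L, L_ratio)``
    with ``L_ratio = L / N_c``.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if df is None:
        df = features.shape[1]
    md2 = mahalanobis_sq(features, labels, cluster_id)
    outside = labels != cluster_id
    L = float(np.sum(stats.chi2.sf(md2[outside], df)))
    n_c = int((~outside).sum())
    return L, L / n_c


def isolation_distance(
    features: np.ndarray, labels: np.ndarray, cluster_id: int
) -> float | None:
    """MD2 of the N_c-th closest noise spike, or None if it does not exist."""
    labels = np.asarray(labels)
    md2 = mahalanobis_sq(features, labels, cluster_id)
    outside = np.sort(md2[labels != cluster_id])
    n_c = int((labels == cluster_id).sum())
    if len(outside) < n_c:
        return None
    return float(outside[n_c - 1])


def quality_report(
    features: np.ndarray, labels: np.ndarray, df: int | None = None
) -> list[ClusterQuality]:
    """L-ratio and isolation distance for every cluster present in ``labels``."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if df is None:
        df = features.shape[1]
    out = []
    for cid in np.unique(labels):
        L, lr = l_ratio(features, labels, cid, df)
        iso = isolation_distance(features, labels, cid)
        out.append(
            ClusterQuality(
                cluster_id=int(cid),
                n_c=int((labels == cid).sum()),
                L=L,
                l_ratio=lr,
                isolation_distance=iso,
                df=df,
            )
        )
    return out
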