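"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (and scipy's chi-square
CDF) so that agreement is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def chi2_cdf(x: float, df: int) -> float:
    """Chi-square CDF via the regularized lower incomplete gamma function.

    Series expansion for x < df + 1, Lentz continued fraction otherwise;
    independent of scipy.
    """
    if x <= 0:
        return 0.0
    a = df / 2.0
    xx = x / 2.0
    lg = math.lgamma(a)
    if xx < a + 1.0:
        # series: P(a,x) = x^a e^-x sum x^n / (a (a+1) ... (a+n))
        term = 1.0 / a
        total = term
        n = a
        for _ in range(500):
            n += 1.0
            term *= xx / n
            total += term
            if abs(term) < abs(total) * 1e-15:
                break
        return total * math.exp(-xx + a * math.log(xx) - lg)
    # continued fraction for Q(a,x) (modified Lentz)
    tiny = 1e-300
    b = xx + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, 500):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        d = tiny if abs(d) < tiny else d
        c = b + an / c
        c = tiny if abs(c) < tiny else c
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-15:
            break
    q = math.exp(-xx + a * math.log(xx) - lg) * h
    return 1.0 - q


def mahalanobis_sq_loop(features: np.ndarray, member_mask: np.ndarray) -> np.ndarray:
    """Per-point squared Mahalanobis distance via an explicit loop."""
    mem = features[member_mask]
    mu = mem.mean(axis=0)
    n = len(mem)
    cov = np.zeros((features.shape[1], features.shape[1]))
    for x in mem:
        d = (x - mu)[:, None]
        cov += d @ d.T
    cov /= n - 1
    out = np.empty(len(features))
    for i, x in enumerate(features):
        d = x - mu
        out[i] = d @ np.linalg.solve(cov, d)
    return out


def l_ratio_bruteforce(
    features: np.ndarray, labels: np.ndarray, cluster_id: int, df: int
) -> tuple[float, float]:
    member = labels == cluster_id
    md2 = mahalanobis_sq_loop(features, member)
    L = sum(1.0 - chi2_cdf(v, df) for v in md2[~member])
    return L, L / member.sum()


def isolation_distance_bruteforce(
    features: np.ndarray, labels: np.ndarray, cluster_id: int
) -> float | None:
    member = labels == cluster_id
    md2 = sorted(mahalanobis_sq_loop(features, member)[~member])
    n_c = int(member.sum())
    return md2[n_c - 1] if len(md2) >= n_c else None


def von_mises_rejection(
    mu_deg: float, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """von Mises angles (degrees) by plain rejection from a uniform proposal."""
    mu = math.radians(mu_deg)
    out = []
    while len(out) < n:
        theta = rng.uniform(-math.pi, math.pi, 4 * n)
        u = rng.uniform(0.0, 1.0, 4 * n)
        acc = theta[u < np.exp(kappa * (np.cos(theta - mu) - 1.0))]
        out.extend(acc.tolist())
    return np.degrees(np.array(out[:n])) % 360.0
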