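"""Rough fuzzy c-means subtyping of vectorized MC features.

Fuzzy c-means memberships are augmented with rough-set regions: the lower
approximation (core) of a cluster holds subjects whose membership exceeds
``mu_core`` (definite members); the boundary holds memberships in
[``mu_boundary``, ``mu_core``) (possible members).  Centroids are a
weighted combination of the core and boundary fuzzy means, weighting the
definite region by ``w_low``.  Cluster count is chosen by the elbow of the
weighted within-cluster dispersion curve; cluster quality is reported with
silhouette, Davies-Bouldin and Dunn indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .connectivity import MCMatrix, significance_mask

__all__ = [
    "RFCMConfig",
    "ClusterResult",
    "rfcm_fit",
    "elbow_select",
    "validity_indices",
    "cluster_profiles",
]


@dataclass
class RFCMConfig:
    n_clusters: int = 3
    fuzziness: float = 2.0
    tol: float = 0.005
    max_iter: int = 1000
    mu_core: float = 0.6
    mu_boundary: float = 0.3
    w_low: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fuzziness <= 1:
            raise ValueError("fuzziness m must exceed 1")
        if not 0 < self.mu_boundary < self.mu_core < 1:
            raise ValueError("need 0 < mu_boundary < mu_core < 1")
        if not 0 < self.w_low <= 1:
            raise ValueError("w_low must be in (0, 1]")


@dataclass
class ClusterResult:
    membership: np.ndarray          # subjects x clusters, rows sum to 1
    centroids: np.ndarray
    lower: list[np.ndarray]         # subject indices per cluster (core)
    upper: list[np.ndarray]         # core union boundary
    iterations: int
    converged: bool
    objective: float = float("nan")
    objective_path: list[float] | None = None

    @property
    def hard_labels(self) -> np.ndarray:
        return self.membership.argmax(axis=1)


def _kmeanspp(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(len(x))]]
    for _ in range(1, c):
        d2 = cdist(x, np.stack(centers)).min(axis=1) ** 2
        if d2.sum() == 0:
            centers.append(x[rng.integers(len(x))])
            continue
        centers.append(x[rng.choice(len(x), p=d2 / d2.sum())])
    return np.stack(centers)


def _memberships(x: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    d = np.maximum(cdist(x, centroids), 1e-12)
    inv = d ** (-2.0 / (m - 1.0))
    return inv / inv.sum(axis=1, keepdims=True)


def _regions(mu: np.ndarray, cfg: RFCMConfig):
    """Core/boundary index sets; every subject lands in >= 1 upper region."""
    n, c = mu.shape
    core = [np.where(mu[:, j] >= cfg.mu_core)[0] for j in range(c)]
    boundary_mask = (mu >= cfg.mu_boundary) & (mu < cfg.mu_core)
    orphan = ~((mu >= cfg.mu_boundary).any(axis=1))
    if orphan.any():  # low-confidence subjects join the boundary of their argmax
        boundary_mask[orphan, mu[orphan].argmax(axis=1)] = True
    boundary = [np.where(boundary_mask[:, j])[0] for j in range(c)]
    upper = [np.union1d(core[j], boundary[j]) for j in range(c)]
    return core, boundary, upper


def rfcm_fit(features: np.ndarray, config: RFCMConfig | None = None) -> ClusterResult:
    """Alternate membership updates, region assignment, and rough centroids."""
    cfg = config or RFCMConfig()
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(x)
    c, m = cfg.n_clusters, cfg.fuzziness
    if c < 1 or n <= c:
        raise ValueError("need n subjects > n_clusters >= 1")
    rng = np.random.default_rng(cfg.seed)
    if c == 1:
        mu = np.ones((n, 1))
        centroid = x.mean(axis=0, keepdims=True)
        return ClusterResult(
            membership=mu, centroids=centroid, lower=[np.arange(n)],
            upper=[np.arange(n)], iterations=0, converged=True,
            objective=float((np.linalg.norm(x - centroid, axis=1) ** 2).sum()),
        )
    centroids = _kmeanspp(x, c, rng)
    mu = _memberships(x, centroids, m)
    converged = False
    it = 0
    path = []
    for it in range(1, cfg.max_iter + 1):
        core, boundary, _ = _regions(mu, cfg)
        w = mu**m
        new_centroids = centroids.copy()
        for j in range(c):
            parts = []
            if len(core[j]):
                parts.append((cfg.w_low if len(boundary[j]) else 1.0,
                              np.average(x[core[j]], axis=0, weights=w[core[j], j])))
            if len(boundary[j]):
                parts.append((1.0 - cfg.w_low if len(core[j]) else 1.0,
                              np.average(x[boundary[j]], axis=0, weights=w[boundary[j], j])))
            if parts:
                new_centroids[j] = sum(wt * v for wt, v in parts) / sum(wt for wt, _ in parts)
            else:  # empty cluster: re-seed from the farthest point
                far = cdist(x, centroids).min(axis=1).argmax()
                new_centroids[j] = x[far]
                warnings.warn(f"cluster {j} empty; re-seeded from farthest point")
        centroids = new_centroids
        new_mu = _memberships(x, centroids, m)
        delta = float(np.abs(new_mu - mu).max())
        mu = new_mu
        path.append(float(((mu**cfg.fuzziness) * cdist(x, centroids) ** 2).sum()))
        if delta < cfg.tol:
            converged = True
            break
    core, _, upper = _regions(mu, cfg)
    d = cdist(x, centroids)
    objective = float(((mu**m) * d**2).sum())
    return ClusterResult(
        membership=mu, centroids=centroids, lower=core, upper=upper,
        iterations=it, converged=converged, objective=objective,
        objective_path=path,
    )


def elbow_select(features: np.ndarray, c_range, config: RFCMConfig | None = None):
    """Pick the cluster count at the elbow (max second difference) of J(c)."""
    cfg = config or RFCMConfig()
    c_range = sorted(c_range)
    x = np.asarray(features, dtype=float)
    if c_range[0] < 1 or c_range[-1] >= len(x):
        raise ValueError("c_range must lie within [1, n-1]")
    from dataclasses import replace

    js = []
    for c in c_range:
        res = rfcm_fit(x, replace(cfg, n_clusters=c))
        js.append(res.objective)
    js = np.array(js)
    curve = dict(zip(c_range, js.tolist()))
    if len(c_range) < 3:
        return c_range[int(np.argmin(js))] if len(c_range) > 1 else c_range[0], curve
    # curvature of log J: scale-invariant, so the elbow reflects the relative
    # flattening of the curve rather than the largest absolute drop
    logj = np.log(np.maximum(js, 1e-300))
    curvature = logj[:-2] - 2 * logj[1:-1] + logj[2:]
    if curvature.max() <= 0:
        warnings.warn("dispersion curve has no elbow; returning smallest c")
        return c_range[0], curve
    return c_range[1 + int(np.argmax(curvature))], curve


def _dunn(x: np.ndarray, labels: np.ndarray) -> float:
    ids = sorted(set(labels.tolist()))
    inter = np.inf
    intra = 0.0
    for a_i, a in enumerate(ids):
        pts_a = x[labels == a]
        if len(pts_a) > 1:
            intra = max(intra, float(cdist(pts_a, pts_a).max()))
        for b in ids[a_i + 1 :]:
            inter = min(inter, float(cdist(pts_a, x[labels == b]).min()))
    if intra == 0:
        return float("inf")
    return inter / intra


def validity_indices(features: np.ndarray, hard_labels: np.ndarray):
    """(silhouette, Davies-Bouldin, Dunn) for a hard clustering."""
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(hard_labels)
    ids = sorted(set(labels.tolist()))
    if len(ids) < 2:
        raise ValueError("validity indices need >= 2 clusters")
    sil = float(silhouette_score(x, labels))
    identical = all(
        np.allclose(x[labels == a].mean(axis=0), x[labels == b].mean(axis=0))
        for a in ids for b in ids if a < b
    )
    if identical:
        warnings.warn("clusters share identical centroids; Davies-Bouldin diverges")
        dbi = float("inf")
    else:
        dbi = float(davies_bouldin_score(x, labels))
    return sil, dbi, _dunn(x, labels)


def cluster_profiles(
    mc_list: list[MCMatrix],
    result: ClusterResult,
    significance: bool = False,
    alpha: float = 0.01,
    q: float = 0.05,
):
    """Entrywise mean MC per cluster (argmax assignment); empty ones omitted."""
    labels = result.hard_labels
    profiles = {}
    flags = {}
    for j in range(result.membership.shape[1]):
        members = [mc_list[i] for i in np.where(labels == j)[0]]
        if not members:
            continue
        mean = np.mean([m.compact for m in members], axis=0)
        profiles[j] = MCMatrix(compact=mean, link_index=mc_list[0].link_index)
        if significance and len(members) >= 3:
            flags[j] = significance_mask(members, alpha, q)
    return (profiles, flags) if significance else profiles
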