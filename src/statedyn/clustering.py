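"""Estimation of K discrete states per session via seven clustering methods.

All methods return a :class:`StatePartition` with 1-based labels in
``{1..K}`` and a K x N centroid matrix.  Quality scores are the total global
explained variance (GEV, cosine-based, GFP-weighted) and the within-cluster
sum of squares (WCSS).

K-means, k-medoids, bisecting K-means, AAHC, TAAHC and the GMM EM loop are
implemented here so that the per-iteration objective trajectories required by
the contracts (RSS non-increasing, log-likelihood non-decreasing, exactly
T - K atomization steps) are observable.  Ward linkage is delegated to
``scipy.cluster.hierarchy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp

from ._errors import ConfigurationError, ConvergenceError, InfeasibleKError

METHODS = (
    "kmeans",
    "kmedoids",
    "ward",
    "aahc",
    "taahc",
    "bisecting_kmeans",
    "gmm",
)

#: absolute RSS-change convergence threshold for the K-means loop
KMEANS_TOL = 1e-5
MAX_ITER = 300
GMM_REG_COVAR = 1e-6
GMM_TOL = 1e-6  # on the mean per-sample log-likelihood change


@dataclass
class StatePartition:
    """Hard assignment of T volumes to K states plus the state centroids."""

    labels: np.ndarray  # values in {1..K}
    centroids: np.ndarray  # K x N
    method: str
    K: int
    seed: int | None = None
    #: per-iteration objective trace (RSS for kmeans, log-likelihood for gmm)
    objective_trace: list[float] = field(default_factory=list)
    #: number of atomization steps taken (aahc/taahc only)
    n_atomize_steps: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != self.K:
            raise ConfigurationError("centroid count must equal K")
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.K:
            raise ConfigurationError("labels must lie in {1..K}")
        if len(present) != self.K:
            raise ConfigurationError("every state in {1..K} must be non-empty")


@dataclass
class GmmParams:
    """Fitted mixture parameters (weights sum to 1, full covariances)."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """<u, v> / (||u|| ||v||); raises on a zero vector."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ConfigurationError("cosine similarity undefined for zero vector")
    return float(np.dot(u, v) / (nu * nv))


def _row_cosines(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cosine of each row of x with the corresponding row of c."""
    nx = np.linalg.norm(x, axis=1)
    nc = np.linalg.norm(c, axis=1)
    if np.any(nx == 0.0) or np.any(nc == 0.0):
        raise ConfigurationError("cosine similarity undefined for zero vector")
    return np.einsum("ij,ij->i", x, c) / (nx * nc)


def _cosine_matrix(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """T x K matrix of cosines between data rows and centroids."""
    nx = np.linalg.norm(x, axis=1)
    nc = np.linalg.norm(c, axis=1)
    if np.any(nx == 0.0) or np.any(nc == 0.0):
        raise ConfigurationError("cosine similarity undefined for zero vector")
    return (x @ c.T) / np.outer(nx, nc)


def _sq_dists(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """T x K matrix of squared Euclidean distances."""
    d = x[:, None, :] - c[None, :, :]
    return np.einsum("tkn,tkn->tk", d, d)


def _check_feasible(x: np.ndarray, k: int) -> None:
    if k < 2:
        raise ConfigurationError("K must be >= 2")
    n_distinct = np.unique(x, axis=0).shape[0]
    if k > n_distinct:
        raise InfeasibleKError(
            f"K={k} exceeds the {n_distinct} distinct data rows"
        )


def _kmeanspp_indices(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: return indices of k rows chosen as initial centers."""
    t = x.shape[0]
    chosen = [int(rng.integers(t))]
    d2 = np.sum((x - x[chosen[0]]) ** 2, axis=1)
    for _ in range(k - 1):
        d2_sel = d2.copy()
        d2_sel[chosen] = 0.0
        total = d2_sel.sum()
        if total <= 0.0:
            # all remaining points coincide with a center; pick any unchosen one
            candidates = np.setdiff1d(np.arange(t), chosen)
            nxt = int(candidates[rng.integers(candidates.size)])
        else:
            nxt = int(rng.choice(t, p=d2_sel / total))
        chosen.append(nxt)
        d2 = np.minimum(d2, np.sum((x - x[nxt]) ** 2, axis=1))
    return np.array(chosen)


def _kmeans_core(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """K-means with k-means++ init.  Returns (labels0, centroids, rss_trace).

    Labels are 0-based.  Converges when the absolute RSS change between
    subsequent iterations falls below ``KMEANS_TOL``.
    """
    centroids = x[_kmeanspp_indices(x, k, rng)].astype(float)
    prev_rss = np.inf
    trace: list[float] = []
    for _ in range(MAX_ITER):
        d2 = _sq_dists(x, centroids)
        labels = np.argmin(d2, axis=1)
        # empty-cluster remedy: re-seed with the point farthest from its centroid
        for ell in range(k):
            if not np.any(labels == ell):
                resid = d2[np.arange(x.shape[0]), labels]
                donor = int(np.argmax(resid))
                labels[donor] = ell
                d2[donor, :] = np.inf  # keep it from being stolen again
        for ell in range(k):
            centroids[ell] = x[labels == ell].mean(axis=0)
        rss = float(
            np.sum((x - centroids[labels]) ** 2)
        )
        trace.append(rss)
        if abs(prev_rss - rss) < KMEANS_TOL:
            return labels, centroids, trace
        prev_rss = rss
    raise ConvergenceError(
        f"k-means did not converge within {MAX_ITER} iterations",
        best_objective=prev_rss,
    )


def _kmedoids_core(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """K-medoids with k-means++-style init; stops when the medoid set repeats."""
    t = x.shape[0]
    dist = np.sqrt(np.maximum(_sq_dists(x, x), 0.0))
    medoids = _kmeanspp_indices(x, k, rng)
    seen = {tuple(sorted(medoids.tolist()))}
    for _ in range(MAX_ITER):
        labels = np.argmin(dist[:, medoids], axis=1)
        for ell in range(k):
            if not np.any(labels == ell):
                resid = dist[np.arange(t), medoids[labels]]
                resid[medoids] = -np.inf
                labels[int(np.argmax(resid))] = ell
        new_medoids = medoids.copy()
        for ell in range(k):
            members = np.flatnonzero(labels == ell)
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[ell] = members[int(np.argmin(within))]
        key = tuple(sorted(new_medoids.tolist()))
        if np.array_equal(new_medoids, medoids) or key in seen:
            medoids = new_medoids
            break
        seen.add(key)
        medoids = new_medoids
    labels = np.argmin(dist[:, medoids], axis=1)
    return labels, x[medoids].astype(float)


def _ward_core(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    z = linkage(x, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust") - 1
    centroids = np.vstack([x[labels == ell].mean(axis=0) for ell in range(k)])
    return labels, centroids


def _gfp(x: np.ndarray) -> np.ndarray:
    """Global field power: per-volume population SD across ROIs."""
    return x.std(axis=1)


def _atomize_once(
    x: np.ndarray,
    members: list[np.ndarray],
    centroids: np.ndarray,
    worst: int,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Dissolve cluster ``worst``; each freed point joins the surviving
    cluster with the largest cosine to its (pre-reassignment) centroid."""
    freed = members[worst]
    surv_members = [m for i, m in enumerate(members) if i != worst]
    surv_centroids = np.delete(centroids, worst, axis=0)
    cos = _cosine_matrix(x[freed], surv_centroids)
    target = np.argmax(cos, axis=1)
    new_members = [list(m) for m in surv_members]
    for point, tgt in zip(freed, target):
        new_members[tgt].append(int(point))
    out_members = [np.array(sorted(m)) for m in new_members]
    out_centroids = np.vstack([x[m].mean(axis=0) for m in out_members])
    return out_members, out_centroids


def _aahc_core(
    x: np.ndarray, k: int, topographic: bool
) -> tuple[np.ndarray, np.ndarray, int]:
    """(T)AAHC from T singleton clusters down to K clusters.

    Worst cluster per step: smallest GEV (AAHC) or smallest correlation sum
    (TAAHC); ties break toward the smallest cluster index.
    """
    t = x.shape[0]
    sigma2 = _gfp(x) ** 2
    sigma2_total = sigma2.sum()
    members: list[np.ndarray] = [np.array([i]) for i in range(t)]
    centroids = x.astype(float).copy()
    n_steps = 0
    while len(members) > k:
        labels = np.empty(t, dtype=int)
        for idx, m in enumerate(members):
            labels[m] = idx
        cos_own = _row_cosines(x, centroids[labels])
        if topographic:
            score = np.bincount(labels, weights=cos_own, minlength=len(members))
        else:
            score = (
                np.bincount(
                    labels, weights=cos_own**2 * sigma2, minlength=len(members)
                )
                / sigma2_total
            )
        worst = int(np.argmin(score))  # argmin takes the smallest index on ties
        members, centroids = _atomize_once(x, members, centroids, worst)
        n_steps += 1
    labels = np.empty(t, dtype=int)
    for idx, m in enumerate(members):
        labels[m] = idx
    return labels, centroids, n_steps


def _bisecting_core(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bisecting K-means: repeatedly 2-means-split the cluster with largest SSE."""
    clusters: list[np.ndarray] = [np.arange(x.shape[0])]
    while len(clusters) < k:
        sse = [
            float(np.sum((x[m] - x[m].mean(axis=0)) ** 2)) for m in clusters
        ]
        pick = int(np.argmax(sse))
        if sse[pick] <= 0.0:
            raise InfeasibleKError(
                "cannot bisect further: remaining clusters have zero SSE"
            )
        m = clusters.pop(pick)
        sub_labels, _, _ = _kmeans_core(x[m], 2, rng)
        clusters.append(m[sub_labels == 0])
        clusters.append(m[sub_labels == 1])
    labels = np.empty(x.shape[0], dtype=int)
    for idx, m in enumerate(clusters):
        labels[m] = idx
    centroids = np.vstack([x[m].mean(axis=0) for m in clusters])
    return labels, centroids


def _log_gaussians(
    x: np.ndarray, means: np.ndarray, covs: np.ndarray
) -> np.ndarray:
    """T x K matrix of component log densities via Cholesky factors."""
    t, n = x.shape
    k = means.shape[0]
    out = np.empty((t, k))
    for ell in range(k):
        chol = np.linalg.cholesky(covs[ell])
        diff = x - means[ell]
        solved = np.linalg.solve(chol, diff.T)
        maha = np.einsum("it,it->t", solved, solved)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, ell] = -0.5 * (n * np.log(2.0 * np.pi) + logdet + maha)
    return out


def _gmm_core(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float], GmmParams]:
    """Full-covariance GMM fitted by EM, initialized from a K-means solution."""
    t, n = x.shape
    init_labels, init_centroids, _ = _kmeans_core(x, k, rng)
    weights = np.bincount(init_labels, minlength=k).astype(float) / t
    means = init_centroids.copy()
    covs = np.empty((k, n, n))
    for ell in range(k):
        xm = x[init_labels == ell] - means[ell]
        covs[ell] = (xm.T @ xm) / max(len(xm), 1) + GMM_REG_COVAR * np.eye(n)

    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(MAX_ITER):
        log_prob = _log_gaussians(x, means, covs) + np.log(weights)
        log_norm = logsumexp(log_prob, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_prob - log_norm[:, None])
        nk = resp.sum(axis=0) + 10.0 * np.finfo(float).eps
        weights = nk / t
        means = (resp.T @ x) / nk[:, None]
        for ell in range(k):
            diff = x - means[ell]
            covs[ell] = (
                (resp[:, ell][:, None] * diff).T @ diff
            ) / nk[ell] + GMM_REG_COVAR * np.eye(n)
        if np.isfinite(prev_ll) and (ll - prev_ll) / t < GMM_TOL:
            break
        prev_ll = ll
    else:
        raise ConvergenceError(
            f"GMM EM did not converge within {MAX_ITER} iterations",
            best_objective=prev_ll,
        )

    log_prob = _log_gaussians(x, means, covs) + np.log(weights)
    labels = np.argmax(log_prob, axis=1)
    # keep every component non-empty: give an empty component its top-
    # responsibility point (rare; EM from a K-means start seldom needs this)
    for ell in range(k):
        if not np.any(labels == ell):
            labels[int(np.argmax(log_prob[:, ell]))] = ell
    params = GmmParams(weights=weights, means=means, covariances=covs)
    return labels, means.copy(), trace, params


def cluster(
    x: np.ndarray, k: int, method: str, seed: int | None = 0
) -> StatePartition:
    """Partition the T volumes of ``x`` into ``k`` states with ``method``.

    Deterministic for identical ``(x, k, method, seed)``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ConfigurationError("x must be a T x N matrix")
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("x contains non-finite values")
    if k > x.shape[0]:
        raise InfeasibleKError(f"K={k} exceeds T={x.shape[0]}")
    _check_feasible(x, k)
    if method not in METHODS:
        raise ConfigurationError(
            f"unknown method {method!r}; expected one of {METHODS}"
        )
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    n_steps = None
    if method == "kmeans":
        labels, centroids, trace = _kmeans_core(x, k, rng)
    elif method == "kmedoids":
        labels, centroids = _kmedoids_core(x, k, rng)
    elif method == "ward":
        labels, centroids = _ward_core(x, k)
    elif method == "aahc":
        labels, centroids, n_steps = _aahc_core(x, k, topographic=False)
    elif method == "taahc":
        labels, centroids, n_steps = _aahc_core(x, k, topographic=True)
    elif method == "bisecting_kmeans":
        labels, centroids = _bisecting_core(x, k, rng)
    else:  # gmm
        labels, centroids, trace, _ = _gmm_core(x, k, rng)
    return StatePartition(
        labels=labels + 1,
        centroids=centroids,
        method=method,
        K=k,
        seed=seed,
        objective_trace=trace,
        n_atomize_steps=n_steps,
    )


def _partition_cosines(x: np.ndarray, part: StatePartition) -> np.ndarray:
    return _row_cosines(x, part.centroids[part.labels - 1])


def _gev_per_cluster(
    x: np.ndarray, part: StatePartition, sigma: np.ndarray
) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0.0):
        raise ConfigurationError("sigma_t must be positive for all volumes")
    cos = _partition_cosines(x, part)
    w = cos**2 * sigma**2
    num = np.bincount(part.labels - 1, weights=w, minlength=part.K)
    return num / np.sum(sigma**2)


def worst_cluster_gev(
    x: np.ndarray, part: StatePartition, sigma: np.ndarray
) -> int:
    """1-based index of the cluster with the smallest GEV (ties -> smallest)."""
    return int(np.argmin(_gev_per_cluster(x, part, sigma))) + 1


def worst_cluster_crs(x: np.ndarray, part: StatePartition) -> int:
    """1-based index of the cluster with the smallest correlation sum."""
    cos = _partition_cosines(x, part)
    crs = np.bincount(part.labels - 1, weights=cos, minlength=part.K)
    return int(np.argmin(crs)) + 1


def atomize_reassign(
    x: np.ndarray, part: StatePartition, worst: int
) -> StatePartition:
    """Dissolve the 1-based ``worst`` cluster and reassign its members to the
    surviving cluster with the largest cosine similarity; surviving centroids
    are recomputed after all reassignments."""
    if part.K < 2:
        raise ConfigurationError("cannot atomize: only one cluster present")
    members = [np.flatnonzero(part.labels == ell + 1) for ell in range(part.K)]
    new_members, new_centroids = _atomize_once(
        x, members, part.centroids, worst - 1
    )
    labels = np.empty(len(part.labels), dtype=int)
    for idx, m in enumerate(new_members):
        labels[m] = idx + 1
    return StatePartition(
        labels=labels,
        centroids=new_centroids,
        method=part.method,
        K=part.K - 1,
        seed=part.seed,
    )


def gev_total(
    x: np.ndarray, part: StatePartition, sigma: np.ndarray | None = None
) -> float:
    """Total global explained variance in [0, 1].

    ``sigma`` defaults to the GFP recomputed from ``x``; pass ``np.ones(T)``
    explicitly for already-standardized data if recomputation is undesirable.
    """
    x = np.asarray(x, dtype=float)
    if sigma is None:
        sigma = _gfp(x)
    return float(np.sum(_gev_per_cluster(x, part, sigma)))


def wcss(x: np.ndarray, part: StatePartition) -> float:
    """Within-cluster sum of squared distances to the assigned centroids."""
    x = np.asarray(x, dtype=float)
    return float(np.sum((x - part.centroids[part.labels - 1]) ** 2))
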