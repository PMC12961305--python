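"""Population-level clustering of per-subject NNMF meta-times.

Every subject contributes its R meta-times (rows of H) as individual
points. Because the NNMF scale split between W and H is arbitrary, each
meta-time is first normalized to unit Euclidean norm (the inverse scale is
absorbed into the matching W column, leaving the reconstruction W H
unchanged) so that clustering groups latency *shapes*, not amplitudes.
k-means with many restarts partitions the pooled meta-times; the cluster
count k is chosen over a 3-7 search range by the mean silhouette, and each
cluster is summarised by the elementwise mean of its member meta-times and
of their paired meta-JIERPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples, silhouette_score

from .factorization import Factorization

__all__ = [
    "ClusterSolution",
    "PooledFactors",
    "normalize_factors",
    "pool_factors",
    "cluster_metatimes",
    "cluster_representatives",
    "MetaTimeKMeans",
    "K_RANGE",
    "N_RESTARTS",
]

logger = logging.getLogger(__name__)

K_RANGE = (3, 7)
N_RESTARTS = 1000


@dataclass
class PooledFactors:
    """Pooled per-subject factors: one row per (subject, factor) pair."""

    meta_times: np.ndarray  # n_points x n_latencies, unit-norm rows
    meta_jierps: np.ndarray  # n_points x b x b, NaN where a bin was excluded
    subject: np.ndarray  # subject id per point
    factor: np.ndarray  # factor index within the subject

    @property
    def n_points(self) -> int:
        return self.meta_times.shape[0]


@dataclass
class ClusterSolution:
    """k-means partition of pooled meta-times with silhouette diagnostics."""

    assignments: np.ndarray
    k: int
    silhouette_values: np.ndarray
    silhouette_mean: float
    silhouette_by_k: dict
    inertia: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)


def normalize_factors(fact: Factorization) -> Factorization:
    """Scale each meta-time to unit norm, absorbing the scale into W.

    All-zero meta-times are dropped (with a log entry), reducing the rank.
    The product W H is unchanged to numeric precision.
    """
    norms = np.linalg.norm(fact.H, axis=1)
    keep = norms > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.warning("normalize_factors: dropped %d all-zero meta-times", n_dropped)
    W = fact.W[:, keep] * norms[keep][None, :]
    H = fact.H[keep] / norms[keep][:, None]
    return Factorization(
        W=W,
        H=H,
        rank=int(keep.sum()),
        frobenius_error=fact.frobenius_error,
        seed=fact.seed,
        stability_score=fact.stability_score,
        n_iter=fact.n_iter,
        converged=fact.converged,
        error_history=fact.error_history,
        meta={**fact.meta, "normalized": True, "n_dropped_factors": n_dropped},
    )


def pool_factors(
    factorizations: list,
    subject_ids: list | None = None,
    bin_lists: list | None = None,
    grid_shape: tuple = (5, 5),
) -> PooledFactors:
    """Stack normalized factors from all subjects into one point cloud.

    ``bin_lists`` gives, per subject, the (row, col) cell behind each W row
    (from :class:`~jierp.factorization.NonNegMatrix`); omitted, W rows are
    assumed to cover the full grid in row-major order.
    """
    if subject_ids is None:
        subject_ids = list(range(len(factorizations)))
    times, jierps, subj, fidx = [], [], [], []
    for s, fact in zip(subject_ids, factorizations):
        fact = normalize_factors(fact)
        bins = (
            bin_lists[subject_ids.index(s)]
            if bin_lists is not None
            else [(r, c) for r in range(grid_shape[0]) for c in range(grid_shape[1])]
        )
        for j in range(fact.rank):
            times.append(fact.H[j])
            mj = np.full(grid_shape, np.nan)
            for row_idx, cell in enumerate(bins):
                mj[cell] = fact.W[row_idx, j]
            jierps.append(mj)
            subj.append(s)
            fidx.append(j)
    return PooledFactors(
        meta_times=np.asarray(times),
        meta_jierps=np.asarray(jierps),
        subject=np.asarray(subj),
        factor=np.asarray(fidx),
    )


class MetaTimeKMeans(ClusterMixin, BaseEstimator):
    """k-means over meta-times with silhouette-based selection of k.

    For each k in ``k_range`` (inclusive) the best of ``n_restarts``
    random-initialization k-means runs is kept; the k maximizing the mean
    silhouette wins (ties toward the smaller k). k values with too few
    points are skipped and logged.

    Attributes after ``fit``: ``labels_``, ``k_``, ``silhouette_values_``,
    ``silhouette_mean_``, ``silhouette_by_k_``, ``inertia_``.
    """

    def __init__(
        self,
        k_range: tuple = K_RANGE,
        n_restarts: int = N_RESTARTS,
        random_state: int | None = None,
    ):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (points x latencies)")
        if np.allclose(X, X[0]):
            raise ValueError(
                "all points identical: silhouette (and clustering) undefined"
            )
        seed = 0 if self.random_state is None else int(self.random_state)
        lo, hi = self.k_range
        results = {}
        for k in range(lo, hi + 1):
            if k >= X.shape[0]:
                logger.warning("k=%d skipped: only %d points", k, X.shape[0])
                continue
            km = KMeans(
                n_clusters=k,
                init="random",
                n_init=self.n_restarts,
                random_state=seed,
            ).fit(X)
            results[k] = (float(silhouette_score(X, km.labels_)), km)
        if not results:
            raise ValueError("no feasible k in the search range")
        best_k = max(results, key=lambda k: (results[k][0], -k))
        score, km = results[best_k]
        self.k_ = best_k
        self.labels_ = km.labels_
        self.cluster_centers_ = km.cluster_centers_
        self.inertia_ = float(km.inertia_)
        self.silhouette_mean_ = score
        self.silhouette_values_ = silhouette_samples(X, km.labels_)
        self.silhouette_by_k_ = {k: results[k][0] for k in results}
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_metatimes(
    metatimes: np.ndarray,
    k_range: tuple = K_RANGE,
    n_restarts: int = N_RESTARTS,
    seed: int | None = None,
) -> ClusterSolution:
    """Functional wrapper over :class:`MetaTimeKMeans`."""
    est = MetaTimeKMeans(k_range=k_range, n_restarts=n_restarts, random_state=seed)
    est.fit(metatimes)
    return ClusterSolution(
        assignments=est.labels_,
        k=est.k_,
        silhouette_values=est.silhouette_values_,
        silhouette_mean=est.silhouette_mean_,
        silhouette_by_k=est.silhouette_by_k_,
        inertia=est.inertia_,
        seed=seed,
        meta={"k_range": tuple(k_range), "n_restarts": n_restarts},
    )


def cluster_representatives(solution: ClusterSolution, pooled: PooledFactors) -> dict:
    """Per-cluster mean meta-time and mean paired meta-JIERP.

    Returns ``{cluster_id: {"meta_time", "meta_jierp", "members",
    "subjects"}}``; meta-JIERP means ignore NaN (excluded) bins.
    """
    if len(solution.assignments) != pooled.n_points:
        raise ValueError("solution and pooled factors are inconsistent")
    reps = {}
    for c in range(solution.k):
        members = np.nonzero(solution.assignments == c)[0]
        if len(members) == 0:
            raise ValueError(f"cluster {c} is empty")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            mj = np.nanmean(pooled.meta_jierps[members], axis=0)
        reps[c] = {
            "meta_time": pooled.meta_times[members].mean(axis=0),
            "meta_jierp": mj,
            "members": members,
            "subjects": pooled.subject[members],
        }
    return reps
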