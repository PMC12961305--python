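"""Stability-selected non-negative matrix factorization (starNNMF).

The post-stimulus JIERP is rearranged as a non-negative matrix M (25 bins x
299 latencies): signal magnitudes |amplitude| are z-scored across bins at
each latency and the global minimum of the resulting matrix is subtracted,
which preserves every pairwise difference while making M >= 0. NNMF then
decomposes M ~ W H into R *meta-JIERPs* (columns of W: prototypical 5x5
bin-modulation patterns) and *meta-times* (rows of H: the latency profile
over which each pattern is expressed).

Because multiplicative-update NNMF depends on its random initialization,
the factorization is repeated from many independent starts and the run most
similar to all the others (the medoid under permutation-matched cosine
similarity of W columns) is returned, together with a stability score in
[0, 1]. The rank is selected by Wold-style cross-validation: random entry
holdouts are masked during fitting and scored on reconstruction, with a
one-standard-error tie-break toward the smaller rank.

:class:`StarNMF` wraps the procedure as a scikit-learn transformer;
:func:`nnmf_factorize`, :func:`select_rank_cv` and :func:`stable_factorize`
are the underlying primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin

from .core import JierpTensor

__all__ = [
    "NonNegMatrix",
    "Factorization",
    "RankSelection",
    "magnitude_transform",
    "nnmf_factorize",
    "select_rank_cv",
    "stable_factorize",
    "matched_cosine_similarity",
    "StarNMF",
    "RANK_RANGE",
    "N_REPS",
]

RANK_RANGE = (2, 10)
N_REPS = 100
_EPS = 1e-12


@dataclass
class NonNegMatrix:
    """Non-negative JIERP magnitude matrix with row provenance.

    ``bins`` lists the (row, col) grid cell behind each matrix row; bins
    invalid in the source tensor are excluded (never imputed) and recorded
    in ``excluded_bins``.
    """

    M: np.ndarray
    bins: list
    time_ms: np.ndarray
    excluded_bins: list = field(default_factory=list)
    transform: str = "z(|amplitude|) - global min"

    @property
    def shape(self) -> tuple:
        return self.M.shape


@dataclass
class Factorization:
    """One NNMF solution M ~ W H with provenance and stability diagnostics."""

    W: np.ndarray  # n_bins x rank, meta-JIERPs in columns
    H: np.ndarray  # rank x n_latencies, meta-times in rows
    rank: int
    frobenius_error: float
    seed: int | None = None
    stability_score: float | None = None
    n_iter: int = 0
    converged: bool = False
    error_history: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class RankSelection:
    """Cross-validated rank search result."""

    best_rank: int
    ranks: np.ndarray
    cv_error: np.ndarray  # mean held-out RMSE per rank
    cv_se: np.ndarray  # standard error over folds
    n_folds: int
    holdout_fraction: float


def magnitude_transform(
    jierp: JierpTensor, post_stimulus_ms: tuple = (1, 299)
) -> NonNegMatrix:
    """Build the non-negative magnitude matrix from a JIERP.

    Restricts to post-stimulus latencies, takes |amplitude|, z-scores across
    valid bins per latency (sample SD), and subtracts the global minimum so
    the matrix minimum is exactly 0. Invalid bins become excluded rows.
    """
    lo, hi = post_stimulus_ms
    tmask = (jierp.time_ms >= lo) & (jierp.time_ms <= hi)
    if not tmask.any():
        raise ValueError(f"post-stimulus window {post_stimulus_ms} outside time axis")
    if jierp.n_valid < 2:
        raise ValueError("need >= 2 valid bins to z-score magnitudes")
    mag = np.abs(jierp.amplitude[jierp.valid][:, tmask])  # n_valid x T'
    mean = mag.mean(axis=0)
    sd = mag.std(axis=0, ddof=1)
    z = (mag - mean) / np.where(sd == 0, 1.0, sd)
    z[:, sd == 0] = 0.0
    M = z - z.min()
    b = jierp.valid.shape[0]
    cells = [(r, c) for r in range(b) for c in range(b)]
    bins = [cell for cell in cells if jierp.valid[cell]]
    excluded = [cell for cell in cells if not jierp.valid[cell]]
    return NonNegMatrix(
        M=M, bins=bins, time_ms=jierp.time_ms[tmask].copy(), excluded_bins=excluded
    )


def _init_wh(
    rng: np.random.Generator, M: np.ndarray, rank: int
) -> tuple[np.ndarray, np.ndarray]:
    scale = np.sqrt(max(M.mean(), _EPS) / rank)
    W = scale * rng.random((M.shape[0], rank))
    H = scale * rng.random((rank, M.shape[1]))
    return W, H


def nnmf_factorize(
    M: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> Factorization:
    """Multiplicative-update NNMF under the Frobenius objective.

    Lee-Seung updates guarantee a non-increasing reconstruction error; the
    full error history is recorded so this can be audited. Iteration stops
    when the relative error change drops below ``tol``. Deterministic for a
    fixed seed.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be 2-D")
    if np.any(M < 0):
        raise ValueError("M must be non-negative")
    if not (1 <= rank <= min(M.shape)):
        raise ValueError(f"rank must lie in [1, {min(M.shape)}], got {rank}")
    rng = np.random.default_rng(seed)
    W, H = _init_wh(rng, M, rank)
    errors = []
    prev = np.linalg.norm(M - W @ H)
    errors.append(prev)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ M) / (W.T @ W @ H + _EPS)
        W *= (M @ H.T) / (W @ (H @ H.T) + _EPS)
        err = np.linalg.norm(M - W @ H)
        errors.append(err)
        if abs(prev - err) <= tol * max(prev, _EPS):
            converged = True
            break
        prev = err
    return Factorization(
        W=W,
        H=H,
        rank=rank,
        frobenius_error=float(errors[-1]),
        seed=seed,
        n_iter=it,
        converged=converged,
        error_history=np.asarray(errors),
    )


def _masked_factorize(
    M: np.ndarray,
    observed: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative updates restricted to observed entries (Wold CV)."""
    W, H = _init_wh(rng, M, rank)
    Mo = observed * M
    prev = np.inf
    for _ in range(max_iter):
        WH = W @ H
        H *= (W.T @ Mo) / (W.T @ (observed * WH) + _EPS)
        WH = W @ H
        W *= (Mo @ H.T) / ((observed * WH) @ H.T + _EPS)
        err = np.linalg.norm(observed * (M - W @ H))
        if abs(prev - err) <= tol * max(prev if np.isfinite(prev) else err, _EPS):
            break
        prev = err
    return W, H


def _draw_holdout(
    rng: np.random.Generator, shape: tuple, fraction: float
) -> np.ndarray:
    """Boolean held-out mask leaving every row and column partly observed.

    Redraws (bounded) if a full row/column would be masked out.
    """
    for _ in range(100):
        held = rng.random(shape) < fraction
        observed = ~held
        if held.any() and observed.any(axis=1).all() and observed.any(axis=0).all():
            return held
    raise RuntimeError("could not draw a valid holdout mask")


def select_rank_cv(
    M: np.ndarray,
    rank_range: tuple = RANK_RANGE,
    holdout_fraction: float = 0.1,
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
    n_restarts: int = 5,
) -> RankSelection:
    """Wold-style cross-validated rank search.

    For each fold a random ``holdout_fraction`` of entries is masked, the
    factorization is fitted on the remaining entries with masked
    multiplicative updates (best of ``n_restarts`` initializations, judged
    on the observed entries), and the held-out RMSE is scored. The selected
    rank is the smallest whose mean error is within one standard error of
    the minimum (ties and flat curves resolve toward parsimony).
    """
    M = np.asarray(M, dtype=float)
    ranks = np.arange(rank_range[0], rank_range[1] + 1)
    if ranks[-1] > min(M.shape):
        raise ValueError("largest rank exceeds matrix dimensions")
    rng = np.random.default_rng(seed)
    errs = np.zeros((len(ranks), n_folds))
    for f in range(n_folds):
        held = _draw_holdout(rng, M.shape, holdout_fraction)
        observed = (~held).astype(float)
        for i, r in enumerate(ranks):
            best_fit = np.inf
            best_wh = None
            for _ in range(n_restarts):
                W, H = _masked_factorize(M, observed, int(r), rng, max_iter, tol)
                fit_err = np.linalg.norm(observed * (M - W @ H))
                if fit_err < best_fit:
                    best_fit, best_wh = fit_err, (W, H)
            W, H = best_wh
            resid = (M - W @ H)[held]
            errs[i, f] = np.sqrt(np.mean(resid**2))
    cv_error = errs.mean(axis=1)
    cv_se = errs.std(axis=1, ddof=1) / np.sqrt(n_folds) if n_folds > 1 else np.zeros(
        len(ranks)
    )
    i_min = int(np.argmin(cv_error))
    # One-standard-error rule on *paired* per-fold differences: folds share
    # holdout masks across ranks, so pairing removes mask-to-mask variance.
    best_i = i_min
    for i in range(i_min):
        d = errs[i] - errs[i_min]
        se = d.std(ddof=1) / np.sqrt(n_folds) if n_folds > 1 else 0.0
        if d.mean() <= se:
            best_i = i
            break
    best = int(ranks[best_i])
    return RankSelection(
        best_rank=best,
        ranks=ranks,
        cv_error=cv_error,
        cv_se=cv_se,
        n_folds=n_folds,
        holdout_fraction=holdout_fraction,
    )


def _unit_columns(W: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(W, axis=0)
    return W / np.where(norms == 0, 1.0, norms)


def matched_cosine_similarity(Wa: np.ndarray, Wb: np.ndarray) -> float:
    """Mean cosine similarity of optimally one-to-one matched columns.

    Invariant to column order and per-column rescaling, i.e. to the NNMF
    scale-permutation equivalence class.
    """
    C = _unit_columns(Wa).T @ _unit_columns(Wb)
    ri, ci = linear_sum_assignment(-C)
    return float(C[ri, ci].mean())


def stable_factorize(
    M: np.ndarray,
    rank: int,
    n_reps: int = N_REPS,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> Factorization:
    """Stability-selected NNMF: the medoid of many random restarts.

    Runs ``n_reps`` factorizations from independent initializations,
    measures pairwise solution similarity as the permutation-matched cosine
    similarity of W columns, and returns the run with maximal mean
    similarity to all others. Its mean similarity is the stability score
    (close to 1 when the decomposition is reproducible regardless of
    initialization).
    """
    M = np.asarray(M, dtype=float)
    if not np.any(M > 0):
        raise ValueError("cannot factorize an all-zero matrix")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_reps)
    runs = [
        nnmf_factorize(M, rank, seed=int(s), max_iter=max_iter, tol=tol)
        for s in seeds
    ]
    if n_reps == 1:
        only = runs[0]
        only.stability_score = None
        only.meta["stability_undefined"] = True
        return only
    S = np.eye(n_reps)
    for a in range(n_reps):
        for b in range(a + 1, n_reps):
            S[a, b] = S[b, a] = matched_cosine_similarity(runs[a].W, runs[b].W)
    mean_sim = (S.sum(axis=1) - 1.0) / (n_reps - 1)
    medoid = int(np.argmax(mean_sim))
    best = runs[medoid]
    best.stability_score = float(mean_sim[medoid])
    best.meta.update({"n_reps": n_reps, "medoid_index": medoid})
    return best


class StarNMF(TransformerMixin, BaseEstimator):
    """Scikit-learn style stability-selected NNMF transformer.

    Parameters
    ----------
    rank : int or "cv"
        Factorization rank; ``"cv"`` selects it by Wold cross-validation
        over ``rank_range``.
    rank_range : (lo, hi) inclusive search range used when ``rank="cv"``.
    n_reps : random restarts pooled by the stability selection.
    max_iter, tol : multiplicative-update stopping rule.
    holdout_fraction, n_folds : Wold CV configuration.
    random_state : seed for all randomness (initializations and holdouts).

    Attributes (after ``fit``)
    --------------------------
    rank_ : selected rank.
    components_ : (rank_, n_features) meta-times H, sklearn convention.
    basis_ : (n_samples, rank_) meta-JIERPs W for the training matrix.
    reconstruction_err_ : Frobenius norm of M - W H.
    stability_score_ : mean matched-cosine similarity of the medoid run.
    rank_selection_ : :class:`RankSelection` when CV ran, else None.
    """

    def __init__(
        self,
        rank="cv",
        rank_range: tuple = RANK_RANGE,
        n_reps: int = N_REPS,
        max_iter: int = 500,
        tol: float = 1e-5,
        holdout_fraction: float = 0.1,
        n_folds: int = 5,
        random_state: int | None = None,
    ):
        self.rank = rank
        self.rank_range = rank_range
        self.n_reps = n_reps
        self.max_iter = max_iter
        self.tol = tol
        self.holdout_fraction = holdout_fraction
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or np.any(X < 0) or not np.all(np.isfinite(X)):
            raise ValueError("X must be a finite non-negative 2-D array")
        seed = 0 if self.random_state is None else int(self.random_state)
        if self.rank == "cv":
            self.rank_selection_ = select_rank_cv(
                X,
                rank_range=self.rank_range,
                holdout_fraction=self.holdout_fraction,
                n_folds=self.n_folds,
                seed=seed,
            )
            rank = self.rank_selection_.best_rank
        else:
            self.rank_selection_ = None
            rank = int(self.rank)
        fact = stable_factorize(
            X,
            rank,
            n_reps=self.n_reps,
            seed=seed,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.rank_ = rank
        self.components_ = fact.H
        self.basis_ = fact.W
        self.reconstruction_err_ = fact.frobenius_error
        self.stability_score_ = fact.stability_score
        self.factorization_ = fact
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Non-negative projection of X onto the fitted meta-times."""
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "components_"):
            raise AttributeError("StarNMF instance is not fitted yet")
        H = self.components_
        rng = np.random.default_rng(
            0 if self.random_state is None else int(self.random_state)
        )
        W = rng.random((X.shape[0], H.shape[0])) * np.sqrt(
            max(X.mean(), _EPS) / H.shape[0]
        )
        HHt = H @ H.T
        for _ in range(self.max_iter):
            W_new = W * (X @ H.T) / (W @ HHt + _EPS)
            if np.max(np.abs(W_new - W)) <= self.tol * max(np.max(np.abs(W)), _EPS):
                W = W_new
                break
            W = W_new
        return W

    def inverse_transform(self, W):
        return np.asarray(W) @ self.components_
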