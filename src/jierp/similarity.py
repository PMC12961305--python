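"""Latency-to-latency similarity of the across-bin modulation pattern.

At each latency the (grand-averaged, z-scored) JIERP is a map of up to 25
bin values. The Spearman rank correlation between the maps of every latency
pair yields a T x T matrix quantifying how similar interval-dependent
modulation is across processing stages. Because nearby latencies are
trivially similar, a diagonal band (default half-width 25 ms) is excluded
from the FDR pool; the Benjamini-Hochberg correction is applied once to the
unique off-band upper-triangle p-values and the rejection mask is mirrored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .core import ZJierp
from .stats import ALPHA, fdr_bh

__all__ = [
    "CrossCorrMatrix",
    "crosscorr_spearman",
    "fdr_offdiagonal",
    "BAND_HALFWIDTH_MS",
]

BAND_HALFWIDTH_MS = 25.0
#: Minimum jointly valid bins required to emit a coefficient.
MIN_JOINT_BINS = 5


@dataclass
class CrossCorrMatrix:
    """Symmetric T x T Spearman coefficients with unit diagonal.

    ``undefined`` marks pairs involving a constant (tied-everywhere) bin map,
    which carry NaN rho and never enter the FDR pool. ``fdr_mask`` is None
    until :func:`fdr_offdiagonal` has been applied.
    """

    rho: np.ndarray
    p: np.ndarray
    time_ms: np.ndarray
    undefined: np.ndarray
    n_bins: int
    fdr_mask: np.ndarray | None = None
    excluded_band_halfwidth_ms: float | None = None
    meta: dict = field(default_factory=dict)


def _rank_columns(x: np.ndarray) -> np.ndarray:
    """Column-wise average ranks (ties share the mean rank)."""
    return sps.rankdata(x, axis=0)


def crosscorr_spearman(zjierp: ZJierp) -> CrossCorrMatrix:
    """Spearman cross-correlation of bin maps between all latency pairs.

    Coefficients are computed over the bins valid in the input (the valid
    mask is shared across latencies, so every pair is complete over the same
    n bins). p-values use the t-approximation with n-2 degrees of freedom;
    rho = +-1 maps to p = 0.
    """
    X = zjierp.z[zjierp.valid]  # n_bins x T
    n, T = X.shape
    if n < MIN_JOINT_BINS:
        raise ValueError(
            f"need >= {MIN_JOINT_BINS} jointly valid bins, got {n}"
        )
    ranks = _rank_columns(X)
    centered = ranks - ranks.mean(axis=0)
    norm = np.sqrt((centered**2).sum(axis=0))
    defined = norm > 0
    unit = np.where(defined[None, :], centered / np.where(norm == 0, 1.0, norm), 0.0)
    rho = unit.T @ unit
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(rho, 1.0)

    undefined = ~(defined[:, None] & defined[None, :])
    rho[undefined] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(tstat), df=n - 2)
    p[np.abs(rho) == 1.0] = 0.0
    p[undefined] = np.nan
    diag_undefined = undefined.diagonal().copy()
    np.fill_diagonal(rho, np.where(diag_undefined, np.nan, 1.0))
    np.fill_diagonal(p, np.where(diag_undefined, np.nan, 0.0))
    return CrossCorrMatrix(
        rho=rho,
        p=p,
        time_ms=zjierp.time_ms.copy(),
        undefined=undefined,
        n_bins=n,
        meta={"source": zjierp.source},
    )


def fdr_offdiagonal(
    ccm: CrossCorrMatrix,
    alpha: float = ALPHA,
    band_halfwidth_ms: float = BAND_HALFWIDTH_MS,
    halfwidth: bool = True,
) -> CrossCorrMatrix:
    """BH-correct the off-band coefficients and mirror the rejection mask.

    Entries with |latency difference| <= band (a half-width by default, or a
    full width when ``halfwidth=False``) are excluded from the p-value pool,
    as is any pair flagged undefined. Each unordered pair enters the pool
    exactly once (upper triangle).
    """
    if band_halfwidth_ms < 0:
        raise ValueError("band half-width must be >= 0")
    band = band_halfwidth_ms if halfwidth else band_halfwidth_ms / 2.0
    time = np.asarray(ccm.time_ms, dtype=float)
    dt = np.abs(time[:, None] - time[None, :])
    iu, ju = np.triu_indices(len(time), k=1)
    pool = (dt[iu, ju] > band) & ~ccm.undefined[iu, ju]
    if not pool.any():
        raise ValueError(
            f"band half-width {band} ms leaves no latency pairs to test"
        )
    reject, p_adj = fdr_bh(ccm.p[iu[pool], ju[pool]], alpha=alpha)
    mask = np.zeros_like(ccm.rho, dtype=bool)
    mask[iu[pool], ju[pool]] = reject
    mask |= mask.T
    meta = dict(ccm.meta)
    meta.update(
        {
            "alpha": alpha,
            "n_pooled_pairs": int(pool.sum()),
            "band_is_halfwidth": halfwidth,
        }
    )
    return replace(
        ccm,
        fdr_mask=mask,
        excluded_band_halfwidth_ms=band,
        meta=meta,
    )
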