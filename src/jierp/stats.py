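"""Mass-univariate statistics over the z-scored JIERP.

At every (bin, latency) cell a two-sided one-sample t-test of the subjects'
z-scores against 0 identifies bins consistently suppressed (negative z) or
enhanced (positive z) relative to the across-bin mean. Multiple comparisons
are corrected jointly across the entire JIERP (all 25 x T cells) with the
Benjamini-Hochberg step-up FDR procedure at alpha = 0.05; the
dependency-robust Benjamini-Yekutieli variant is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatMap",
    "bin_ttest",
    "fdr_bh",
    "null_fdp_simulation",
    "ALPHA",
    "MIN_SUBJECTS",
]

ALPHA = 0.05
#: Minimum subjects contributing to a cell for a test to be emitted.
MIN_SUBJECTS = 3


@dataclass
class StatMap:
    """Per-cell t/p values with a joint FDR rejection mask.

    ``tested`` marks cells with enough contributing subjects; ``degenerate``
    marks tested cells with zero across-subject variance (t=0, p=1).
    """

    t: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    p_adjusted: np.ndarray
    n_subjects: np.ndarray
    tested: np.ndarray
    degenerate: np.ndarray
    alpha: float = ALPHA
    meta: dict = field(default_factory=dict)


def fdr_bh(
    p_values: np.ndarray, alpha: float = ALPHA, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg (or -Yekutieli) FDR over a flat p-value list.

    Returns ``(reject_mask, adjusted_p)``; empty input yields empty arrays.
    """
    p_values = np.asarray(p_values, dtype=float).ravel()
    if p_values.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p_values < 0) | (p_values > 1) | ~np.isfinite(p_values)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown FDR method {method!r}; use 'bh' or 'by'")
    reject, p_adj, _, _ = multipletests(p_values, alpha=alpha, method=sm_method)
    return reject, p_adj


def bin_ttest(
    z_jierps: list,
    alpha: float = ALPHA,
    min_subjects: int = MIN_SUBJECTS,
    method: str = "bh",
) -> StatMap:
    """One-sample t-tests of subject z-scores vs 0 at every cell, with FDR
    applied jointly across all tested cells of the JIERP.

    ``z_jierps`` is a list of per-subject :class:`~jierp.core.ZJierp`; a
    subject contributes to a cell only where its bin is valid. Cells with
    fewer than ``min_subjects`` contributors are flagged untested and do not
    enter the FDR pool. Zero-variance cells get t=0, p=1 and a degenerate
    flag.
    """
    if not z_jierps:
        raise ValueError("need at least one subject")
    stack = np.stack([zj.z for zj in z_jierps])  # S x b x b x T
    shape = stack.shape[1:]
    n = np.sum(~np.isnan(stack), axis=0)
    tested = n >= min_subjects

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / ddof slices
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    degenerate = tested & (sd == 0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    safe_n = np.maximum(n, 2)
    t = mean / (safe_sd / np.sqrt(safe_n))
    p = 2.0 * sps.t.sf(np.abs(t), df=safe_n - 1)
    t = np.where(tested, t, np.nan)
    p = np.where(tested, p, np.nan)
    t[degenerate] = 0.0
    p[degenerate] = 1.0

    fdr_mask = np.zeros(shape, dtype=bool)
    p_adj = np.full(shape, np.nan)
    if tested.any():
        reject_flat, p_adj_flat = fdr_bh(p[tested], alpha=alpha, method=method)
        fdr_mask[tested] = reject_flat
        p_adj[tested] = p_adj_flat
    return StatMap(
        t=t,
        p=p,
        fdr_mask=fdr_mask,
        p_adjusted=p_adj,
        n_subjects=n,
        tested=tested,
        degenerate=degenerate,
        alpha=alpha,
        meta={
            "method": method,
            "min_subjects": min_subjects,
            "n_tested_cells": int(tested.sum()),
            "n_significant": int(fdr_mask.sum()),
        },
    )


def null_fdp_simulation(
    n_replicates: int = 200,
    n_subjects: int = 30,
    shape: tuple = (5, 5, 299),
    alpha: float = ALPHA,
    seed: int = 0,
    method: str = "bh",
) -> np.ndarray:
    """Per-replicate false-discovery proportions under a global null.

    Each replicate draws per-subject z-maps as i.i.d. standard normal over
    ``shape`` (no effect anywhere), runs the per-cell one-sample t-test with
    joint FDR correction, and records V / max(R, 1); with no true effects
    every rejection is false. The mean over replicates estimates the
    realized FDR of the procedure, which Benjamini-Hochberg controls at
    ``alpha`` for independent cells.
    """
    from .core import ZJierp

    rng = np.random.default_rng(seed)
    valid = np.ones(shape[:2], dtype=bool)
    time_ms = np.arange(1, shape[2] + 1)
    fdps = np.empty(n_replicates)
    for r in range(n_replicates):
        zjs = [
            ZJierp(
                z=rng.standard_normal(shape),
                valid=valid,
                time_ms=time_ms,
                source="individual",
                degenerate_latencies=np.zeros(shape[2], dtype=bool),
            )
            for _ in range(n_subjects)
        ]
        sm = bin_ttest(zjs, alpha=alpha, method=method)
        n_reject = int(sm.fdr_mask.sum())
        fdps[r] = n_reject / max(n_reject, 1)
    return fdps
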