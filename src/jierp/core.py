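"""JIERP construction: joint-interval binning and per-bin ERP estimation.

Each stimulus from the third event of a train onward forms a *triad* with
its two predecessors, characterised by the previous interval k and the
penultimate interval k-1 (both in seconds). Triads are assigned to a 5x5
joint-interval grid with upper bin edges 0.5/1/2/4/8 s (half-open (lower,
upper] membership; triads with either interval above the largest edge are
excluded). Per bin, the ERP is the mean of the pooled single-trial epochs of
the selected channel, valid only when at least ``min_trials`` (default 10)
trials contribute. JIERPs can be grand-averaged across subjects and z-scored
across bins at every latency.

Axis convention, stamped into all outputs: row = penultimate-interval (k-1)
bin, column = previous-interval (k) bin; indices are 0-based in code and
1-based in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochSet
from .simulate import BIN_EDGES_S, StimulationTrain

__all__ = [
    "Triad",
    "BinGrid",
    "JierpTensor",
    "ZJierp",
    "compute_triads",
    "assign_bin",
    "build_jierp",
    "grand_average",
    "zscore_latencywise",
    "MIN_TRIALS",
]

logger = logging.getLogger(__name__)

MIN_TRIALS = 10
AXIS_CONVENTION = "row=penultimate(k-1), col=previous(k)"


@dataclass(frozen=True)
class Triad:
    """One stimulation triad, attributed to its third (last) event."""

    event_index: int
    k_s: float  # previous interval, seconds
    k_minus_1_s: float  # penultimate interval, seconds


@dataclass(frozen=True)
class BinGrid:
    """Quadratic joint-interval grid defined by upper bin edges in seconds."""

    upper_edges_s: tuple = BIN_EDGES_S

    def __post_init__(self) -> None:
        edges = np.asarray(self.upper_edges_s, dtype=float)
        if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("upper edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.upper_edges_s)

    @property
    def centers_s(self) -> np.ndarray:
        """Geometric bin centers (first bin uses half its upper edge as lower)."""
        edges = np.asarray(self.upper_edges_s)
        lowers = np.concatenate(([edges[0] / 2], edges[:-1]))
        return np.sqrt(lowers * edges)


@dataclass
class JierpTensor:
    """Per-bin ERP tensor: ``amplitude`` is n_bins x n_bins x T in uV.

    Invalid bins (fewer than ``min_trials`` trials) carry NaN amplitude and
    ``valid=False``. ``meta`` records the channel, axis convention, and the
    event-accounting used to check count conservation.
    """

    amplitude: np.ndarray
    trial_count: np.ndarray
    valid: np.ndarray
    time_ms: np.ndarray
    grid: BinGrid
    min_trials: int = MIN_TRIALS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.trial_count = np.asarray(self.trial_count, dtype=int)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.time_ms = np.asarray(self.time_ms)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class ZJierp:
    """Latency-wise z-scored JIERP (mean 0, SD 1 across valid bins).

    ``degenerate_latencies`` flags latencies where the across-bin SD was 0
    (z set to 0 there). ``source`` is ``"individual"`` or ``"grand-average"``.
    """

    z: np.ndarray
    valid: np.ndarray
    time_ms: np.ndarray
    source: str
    degenerate_latencies: np.ndarray
    meta: dict = field(default_factory=dict)


def compute_triads(train: StimulationTrain) -> list:
    """List the (k-1, k) interval pairs for every event from the third on.

    Returns an empty list for trains with fewer than three events.
    """
    onsets = train.onsets_ms
    if len(onsets) < 3:
        return []
    k = np.diff(onsets) / 1000.0
    return [
        Triad(event_index=i, k_s=float(k[i - 1]), k_minus_1_s=float(k[i - 2]))
        for i in range(2, len(onsets))
    ]


def assign_bin(triad: Triad, grid: BinGrid = BinGrid()) -> tuple | None:
    """Map a triad to its (row, col) grid cell, or ``None`` if excluded.

    Membership is upper-bound inclusive: interval x belongs to the smallest
    bin b with x <= upper_edges[b]; the first bin is (0, edges[0]]. A triad
    is excluded when either interval exceeds the largest edge.
    """
    if triad.k_s <= 0 or triad.k_minus_1_s <= 0:
        raise ValueError("intervals must be positive")
    edges = np.asarray(grid.upper_edges_s)
    if triad.k_s > edges[-1] or triad.k_minus_1_s > edges[-1]:
        return None
    row = int(np.searchsorted(edges, triad.k_minus_1_s, side="left"))
    col = int(np.searchsorted(edges, triad.k_s, side="left"))
    return row, col


def build_jierp(
    epochs: EpochSet,
    triads: list,
    grid: BinGrid = BinGrid(),
    min_trials: int = MIN_TRIALS,
    channel: int = 0,
) -> JierpTensor:
    """Average single-trial epochs of one channel within each joint bin.

    Rejected epochs are excluded before pooling. Events without a retained
    epoch, triads with an interval beyond the largest edge, and the first two
    events of the train are all counted in ``meta`` so that
    ``sum(trial_count) + exclusions == total events``.
    """
    b = grid.n_bins
    n_time = len(epochs.time_ms)
    sums = np.zeros((b, b, n_time))
    counts = np.zeros((b, b), dtype=int)
    n_out_of_range = 0
    n_no_epoch = 0

    epoch_of_event = {
        int(ev): j for j, ev in enumerate(epochs.event_index) if epochs.retained[j]
    }
    for tr in triads:
        cell = assign_bin(tr, grid)
        if cell is None:
            n_out_of_range += 1
            continue
        j = epoch_of_event.get(tr.event_index)
        if j is None:
            n_no_epoch += 1
            continue
        sums[cell] += epochs.epochs[j, channel, :]
        counts[cell] += 1

    valid = counts >= min_trials
    if not valid.any():
        raise ValueError(
            "no valid bins: per-bin trial counts "
            f"{counts.tolist()} all below min_trials={min_trials}"
        )
    amplitude = np.full((b, b, n_time), np.nan)
    amplitude[valid] = sums[valid] / counts[valid][:, None]
    n_total_events = epochs.meta.get("n_events_total", len(triads) + 2)
    meta = {
        "channel": channel,
        "axis_convention": AXIS_CONVENTION,
        "n_events_total": n_total_events,
        "n_pre_triad_events": n_total_events - len(triads),
        "n_out_of_range": n_out_of_range,
        "n_no_epoch": n_no_epoch,
        "n_pooled": int(counts.sum()),
    }
    logger.info(
        "build_jierp: pooled %d trials, %d out-of-range, %d without epoch",
        meta["n_pooled"],
        n_out_of_range,
        n_no_epoch,
    )
    return JierpTensor(
        amplitude=amplitude,
        trial_count=counts,
        valid=valid,
        time_ms=epochs.time_ms,
        grid=grid,
        min_trials=min_trials,
        meta=meta,
    )


def grand_average(jierps: list, min_subject_fraction: float = 0.8) -> JierpTensor:
    """Across-subject mean JIERP.

    A grand bin is the mean over the subjects whose bin is valid, and is
    itself valid only when at least ``min_subject_fraction`` of subjects
    contribute (the per-subject-missingness rule is a package addition).
    """
    if not jierps:
        raise ValueError("need at least one JIERP to grand-average")
    ref = jierps[0]
    for j in jierps[1:]:
        if j.amplitude.shape != ref.amplitude.shape or not np.array_equal(
            j.time_ms, ref.time_ms
        ):
            raise ValueError("incompatible JIERP shapes or time axes")
        if j.grid.upper_edges_s != ref.grid.upper_edges_s:
            raise ValueError("incompatible bin grids")
    stack = np.stack([j.amplitude for j in jierps])  # S x b x b x T
    valid_stack = np.stack([j.valid for j in jierps])
    n_contrib = valid_stack.sum(axis=0)
    frac = n_contrib / len(jierps)
    valid = (frac >= min_subject_fraction) & (n_contrib > 0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        amplitude = np.nanmean(stack, axis=0)
    amplitude[~valid] = np.nan
    return JierpTensor(
        amplitude=amplitude,
        trial_count=np.stack([j.trial_count for j in jierps]).sum(axis=0),
        valid=valid,
        time_ms=ref.time_ms,
        grid=ref.grid,
        min_trials=ref.min_trials,
        meta={
            "axis_convention": AXIS_CONVENTION,
            "n_subjects": len(jierps),
            "min_subject_fraction": min_subject_fraction,
            "n_contributors": n_contrib,
        },
    )


def zscore_latencywise(jierp: JierpTensor, source: str = "individual") -> ZJierp:
    """Standardise amplitudes across valid bins at each latency.

    Uses the sample SD (ddof=1). Latencies where all valid bins share one
    value get z=0 and are flagged degenerate.
    """
    if jierp.n_valid < 2:
        raise ValueError("z-scoring needs at least 2 valid bins")
    vals = jierp.amplitude[jierp.valid]  # n_valid x T
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    degenerate = sd == 0
    safe_sd = np.where(degenerate, 1.0, sd)
    zv = (vals - mean) / safe_sd
    zv[:, degenerate] = 0.0
    z = np.full_like(jierp.amplitude, np.nan)
    z[jierp.valid] = zv
    return ZJierp(
        z=z,
        valid=jierp.valid.copy(),
        time_ms=jierp.time_ms.copy(),
        source=source,
        degenerate_latencies=degenerate,
        meta={"axis_convention": AXIS_CONVENTION},
    )
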