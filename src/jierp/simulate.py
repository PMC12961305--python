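"""Synthetic tactile-stimulation EEG generator.

Emulates the experimental structure the JIERP analysis assumes: a long train
of brief tactile pulses with inter-stimulus intervals (ISIs) spanning roughly
0.1-10 s, a somatosensory evoked-potential template with alternating-polarity
components near 50/75/100/150/200 ms, and interval-history-dependent gain
modulation applied per processing stage (early 1-75 ms, intermediate
75-150 ms, late 150-300 ms). Every downstream stage of the pipeline is
testable against this generator without any recorded data.

Units: time in ms, amplitudes in microvolts (uV), intervals handed to the
modulation rules in seconds. Sampling rate is fixed at 1 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulationTrain",
    "ErpTemplate",
    "ModulationSpec",
    "ContinuousRecording",
    "generate_train",
    "erp_template",
    "modulation_gain",
    "synthesize_recording",
    "INTERVAL_RANGE_MS",
    "BIN_EDGES_S",
    "LATENCY_WINDOWS_MS",
    "DEFAULT_PEAKS",
    "SRATE",
]

SRATE = 1000.0
INTERVAL_RANGE_MS = (100.0, 10_000.0)
#: Upper bin edges of the joint-interval grid, in seconds.
BIN_EDGES_S = (0.5, 1.0, 2.0, 4.0, 8.0)
#: Processing-stage latency windows, half-open [lo, hi) in ms post-stimulus.
LATENCY_WINDOWS_MS = {
    "early": (1, 75),
    "intermediate": (75, 150),
    "late": (150, 300),
}
#: Default evoked components: (peak latency ms, polarity +/-1, amplitude uV).
DEFAULT_PEAKS = (
    (50.0, +1, 5.0),
    (75.0, -1, 5.0),
    (100.0, +1, 4.0),
    (150.0, -1, 3.0),
    (200.0, +1, 3.0),
)


class ConfigurationError(ValueError):
    """Raised for unknown preset / distribution / window names."""


@dataclass
class StimulationTrain:
    """Timed stimulus events.

    onsets_ms are strictly increasing event times from recording start;
    finger and block are per-event labels (constant within a generated train).
    """

    onsets_ms: np.ndarray
    finger: np.ndarray
    block: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.onsets_ms = np.asarray(self.onsets_ms, dtype=float)
        self.finger = np.asarray(self.finger)
        self.block = np.asarray(self.block, dtype=int)
        if self.onsets_ms.ndim != 1:
            raise ValueError("onsets must be a 1-D array")
        if np.any(np.diff(self.onsets_ms) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if not (len(self.onsets_ms) == len(self.finger) == len(self.block)):
            raise ValueError("onsets, finger and block must have equal length")

    @property
    def n_events(self) -> int:
        return len(self.onsets_ms)

    @property
    def intervals_ms(self) -> np.ndarray:
        return np.diff(self.onsets_ms)


@dataclass
class ErpTemplate:
    """Evoked-response waveform on a ms latency grid starting at 0."""

    latencies_ms: np.ndarray
    amplitude_uv: np.ndarray
    component_peaks: tuple

    @property
    def n_samples(self) -> int:
        return len(self.latencies_ms)


@dataclass
class ContinuousRecording:
    """Multichannel continuous EEG at 1 kHz, in uV."""

    data: np.ndarray  # channels x samples
    srate: float
    channel_labels: list
    events: StimulationTrain
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        last = self.events.onsets_ms[-1] if self.events.n_events else 0.0
        if last >= self.data.shape[1] / self.srate * 1000.0:
            raise ValueError("event onsets fall outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def generate_train(
    n_events: int,
    interval_range_ms: tuple = INTERVAL_RANGE_MS,
    distribution: str = "log-uniform",
    seed: int = 0,
    finger: str = "index",
    block: int = 0,
    start_ms: float = 1000.0,
) -> StimulationTrain:
    """Draw a stimulation train with i.i.d. inter-stimulus intervals.

    The default log-uniform law spreads intervals evenly in log time so the
    quadratic joint-interval bins (upper edges 0.5/1/2/4/8 s) each receive a
    usable number of triads; ``uniform`` is offered as an alternative. The
    true sampling law of the original stimulation protocol is not asserted.

    Parameters
    ----------
    n_events : number of stimuli (>= 3, the minimum for one triad).
    interval_range_ms : inclusive truncation range of the intervals.
    distribution : ``"log-uniform"`` (default) or ``"uniform"``.
    seed : RNG seed; fixed seed reproduces the train exactly.
    """
    if n_events < 3:
        raise ValueError("n_events must be >= 3 (one triad needs 3 events)")
    lo, hi = float(interval_range_ms[0]), float(interval_range_ms[1])
    if not (0 < lo < hi):
        raise ValueError("interval range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(seed)
    if distribution in ("log-uniform", "loguniform"):
        intervals = np.exp(rng.uniform(np.log(lo), np.log(hi), n_events - 1))
    elif distribution == "uniform":
        intervals = rng.uniform(lo, hi, n_events - 1)
    else:
        raise ConfigurationError(
            f"unknown interval distribution {distribution!r}; "
            "expected 'log-uniform' or 'uniform'"
        )
    intervals = np.clip(intervals, lo, hi)
    onsets = start_ms + np.concatenate(([0.0], np.cumsum(intervals)))
    n = len(onsets)
    return StimulationTrain(
        onsets_ms=onsets,
        finger=np.full(n, finger, dtype=object),
        block=np.full(n, block),
        seed=seed,
    )


def erp_template(
    component_peaks: tuple = DEFAULT_PEAKS,
    latency_grid_ms: np.ndarray | None = None,
    width_ms: float = 8.0,
) -> ErpTemplate:
    """Build a smooth evoked waveform as a sum of Gaussian-windowed components.

    Each component contributes ``polarity * amplitude * exp(-(t-peak)^2 /
    (2*width^2))``. With the default 8 ms width the components are narrow
    enough that each configured peak is attained within +-2 ms and +-5%
    amplitude despite overlap. The waveform is pinned to exactly 0 at
    latency 0 (the residual there is ~1e-8 of the peak amplitude).
    """
    if latency_grid_ms is None:
        latency_grid_ms = np.arange(300.0)
    latency_grid_ms = np.asarray(latency_grid_ms, dtype=float)
    peaks = tuple((float(l), int(pol), float(a)) for l, pol, a in component_peaks)
    lats = [p[0] for p in peaks]
    if lats != sorted(lats):
        raise ValueError("component peaks must be sorted by latency")
    for lat, pol, amp in peaks:
        if not (latency_grid_ms[0] <= lat <= latency_grid_ms[-1]):
            raise ValueError(f"peak latency {lat} ms outside the latency grid")
        if pol not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if amp < 0:
            raise ValueError("amplitude must be non-negative")
    wave = np.zeros_like(latency_grid_ms)
    for lat, pol, amp in peaks:
        wave += pol * amp * np.exp(-((latency_grid_ms - lat) ** 2) / (2 * width_ms**2))
    wave -= wave[0]  # exact zero at latency 0
    return ErpTemplate(
        latencies_ms=latency_grid_ms, amplitude_uv=wave, component_peaks=peaks
    )


def _edge_bin(x_s: float) -> int:
    """Bin index of an interval on the joint-interval edges, clamping above 8 s."""
    edges = np.asarray(BIN_EDGES_S)
    return int(min(np.searchsorted(edges, x_s, side="left"), len(edges) - 1))


def _gain_tables(preset: str) -> dict:
    """Per-window 5x5 gain tables; rows index the penultimate-interval bin
    (k-1), columns the previous-interval bin (k)."""
    ones = np.ones((5, 5))
    if preset == "none":
        return {w: ones.copy() for w in LATENCY_WINDOWS_MS}
    if preset == "early_late_suppression":
        # Early and late stages: suppression for previous interval < 0.5 s,
        # enhancement for > 2 s, irrespective of the penultimate interval.
        col = np.array([0.6, 1.0, 1.0, 1.3, 1.3])
        by_k = np.tile(col, (5, 1))
        # Intermediate stage: an independent rule keyed to the penultimate
        # interval instead, so its bin pattern decorrelates from the others.
        by_k1 = np.tile(col[:, None], (1, 5))
        return {"early": by_k, "intermediate": by_k1, "late": by_k.copy()}
    if preset == "diagonal":
        m = np.array([0.6, 0.8, 1.0, 1.2, 1.4])
        i, j = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        table = m[np.minimum(i, j)]
        return {w: table.copy() for w in LATENCY_WINDOWS_MS}
    raise ConfigurationError(f"unknown modulation preset {preset!r}")


@dataclass
class ModulationSpec:
    """Interval-conditioned gain rules, one 5x5 table per latency window."""

    preset: str
    tables: dict

    @classmethod
    def from_preset(cls, preset: str) -> "ModulationSpec":
        return cls(preset=preset, tables=_gain_tables(preset))

    def __post_init__(self) -> None:
        for name, tab in self.tables.items():
            tab = np.asarray(tab, dtype=float)
            if tab.shape != (5, 5) or not np.all(np.isfinite(tab)) or np.any(tab < 0):
                raise ValueError(f"gain table {name!r} must be finite, >=0, 5x5")
            self.tables[name] = tab


def modulation_gain(
    k_s: float, k_minus_1_s: float, latency_window: str, spec: ModulationSpec
) -> float:
    """Multiplicative gain for an event with previous interval ``k_s`` and
    penultimate interval ``k_minus_1_s`` within one latency window."""
    if k_s <= 0 or k_minus_1_s <= 0:
        raise ValueError("intervals must be positive")
    if latency_window not in spec.tables:
        raise ConfigurationError(
            f"unknown latency window {latency_window!r}; "
            f"expected one of {sorted(spec.tables)}"
        )
    row = _edge_bin(k_minus_1_s)
    col = _edge_bin(k_s)
    return float(spec.tables[latency_window][row, col])


def _pink_noise(rng: np.random.Generator, shape: tuple, sd: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit-variance scaled to ``sd``."""
    white = rng.standard_normal(shape)
    f = np.fft.rfftfreq(shape[-1], d=1.0 / SRATE)
    scale = np.where(f > 0, 1.0 / np.sqrt(f), 0.0)
    pink = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=shape[-1], axis=-1)
    pink /= max(pink.std(), 1e-12)
    return sd * pink


def synthesize_recording(
    train: StimulationTrain,
    template: ErpTemplate | None = None,
    spec: ModulationSpec | str = "none",
    n_channels: int = 8,
    noise_sd: float = 1.0,
    seed: int = 0,
    som_channels: tuple = (0,),
    other_scale: float = 0.4,
    noise_color: str = "white",
    channel_labels: list | None = None,
) -> ContinuousRecording:
    """Render a continuous 1 kHz recording from a stimulation train.

    From the third event onward the template is scaled, per latency window,
    by the modulation gain of the event's (previous, penultimate) interval
    pair; the first two events (no triad) receive unit gain. The scaled
    template is added at full amplitude on ``som_channels`` (the designated
    somatosensory sites) and at ``other_scale`` elsewhere. Overlapping
    responses sum linearly. With ``noise_sd=0`` the post-stimulus epoch at an
    isolated event equals the gain-scaled template exactly.
    """
    if train.n_events == 0:
        raise ValueError("train must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if template is None:
        template = erp_template()
    if isinstance(spec, str):
        spec = ModulationSpec.from_preset(spec)

    onset_samples = np.round(train.onsets_ms).astype(int)
    tlen = template.n_samples
    n_samples = int(onset_samples[-1]) + tlen + 200
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        if noise_color == "white":
            data = rng.normal(0.0, noise_sd, (n_channels, n_samples))
        elif noise_color == "pink":
            data = _pink_noise(rng, (n_channels, n_samples), noise_sd)
        else:
            raise ConfigurationError(f"unknown noise_color {noise_color!r}")
    else:
        data = np.zeros((n_channels, n_samples))

    ch_scale = np.full(n_channels, other_scale)
    ch_scale[list(som_channels)] = 1.0

    onsets = train.onsets_ms
    for i, s0 in enumerate(onset_samples):
        wave = template.amplitude_uv.copy()
        if i >= 2:
            k = (onsets[i] - onsets[i - 1]) / 1000.0
            k1 = (onsets[i - 1] - onsets[i - 2]) / 1000.0
            for window, (lo, hi) in LATENCY_WINDOWS_MS.items():
                g = modulation_gain(k, k1, window, spec)
                wave[lo : min(hi, tlen)] *= g
        data[:, s0 : s0 + tlen] += ch_scale[:, None] * wave[None, :]

    if channel_labels is None:
        channel_labels = [
            f"SOM{c}" if c in som_channels else f"CH{c}" for c in range(n_channels)
        ]
    return ContinuousRecording(
        data=data,
        srate=SRATE,
        channel_labels=list(channel_labels),
        events=train,
        meta={
            "preset": spec.preset,
            "noise_sd": noise_sd,
            "noise_color": noise_color,
            "seed": seed,
            "som_channels": tuple(som_channels),
            "other_scale": other_scale,
            "unit": "uV",
        },
    )
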