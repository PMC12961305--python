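"""Structured pipeline configuration.

Every default mirrors the analysis constants of the study protocol: epoch
window -200..299 ms, +-80 uV rejection, baseline -200..-50 ms, joint-interval
upper edges 0.5/1/2/4/8 s, 10-trial bin validity, alpha 0.05, 25 ms
cross-correlation exclusion band, NNMF rank search 2-10, k-means cluster
search 3-7.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # --- synthetic input (used when no recordings are supplied) ---
    n_subjects: int = 5
    n_events: int = 600
    interval_range_ms: tuple = (100.0, 10_000.0)
    interval_distribution: str = "log-uniform"
    preset: str = "early_late_suppression"
    noise_sd_uv: float = 2.0
    n_channels: int = 8

    # --- preprocessing ---
    filter_low_hz: float = 1.0
    filter_high_hz: float = 45.0
    two_stage_filter: bool = False  # prepend the 0.1-75 Hz stage
    apply_filter: bool = True
    epoch_window_ms: tuple = (-200, 299)
    reject_uv: float = 80.0
    baseline_ms: tuple = (-200, -50)
    roi: tuple | None = None
    select_window_ms: tuple = (25, 75)
    select_criterion: str = "max"

    # --- JIERP ---
    edges_s: tuple = (0.5, 1.0, 2.0, 4.0, 8.0)
    min_trials: int = 10
    min_subject_fraction: float = 0.8

    # --- statistics ---
    alpha: float = 0.05
    fdr_method: str = "bh"
    band_halfwidth_ms: float = 25.0

    # --- factorization & clustering ---
    rank_range: tuple = (2, 10)
    n_reps: int = 100
    k_range: tuple = (3, 7)
    n_restarts: int = 1000

    # --- bookkeeping ---
    seed: int = 0
    finger: str = "index"
    input_paths: tuple = ()
    events_paths: tuple = ()
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in known.items():
            if isinstance(value, list):
                known[key] = tuple(value)
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)
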