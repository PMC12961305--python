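"""Readers and writers for the pipeline's on-disk formats.

TSV is the canonical event interchange (columns: onset_ms, finger, block);
recordings, epochs, JIERPs, statistics and factorizations are stored in
plain HDF5 containers with the layouts documented per function. BrainVision
and EDF recordings are read through mne. Every writer can stamp a config
hash into the container so stages from different configurations are never
mixed silently.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import BinGrid, JierpTensor
from .preprocess import EpochSet
from .simulate import ContinuousRecording, StimulationTrain

__all__ = [
    "read_events",
    "write_events",
    "read_recording",
    "write_recording",
    "read_epochs",
    "write_epochs",
    "read_jierp",
    "write_jierp",
    "check_config_hash",
]

logger = logging.getLogger(__name__)

_EVENT_COLUMNS = ("onset_ms", "finger", "block")


def read_events(path) -> StimulationTrain:
    """Parse an events TSV into a stimulation train.

    Malformed rows (non-numeric onset or block) are rejected with their line
    numbers logged; non-monotone onsets raise, naming the offending line.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} missing columns {missing}")
    onset = pd.to_numeric(df["onset_ms"], errors="coerce")
    block = pd.to_numeric(df["block"], errors="coerce")
    bad = onset.isna() | block.isna() | df["finger"].isna()
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        logger.warning("read_events: rejected malformed lines %s", lines)
    df = df[~bad]
    onset = onset[~bad].to_numpy(dtype=float)
    diffs = np.diff(onset)
    if np.any(diffs <= 0):
        line = int(df.index[np.nonzero(diffs <= 0)[0][0] + 1]) + 2
        raise ValueError(f"non-monotone onset at line {line} of {path}")
    return StimulationTrain(
        onsets_ms=onset,
        finger=df["finger"].to_numpy(dtype=object),
        block=block[~bad].to_numpy(dtype=int),
    )


def write_events(train: StimulationTrain, path) -> None:
    pd.DataFrame(
        {
            "onset_ms": train.onsets_ms,
            "finger": train.finger,
            "block": train.block,
        }
    ).to_csv(path, sep="\t", index=False)


def write_recording(
    recording: ContinuousRecording, path, config_hash: str | None = None
) -> None:
    """HDF5 layout: /data (channels x samples, uV), /srate, /channel_labels."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f["data"].attrs["unit"] = "uV"
        f.create_dataset("srate", data=recording.srate)
        f.create_dataset(
            "channel_labels",
            data=np.array(recording.channel_labels, dtype="S"),
        )
        f.create_dataset("events/onset_ms", data=recording.events.onsets_ms)
        f.create_dataset(
            "events/finger",
            data=np.array(recording.events.finger, dtype="S"),
        )
        f.create_dataset("events/block", data=recording.events.block)
        f.attrs["meta"] = json.dumps(recording.meta, default=str)
        if config_hash:
            f.attrs["config_hash"] = config_hash


def _read_hdf5_recording(path, events: StimulationTrain | None) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        srate = float(np.asarray(f["srate"][()]))
        labels = [s.decode() for s in f["channel_labels"][()]]
        meta = json.loads(f.attrs.get("meta", "{}"))
        embedded = None
        if "events" in f:
            embedded = StimulationTrain(
                onsets_ms=f["events/onset_ms"][()],
                finger=np.array([s.decode() for s in f["events/finger"][()]], dtype=object),
                block=f["events/block"][()],
            )
    if events is not None and embedded is not None:
        logger.warning("read_recording: external events TSV overrides embedded markers")
    train = events if events is not None else embedded
    if train is None:
        raise ValueError(f"{path} has no embedded events and none were supplied")
    return ContinuousRecording(
        data=data, srate=srate, channel_labels=labels, events=train, meta=meta
    )


def _read_mne_recording(path, events: StimulationTrain | None) -> ContinuousRecording:
    import mne

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads volts
    embedded = None
    try:
        ann = raw.annotations
        if len(ann):
            onsets = np.asarray(ann.onset) * 1000.0
            embedded = StimulationTrain(
                onsets_ms=onsets,
                finger=np.full(len(onsets), "unknown", dtype=object),
                block=np.zeros(len(onsets), dtype=int),
            )
    except Exception:  # pragma: no cover - marker-less files
        embedded = None
    if events is not None and embedded is not None:
        logger.warning("read_recording: external events TSV overrides embedded markers")
    train = events if events is not None else embedded
    if train is None:
        raise ValueError(f"{path} has no usable markers and no events TSV was supplied")
    return ContinuousRecording(
        data=data_uv,
        srate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=train,
        meta={"source": str(path), "original_unit": "V"},
    )


def read_recording(path, events_path=None) -> ContinuousRecording:
    """Load a recording from HDF5 (.h5/.hdf5), BrainVision (.vhdr) or EDF.

    Data are returned in uV. If ``events_path`` is given, its TSV events
    take precedence over any embedded markers (logged).
    """
    path = Path(path)
    events = read_events(events_path) if events_path is not None else None
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return _read_hdf5_recording(path, events)
    if suffix in (".vhdr", ".edf"):
        return _read_mne_recording(path, events)
    raise ValueError(
        f"unsupported recording format {suffix!r}; "
        "supported: .h5/.hdf5, .vhdr (BrainVision), .edf"
    )


def write_epochs(epochs: EpochSet, path, config_hash: str | None = None) -> None:
    """HDF5 layout: /epochs, /time_ms, /rejected, /event_index."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.epochs)
        f.create_dataset("time_ms", data=epochs.time_ms)
        f.create_dataset("rejected", data=epochs.rejected)
        f.create_dataset("event_index", data=epochs.event_index)
        f.create_dataset(
            "channel_labels", data=np.array(epochs.channel_labels, dtype="S")
        )
        f.create_dataset("srate", data=epochs.srate)
        f.attrs["meta"] = json.dumps(epochs.meta, default=str)
        if config_hash:
            f.attrs["config_hash"] = config_hash


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            epochs=f["epochs"][()],
            time_ms=f["time_ms"][()],
            event_index=f["event_index"][()],
            rejected=f["rejected"][()],
            channel_labels=[s.decode() for s in f["channel_labels"][()]],
            srate=float(np.asarray(f["srate"][()])),
            meta=json.loads(f.attrs.get("meta", "{}")),
        )


def write_jierp(jierp: JierpTensor, path, config_hash: str | None = None) -> None:
    """HDF5 layout: /jierp/{amplitude,trial_count,valid,time_ms,edges_s}."""
    with h5py.File(path, "w") as f:
        g = f.create_group("jierp")
        g.create_dataset("amplitude", data=jierp.amplitude)
        g.create_dataset("trial_count", data=jierp.trial_count)
        g.create_dataset("valid", data=jierp.valid)
        g.create_dataset("time_ms", data=jierp.time_ms)
        g.create_dataset("edges_s", data=np.asarray(jierp.grid.upper_edges_s))
        g.attrs["min_trials"] = jierp.min_trials
        f.attrs["meta"] = json.dumps(jierp.meta, default=str)
        if config_hash:
            f.attrs["config_hash"] = config_hash


def read_jierp(path) -> JierpTensor:
    with h5py.File(path, "r") as f:
        g = f["jierp"]
        return JierpTensor(
            amplitude=g["amplitude"][()],
            trial_count=g["trial_count"][()],
            valid=g["valid"][()],
            time_ms=g["time_ms"][()],
            grid=BinGrid(tuple(float(e) for e in g["edges_s"][()])),
            min_trials=int(g.attrs["min_trials"]),
            meta=json.loads(f.attrs.get("meta", "{}")),
        )


def check_config_hash(path, expected: str) -> None:
    """Refuse to mix containers produced under different configurations."""
    with h5py.File(path, "r") as f:
        found = f.attrs.get("config_hash")
    if found is not None and found != expected:
        raise ValueError(
            f"{path} was produced under config hash {found}, expected {expected}"
        )
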