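"""File I/O for the raw-binary and tabular session formats.

Raw recordings follow the de-facto ``.dat`` convention: little-endian signed
16-bit samples, channel-interleaved (sample 0 of every channel, then sample 1,
...).  All tables are TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import EVENT_COLUMNS, EventTable, IntervalSet, MalformedFileError, Recording, SpikeData

RAW_DTYPE = np.dtype("<i2")

CHANNEL_MAP_COLUMNS = ["id", "shank", "depth_um", "region"]


def read_channel_map(path) -> pd.DataFrame:
    cm = pd.read_csv(path, sep="\t")
    missing = set(CHANNEL_MAP_COLUMNS) - set(cm.columns)
    if missing:
        raise ValueError(f"channel map missing columns: {sorted(missing)}")
    return cm


def write_channel_map(channels: pd.DataFrame, path) -> None:
    channels.to_csv(path, sep="\t", index=False)


def read_binary_recording(path, n_channels: int, fs: float, channel_map: pd.DataFrame, t0: float = 0.0) -> Recording:
    """Read a flat interleaved int16 binary file into a Recording.

    No scaling is applied unless the channel map carries a ``gain`` column
    (µV per count), in which case samples are multiplied per channel.
    """
    raw = np.fromfile(path, dtype=RAW_DTYPE)
    if raw.size % n_channels:
        raise MalformedFileError(
            f"{path}: {raw.size} samples not divisible by {n_channels} channels"
        )
    samples = raw.reshape(-1, n_channels).T.astype(float)
    if "gain" in channel_map.columns:
        samples = samples * channel_map["gain"].to_numpy()[:, None]
    return Recording(samples=samples, fs=fs, channels=channel_map.reset_index(drop=True), t0=t0)


def write_binary_recording(rec: Recording, path) -> None:
    """Write samples as interleaved little-endian int16 (values are rounded)."""
    data = np.round(rec.samples.T).astype(RAW_DTYPE)
    data.tofile(path)


def read_events(path) -> EventTable:
    with open(path) as fh:
        first = fh.readline()
    kind = first.removeprefix("# kind=").strip() if first.startswith("# kind=") else "event"
    ev = pd.read_csv(path, sep="\t", comment="#")
    return EventTable(kind=kind, events=ev[EVENT_COLUMNS] if len(ev) else ev)


def write_events(table: EventTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind={table.kind}\n")
        table.events.to_csv(fh, sep="\t", index=False)


def read_spike_data(spikes_path, units_path) -> SpikeData:
    spikes = pd.read_csv(spikes_path, sep="\t")
    units = pd.read_csv(units_path, sep="\t")
    return SpikeData(spikes=spikes, units=units)


def write_spike_data(sd: SpikeData, spikes_path, units_path) -> None:
    sd.spikes.to_csv(spikes_path, sep="\t", index=False)
    sd.units.to_csv(units_path, sep="\t", index=False)


def read_intervals(path) -> IntervalSet:
    return IntervalSet(intervals=pd.read_csv(path, sep="\t"))


def write_intervals(iv: IntervalSet, path) -> None:
    iv.intervals.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
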