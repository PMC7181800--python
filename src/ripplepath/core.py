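"""Domain containers and basic LFP preprocessing.

Times are seconds (float) everywhere outside raw files; sample indexing is
0-based; intervals are half-open ``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

REGIONS = ("CA1", "SUB", "gRSC_sup", "gRSC_deep", "other")

EVENT_COLUMNS = ["onset_s", "peak_s", "offset_s", "amplitude", "channel"]


class MalformedFileError(ValueError):
    """Raw binary file does not match the declared channel layout."""


class InsufficientDataError(ValueError):
    """Not enough events/spikes/channels to compute the statistic."""


@dataclass
class Recording:
    """Multichannel extracellular signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_time)
        Signal values in µV or arbitrary units (amplitude calibration is
        treated as opaque).
    fs : float
        Sampling rate in Hz.
    channels : DataFrame with columns id, shank, depth_um, region
        One row per channel, aligned with the rows of ``samples``.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    channels: pd.DataFrame
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel table length must equal sample rows")
        if self.channels["id"].duplicated().any():
            raise ValueError("channel ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, channel_id: int) -> np.ndarray:
        """Return the trace of the channel with the given id."""
        idx = np.flatnonzero(self.channels["id"].to_numpy() == channel_id)
        if idx.size == 0:
            raise KeyError(f"no channel with id {channel_id}")
        return self.samples[idx[0]]


@dataclass
class SpikeData:
    """Sorted spike times with per-unit metadata.

    ``spikes`` has columns (time_s, unit_id); ``units`` has columns
    (unit_id, region, layer, mean_rate_hz, trough_to_peak_ms, asymmetry,
    type).  Spike times are non-decreasing within each unit.
    """

    spikes: pd.DataFrame
    units: pd.DataFrame

    def __post_init__(self) -> None:
        known = set(self.units["unit_id"])
        present = set(self.spikes["unit_id"].unique())
        if not present <= known:
            raise ValueError("spike table references unknown unit ids")

    def unit_times(self, unit_id: int) -> np.ndarray:
        t = self.spikes.loc[self.spikes["unit_id"] == unit_id, "time_s"].to_numpy()
        return np.sort(t)

    def select_units(self, unit_ids) -> "SpikeData":
        unit_ids = list(unit_ids)
        units = self.units[self.units["unit_id"].isin(unit_ids)].reset_index(drop=True)
        spikes = self.spikes[self.spikes["unit_id"].isin(unit_ids)].reset_index(drop=True)
        return SpikeData(spikes=spikes, units=units)

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass
class EventTable:
    """Typed events with onset/peak/offset times and peak amplitudes."""

    kind: str
    events: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ev = self.events
        if len(ev):
            if not ((ev["onset_s"] <= ev["peak_s"]) & (ev["peak_s"] <= ev["offset_s"])).all():
                raise ValueError("need onset <= peak <= offset per event")
            if not ev["onset_s"].is_monotonic_increasing:
                self.events = ev.sort_values("onset_s").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return self.events["onset_s"].to_numpy()

    @property
    def peaks(self) -> np.ndarray:
        return self.events["peak_s"].to_numpy()

    @property
    def offsets(self) -> np.ndarray:
        return self.events["offset_s"].to_numpy()


@dataclass
class IntervalSet:
    """Labelled half-open intervals [start_s, stop_s)."""

    intervals: pd.DataFrame  # columns: start_s, stop_s, label

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and not (iv["start_s"] < iv["stop_s"]).all():
            raise ValueError("intervals need start < stop")

    def __len__(self) -> int:
        return len(self.intervals)

    def total_duration(self, label: str | None = None) -> float:
        iv = self.intervals
        if label is not None:
            iv = iv[iv["label"] == label]
        return float((iv["stop_s"] - iv["start_s"]).sum())

    def contains(self, times: np.ndarray, label: str | None = None) -> np.ndarray:
        """Boolean mask: which times fall inside an interval (of the label)."""
        times = np.asarray(times, dtype=float)
        mask = np.zeros(times.shape, dtype=bool)
        iv = self.intervals
        if label is not None:
            iv = iv[iv["label"] == label]
        for start, stop in zip(iv["start_s"], iv["stop_s"]):
            mask |= (times >= start) & (times < stop)
        return mask

    def label_at(self, times: np.ndarray, default: str = "unlabelled") -> np.ndarray:
        times = np.asarray(times, dtype=float)
        out = np.full(times.shape, default, dtype=object)
        for start, stop, label in self.intervals.itertuples(index=False):
            out[(times >= start) & (times < stop)] = label
        return out


# ---------------------------------------------------------------------------
# Preprocessing


def resample_lfp(rec: Recording, target_fs: float, cutoff_hz: float = 450.0) -> Recording:
    """Anti-aliased resampling with a windowed-sinc low-pass.

    The signal is low-pass filtered at ``cutoff_hz`` (default 450 Hz) with a
    linear-phase FIR sinc kernel before polyphase decimation, so frequencies
    below the cutoff survive and everything near/above the new Nyquist is
    suppressed.
    """
    if target_fs >= rec.fs:
        raise ValueError("target_fs must be below the current sampling rate")
    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    # Kernel designed at the upsampled rate; long enough for a steep sinc rolloff.
    fs_up = rec.fs * up
    numtaps = int(10 * fs_up / cutoff_hz) | 1
    h = signal.firwin(numtaps, cutoff_hz, fs=fs_up)
    out = signal.resample_poly(rec.samples, up, down, axis=-1, window=h * up)
    return Recording(samples=out, fs=rec.fs * up / down, channels=rec.channels.copy(), t0=rec.t0)


def bandpass_zero_phase(
    trace: np.ndarray, fs: float, low: float, high: float, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward and reverse application).

    The effective magnitude response is the squared single-pass response;
    net phase shift is zero.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={fs / 2}) Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float), axis=-1)


def lowpass_zero_phase(trace: np.ndarray, fs: float, cutoff: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass."""
    if not (0 < cutoff < fs / 2):
        raise ValueError("cutoff outside (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float), axis=-1)
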