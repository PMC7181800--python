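"""Brain-state analysis: population packets, state index, EMG, segmentation.

The awake cortical population alternates between a synchronized regime —
brief activity packets (3-10 Hz) surrounded by near-silence — and a
desynchronized regime of tonic firing.  The state index (SI) is the
fraction of nonzero 1-ms population spike-count bins within a 0.5 s moving
window: near-silent packet troughs pull it down, tonic firing keeps it up.
Desynchronized epochs are further split by muscular activity estimated from
the LFP itself (shared 300-600 Hz power across channels).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .core import EventTable, InsufficientDataError, IntervalSet, Recording, SpikeData, bandpass_zero_phase

__all__ = [
    "smoothed_mua",
    "detect_packets",
    "state_index",
    "emg_from_lfp",
    "histogram_valley",
    "segment_states",
]

MUA_BIN_S = 0.001  # 1 ms population-count bins throughout


def smoothed_mua(
    spikedata: SpikeData,
    duration: float,
    gaussian_sd_s: float = 0.03,
    min_units: int = 16,
):
    """Gaussian-smoothed multi-unit population rate.

    All units' spikes are pooled into 1-ms bins and convolved with a
    Gaussian kernel (default SD 30 ms).  Sessions with fewer than
    ``min_units`` units are refused (packet structure is not interpretable
    from a handful of units).

    Returns (times, rate_hz, counts) where ``counts`` are the raw 1-ms bins.
    """
    if spikedata.n_units < min_units:
        raise InsufficientDataError(
            f"packet analysis needs at least {min_units} units, got {spikedata.n_units}"
        )
    n_bins = int(round(duration / MUA_BIN_S))
    t = spikedata.spikes["time_s"].to_numpy()
    counts = np.histogram(t, bins=n_bins, range=(0, duration))[0].astype(float)
    sd_bins = gaussian_sd_s / MUA_BIN_S
    rate = gaussian_filter1d(counts, sd_bins, mode="nearest", truncate=4.0) / MUA_BIN_S
    times = (np.arange(n_bins) + 0.5) * MUA_BIN_S
    return times, rate, counts


def detect_packets(
    rate: np.ndarray,
    fs: float = 1.0 / MUA_BIN_S,
    local_window_s: float = 10.0,
    min_duration_s: float = 0.025,
    peak_excess: float = 0.6,
    trough_frac: float = 0.2,
    merge_gap_s: float = 0.015,
    flank_search_s: float = 1.0,
) -> EventTable:
    """Detect population activity packets in a smoothed MUA rate series.

    A packet is an epoch where the rate exceeds the local average (centred
    10 s window) by at least 60% for at least 25 ms, flanked on both sides
    (within 1 s) by troughs below 20% of the local average lasting at least
    25 ms.  Packets closer than 15 ms (peak to peak) are merged.  All
    criteria are relative to the local average, so detection is invariant
    to rescaling of the rate.
    """
    rate = np.asarray(rate, dtype=float)
    if rate.size < local_window_s * fs:
        raise ValueError("series must be at least one local window long")
    local = uniform_filter1d(rate, int(local_window_s * fs), mode="nearest")
    min_len = int(round(min_duration_s * fs))
    flank = int(round(flank_search_s * fs))

    def runs(mask):
        d = np.diff(mask.astype(int))
        starts = np.flatnonzero(d == 1) + 1
        stops = np.flatnonzero(d == -1) + 1
        if mask[0]:
            starts = np.r_[0, starts]
        if mask[-1]:
            stops = np.r_[stops, mask.size]
        keep = (stops - starts) >= min_len
        return starts[keep], stops[keep]

    hi_s, hi_e = runs(rate > (1.0 + peak_excess) * local)
    lo_s, lo_e = runs(rate < trough_frac * local)

    rows = []
    for s, e in zip(hi_s, hi_e):
        left_ok = np.any((lo_e <= s) & (lo_e >= s - flank)) or np.any((lo_s < s) & (lo_e > s))
        right_ok = np.any((lo_s >= e) & (lo_s <= e + flank)) or np.any((lo_s < e) & (lo_e > e))
        if not (left_ok and right_ok):
            continue
        pk = s + int(np.argmax(rate[s:e]))
        rows.append(dict(onset_s=s / fs, peak_s=pk / fs, offset_s=e / fs,
                         amplitude=float(rate[pk]), channel=-1))
    # merge peaks closer than the merge gap, keeping the envelope of both
    merged: list[dict] = []
    for r in rows:
        if merged and r["peak_s"] - merged[-1]["peak_s"] < merge_gap_s:
            prev = merged[-1]
            prev["offset_s"] = max(prev["offset_s"], r["offset_s"])
            if r["amplitude"] > prev["amplitude"]:
                prev["amplitude"], prev["peak_s"] = r["amplitude"], r["peak_s"]
        else:
            merged.append(r)
    ev = pd.DataFrame(merged, columns=["onset_s", "peak_s", "offset_s", "amplitude", "channel"])
    return EventTable(kind="packet", events=ev,
                      params=dict(peak_excess=peak_excess, trough_frac=trough_frac,
                                  min_duration_s=min_duration_s))


def state_index(counts: np.ndarray, window_s: float = 0.5, fs: float = 1.0 / MUA_BIN_S) -> np.ndarray:
    """State index: moving-window fraction of nonzero 1-ms count bins."""
    counts = np.asarray(counts)
    win = int(round(window_s * fs))
    if win > counts.size:
        raise ValueError("window longer than the series")
    return uniform_filter1d((counts > 0).astype(float), win, mode="nearest")


def emg_from_lfp(
    rec: Recording,
    band: tuple = (300.0, 600.0),
    window_s: float = 0.5,
    step_s: float = 0.25,
):
    """EMG proxy: windowed zero-lag correlation of high-band-passed channels.

    The 300-600 Hz band of the LFP is dominated by volume-conducted muscle
    activity shared across recording sites; its mean pairwise correlation
    over 0.5 s windows tracks muscular tone.

    Returns (window_centre_times, emg_values).
    """
    if rec.n_channels < 2:
        raise InsufficientDataError("EMG extraction needs at least 2 channels")
    filt = bandpass_zero_phase(rec.samples, rec.fs, band[0], band[1], order=4)
    win = int(round(window_s * rec.fs))
    step = max(int(round(step_s * rec.fs)), 1)
    starts = np.arange(0, rec.n_samples - win + 1, step)
    iu = np.triu_indices(rec.n_channels, k=1)
    vals = np.empty(starts.size)
    for i, s in enumerate(starts):
        seg = filt[:, s : s + win]
        sd = seg.std(axis=1)
        if np.any(sd == 0):
            vals[i] = 0.0
            continue
        c = np.corrcoef(seg)
        vals[i] = c[iu].mean()
    times = (starts + win / 2) / rec.fs
    return times, vals


def histogram_valley(values: np.ndarray, n_bins: int = 100, smooth_bins: float = 3.0):
    """Cutoff at the deepest interior minimum between the two largest modes.

    Returns None when the smoothed density is unimodal.
    """
    values = np.asarray(values, dtype=float)
    hist, edges = np.histogram(values, bins=n_bins)
    dens = gaussian_filter1d(hist.astype(float), smooth_bins, mode="nearest")
    centers = (edges[:-1] + edges[1:]) / 2
    interior = np.arange(1, n_bins - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    peaks = interior[is_max & (dens[interior] > 0)]
    if peaks.size < 2:
        return None
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(top2)
    if hi - lo < 2:
        return None
    seg = dens[lo + 1 : hi]
    valley = lo + 1 + int(np.argmin(seg))
    if dens[valley] >= 0.9 * min(dens[lo], dens[hi]):
        return None  # no real dip between the modes
    return float(centers[valley])


def segment_states(
    si_times: np.ndarray,
    si: np.ndarray,
    emg_times: np.ndarray,
    emg: np.ndarray,
    min_duration_s: float = 2.0,
    si_fallback: float = 0.5,
    emg_fallback: float = 0.4,
) -> IntervalSet:
    """Segment the session into synchronized / desynchronized(±EMG) states.

    Cutoffs are placed at the valley of the bimodal SI and EMG
    distributions; if a distribution is unimodal, a fixed fallback cutoff
    is used with a warning.  Low SI marks the synchronized (packet) regime;
    desynchronized time is split by the EMG cutoff.  Intervals shorter than
    ``min_duration_s`` are absorbed into their predecessor.
    """
    emg_i = np.interp(si_times, emg_times, emg)
    si_thr = histogram_valley(si)
    if si_thr is None:
        warnings.warn("SI distribution unimodal; using fallback cutoff")
        si_thr = si_fallback
    emg_thr = histogram_valley(emg_i)
    if emg_thr is None:
        warnings.warn("EMG distribution unimodal; using fallback cutoff")
        emg_thr = emg_fallback
    labels = np.where(si < si_thr, "synchronized",
                      np.where(emg_i >= emg_thr, "desync_highEMG", "desync_lowEMG"))
    # run-length encode and absorb short intervals
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.r_[0, change, labels.size]
    rows = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        start = si_times[s] if s else 0.0
        stop = si_times[e - 1] + (si_times[1] - si_times[0]) if e < labels.size else si_times[-1]
        rows.append([start, stop, labels[s]])
    merged: list[list] = []
    for row in rows:
        if merged and (row[1] - row[0]) < min_duration_s:
            merged[-1][1] = row[1]
        elif merged and merged[-1][2] == row[2]:
            merged[-1][1] = row[1]
        else:
            merged.append(row)
    return IntervalSet(pd.DataFrame(merged, columns=["start_s", "stop_s", "label"]))
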