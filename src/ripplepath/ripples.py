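"""Ripple and negative-wave detection, and event-level coupling statistics.

Ripples are detected on a single channel: the LFP is band-passed at
100-280 Hz with a zero-phase 2nd-order Butterworth filter, rectified, and
smoothed with a Savitzky-Golay filter.  Events are epochs where the smoothed
envelope exceeds its mean by 2 SD while the filtered trace exceeds its mean
by 4 SD, lasting at least 20 ms; of two events whose peaks are closer than
40 ms, the smaller-amplitude one is discarded.  Because the thresholds are
in SD units, detection is invariant to rescaling of the trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .core import EventTable, InsufficientDataError, bandpass_zero_phase, lowpass_zero_phase

__all__ = [
    "RippleParams",
    "ripple_envelope",
    "detect_ripples",
    "ripple_shape_stats",
    "adaptive_negative_wave_template",
    "detect_negative_waves",
    "event_ccg",
    "ripple_power_coupling",
    "peak_power_lags",
]

MIN_EVENTS_FOR_SESSION = 100


@dataclass
class RippleParams:
    band: tuple = (100.0, 280.0)
    filter_order: int = 2
    smooth_window_ms: float = 11.0
    smooth_polyorder: int = 2
    thresh_smoothed_sd: float = 2.0
    thresh_filtered_sd: float = 4.0
    min_duration_ms: float = 20.0
    merge_peak_gap_ms: float = 40.0
    min_events_for_session: int = MIN_EVENTS_FOR_SESSION


def ripple_envelope(trace: np.ndarray, fs: float, params: RippleParams | None = None):
    """Return (filtered, smoothed rectified envelope) of the ripple band."""
    params = params or RippleParams()
    low, high = params.band
    if high >= fs / 2:
        raise ValueError(f"ripple band {params.band} incompatible with fs={fs}")
    filt = bandpass_zero_phase(trace, fs, low, high, order=params.filter_order)
    win = max(int(round(params.smooth_window_ms / 1000 * fs)) | 1, params.smooth_polyorder + 2)
    if win % 2 == 0:
        win += 1
    env = signal.savgol_filter(np.abs(filt), win, params.smooth_polyorder)
    return filt, env


def _merge_close_events(rows: list[dict], gap_s: float) -> list[dict]:
    """Drop the smaller-amplitude event of any peak pair closer than the gap.

    Applied to exhaustion, so the result is idempotent and independent of
    input order.
    """
    rows = sorted(rows, key=lambda r: r["peak_s"])
    changed = True
    while changed:
        changed = False
        for i in range(len(rows) - 1):
            if rows[i + 1]["peak_s"] - rows[i]["peak_s"] < gap_s:
                drop = i if rows[i]["amplitude"] < rows[i + 1]["amplitude"] else i + 1
                rows.pop(drop)
                changed = True
                break
    return rows


def detect_ripples(trace: np.ndarray, fs: float, params: RippleParams | None = None) -> EventTable:
    """Detect ripple events on one channel (see module docstring for the rule)."""
    params = params or RippleParams()
    if trace.size < fs:
        raise ValueError("need at least 1 s of signal")
    filt, env = ripple_envelope(trace, fs, params)
    thr_env = env.mean() + params.thresh_smoothed_sd * env.std()
    thr_filt = filt.mean() + params.thresh_filtered_sd * filt.std()

    above = env > thr_env
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]

    min_len = params.min_duration_ms / 1000 * fs
    rows = []
    for s, e in zip(starts, stops):
        if e - s < min_len:
            continue
        if filt[s:e].max() <= thr_filt:
            continue
        pk = s + int(np.argmax(env[s:e]))
        rows.append(
            dict(onset_s=s / fs, peak_s=pk / fs, offset_s=e / fs,
                 amplitude=float(env[pk]), channel=0)
        )
    rows = _merge_close_events(rows, params.merge_peak_gap_ms / 1000)
    ev = pd.DataFrame(rows, columns=["onset_s", "peak_s", "offset_s", "amplitude", "channel"])
    return EventTable(kind="ripple", events=ev, params=vars(params).copy() if hasattr(params, "__dict__") else {})


def ripple_shape_stats(events: EventTable, filtered: np.ndarray, fs: float) -> pd.DataFrame:
    """Per-event duration (ms), cycle count and peak power.

    The cycle count is the number of positive peaks of the band-passed trace
    above half the event's peak amplitude between onset and offset.
    """
    out = []
    for row in events.events.itertuples(index=False):
        s = int(round(row.onset_s * fs))
        e = int(round(row.offset_s * fs))
        if s < 0 or e > filtered.size:
            raise IndexError("event outside trace")
        seg = filtered[s:e]
        if seg.size == 0:
            out.append((0.0, 0, 0.0))
            continue
        amp = np.abs(seg).max()
        pk_idx, _ = signal.find_peaks(seg, height=amp / 2)
        out.append(((row.offset_s - row.onset_s) * 1000, int(pk_idx.size), float(amp**2)))
    return pd.DataFrame(out, columns=["duration_ms", "n_cycles", "peak_power"])


def adaptive_negative_wave_template(
    trace: np.ndarray, fs: float, n_waves: int = 50, lowpass_hz: float = 30.0,
    half_width_s: float = 0.05,
) -> np.ndarray:
    """Session-adaptive template: mean of the largest low-pass negative deflections."""
    lp = lowpass_zero_phase(trace, fs, lowpass_hz)
    half = int(round(half_width_s * fs))
    troughs, props = signal.find_peaks(-lp, distance=2 * half)
    if troughs.size == 0:
        raise ValueError("no negative deflections found")
    order = np.argsort(lp[troughs])[:n_waves]
    segs = []
    for idx in troughs[order]:
        if half <= idx < lp.size - half:
            segs.append(lp[idx - half : idx + half + 1])
    return np.mean(segs, axis=0)


def detect_negative_waves(
    trace: np.ndarray, fs: float, template: np.ndarray, threshold_rms: float = 1.0
) -> EventTable:
    """Template-matching detection of negative LFP waves.

    The zero-mean template is cross-correlated with the trace; events are
    local maxima of the matched-filter output exceeding ``threshold_rms``
    times its RMS.  The event peak is the most negative trace sample within
    the template window; detection is sign-sensitive (polarity-inverted
    waves produce negative matched-filter output and are not detected).
    """
    template = np.asarray(template, dtype=float)
    tz = template - template.mean()
    scale = np.linalg.norm(tz)
    if scale == 0:
        raise ValueError("degenerate (flat) template")
    tz = tz / scale
    m = np.correlate(trace, tz, mode="same")
    rms = np.sqrt(np.mean(m**2))
    half = template.size // 2
    pk_idx, _ = signal.find_peaks(m, height=threshold_rms * rms, distance=max(half, 1))
    rows = []
    for idx in pk_idx:
        lo = max(idx - half, 0)
        hi = min(idx + half + 1, trace.size)
        trough = lo + int(np.argmin(trace[lo:hi]))
        if trace[trough] >= 0:
            continue  # matched-filter sidelobe, not a negative deflection
        rows.append(
            dict(onset_s=lo / fs, peak_s=trough / fs, offset_s=(hi - 1) / fs,
                 amplitude=float(-trace[trough]), channel=0)
        )
    ev = pd.DataFrame(rows, columns=["onset_s", "peak_s", "offset_s", "amplitude", "channel"])
    return EventTable(kind="negative_wave", events=ev, params={"threshold_rms": threshold_rms})


def _ccg_counts(ref: np.ndarray, targ: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts = np.zeros(edges.size - 1)
    half = max(abs(edges[0]), abs(edges[-1]))
    j0 = 0
    for r in ref:
        lags = targ[(targ >= r - half) & (targ <= r + half)] - r
        counts += np.histogram(lags, bins=edges)[0]
    return counts


def event_ccg(
    reference: EventTable,
    target: EventTable,
    binsize: float = 0.01,
    halfwindow: float = 0.5,
    n_jitter: int = 200,
    rng: np.random.Generator | None = None,
):
    """Event cross-correlogram with jitter-based 95% confidence bands.

    Target peaks are counted in lag bins relative to each reference peak;
    the null bands come from ``n_jitter`` surrogates in which each target
    time is jittered uniformly within ±halfwindow.
    """
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    if len(reference) == 0 or len(target) == 0:
        raise InsufficientDataError("both event tables must be non-empty")
    rng = rng or np.random.default_rng()
    edges = np.arange(-halfwindow, halfwindow + binsize / 2, binsize)
    lags = (edges[:-1] + edges[1:]) / 2
    ref, targ = reference.peaks, np.sort(target.peaks)
    counts = _ccg_counts(ref, targ, edges)
    sur = np.empty((n_jitter, lags.size))
    for i in range(n_jitter):
        jittered = np.sort(targ + rng.uniform(-halfwindow, halfwindow, targ.size))
        sur[i] = _ccg_counts(ref, jittered, edges)
    lo, hi = np.percentile(sur, [2.5, 97.5], axis=0)
    return lags, counts, (lo, hi)


def ripple_power_coupling(
    events: EventTable, power_a: np.ndarray, power_b: np.ndarray, fs: float,
    window_s: float = 0.02,
):
    """Relation between per-event peak ripple-band power in two regions.

    Returns (slope, spearman_rho, per-event powers) where the slope is the
    least-squares fit of B on A and rho the rank correlation.
    """
    if len(events) < 3:
        raise InsufficientDataError("need at least 3 events")
    w = int(round(window_s * fs))
    pa, pb = [], []
    for pk in events.peaks:
        i = int(round(pk * fs))
        lo, hi = max(i - w, 0), min(i + w + 1, power_a.size)
        pa.append(power_a[lo:hi].max())
        pb.append(power_b[lo:hi].max())
    pa, pb = np.asarray(pa), np.asarray(pb)
    if np.ptp(pa) == 0:
        slope = 0.0
    else:
        slope = float(np.polyfit(pa, pb, 1)[0])
    rho = float(stats.spearmanr(pa, pb).statistic) if np.ptp(pb) > 0 and np.ptp(pa) > 0 else 0.0
    return slope, rho, (pa, pb)


def peak_power_lags(
    reference: EventTable, target_envelope: np.ndarray, fs: float, search_window_s: float = 0.025
):
    """Per-event lag of the target ripple-envelope maximum near each reference peak.

    Returns (lags_ms, median_ms, sem_ms).  The search window is clipped at
    the trace edges.
    """
    w = int(round(search_window_s * fs))
    lags = []
    for pk in reference.peaks:
        i = int(round(pk * fs))
        lo, hi = max(i - w, 0), min(i + w + 1, target_envelope.size)
        if hi <= lo:
            continue
        j = lo + int(np.argmax(target_envelope[lo:hi]))
        lags.append((j - i) / fs * 1000)
    lags = np.asarray(lags)
    if lags.size == 0:
        raise InsufficientDataError("no events inside trace")
    median = float(np.median(lags))
    sem = float(lags.std(ddof=1) / np.sqrt(lags.size)) if lags.size > 1 else 0.0
    return lags, median, sem
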