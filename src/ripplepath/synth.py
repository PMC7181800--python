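"""Synthetic two-region sessions with ground truth.

Emulates the phenomenology of awake head-fixed recordings from dorsal
hippocampus (CA1) and granular retrosplenial cortex (gRSC):

* CA1 LFP: 1/f (pink) background with embedded 140-200 Hz ripple bursts
  (Hann envelope) riding on negative sharp-wave deflections.
* gRSC LFP: a laminar stack in which superficial channels carry a negative
  wave plus a delayed, attenuated ripple for the subset of hippocampal
  events that propagate, while deep channels carry the polarity-reversed
  low-frequency wave and no ripple.
* Spikes: inhomogeneous Poisson trains, rate-gained during ripples and
  phase-locked to the ripple oscillation with unit-specific von Mises
  concentration kappa.
* Brain state: alternating synchronized epochs (3-10 Hz activity packets
  with near-silent troughs in the cortical population) and desynchronized
  epochs (tonic firing), the latter split into high- and low-EMG halves via
  a shared 300-600 Hz contaminant added to all channels.

Everything is drawn from one seeded generator with independent sub-streams
per component, so the session is a pure function of the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import i0

from .core import EventTable, IntervalSet, Recording, SpikeData

__all__ = ["SynthConfig", "GroundTruth", "generate_session", "plant_ripple_types", "pink_noise"]


@dataclass
class SynthConfig:
    """Parameters of the synthetic session.

    Defaults follow the in-vivo statistics of the modelled preparation:
    CA1 ripple incidence 0.68 Hz, ripple frequency 170 Hz (inside the
    140-200 Hz band), median ripple duration 26 ms, and a ~5 ms
    CA1-to-gRSC propagation delay.
    """

    duration: float = 600.0          # s
    fs: float = 1250.0               # Hz
    ca1_ripple_rate: float = 0.68    # Hz
    ripple_freq: float = 170.0       # Hz
    ripple_duration_ms: float = 26.0
    ripple_min_gap_s: float = 0.15   # refractory gap between planted events
    propagation_prob: float = 0.4
    propagation_delay_ms: float = 5.0
    propagation_jitter_ms: float = 1.0
    ripple_snr: float = 8.0          # ripple peak amplitude / broadband noise SD
    sharp_wave_rel_amp: float = 1.5  # sharp-wave trough depth relative to ripple peak
    sharp_wave_sigma_ms: float = 15.0
    grsc_ripple_rel_amp: float = 0.6
    amplitude_cv: float = 0.25       # lognormal sigma of per-event amplitude
    n_grsc_channels: int = 8
    # unit counts
    n_ca1_pyr: int = 30
    n_ca1_int: int = 5
    n_grsc_sup: int = 16
    n_grsc_deep: int = 16
    # firing
    ca1_pyr_rate: float = 2.0        # Hz baseline (lognormal spread applied)
    ca1_int_rate: float = 12.0
    grsc_rate: float = 15.0
    ripple_gain_pyr: float = 5.0     # multiplicative rate gain inside ripples
    ripple_gain_int: float = 3.0
    grsc_sup_gain: float = 3.0       # gain of superficial gRSC units on propagated events
    grsc_deep_gain: float = 0.7
    kappa_pyr: float = 1.0           # von Mises concentration of ripple-phase locking
    kappa_int: float = 2.0
    refractory_ms: float = 2.5       # absolute refractory period of every unit
    # brain state
    sync_dwell_s: float = 25.0
    desync_dwell_s: float = 25.0
    min_dwell_s: float = 5.0
    packet_rate: float = 3.5         # Hz, within the 3-10 Hz packet band
    packet_sigma_ms: float = 20.0
    packet_peak_gain: float = 4.0
    packet_floor: float = 0.01       # relative cortical rate in packet troughs
    couple_ripples_to_packets: float = 0.0  # fraction of ripples snapped to packet times
    emg_amplitude: float = 0.6       # shared 300-600 Hz source SD, units of noise SD
    emg_low: float = 0.05
    # ripple typing
    n_ripple_types: int = 1
    type_separation: float = 1.5     # log-gain SD between type templates
    grsc_type_coupling: float = 0.0  # type-specific log-gain SD for gRSC sup units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0 or self.ca1_ripple_rate <= 0:
            raise ValueError("duration, fs and ripple rate must be positive")
        if not 0 <= self.propagation_prob <= 1:
            raise ValueError("propagation_prob must be in [0, 1]")
        if not 0 <= self.couple_ripples_to_packets <= 1:
            raise ValueError("couple_ripples_to_packets must be in [0, 1]")
        if self.ripple_snr <= 0:
            raise ValueError("ripple_snr must be positive")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted truth of one synthetic session."""

    ca1_events: EventTable
    grsc_events: EventTable
    states: IntervalSet
    packet_times: np.ndarray
    ripple_labels: np.ndarray          # type label (1..n_types) per CA1 ripple
    type_templates: np.ndarray         # n_types x n_ca1_pyr multiplicative gains
    unit_truth: pd.DataFrame           # unit_id, base_rate, kappa, pref_phase, ...
    propagated: np.ndarray             # bool per CA1 ripple


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def plant_ripple_types(
    rng: np.random.Generator, n_units: int, n_types: int, separation: float,
    jitter: float = 0.2,
) -> np.ndarray:
    """Per-type ensemble gain templates for the CA1 pyramidal units.

    Each type prefers its own subset of units (assigned round-robin), whose
    ripple gain is boosted by exp(separation) relative to the rest; a mild
    lognormal jitter individualizes the remaining units.  separation = 0
    collapses all templates onto a common profile, so downstream clustering
    recovery drops to chance.
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    member = rng.permutation(n_units) % n_types  # preferred type per unit
    boost = np.where(member[None, :] == np.arange(n_types)[:, None], np.exp(separation), 1.0)
    z = rng.standard_normal((n_types, n_units))
    templates = boost * np.exp(jitter * z - jitter**2 / 2)
    return templates


def _draw_states(cfg: SynthConfig, rng: np.random.Generator) -> IntervalSet:
    rows = []
    t = 0.0
    sync = bool(rng.integers(2))
    desync_high = bool(rng.integers(2))
    while t < cfg.duration:
        mean = cfg.sync_dwell_s if sync else cfg.desync_dwell_s
        dwell = max(cfg.min_dwell_s, rng.exponential(mean))
        stop = min(t + dwell, cfg.duration)
        if sync:
            label = "synchronized"
        else:
            label = "desync_highEMG" if desync_high else "desync_lowEMG"
            desync_high = not desync_high
        rows.append((t, stop, label))
        t = stop
        sync = not sync
    return IntervalSet(pd.DataFrame(rows, columns=["start_s", "stop_s", "label"]))


def _draw_ripple_times(cfg: SynthConfig, rng: np.random.Generator, packet_times: np.ndarray) -> np.ndarray:
    """Poisson event times with a refractory gap; optionally snapped to packets."""
    pad = 0.1 + cfg.ripple_duration_ms / 1000
    n_target = rng.poisson(cfg.ca1_ripple_rate * cfg.duration)
    candidates = np.sort(rng.uniform(pad, cfg.duration - pad, size=int(n_target * 1.5) + 20))
    times: list[float] = []
    last = -np.inf
    for t in candidates:
        if t - last >= cfg.ripple_min_gap_s:
            times.append(t)
            last = t
            if len(times) >= n_target:
                break
    times_arr = np.array(times)
    if cfg.couple_ripples_to_packets > 0 and packet_times.size:
        snap = rng.random(times_arr.size) < cfg.couple_ripples_to_packets
        idx = np.abs(packet_times[None, :] - times_arr[snap, None]).argmin(axis=1)
        moved = packet_times[idx] + rng.normal(0.01, 0.005, size=idx.size)
        times_arr[snap] = np.clip(moved, pad, cfg.duration - pad)
        times_arr = np.sort(times_arr)
        # re-impose the refractory gap after snapping
        keep = np.ones(times_arr.size, dtype=bool)
        last = -np.inf
        for i, t in enumerate(times_arr):
            if t - last < cfg.ripple_min_gap_s:
                keep[i] = False
            else:
                last = t
        times_arr = times_arr[keep]
    return times_arr


def _packet_times(cfg: SynthConfig, states: IntervalSet, rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic packet peak times inside synchronized epochs."""
    times = []
    iv = states.intervals
    for start, stop, label in iv.itertuples(index=False):
        if label != "synchronized":
            continue
        t = start + rng.uniform(0, 1 / cfg.packet_rate)
        while t < stop - 0.05:
            times.append(t)
            t += max(1 / cfg.packet_rate + rng.normal(0, 0.02), 0.06)
    return np.asarray(times)


def _ripple_waveforms(cfg: SynthConfig):
    """Time grid offsets (s) and Hann envelope for one ripple.

    ``ripple_duration_ms`` is the envelope's full width at half maximum —
    the effective (detectable) event duration — so the Hann window spans
    twice that.
    """
    full = 2 * cfg.ripple_duration_ms / 1000
    n_samp = max(int(round(full * cfg.fs)) | 1, 5)
    offs = np.arange(n_samp) - n_samp // 2
    t_rel = offs / cfg.fs
    env = np.hanning(n_samp)
    return t_rel, env


def _add_bump(trace: np.ndarray, fs: float, t_center: float, rel_t: np.ndarray, wave: np.ndarray) -> None:
    i0_ = int(round(t_center * fs)) + int(round(rel_t[0] * fs))
    n = wave.size
    lo = max(i0_, 0)
    hi = min(i0_ + n, trace.size)
    if hi > lo:
        trace[lo:hi] += wave[lo - i0_ : hi - i0_]


def _gauss_wave(fs: float, sigma_s: float, half_width_sigmas: float = 4.0):
    n = int(round(2 * half_width_sigmas * sigma_s * fs)) | 1
    t = (np.arange(n) - n // 2) / fs
    return t, np.exp(-0.5 * (t / sigma_s) ** 2)


def _state_gain_series(cfg: SynthConfig, states: IntervalSet, packet_times: np.ndarray, n: int) -> np.ndarray:
    """Cortical population rate gain: packets in sync epochs, tonic in desync."""
    gain = np.ones(n)
    t = np.arange(n) / cfg.fs
    sync_mask = states.contains(t, "synchronized")
    gain[sync_mask] = cfg.packet_floor
    sig = cfg.packet_sigma_ms / 1000
    t_rel, g = _gauss_wave(cfg.fs, sig, 3.0)
    bump = g * cfg.packet_peak_gain
    for pt in packet_times:
        _add_bump(gain, cfg.fs, pt, t_rel, bump)
    return gain


def _sample_inhomogeneous(
    rate: np.ndarray, fs: float, rng: np.random.Generator, refractory_s: float = 0.0
) -> np.ndarray:
    """Inhomogeneous Poisson train (inverse-CDF sampling) with dead time.

    Spikes violating the absolute refractory period are removed, as in a
    real neuron; at physiological rates this trims only a few percent.
    """
    dt = 1.0 / fs
    cum = np.cumsum(rate) * dt
    total = cum[-1]
    n = rng.poisson(total)
    if n == 0:
        return np.array([])
    u = np.sort(rng.uniform(0, total, n))
    idx = np.searchsorted(cum, u)
    frac = rng.uniform(0, 1, n)
    t = np.clip((idx + frac) * dt, 0, rate.size * dt)
    if refractory_s > 0 and t.size > 1:
        keep = [0]
        last = t[0]
        for i in range(1, t.size):
            if t[i] - last >= refractory_s:
                keep.append(i)
                last = t[i]
        t = t[keep]
    return t


def generate_session(cfg: SynthConfig):
    """Generate one synthetic session.

    Returns
    -------
    (ca1 : Recording, grsc : Recording, spikes : SpikeData, truth : GroundTruth)
    """
    root = np.random.SeedSequence(cfg.seed)
    (ss_states, ss_events, ss_noise_ca1, ss_noise_grsc, ss_types,
     ss_spikes, ss_emg, ss_amps) = root.spawn(8)
    n = int(round(cfg.duration * cfg.fs))
    t_axis = np.arange(n) / cfg.fs

    # --- states and packets ------------------------------------------------
    rng_states = np.random.default_rng(ss_states)
    states = _draw_states(cfg, rng_states)
    packet_times = _packet_times(cfg, states, rng_states)

    # --- ripple events ------------------------------------------------------
    rng_events = np.random.default_rng(ss_events)
    peaks = _draw_ripple_times(cfg, rng_events, packet_times)
    n_rip = peaks.size
    rng_amps = np.random.default_rng(ss_amps)
    amp_ca1 = cfg.ripple_snr * np.exp(rng_amps.normal(0, cfg.amplitude_cv, n_rip))
    propagated = rng_events.random(n_rip) < cfg.propagation_prob
    delays = (
        cfg.propagation_delay_ms + rng_events.normal(0, cfg.propagation_jitter_ms, n_rip)
    ) / 1000
    # gRSC amplitude correlates with CA1 amplitude (stronger ripples propagate better)
    amp_grsc = cfg.grsc_ripple_rel_amp * amp_ca1 * np.exp(rng_amps.normal(0, 0.15, n_rip))

    # --- ripple typing ------------------------------------------------------
    rng_types = np.random.default_rng(ss_types)
    templates = plant_ripple_types(rng_types, cfg.n_ca1_pyr, cfg.n_ripple_types, cfg.type_separation)
    labels = rng_types.integers(1, cfg.n_ripple_types + 1, size=n_rip)
    if cfg.n_ripple_types == 1:
        labels = np.ones(n_rip, dtype=int)
    grsc_type_offsets = np.exp(
        cfg.grsc_type_coupling * rng_types.standard_normal((cfg.n_ripple_types, cfg.n_grsc_sup))
        - cfg.grsc_type_coupling**2 / 2
    )

    # --- LFP construction ---------------------------------------------------
    rng_nc = np.random.default_rng(ss_noise_ca1)
    rng_ng = np.random.default_rng(ss_noise_grsc)
    ca1_trace = pink_noise(n, rng_nc)
    grsc = np.stack([pink_noise(n, rng_ng) for _ in range(cfg.n_grsc_channels)])

    t_rel, env = _ripple_waveforms(cfg)
    sw_t, sw_g = _gauss_wave(cfg.fs, cfg.sharp_wave_sigma_ms / 1000)
    # depth weights of the negative wave: +1 superficial -> -0.5 deep (polarity reversal)
    depth_w = np.linspace(1.0, -0.5, cfg.n_grsc_channels)
    sup_half = np.arange(cfg.n_grsc_channels) < cfg.n_grsc_channels // 2
    ripple_w = np.where(sup_half, np.linspace(1.0, 0.3, cfg.n_grsc_channels), 0.0)

    for k in range(n_rip):
        carrier = env * np.sin(2 * np.pi * cfg.ripple_freq * t_rel)
        _add_bump(ca1_trace, cfg.fs, peaks[k], t_rel, amp_ca1[k] * carrier)
        _add_bump(ca1_trace, cfg.fs, peaks[k], sw_t, -cfg.sharp_wave_rel_amp * amp_ca1[k] * sw_g)
        if propagated[k]:
            tk = peaks[k] + delays[k]
            for c in range(cfg.n_grsc_channels):
                if ripple_w[c] > 0:
                    _add_bump(grsc[c], cfg.fs, tk, t_rel, amp_grsc[k] * ripple_w[c] * carrier)
                _add_bump(
                    grsc[c], cfg.fs, tk, sw_t,
                    -cfg.sharp_wave_rel_amp * amp_grsc[k] * depth_w[c] * sw_g,
                )

    # --- shared EMG contaminant --------------------------------------------
    rng_emg = np.random.default_rng(ss_emg)
    from .core import bandpass_zero_phase

    emg_src = bandpass_zero_phase(rng_emg.standard_normal(n), cfg.fs, 300, 600, order=4)
    sd = emg_src.std()
    if sd > 0:
        emg_src /= sd
    emg_env = np.full(n, cfg.emg_low)
    emg_env[states.contains(t_axis, "desync_highEMG")] = cfg.emg_amplitude
    emg = emg_src * emg_env
    ca1_trace += emg
    grsc += emg[None, :] * (0.8 + 0.4 * rng_emg.random(cfg.n_grsc_channels))[:, None]

    ca1_channels = pd.DataFrame({"id": [0], "shank": [0], "depth_um": [0.0], "region": ["CA1"]})
    grsc_channels = pd.DataFrame(
        {
            "id": np.arange(100, 100 + cfg.n_grsc_channels),
            "shank": 0,
            "depth_um": np.arange(cfg.n_grsc_channels) * 100.0,
            "region": np.where(sup_half, "gRSC_sup", "gRSC_deep"),
        }
    )
    ca1_rec = Recording(samples=ca1_trace[None, :], fs=cfg.fs, channels=ca1_channels)
    grsc_rec = Recording(samples=grsc, fs=cfg.fs, channels=grsc_channels)

    # --- spikes -------------------------------------------------------------
    rng_sp = np.random.default_rng(ss_spikes)
    half_rip = cfg.ripple_duration_ms / 2000
    half_gain = cfg.ripple_duration_ms / 1000  # spiking gain spans the full envelope
    state_gain = _state_gain_series(cfg, states, packet_times, n)

    truth_rows: list[dict] = []
    uid = 0

    def make_units(count, region, layer, utype, base_mean, gain, kappa):
        nonlocal uid
        out = []
        for _ in range(count):
            base = base_mean * np.exp(rng_sp.normal(0, 0.3))
            pref = rng_sp.uniform(-np.pi, np.pi)
            width = rng_sp.normal(0.7, 0.05) if utype == "pyramidal" else rng_sp.normal(0.3, 0.04)
            asym = rng_sp.normal(0.3 if utype == "pyramidal" else -0.1, 0.1)
            out.append(dict(unit_id=uid, region=region, layer=layer, type=utype,
                            base_rate=base, ripple_gain=gain, kappa=kappa, pref_phase=pref,
                            trough_to_peak_ms=max(width, 0.1), asymmetry=asym))
            uid += 1
        return out

    ca1_pyr = make_units(cfg.n_ca1_pyr, "CA1", "unknown", "pyramidal",
                         cfg.ca1_pyr_rate, cfg.ripple_gain_pyr, cfg.kappa_pyr)
    ca1_int = make_units(cfg.n_ca1_int, "CA1", "unknown", "interneuron",
                         cfg.ca1_int_rate, cfg.ripple_gain_int, cfg.kappa_int)
    grsc_sup_u = make_units(cfg.n_grsc_sup, "gRSC_sup", "superficial", "pyramidal",
                            cfg.grsc_rate, cfg.grsc_sup_gain, cfg.kappa_pyr)
    grsc_deep_u = make_units(cfg.n_grsc_deep, "gRSC_deep", "deep", "pyramidal",
                             cfg.grsc_rate, cfg.grsc_deep_gain, 0.0)

    phase_at = lambda tt, pk: 2 * np.pi * cfg.ripple_freq * (tt - pk)  # noqa: E731

    def rate_series(u, idx_in_group=None):
        rate = np.full(n, u["base_rate"])
        if u["region"].startswith("gRSC"):
            rate = rate * state_gain
        kappa = u["kappa"]
        norm = i0(kappa)
        if u["region"] == "CA1":
            ev_peaks, ev_props = peaks, np.ones(n_rip, dtype=bool)
        else:
            ev_peaks, ev_props = peaks + delays, propagated
        for k in range(n_rip):
            if not ev_props[k]:
                continue
            pk = ev_peaks[k]
            lo = max(int((pk - half_gain) * cfg.fs), 0)
            hi = min(int((pk + half_gain) * cfg.fs) + 1, n)
            if hi <= lo:
                continue
            gain = u["ripple_gain"]
            if u["region"] == "CA1" and u["type"] == "pyramidal" and idx_in_group is not None:
                gain = gain * templates[labels[k] - 1, idx_in_group]
            elif u["region"] == "gRSC_sup" and idx_in_group is not None:
                gain = gain * grsc_type_offsets[labels[k] - 1, idx_in_group]
            tt = np.arange(lo, hi) / cfg.fs
            ph_mod = np.exp(kappa * np.cos(phase_at(tt, pk) - u["pref_phase"])) / norm
            rate[lo:hi] = u["base_rate"] * gain * ph_mod * (
                state_gain[lo:hi] if u["region"].startswith("gRSC") else 1.0
            )
        return rate

    groups = [(ca1_pyr, True), (ca1_int, False), (grsc_sup_u, True), (grsc_deep_u, False)]
    all_times, all_uids = [], []
    for group, indexed in groups:
        for j, u in enumerate(group):
            r = rate_series(u, j if indexed else None)
            st = _sample_inhomogeneous(r, cfg.fs, rng_sp, cfg.refractory_ms / 1000)
            all_times.append(np.sort(st))
            all_uids.append(np.full(st.size, u["unit_id"], dtype=int))
            truth_rows.append(u)

    spikes_df = pd.DataFrame(
        {"time_s": np.concatenate(all_times), "unit_id": np.concatenate(all_uids)}
    )
    unit_truth = pd.DataFrame(truth_rows)
    counts = spikes_df.groupby("unit_id").size()
    units_df = unit_truth[["unit_id", "region", "layer", "trough_to_peak_ms", "asymmetry", "type"]].copy()
    units_df["mean_rate_hz"] = units_df["unit_id"].map(counts).fillna(0).astype(float) / cfg.duration
    units_df = units_df[["unit_id", "region", "layer", "mean_rate_hz",
                         "trough_to_peak_ms", "asymmetry", "type"]]
    spike_data = SpikeData(spikes=spikes_df, units=units_df)

    # --- ground truth tables ------------------------------------------------
    def ev_table(pk, amp, channel, kind):
        return EventTable(
            kind=kind,
            events=pd.DataFrame(
                {
                    "onset_s": pk - half_rip,
                    "peak_s": pk,
                    "offset_s": pk + half_rip,
                    "amplitude": amp,
                    "channel": channel,
                }
            ),
            params={"synthetic": True},
        )

    truth = GroundTruth(
        ca1_events=ev_table(peaks, amp_ca1, 0, "ripple"),
        grsc_events=ev_table((peaks + delays)[propagated], amp_grsc[propagated], 100, "ripple"),
        states=states,
        packet_times=packet_times,
        ripple_labels=labels,
        type_templates=templates,
        unit_truth=unit_truth,
        propagated=propagated,
    )
    return ca1_rec, grsc_rec, spike_data, truth
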