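"""Laminar source analysis: inverse CSD and ICA depth-loading profiles.

The CSD estimate uses the inverse (delta-source) method: each electrode
depth hosts an infinitely thin disk of current, the forward matrix maps
disk current densities to electrode potentials, and the CSD is the inverse
applied to the (shank-average-referenced) potential profile.  Sinks are
negative by convention.

Note that this model assumes current flow along the depth axis; oblique
probe insertions violate that assumption, so absolute source localization
on real data is approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ranksums
from sklearn.decomposition import FastICA

__all__ = ["DepthProfile", "csd_forward_matrix", "inverse_csd", "ica_event_loadings"]


@dataclass
class DepthProfile:
    """Values per (depth, time) with the method that produced them."""

    values: np.ndarray
    depths_um: np.ndarray
    times: np.ndarray
    method: str  # "iCSD" or "ICA-load"
    meta: dict = field(default_factory=dict)


def csd_forward_matrix(depths_um: np.ndarray, diameter_um: float = 500.0, conductivity: float = 1.0) -> np.ndarray:
    """Forward matrix of the delta-source inverse CSD model.

    Element (j, i) is the potential at electrode j produced by a unit planar
    current-source disk (radius = diameter/2) at electrode depth i.
    Conductivity and disk thickness are in relative units (amplitude
    calibration of the recordings is opaque anyway).
    """
    z = np.asarray(depths_um, dtype=float)
    r = diameter_um / 2.0
    h = np.median(np.diff(np.sort(z)))
    dz = z[:, None] - z[None, :]
    return (h / (2.0 * conductivity)) * (np.sqrt(dz**2 + r**2) - np.abs(dz))


def inverse_csd(
    mean_lfp: np.ndarray,
    depths_um: np.ndarray,
    diameter_um: float = 500.0,
    conductivity: float = 1.0,
    subtract_mean: bool = True,
    times: np.ndarray | None = None,
) -> DepthProfile:
    """Inverse-method CSD of an event-triggered average potential profile.

    Parameters
    ----------
    mean_lfp : ndarray, shape (n_depths, n_time)
        Event-triggered average LFP (one row per depth, ordered).
    depths_um : depths of the rows in µm, strictly ordered.
    subtract_mean : subtract the shank-average reference before inversion.
    """
    v = np.atleast_2d(np.asarray(mean_lfp, dtype=float))
    z = np.asarray(depths_um, dtype=float)
    if v.shape[0] < 3:
        raise ValueError("need at least 3 depths for CSD")
    if v.shape[0] != z.size:
        raise ValueError("depth vector must match LFP rows")
    if not (np.all(np.diff(z) > 0) or np.all(np.diff(z) < 0)):
        raise ValueError("depths must be strictly ordered")
    if subtract_mean:
        v = v - v.mean(axis=0, keepdims=True)
    f = csd_forward_matrix(z, diameter_um, conductivity)
    csd = np.linalg.solve(f, v)
    if times is None:
        times = np.arange(v.shape[1], dtype=float)
    return DepthProfile(values=csd, depths_um=z, times=np.asarray(times), method="iCSD",
                        meta={"diameter_um": diameter_um, "sink_sign": "negative",
                              "referenced": subtract_mean})


def ica_event_loadings(
    samples: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    window: tuple = (-0.05, 0.05),
    n_components: int = 3,
    rng: np.random.Generator | int | None = 0,
):
    """Depth loadings of the leading independent component around events.

    Event windows are concatenated and decomposed with ICA; the leading
    component is the one whose event-locked (trial-averaged) source waveform
    carries the most variance, and its per-channel mixing weights are the
    loadings.  A two-sided rank-sum test compares the loadings of the top
    (superficial) half against the bottom (deep) half of channels.

    Returns (loadings, p_value, sources_meta).
    """
    x = np.asarray(samples, dtype=float)
    n_ch = x.shape[0]
    if n_ch < n_components:
        raise ValueError("need at least as many channels as components")
    w0 = int(round(window[0] * fs))
    w1 = int(round(window[1] * fs))
    segs = []
    for t in np.atleast_1d(event_times):
        i = int(round(t * fs))
        if i + w0 >= 0 and i + w1 <= x.shape[1]:
            segs.append(x[:, i + w0 : i + w1])
    if not segs:
        raise ValueError("no events with full windows inside the trace")
    data = np.concatenate(segs, axis=1)  # channels x (events*win)
    if np.linalg.matrix_rank(data - data.mean(axis=1, keepdims=True)) < n_components:
        raise ValueError("rank-deficient data for requested components")
    seed = rng if isinstance(rng, (int, np.integer)) or rng is None else int(rng.integers(2**31))
    ica = FastICA(n_components=n_components, random_state=seed, whiten="unit-variance",
                  max_iter=1000)
    sources = ica.fit_transform(data.T).T  # comps x time
    mixing = ica.mixing_  # channels x comps
    win_len = w1 - w0
    n_ev = sources.shape[1] // win_len
    trial = sources[:, : n_ev * win_len].reshape(n_components, n_ev, win_len)
    locked_var = trial.mean(axis=1).var(axis=1) * (mixing**2).sum(axis=0)
    lead = int(np.argmax(locked_var))
    loadings = mixing[:, lead]
    top = loadings[: n_ch // 2]
    bottom = loadings[n_ch - n_ch // 2 :]
    p = float(ranksums(top, bottom).pvalue)
    return loadings, p, {"component": lead, "event_locked_variance": locked_var,
                         "n_events": n_ev}
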