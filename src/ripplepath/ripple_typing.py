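"""Ripple-type analysis: cluster ripples by CA1 ensemble content and test
whether downstream (gRSC) unit firing and LFP spectral content discriminate
the ripple type.

The discrimination model is an ANCOVA: the response (a unit's spike count
in one lag bin, or a band's z-scored amplitude at one lag) is regressed on
ripple-cluster label dummies plus the CA1 population firing rate as a
continuous nuisance covariate, and the label block is tested with a partial
F-test.  Across sessions, per-cell p-values are combined with Fisher's
method (−2·Σ log pᵢ ~ χ² with 2n d.f.).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .core import InsufficientDataError, SpikeData

__all__ = [
    "ripple_rate_vectors",
    "population_rate_per_event",
    "cluster_ripples",
    "ancova_fp",
    "unit_discrimination_ancova",
    "lfp_band_pvals",
    "fisher_combine",
    "lfp_discrimination",
    "tsne_density_test",
]


def _counts_in_windows(spike_times: np.ndarray, starts: np.ndarray, width: float) -> np.ndarray:
    t = np.sort(np.asarray(spike_times, dtype=float))
    return (np.searchsorted(t, starts + width) - np.searchsorted(t, starts)).astype(float)


def ripple_rate_vectors(
    spikedata: SpikeData,
    ripple_onsets: np.ndarray,
    window_s: float = 0.1,
    exclude_types: tuple = ("interneuron",),
    normalize: str = "zscore",
):
    """Per-ripple ensemble firing-rate vectors.

    Spike counts per unit in [onset, onset + window) are normalized per unit
    across ripples (z-score by default, 'minmax' as alternative).
    Fast-spiking interneurons are excluded.  Zero-variance units stay as
    all-zero columns.

    Returns (matrix n_ripples × n_units, unit_ids).
    """
    units = spikedata.units
    keep = units[~units["type"].isin(exclude_types)]["unit_id"].to_numpy()
    if keep.size == 0:
        raise InsufficientDataError("no non-excluded units")
    onsets = np.asarray(ripple_onsets, dtype=float)
    mat = np.column_stack(
        [_counts_in_windows(spikedata.unit_times(u), onsets, window_s) for u in keep]
    )
    if normalize == "zscore":
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0)
        sd[sd == 0] = np.inf
        mat = (mat - mu) / sd
    elif normalize == "minmax":
        lo, hi = mat.min(axis=0), mat.max(axis=0)
        rng_ = hi - lo
        rng_[rng_ == 0] = np.inf
        mat = (mat - lo) / rng_
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    return mat, keep


def population_rate_per_event(
    spikedata: SpikeData, onsets: np.ndarray, window_s: float = 0.1
) -> np.ndarray:
    """Mean population firing rate (Hz/unit) in the window after each event."""
    onsets = np.asarray(onsets, dtype=float)
    total = np.zeros(onsets.size)
    for u in spikedata.units["unit_id"]:
        total += _counts_in_windows(spikedata.unit_times(u), onsets, window_s)
    return total / (window_s * max(spikedata.n_units, 1))


def cluster_ripples(matrix: np.ndarray, k: int = 10, seed: int = 0):
    """K-means (squared Euclidean) clustering of ripple rate vectors.

    Returns (labels 1..k, similarity, order) where ``similarity`` is the
    ripple × ripple Pearson-correlation matrix re-ordered by cluster label
    and ``order`` the permutation used.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < k:
        raise ValueError(f"need at least k={k} ripples, got {matrix.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed).fit(matrix)
    labels = km.labels_ + 1
    order = np.argsort(labels, kind="stable")
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    norms[norms == 0] = np.inf
    sim = (centered / norms[:, None]) @ (centered / norms[:, None]).T
    np.fill_diagonal(sim, 1.0)
    return labels, sim[np.ix_(order, order)], order


def _design_matrices(labels: np.ndarray, covariate: np.ndarray | None):
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct labels")
    dummies = (labels[:, None] == uniq[None, 1:]).astype(float)
    cols = [np.ones((labels.size, 1)), dummies]
    red_cols = [np.ones((labels.size, 1))]
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        if np.ptp(cov) == 0:
            warnings.warn("constant covariate dropped from ANCOVA design")
        else:
            c = (cov - cov.mean())[:, None]
            cols.append(c)
            red_cols.append(c)
    x_full = np.column_stack(cols)
    x_red = np.column_stack(red_cols)
    return x_full, x_red, uniq.size


def ancova_fp(y: np.ndarray, labels: np.ndarray, covariate: np.ndarray | None):
    """Partial F-test of the label block in an OLS ANCOVA.

    ``y`` may be 1-D (single response) or 2-D (n_obs × m responses tested
    in parallel against the same design).  Returns (F, p) arrays of length m.
    """
    y = np.asarray(y, dtype=float)
    y2 = y[:, None] if y.ndim == 1 else y
    x_full, x_red, k = _design_matrices(labels, covariate)
    n = y2.shape[0]
    df1 = k - 1
    df2 = n - x_full.shape[1]
    if df2 <= 0:
        raise ValueError("not enough observations for the design")

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y2, rcond=None)
        r = y2 - x @ beta
        return (r**2).sum(axis=0)

    rss_full = rss(x_full)
    rss_red = rss(x_red)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f = np.where(rss_full > 0, f, 0.0)
    p = stats.f.sf(f, df1, df2)
    if y.ndim == 1:
        return float(f[0]), float(p[0])
    return f, p


def unit_discrimination_ancova(
    spikedata: SpikeData,
    ripple_onsets: np.ndarray,
    labels: np.ndarray,
    ca1_pop_rate: np.ndarray,
    binsize: float = 0.01,
    halfwindow: float = 0.1,
    alpha: float = 0.01,
    min_per_label: int = 5,
    n_shuffles: int = 0,
    rng: np.random.Generator | None = None,
):
    """Per-unit, per-lag-bin ANCOVA of spike counts on ripple-cluster label.

    A unit "discriminates" ripple type if any post-onset bin has a label
    main-effect p < alpha.  With ``n_shuffles`` > 0, a label-shuffle null of
    the maximal F-ratio is returned per unit.

    Returns (table, fraction_discriminating) where the table has one row per
    (unit, lag bin) with F, p and the covariate slope.
    """
    onsets = np.asarray(ripple_onsets, dtype=float)
    labels = np.asarray(labels)
    uniq, cnt = np.unique(labels, return_counts=True)
    if (cnt >= min_per_label).sum() < 2:
        raise InsufficientDataError("need >= 2 labels with enough ripples")
    ok_labels = uniq[cnt >= min_per_label]
    sel = np.isin(labels, ok_labels)
    onsets, labels = onsets[sel], labels[sel]
    cov = np.asarray(ca1_pop_rate, dtype=float)[sel]
    edges = np.arange(-halfwindow, halfwindow + binsize / 2, binsize)
    lag_centers = (edges[:-1] + edges[1:]) / 2
    post = lag_centers >= 0
    rng = rng or np.random.default_rng()

    rows = []
    discriminating = []
    shuffle_null = {}
    for u in spikedata.units["unit_id"]:
        t = np.sort(spikedata.unit_times(u))
        y = np.column_stack(
            [
                (np.searchsorted(t, onsets + e1) - np.searchsorted(t, e0 + onsets)).astype(float)
                for e0, e1 in zip(edges[:-1], edges[1:])
            ]
        )
        f, p = ancova_fp(y, labels, cov)
        slope = np.full(lag_centers.size, np.nan)
        if np.ptp(cov) > 0:
            c = cov - cov.mean()
            slope = (y - y.mean(axis=0)).T @ c / (c @ c)
        for j, lag in enumerate(lag_centers):
            rows.append((u, lag, f[j], p[j], slope[j]))
        disc = bool((p[post] < alpha).any())
        discriminating.append(disc)
        if n_shuffles:
            null_max = np.empty(n_shuffles)
            for s in range(n_shuffles):
                f_s, _ = ancova_fp(y[:, post], rng.permutation(labels), cov)
                null_max[s] = f_s.max()
            shuffle_null[u] = null_max
    table = pd.DataFrame(rows, columns=["unit_id", "lag_s", "F", "p", "cov_slope"])
    frac = float(np.mean(discriminating)) if discriminating else 0.0
    out = {"table": table, "fraction_discriminating": frac,
           "discriminates": dict(zip(spikedata.units["unit_id"], discriminating))}
    if n_shuffles:
        out["shuffle_null_maxF"] = shuffle_null
    return out


def lfp_band_pvals(
    trace: np.ndarray,
    fs: float,
    ripple_onsets: np.ndarray,
    labels: np.ndarray,
    ca1_pop_rate: np.ndarray,
    bands: np.ndarray | None = None,
    halfwindow: float = 0.5,
    lag_step: float = 0.02,
    cycle_range: tuple = (3.0, 12.0),
):
    """Per-(band, lag) ANCOVA p-map for one session.

    Wavelet amplitudes at ``bands`` (default 80 log-spaced 5-300 Hz) are
    z-scored per band over the ±halfwindow observation window of each event
    and tested for a ripple-label main effect with the CA1 population rate
    as covariate.

    Returns (bands, lags, p_map[band, lag]).
    """
    from .spectral import morlet_spectrogram

    if bands is None:
        bands = np.logspace(np.log10(5), np.log10(300), 80)
    bands = np.asarray(bands, dtype=float)
    spec = morlet_spectrogram(trace, fs, bands, cycle_range)
    amp = np.abs(spec.values)
    w = int(round(halfwindow * fs))
    step = max(int(round(lag_step * fs)), 1)
    lag_idx = np.arange(-w, w + 1, step)
    lags = lag_idx / fs
    feats = []
    keep = []
    for idx, t in enumerate(np.asarray(ripple_onsets, dtype=float)):
        i = int(round(t * fs))
        if i - w < 0 or i + w + 1 > amp.shape[1]:
            continue
        win = amp[:, i - w : i + w + 1]
        mu = win.mean(axis=1, keepdims=True)
        sd = win.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf
        z = (win - mu) / sd
        feats.append(z[:, lag_idx + w])
        keep.append(idx)
    if len(keep) < 10:
        raise InsufficientDataError("too few events with full windows")
    feats = np.stack(feats)  # events x bands x lags
    labels = np.asarray(labels)[keep]
    cov = np.asarray(ca1_pop_rate, dtype=float)[keep]
    n_ev = feats.shape[0]
    y = feats.reshape(n_ev, -1)
    _, p = ancova_fp(y, labels, cov)
    return bands, lags, p.reshape(bands.size, lags.size)


def fisher_combine(p_maps: list[np.ndarray]) -> np.ndarray:
    """Fisher's method across sessions: −2·Σ log pᵢ ~ χ²(2n)."""
    if len(p_maps) == 1:
        return np.asarray(p_maps[0])
    stacked = np.stack([np.asarray(p, dtype=float) for p in p_maps])
    stat = -2.0 * np.log(np.clip(stacked, np.finfo(float).tiny, 1.0)).sum(axis=0)
    return stats.chi2.sf(stat, 2 * len(p_maps))


def lfp_discrimination(sessions: list[dict], alpha_bonf: float = 0.0004, **kwargs):
    """Combined (band × lag) LFP discrimination map across sessions.

    Each session dict needs keys trace, fs, onsets, labels, cov.  Returns a
    dict with bands, lags, per-session p-maps, the Fisher-combined map, and
    the significance mask at ``alpha_bonf`` (Bonferroni-style cutoff).
    """
    maps = []
    bands = lags = None
    for s in sessions:
        bands, lags, pm = lfp_band_pvals(
            s["trace"], s["fs"], s["onsets"], s["labels"], s["cov"], **kwargs
        )
        maps.append(pm)
    combined = fisher_combine(maps)
    return {"bands": bands, "lags": lags, "session_p": maps,
            "combined_p": combined, "significant": combined < alpha_bonf,
            "alpha": alpha_bonf}


def _label_densities(xy, labels, uniq, x_edges, y_edges, sigma_bins):
    out = {}
    for lab in uniq:
        pts = xy[labels == lab]
        h = np.histogram2d(pts[:, 0], pts[:, 1], bins=(x_edges, y_edges))[0]
        out[lab] = ndimage.gaussian_filter(h, sigma_bins, mode="constant") / max(len(pts), 1)
    return out


def density_permutation_test(
    xy: np.ndarray,
    labels: np.ndarray,
    bin_au: float = 1.0,
    sigma_au: float = 4.0,
    n_perm: int = 1000,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
):
    """Per-label binned/smoothed density maps with a label-permutation null.

    Densities are per-bin histograms of the embedding coordinates, smoothed
    with a 2-D Gaussian (σ in embedding units) and normalized by the label's
    point count; each bin's p-value is the fraction of label permutations
    whose density reaches the observed one.  The maps depend only on the
    *set* of (point, label) pairs, not their order.
    """
    rng = rng or np.random.default_rng()
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    pad = 2 * sigma_au
    x_edges = np.arange(xy[:, 0].min() - pad, xy[:, 0].max() + pad + bin_au, bin_au)
    y_edges = np.arange(xy[:, 1].min() - pad, xy[:, 1].max() + pad + bin_au, bin_au)
    sigma_bins = sigma_au / bin_au
    obs = _label_densities(xy, labels, uniq, x_edges, y_edges, sigma_bins)
    exceed = {lab: np.zeros_like(obs[lab]) for lab in uniq}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        d = _label_densities(xy, perm, uniq, x_edges, y_edges, sigma_bins)
        for lab in uniq:
            exceed[lab] += d[lab] >= obs[lab]
    pvals = {lab: (exceed[lab] + 1) / (n_perm + 1) for lab in uniq}
    masks = {lab: pvals[lab] < alpha for lab in uniq}
    return {"density": obs, "pvals": pvals, "significant": masks,
            "x_edges": x_edges, "y_edges": y_edges}


def tsne_density_test(
    ca1_vectors: np.ndarray,
    grsc_vectors: np.ndarray,
    labels: np.ndarray,
    perplexity: float = 30.0,
    bin_au: float = 1.0,
    sigma_au: float = 4.0,
    n_perm: int = 1000,
    alpha: float = 0.01,
    min_per_label: int = 5,
    seed: int = 0,
):
    """Low-dimensional embedding of ripple ensembles with a density
    permutation test.

    CA1 and gRSC rate vectors are embedded separately with t-SNE
    (perplexity 30, random Gaussian initialization).  For each ripple
    cluster the gRSC embedding is binned (1 AU), smoothed (2-D Gaussian,
    σ = 4 AU) and normalized by the cluster's ripple count; each bin's
    density is compared against ``n_perm`` label permutations, flagging bins
    with permutation p < alpha.

    Returns a dict with embeddings, per-label density maps, p-maps and
    significance masks.
    """
    labels = np.asarray(labels)
    if len(labels) < 50:
        raise InsufficientDataError("need at least 50 ripples")
    uniq, cnt = np.unique(labels, return_counts=True)
    small = uniq[cnt < min_per_label]
    if small.size:
        warnings.warn(f"labels {small.tolist()} have < {min_per_label} ripples; excluded")
    uniq = uniq[cnt >= min_per_label]
    keep = np.isin(labels, uniq)
    labels = labels[keep]
    rng = np.random.default_rng(seed)

    def embed(x):
        perp = min(perplexity, (x.shape[0] - 1) / 3)
        ts = TSNE(n_components=2, perplexity=perp, init="random", random_state=seed)
        return ts.fit_transform(np.asarray(x, dtype=float)[keep])

    emb_ca1 = embed(ca1_vectors)
    emb_grsc = embed(grsc_vectors)
    out = density_permutation_test(emb_grsc, labels, bin_au=bin_au, sigma_au=sigma_au,
                                   n_perm=n_perm, alpha=alpha, rng=rng)
    out.update({"embedding_ca1": emb_ca1, "embedding_grsc": emb_grsc, "labels": labels})
    return out
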