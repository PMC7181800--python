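import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2
from sklearn.metrics import adjusted_rand_score

import ripplepath as rp
from ripplepath import ripple_typing as rt
from ripplepath.core import InsufficientDataError
from ripplepath.synth import pink_noise


def make_ca1(trains: dict, types: dict | None = None) -> rp.SpikeData:
    rows, urows = [], []
    for uid, t in trains.items():
        rows.extend((x, uid) for x in np.sort(t))
        urows.append(dict(unit_id=uid, region="CA1", layer="unknown",
                          mean_rate_hz=1.0, trough_to_peak_ms=0.6, asymmetry=0.2,
                          type=(types or {}).get(uid, "pyramidal")))
    return rp.SpikeData(spikes=pd.DataFrame(rows, columns=["time_s", "unit_id"]),
                        units=pd.DataFrame(urows))


class TestRateVectors:
    def test_constant_column_normalized_to_zero(self):
        onsets = np.arange(1.0, 21.0)
        sd = make_ca1({1: onsets + 0.05, 2: np.arange(0.5, 20.5, 0.1)})
        mat, uids = rt.ripple_rate_vectors(sd, onsets)
        col = mat[:, list(uids).index(1)]
        assert np.allclose(col, 0.0)  # one spike per window, zero variance

    def test_interneurons_excluded(self):
        onsets = np.arange(1.0, 11.0)
        sd = make_ca1({1: onsets + 0.05, 2: onsets + 0.02}, types={2: "interneuron"})
        mat, uids = rt.ripple_rate_vectors(sd, onsets)
        assert list(uids) == [1]

    def test_planted_types_correlate_within_type(self, typed_session):
        cfg, _, _, spikes, truth = typed_session
        ca1 = spikes.select_units(spikes.units[spikes.units.region == "CA1"]["unit_id"])
        mat, _ = rt.ripple_rate_vectors(ca1, truth.ca1_events.onsets)
        labels = truth.ripple_labels
        c = np.corrcoef(mat)
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        within = c[same].mean()
        between = c[~same & ~np.eye(len(labels), dtype=bool)].mean()
        assert within > between + 0.1


class TestClusterRipples:
    def test_two_orthogonal_templates_perfectly_recovered(self):
        rng = np.random.default_rng(0)
        labels_true = rng.integers(0, 2, 200)
        mat = np.zeros((200, 20))
        mat[labels_true == 0, :10] = 1.0 + 0.05 * rng.standard_normal((int((labels_true == 0).sum()), 10))
        mat[labels_true == 1, 10:] = 1.0 + 0.05 * rng.standard_normal((int((labels_true == 1).sum()), 10))
        labels, sim, order = rt.cluster_ripples(mat, k=2)
        assert adjusted_rand_score(labels_true, labels) == 1.0

    def test_identical_rows_single_cluster_unit_similarity(self):
        mat = np.tile(np.arange(5.0), (20, 1))
        labels, sim, _ = rt.cluster_ripples(mat, k=2)
        assert np.allclose(sim, 1.0)

    def test_fewer_rows_than_k_rejected(self):
        with pytest.raises(ValueError):
            rt.cluster_ripples(np.zeros((5, 3)), k=10)

    def test_similarity_invariant_to_unitwise_affine_rescale(self, typed_session):
        cfg, _, _, spikes, truth = typed_session
        ca1 = spikes.select_units(spikes.units[spikes.units.region == "CA1"]["unit_id"])
        onsets = truth.ca1_events.onsets[:100]
        raw, _ = rt.ripple_rate_vectors(ca1, onsets, normalize="none")
        rng = np.random.default_rng(1)
        scaled = raw * rng.uniform(0.5, 3.0, raw.shape[1]) + rng.uniform(-2, 2, raw.shape[1])

        def zscore(m):
            sd = m.std(axis=0)
            sd[sd == 0] = np.inf
            return (m - m.mean(axis=0)) / sd

        _, sim1, _ = rt.cluster_ripples(zscore(raw), k=3, seed=0)
        _, sim2, _ = rt.cluster_ripples(zscore(scaled), k=3, seed=0)
        assert np.allclose(sim1, sim2, atol=1e-8)


def simulate_counts(rng, n_ripples=400, k=4, gain_label=None, gain=1.5, base=2.0):
    """Poisson counts per ripple with an optional label-specific gain; the
    covariate (CA1 population rate) also drives counts."""
    labels = rng.integers(1, k + 1, n_ripples)
    cov = rng.lognormal(0, 0.3, n_ripples)
    lam = base * cov
    if gain_label is not None:
        lam = lam * np.where(labels == gain_label, gain, 1.0)
    y = rng.poisson(lam).astype(float)
    return y, labels, cov


class TestAncova:
    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_tests = 2000
        for _ in range(n_tests):
            y, labels, cov = simulate_counts(rng)
            _, p = rt.ancova_fp(y, labels, cov)
            rejections += p < 0.01
        rate = rejections / n_tests
        assert rate <= 0.01 + 2.5 * np.sqrt(0.01 * 0.99 / n_tests)

    def test_planted_gain_detected(self):
        rng = np.random.default_rng(3)
        detected = 0
        for _ in range(200):
            y, labels, cov = simulate_counts(rng, gain_label=1, gain=1.5)
            _, p = rt.ancova_fp(y, labels, cov)
            detected += p < 0.01
        assert detected / 200 >= 0.9

    def test_covariate_absorbs_common_drive(self):
        # response fully explained by the covariate: label effect ~ alpha
        rng = np.random.default_rng(4)
        rejections = 0
        for _ in range(500):
            labels = rng.integers(1, 5, 300)
            cov = rng.standard_normal(300)
            y = 2.0 * cov + 0.1 * rng.standard_normal(300)
            _, p = rt.ancova_fp(y, labels, cov)
            rejections += p < 0.05
        assert rejections / 500 < 0.1

    def test_matches_statsmodels_reference(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        y, labels, cov = simulate_counts(rng, n_ripples=200)
        f, p = rt.ancova_fp(y, labels, cov)
        df = pd.DataFrame({"y": y, "lab": labels.astype(str), "cov": cov})
        fit = smf.ols("y ~ C(lab) + cov", data=df).fit()
        from statsmodels.stats.anova import anova_lm

        tab = anova_lm(fit, typ=2)
        assert f == pytest.approx(tab.loc["C(lab)", "F"], rel=1e-8)
        assert p == pytest.approx(tab.loc["C(lab)", "PR(>F)"], rel=1e-6)

    def test_shuffle_null_quantiles_uniform(self):
        rng = np.random.default_rng(6)
        y, labels, cov = simulate_counts(rng)
        f_obs, _ = rt.ancova_fp(y, labels, cov)
        null = np.array([rt.ancova_fp(y, rng.permutation(labels), cov)[0]
                         for _ in range(300)])
        q = (null < f_obs).mean()
        assert 0.01 < q < 0.99  # null data: observed F is a typical shuffle draw

    def test_unit_discrimination_on_planted_session(self, typed_session):
        cfg, _, _, spikes, truth = typed_session
        ca1 = spikes.select_units(spikes.units[spikes.units.region == "CA1"]["unit_id"])
        grsc = spikes.select_units(spikes.units[spikes.units.region == "gRSC_sup"]["unit_id"])
        onsets = truth.ca1_events.onsets
        cov = rt.population_rate_per_event(ca1, onsets)
        res = rt.unit_discrimination_ancova(grsc, onsets, truth.ripple_labels, cov)
        assert res["fraction_discriminating"] > 0.3
        null = rt.unit_discrimination_ancova(
            grsc, onsets, np.random.default_rng(0).permutation(truth.ripple_labels), cov)
        assert null["fraction_discriminating"] < res["fraction_discriminating"]


class TestFisher:
    def test_closed_form_chi2(self):
        combined = rt.fisher_combine([np.array([0.5]), np.array([0.5]), np.array([0.5])])
        assert combined[0] == pytest.approx(chi2.sf(-2 * 3 * np.log(0.5), 6), rel=1e-12)

    def test_single_session_identity(self):
        p = np.array([[0.1, 0.9]])
        assert np.array_equal(rt.fisher_combine([p]), p)


class TestLfpDiscrimination:
    def test_planted_preonset_band_difference_flagged(self):
        rng = np.random.default_rng(7)
        fs = 625.0
        n = int(400 * fs)
        trace = pink_noise(n, rng)
        onsets = np.arange(2.0, 398.0, 1.0)
        labels = rng.integers(1, 3, onsets.size)
        tt = np.arange(int(0.3 * fs)) / fs
        osc = np.hanning(tt.size) * np.sin(2 * np.pi * 8 * tt)
        for t, lab in zip(onsets, labels):
            if lab == 1:  # 8 Hz burst in the 300 ms before onset for label 1 only
                i = int((t - 0.3) * fs)
                trace[i : i + tt.size] += 2.0 * osc
        cov = rng.lognormal(0, 0.2, onsets.size)
        bands = np.logspace(np.log10(5), np.log10(50), 12)
        bands_, lags, pm = rt.lfp_band_pvals(trace, fs, onsets, labels, cov,
                                             bands=bands, halfwindow=0.5)
        band_sel = (bands_ >= 6) & (bands_ <= 10)
        pre = lags < 0
        assert pm[np.ix_(band_sel, pre)].min() < 1e-6
        # the effect is pre-onset, band-specific
        far = (bands_ > 25)
        assert pm[np.ix_(far, pre)].min() > pm[np.ix_(band_sel, pre)].min()

    def test_null_calibrated(self):
        rng = np.random.default_rng(8)
        fs = 625.0
        trace = pink_noise(int(200 * fs), rng)
        onsets = np.arange(2.0, 198.0, 1.0)
        labels = rng.integers(1, 3, onsets.size)
        cov = rng.lognormal(0, 0.2, onsets.size)
        _, _, pm = rt.lfp_band_pvals(trace, fs, onsets, labels, cov,
                                     bands=np.array([10.0, 40.0, 120.0]),
                                     halfwindow=0.3)
        assert (pm < 0.01).mean() < 0.06


class TestTsneDensity:
    def test_point_order_permutation_leaves_density_test_unchanged(self):
        # the density maps depend on the set of (point, label) pairs only
        rng = np.random.default_rng(9)
        xy = rng.standard_normal((120, 2)) * 10
        labels = rng.integers(1, 3, 120)
        r1 = rt.density_permutation_test(xy, labels, n_perm=50,
                                         rng=np.random.default_rng(0))
        perm = rng.permutation(120)
        r2 = rt.density_permutation_test(xy[perm], labels[perm], n_perm=50,
                                         rng=np.random.default_rng(0))
        for lab in r1["density"]:
            assert np.allclose(r1["density"][lab], r2["density"][lab], atol=1e-12)

    def test_planted_types_give_disjoint_significant_regions(self):
        cfg = rp.SynthConfig(duration=400.0, n_ripple_types=2, type_separation=2.5,
                             grsc_type_coupling=1.5, seed=31)
        _, _, spikes, truth = rp.generate_session(cfg)
        ca1 = spikes.select_units(spikes.units[spikes.units.region == "CA1"]["unit_id"])
        grsc = spikes.select_units(spikes.units[spikes.units.region == "gRSC_sup"]["unit_id"])
        onsets = truth.ca1_events.onsets
        v_ca1, _ = rt.ripple_rate_vectors(ca1, onsets)
        v_grsc, _ = rt.ripple_rate_vectors(grsc, onsets, window_s=0.2, exclude_types=())
        res = rt.tsne_density_test(v_ca1, v_grsc, truth.ripple_labels, n_perm=500, seed=0)
        m1, m2 = res["significant"][1], res["significant"][2]
        assert m1.sum() > 0 and m2.sum() > 0
        assert (m1 & m2).sum() == 0

    def test_too_few_ripples_rejected(self):
        with pytest.raises(InsufficientDataError):
            rt.tsne_density_test(np.zeros((10, 3)), np.zeros((10, 3)),
                                 np.ones(10, dtype=int))
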