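import numpy as np
import pytest
from scipy.special import i0, i1
from scipy.stats import kstest

from ripplepath import spectral
from ripplepath.core import InsufficientDataError

FS = 1250.0


class TestMorlet:
    def test_sine_power_ridge(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 150 * t)
        freqs = np.arange(50, 310, 10.0)
        sp = spectral.morlet_spectrogram(x, FS, freqs)
        pw = sp.power()[:, 1000:-1000].mean(axis=1)
        assert freqs[pw.argmax()] == 150.0
        assert pw.max() >= 10 * pw[np.abs(freqs - 150) > 30].max()

    def test_zero_signal_zero_power(self):
        sp = spectral.morlet_spectrogram(np.zeros(2000), FS, np.array([100.0]))
        assert np.abs(sp.values).max() == 0.0

    def test_linearity_amplitude_squared(self):
        t = np.arange(int(2 * FS)) / FS
        x = np.sin(2 * np.pi * 120 * t)
        freqs = np.array([80.0, 120.0, 200.0])
        p1 = spectral.morlet_spectrogram(x, FS, freqs).power()
        p2 = spectral.morlet_spectrogram(2 * x, FS, freqs).power()
        assert np.allclose(p2, 4 * p1)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(3000)
        freqs = np.array([50.0, 150.0])
        a = spectral.morlet_spectrogram(x, FS, freqs).power()
        b = spectral.morlet_spectrogram(x + 100.0, FS, freqs).power()
        assert np.allclose(a, b, rtol=1e-6, atol=1e-9)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            spectral.morlet_spectrogram(np.zeros(1000), FS, np.array([700.0]))


class TestEventTriggeredSpectrogram:
    def test_stationary_noise_z_bounded(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(120 * FS))
        sp = spectral.morlet_spectrogram(x, FS, np.array([50.0, 150.0, 250.0]))
        events = np.arange(2.0, 118.0, 1.0)
        out = spectral.event_triggered_spectrogram(sp, events)
        # averaged z over ~116 events shrinks; no bin should reach |z|=3
        assert np.abs(out.values).max() < 3

    def test_single_event_equals_its_map(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(10 * FS))
        sp = spectral.morlet_spectrogram(x, FS, np.array([100.0]))
        one = spectral.event_triggered_spectrogram(sp, np.array([5.0]))
        again = spectral.event_triggered_spectrogram(sp, np.array([5.0, 5.0]))
        assert np.allclose(one.values, again.values)

    def test_planted_ripples_peak_at_ripple_band(self, session600):
        cfg, ca1, _, _, truth = session600
        x = ca1.channel(0)[: int(150 * cfg.fs)]
        freqs = np.array([30.0, 90.0, 170.0, 250.0])
        sp = spectral.morlet_spectrogram(x, cfg.fs, freqs)
        peaks = truth.ca1_events.peaks
        peaks = peaks[(peaks > 1) & (peaks < 148)]
        out = spectral.event_triggered_spectrogram(sp, peaks, window=(-0.05, 0.05))
        band_max = out.values.max(axis=1)
        assert freqs[band_max.argmax()] == 170.0

    def test_late_baseline_rejected(self):
        sp = spectral.Spectrogram(values=np.zeros((1, 100), complex),
                                  freqs=np.array([10.0]),
                                  times=np.arange(100) / FS)
        with pytest.raises(ValueError):
            spectral.event_triggered_spectrogram(sp, np.array([0.04]),
                                                 baseline=(-0.2, -0.05))


class TestPhaseCoherogram:
    def test_identical_traces_full_coherence(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(30 * FS))
        events = np.arange(1.0, 29.0, 1.0)
        out = spectral.phase_coherogram(x, x, FS, events, np.array([20.0, 100.0]))
        assert np.allclose(out.values, 1.0)

    def test_independent_noise_low_coherence(self):
        rng = np.random.default_rng(4)
        n = int(120 * FS)
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        events = np.arange(1.0, 119.0, 1.18)  # ~100 events
        out = spectral.phase_coherogram(a, b, FS, events, np.array([50.0]))
        # null resultant ~ sqrt(pi/(4n)) ≈ 0.089 at n=100
        assert out.values.mean() < 0.2

    def test_delay_gives_constant_phase_offset_and_high_coherence(self):
        rng = np.random.default_rng(5)
        n = int(30 * FS)
        a = rng.standard_normal(n)
        delay = int(0.004 * FS)  # 4 ms
        b = np.roll(a, delay)
        events = np.arange(1.0, 29.0, 0.5)
        sa = spectral.morlet_spectrogram(a, FS, np.array([100.0]))
        sb = spectral.morlet_spectrogram(b, FS, np.array([100.0]))
        dphi = np.angle(sa.values[0, 2000:-2000]) - np.angle(sb.values[0, 2000:-2000])
        mean_off = np.angle(np.mean(np.exp(1j * dphi)))
        expected = 2 * np.pi * 100.0 * delay / FS  # reference leads its delayed copy
        err = np.angle(np.exp(1j * (mean_off - expected)))
        assert abs(err) < 0.1
        out = spectral.phase_coherogram(a, b, FS, events, np.array([100.0]))
        # near 1, limited by wavelet-bandwidth dephasing over the 4 ms delay
        assert out.values.mean() > 0.85

    def test_swap_symmetry(self):
        rng = np.random.default_rng(6)
        n = int(20 * FS)
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        events = np.arange(1.0, 19.0, 1.0)
        ab = spectral.phase_coherogram(a, b, FS, events, np.array([80.0]))
        ba = spectral.phase_coherogram(b, a, FS, events, np.array([80.0]))
        assert np.allclose(ab.values, ba.values)


class TestSpikeFieldCoherence:
    def test_trough_locked_spikes_peak_at_sine_frequency(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 160 * t)
        troughs = (np.arange(0.75, 160 * 59, 1.0)) / 160.0  # every trough
        events = np.arange(1.0, 59.0, 0.5)
        freqs, coh = spectral.spike_field_coherence(troughs, x, FS, events)
        band = (freqs > 120) & (freqs < 200)
        assert coh[band].max() > 0.9
        assert freqs[np.argmax(coh * band)] == pytest.approx(160.0, abs=15)

    def test_independent_poisson_low_coherence(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(int(60 * FS))
        spikes = np.sort(rng.uniform(0, 60, 600))
        events = np.arange(1.0, 59.0, 0.5)
        freqs, coh = spectral.spike_field_coherence(spikes, x, FS, events)
        # jittered-spike surrogate bias floor
        floors = []
        for _ in range(5):
            jit = np.sort(spikes + rng.uniform(-0.05, 0.05, spikes.size))
            _, c = spectral.spike_field_coherence(jit, x, FS, events)
            floors.append(c)
        floor = np.mean(floors, axis=0) + 3 * np.std(floors, axis=0)
        assert (coh[1:] <= floor[1:] + 0.15).mean() > 0.95

    def test_zero_spikes_raises(self):
        with pytest.raises(InsufficientDataError):
            spectral.spike_field_coherence(np.array([]), np.zeros(int(2 * FS)), FS,
                                           np.array([1.0]))


class TestFilterHilbertPhase:
    def test_phase_advances_at_signal_frequency(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 150 * t)
        ph, amp = spectral.filter_hilbert_phase(x, FS, (100, 280))
        slope = np.polyfit(t[500:-500], np.unwrap(ph)[500:-500], 1)[0] / (2 * np.pi)
        assert slope == pytest.approx(150.0, rel=0.001)

    def test_constant_signal_flagged_by_amplitude(self):
        ph, amp = spectral.filter_hilbert_phase(np.full(int(2 * FS), 5.0), FS, (100, 280))
        assert np.abs(amp[200:-200]).max() < 1e-6

    def test_sign_flip_shifts_phase_by_pi(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 150 * t)
        ph1, _ = spectral.filter_hilbert_phase(x, FS, (100, 280))
        ph2, _ = spectral.filter_hilbert_phase(-x, FS, (100, 280))
        d = np.angle(np.exp(1j * (ph1 - ph2)))[500:-500]
        assert np.allclose(np.abs(d), np.pi, atol=1e-6)


class TestITPC:
    def test_all_equal_phases(self):
        assert spectral.itpc(np.full(7, 0.3)) == pytest.approx(1.0)

    def test_symmetric_phases_cancel(self):
        assert spectral.itpc(np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])) < 1e-12

    def test_von_mises_matches_bessel_ratio(self):
        rng = np.random.default_rng(8)
        ph = rng.vonmises(0.0, 2.0, 1000)
        assert spectral.itpc(ph) == pytest.approx(i1(2) / i0(2), abs=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spectral.itpc(np.array([]))

    def test_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            v = spectral.itpc(rng.uniform(-np.pi, np.pi, rng.integers(1, 50)))
            assert 0.0 <= v <= 1.0


class TestRayleigh:
    def test_uniform_p_values_are_uniform(self):
        rng = np.random.default_rng(10)
        ps = [spectral.rayleigh_test(rng.uniform(-np.pi, np.pi, 60)) for _ in range(400)]
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_concentrated_phases_tiny_p(self):
        assert spectral.rayleigh_test(np.full(50, 1.0)) < 1e-10

    def test_small_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            spectral.rayleigh_test(np.zeros(4))

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        ph = rng.vonmises(1.0, 0.5, 80)
        z, p_ref = pingouin.circ_rayleigh(ph)
        assert spectral.rayleigh_test(ph) == pytest.approx(p_ref, rel=1e-6)


class TestPAC:
    def test_single_bin_concentration_gives_mi_one(self):
        dig = np.zeros(1000, dtype=int)  # all phases in bin 0
        amp = np.ones((1, 1000))
        mi = spectral._binned_mi(dig, amp, 50)
        assert mi[0] == 1.0

    def test_uniform_amplitude_gives_mi_zero(self):
        rng = np.random.default_rng(12)
        dig = rng.integers(0, 50, 100_000)
        amp = np.ones((1, 100_000))
        mi = spectral._binned_mi(dig, amp, 50)
        assert mi[0] == pytest.approx(0.0, abs=1e-12)

    def test_cosine_modulation_matches_brute_force(self):
        rng = np.random.default_rng(13)
        fs = FS
        n = int(40 * fs)
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 8 * t) + (1 + np.cos(2 * np.pi * 8 * t)) * 0.3 * np.sin(
            2 * np.pi * 160 * t) + 0.05 * rng.standard_normal(n)
        pf, af = np.array([8.0]), np.array([160.0])
        mi, pz, masked = spectral.pac_modulation_index(x, fs, pf, af, n_surrogates=20,
                                                       rng=np.random.default_rng(0))
        # independent brute-force KL computation from the same wavelet outputs
        sp = spectral.morlet_spectrogram(x, fs, pf)
        sa = spectral.morlet_spectrogram(x, fs, af)
        phases = np.angle(sp.values[0])
        amps = np.abs(sa.values[0])
        edges = np.linspace(-np.pi, np.pi, 51)
        means = np.zeros(50)
        for b in range(50):
            sel = (phases >= edges[b]) & (phases < edges[b + 1])
            means[b] = amps[sel].mean() if sel.any() else 0.0
        p = means / means.sum()
        h = -(p[p > 0] * np.log(p[p > 0])).sum()
        mi_bf = (np.log(50) - h) / np.log(50)
        assert mi[0, 0] == pytest.approx(mi_bf, abs=1e-6)

    def test_null_masked_to_zero(self):
        nz = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = rng.standard_normal(int(15 * 1000))
            _, _, masked = spectral.pac_modulation_index(
                x, 1000.0, np.array([8.0]), np.array([160.0]),
                n_surrogates=200, rng=rng)
            nz += int((masked > 0).any())
        assert nz <= 1

    def test_mi_bounds(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal(int(10 * 1000))
        mi, _, masked = spectral.pac_modulation_index(
            x, 1000.0, np.array([6.0, 10.0]), np.array([100.0, 200.0]),
            n_surrogates=20, rng=rng)
        assert np.all(mi >= 0) and np.all(mi <= 1)
        assert np.all(masked >= 0)
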