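import numpy as np
import pytest

import ripplepath as rp


@pytest.fixture(scope="session")
def session600():
    """Standard 600 s two-region session: ripple rate 0.5 Hz, SNR 8."""
    cfg = rp.SynthConfig(duration=600.0, ca1_ripple_rate=0.5, ripple_snr=8.0,
                         propagation_prob=0.5, seed=1)
    ca1, grsc, spikes, truth = rp.generate_session(cfg)
    return cfg, ca1, grsc, spikes, truth


@pytest.fixture(scope="session")
def typed_session():
    """Session with 10 well-separated planted ripple types and gRSC coupling."""
    cfg = rp.SynthConfig(duration=600.0, n_ripple_types=10, type_separation=2.5,
                         grsc_type_coupling=1.0, seed=7)
    ca1, grsc, spikes, truth = rp.generate_session(cfg)
    return cfg, ca1, grsc, spikes, truth


def match_events(true_times: np.ndarray, detected_times: np.ndarray, tol: float):
    """Greedy one-to-one matching of event times; returns (n_matched, errors)."""
    used = set()
    errors = []
    detected_times = np.asarray(detected_times)
    for t in np.asarray(true_times):
        if detected_times.size == 0:
            break
        d = np.abs(detected_times - t)
        j = int(np.argmin(d))
        if d[j] <= tol and j not in used:
            used.add(j)
            errors.append(d[j])
    return len(errors), np.asarray(errors)
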