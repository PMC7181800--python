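"""End-to-end orchestration of the analysis stages on one session.

``run_pipeline`` executes the stages in dependency order (generate/load →
ripple detection → spectral & laminar → units & state → ripple typing),
writes every stage's tables under the output directory, and records a
manifest with the full parameter set, seed and package versions, so a run
is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, ripples, ripple_typing, state, units
from .synth import SynthConfig, generate_session

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("detect", "spectral", "laminar", "units", "state", "typing")
DEPENDS = {"spectral": ("detect",), "laminar": ("detect",), "units": ("detect",),
           "state": (), "typing": ("detect",)}


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters with their literature defaults; YAML round-trips."""

    seed: int = 0
    out_dir: str = "results/pipeline"
    stages: tuple = STAGES
    synth: dict = dataclasses.field(default_factory=dict)
    ripple_params: dict = dataclasses.field(default_factory=dict)
    typing_k: int = 10
    rate_vector_window_s: float = 0.1
    peth_binsize: float = 0.01
    peth_halfwindow: float = 0.5

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["stages"] = tuple(d.get("stages", STAGES))
        return cls(**d)


class DependencyError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages on a synthetic session; returns the result bundle."""
    out = io.ensure_dir(config.out_dir)
    log: list[str] = []
    enabled = set(config.stages)
    for stage in enabled:
        for dep in DEPENDS.get(stage, ()):
            if dep not in enabled:
                raise DependencyError(f"stage '{stage}' requires disabled stage '{dep}'")

    cfg = SynthConfig(**{**config.synth, "seed": config.seed})
    ca1, grsc, spikes, truth = generate_session(cfg)
    log.append(f"synth: {cfg.duration:.0f} s session, {len(truth.ca1_events)} planted ripples")
    io.write_spike_data(spikes, out / "spikes.tsv", out / "units.tsv")
    io.write_intervals(truth.states, out / "true_states.tsv")

    results: dict = {"config": config, "truth": truth}
    ca1_trace = ca1.channel(0)
    sup_trace = grsc.samples[0]

    for stage in STAGES:
        if stage not in enabled:
            log.append(f"{stage}: skipped (disabled)")
            continue
        if stage == "detect":
            params = ripples.RippleParams(**config.ripple_params)
            ev = ripples.detect_ripples(ca1_trace, ca1.fs, params)
            io.write_events(ev, out / "ripples_ca1.tsv")
            results["ripples"] = ev
            log.append(f"detect: {len(ev)} CA1 ripple events")
        elif stage == "spectral":
            ev = results["ripples"]
            _, env = ripples.ripple_envelope(sup_trace, grsc.fs)
            lags, med, sem = ripples.peak_power_lags(ev, env, grsc.fs)
            pd.DataFrame({"lag_ms": lags}).to_csv(out / "peak_power_lags.tsv", sep="\t", index=False)
            results["propagation_lag_ms"] = (med, sem)
            log.append(f"spectral: median gRSC envelope lag {med:.2f} ms")
        elif stage == "laminar":
            ev = results["ripples"]
            from .laminar import inverse_csd

            w = int(0.05 * grsc.fs)
            segs = []
            for pk in ev.peaks:
                i = int(pk * grsc.fs)
                if i - w >= 0 and i + w < grsc.n_samples:
                    segs.append(grsc.samples[:, i - w : i + w])
            mean_lfp = np.mean(segs, axis=0)
            prof = inverse_csd(mean_lfp, grsc.channels["depth_um"].to_numpy())
            pd.DataFrame(prof.values).to_csv(out / "csd.tsv", sep="\t", index=False)
            results["csd"] = prof
            log.append(f"laminar: CSD over {len(prof.depths_um)} depths, {len(segs)} events")
        elif stage == "units":
            qc = units.qc_filter_units(spikes, cfg.duration)
            ev = results["ripples"]
            flags = {}
            for uid in qc.units["unit_id"]:
                try:
                    ph = units.peth(qc.unit_times(uid), ev.onsets,
                                    binsize=config.peth_binsize,
                                    halfwindow=config.peth_halfwindow)
                    flags[uid] = units.peth_significance(ph).modulation
                except Exception:
                    flags[uid] = "none"
            pd.DataFrame(flags.items(), columns=["unit_id", "modulation"]).to_csv(
                out / "peth_modulation.tsv", sep="\t", index=False)
            results["peth_flags"] = flags
            n_exc = sum(v == "excited" for v in flags.values())
            log.append(f"units: {qc.n_units} units pass QC, {n_exc} ripple-excited")
        elif stage == "state":
            grsc_units = spikes.select_units(
                spikes.units[spikes.units["region"].str.startswith("gRSC")]["unit_id"])
            times, rate, counts = state.smoothed_mua(grsc_units, cfg.duration)
            packets = state.detect_packets(rate)
            si = state.state_index(counts)
            emg_t, emg_v = state.emg_from_lfp(grsc)
            seg = state.segment_states(times, si, emg_t, emg_v)
            io.write_events(packets, out / "packets.tsv")
            io.write_intervals(seg, out / "states.tsv")
            results["states"] = seg
            results["packets"] = packets
            log.append(f"state: {len(packets)} packets, {len(seg)} state intervals")
        elif stage == "typing":
            ev = results["ripples"]
            ca1_units = spikes.select_units(
                spikes.units[spikes.units["region"] == "CA1"]["unit_id"])
            mat, _ = ripple_typing.ripple_rate_vectors(
                ca1_units, ev.onsets, config.rate_vector_window_s)
            if mat.shape[0] >= config.typing_k:
                labels, sim, order = ripple_typing.cluster_ripples(
                    mat, k=config.typing_k, seed=config.seed)
                pd.DataFrame({"onset_s": ev.onsets, "label": labels}).to_csv(
                    out / "ripple_labels.tsv", sep="\t", index=False)
                results["ripple_labels"] = labels
                log.append(f"typing: {config.typing_k} clusters over {len(labels)} ripples")
            else:
                log.append("typing: skipped (fewer ripples than k)")

    manifest = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "synth_config": dataclasses.asdict(cfg),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "log": log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    results["log"] = log
    results["manifest"] = manifest
    return results
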