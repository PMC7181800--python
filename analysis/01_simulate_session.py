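#!/usr/bin/env python
"""Generate the standard synthetic two-region session and write it to disk.

Emits the raw-binary + TSV session formats (CA1 and gRSC recordings,
spikes, unit metadata) plus the ground-truth bundle (planted ripple and
packet times, state intervals, ripple-type labels) that the later analysis
stages are checked against.
"""

import argparse
from pathlib import Path

import pandas as pd

import ripplepath as rp
from ripplepath import io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--duration", type=float, default=600.0)
    ap.add_argument("--out-dir", type=Path, default=Path("results/session"))
    args = ap.parse_args()

    cfg = rp.SynthConfig(duration=args.duration, ca1_ripple_rate=0.5,
                         ripple_snr=8.0, propagation_prob=0.5, seed=args.seed)
    ca1, grsc, spikes, truth = rp.generate_session(cfg)
    out = io.ensure_dir(args.out_dir)

    # session data in the raw acquisition conventions (scaled into int16 range)
    scale = 1000.0
    io.write_binary_recording(rp.Recording(ca1.samples * scale, ca1.fs, ca1.channels),
                              out / "ca1.dat")
    io.write_binary_recording(rp.Recording(grsc.samples * scale, grsc.fs, grsc.channels),
                              out / "grsc.dat")
    io.write_channel_map(ca1.channels, out / "ca1.channels.tsv")
    io.write_channel_map(grsc.channels, out / "grsc.channels.tsv")
    io.write_spike_data(spikes, out / "spikes.tsv", out / "units.tsv")

    # ground truth bundle
    io.write_events(truth.ca1_events, out / "truth_ripples_ca1.tsv")
    io.write_events(truth.grsc_events, out / "truth_ripples_grsc.tsv")
    io.write_intervals(truth.states, out / "truth_states.tsv")
    pd.DataFrame({"peak_s": truth.packet_times}).to_csv(
        out / "truth_packets.tsv", sep="\t", index=False)
    pd.DataFrame({"onset_s": truth.ca1_events.onsets,
                  "label": truth.ripple_labels}).to_csv(
        out / "truth_ripple_labels.tsv", sep="\t", index=False)

    print(f"session: {cfg.duration:.0f} s at {cfg.fs:.0f} Hz, seed {cfg.seed}")
    print(f"planted CA1 ripples: {len(truth.ca1_events)} "
          f"({len(truth.grsc_events)} propagate to gRSC)")
    print(f"units: {spikes.n_units}  spikes: {len(spikes.spikes)}")
    print(f"state intervals: {len(truth.states)}  packets: {truth.packet_times.size}")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
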