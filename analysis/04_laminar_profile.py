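#!/usr/bin/env python
"""Laminar source analysis of the gRSC response to hippocampal ripples.

Builds the CA1-ripple-triggered average across the gRSC depth stack, runs
the inverse-method CSD on it (superficial sink expected where the negative
wave and ripple ride), and cross-validates the depth profile with ICA
loadings of the leading event-locked component.
"""

import argparse
from pathlib import Path
import sys
from importlib import import_module

import numpy as np
import pandas as pd

from ripplepath import io, laminar

sys.path.insert(0, str(Path(__file__).parent))
load_session = import_module("02_detect_ripples").load_session


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--session-dir", type=Path, default=Path("results/session"))
    ap.add_argument("--ripple-dir", type=Path, default=Path("results/ripples"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/laminar"))
    args = ap.parse_args()

    _, grsc = load_session(args.session_dir)
    ev = io.read_events(args.ripple_dir / "ripples_ca1.tsv")
    out = io.ensure_dir(args.out_dir)

    w = int(0.05 * grsc.fs)
    segs = []
    for pk in ev.peaks:
        i = int(pk * grsc.fs)
        if i - w >= 0 and i + w < grsc.n_samples:
            segs.append(grsc.samples[:, i - w : i + w])
    mean_lfp = np.mean(segs, axis=0)
    depths = grsc.channels["depth_um"].to_numpy()
    times = (np.arange(-w, w) / grsc.fs)

    prof = laminar.inverse_csd(mean_lfp, depths, times=times)
    pd.DataFrame(prof.values, index=depths, columns=np.round(times, 4)).to_csv(
        out / "csd.tsv", sep="\t")
    sink_depth = depths[np.argmin(prof.values.min(axis=1))]

    loads, p, meta = laminar.ica_event_loadings(grsc.samples, grsc.fs, ev.peaks,
                                                rng=args.seed)
    pd.DataFrame({"depth_um": depths, "loading": loads}).to_csv(
        out / "ica_loadings.tsv", sep="\t", index=False)
    sup = np.abs(loads[: len(loads) // 2]).mean()
    deep = np.abs(loads[len(loads) // 2 :]).mean()

    print(f"event-triggered average over {len(segs)} ripples, {len(depths)} depths")
    print(f"strongest CSD sink at {sink_depth:.0f} µm (superficial = 0 µm)")
    print(f"leading IC loadings: |superficial| {sup:.2f} vs |deep| {deep:.2f} "
          f"(rank-sum p = {p:.2g})")
    print(f"tables under {out}")


if __name__ == "__main__":
    main()
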