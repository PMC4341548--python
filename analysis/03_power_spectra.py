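#!/usr/bin/env python
"""Conventional spectral analysis of the same segments.

Computes the Hann-windowed, epoch-averaged log10 power spectra
(2 s epochs, 0.5 Hz resolution), writes the tidy table to
results/spectra.csv, runs the occipital alpha-dominance wakefulness check
per session, and prints per-condition band powers (theta-alpha 4-13 Hz vs
beta-gamma 13-60 Hz), which fall with ECT in the slow range.
"""

import argparse
from pathlib import Path

import numpy as np

from ectmse.io import CONDITIONS
from ectmse.pipeline import load_study, spectra_table
from ectmse.spectral import alpha_dominance_check, power_spectrum

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=ROOT / "scratch" / "study")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "spectra.csv")
    args = ap.parse_args()

    sessions = load_study(args.study / "manifest.yaml", args.study / "clinical.csv")
    df = spectra_table(sessions)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    print(f"{len(df)} spectrum rows -> {args.out}")

    n_awake = sum(
        alpha_dominance_check(
            power_spectrum(rec.segments["O1"][0]), power_spectrum(rec.segments["O2"][0])
        )
        for rec in sessions
    )
    print(f"alpha-dominant (eyes-closed wakefulness) sessions: {n_awake}/{len(sessions)}")

    lin = 10.0 ** df["log_power"]
    df = df.assign(power=lin)
    print("\nmean band power per condition (slow 4-13 Hz | fast 13-60 Hz):")
    for cond in CONDITIONS:
        sub = df[df["condition"] == cond]
        slow = sub[(sub.freq_hz >= 4) & (sub.freq_hz < 13)]["power"].mean()
        fast = sub[(sub.freq_hz >= 13) & (sub.freq_hz < 60)]["power"].mean()
        print(f"  {cond:<12} {slow:9.3f} | {fast:7.3f}")


if __name__ == "__main__":
    main()
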