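#!/usr/bin/env python
"""Generate the surrogate treatment-course study.

Writes a full 24-session course (3 pre-ECT, 7 during, 8 after, 6 lorazepam;
two segments x 8 channels each) as matrix CSVs plus the clinical and ECT
course tables.  Segments are 10 s here — long enough for stable entropy
estimates at every scale factor while keeping the downstream analyses quick;
pass --segment-s 30 for the full-length protocol.

EEG data land under scratch/study (bulky intermediates); the session
manifest path is printed for the next stages.
"""

import argparse
from pathlib import Path

from ectmse.synth import GeneratorConfig, write_study

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--segment-s", type=float, default=10.0)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "study")
    args = ap.parse_args()

    cfg = GeneratorConfig(seed=args.seed, segment_s=args.segment_s)
    manifest = write_study(cfg, args.out)
    n = sum(cfg.n_sessions_per_condition.values())
    print(f"wrote {n} sessions ({cfg.segment_s:g} s segments, seed {cfg.seed})")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
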