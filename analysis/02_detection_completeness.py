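#!/usr/bin/env python
"""Is every cavity entry visible as a clear vibroacoustic excitation?

Simulates 154 cavity-reaching insertions, runs the pre-processing and
excitation-detection stages on each full recording, and reports the
fraction in which a cavity-class excitation (dominant peak with a slow,
free-oscillation decay) is found — the study's headline detection claim
is 100 %.

Output: results/detection.csv (per-insertion outcome).
"""

import argparse
from pathlib import Path

from vaneedle.study import detection_cohort


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20240805)
    ap.add_argument("--n", type=int, default=154)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = detection_cohort(n=args.n, seed=args.seed)
    args.results.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.results / "detection.csv", index=False)
    n_det = int(df["detected"].sum())
    print(f"cavity excitation detected in {n_det}/{len(df)} insertions "
          f"({100.0 * n_det / len(df):.2f} %)")
    print(f"worst peak-timing error: {df['peak_error_ms'].max():.2f} ms")
    print(f"wrote {args.results / 'detection.csv'}")


if __name__ == "__main__":
    main()
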