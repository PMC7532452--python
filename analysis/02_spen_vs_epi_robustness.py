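#!/usr/bin/env python
"""Quantify SPEN's off-resonance robustness against an interleaved-EPI
comparator.

Twenty phantoms are imaged by both pipelines with and without a uniform
300 Hz static field offset; the apparent displacement along the phase/SPEN
axis is measured by cross-correlation.  Writes the per-replicate table to
results/spen_vs_epi.csv and prints the summary.
"""

import argparse
from pathlib import Path

from fetomri.experiments import offresonance_robustness

HERE = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--df-hz", type=float, default=300.0)
    ap.add_argument("--out", type=Path, default=HERE / "results")
    args = ap.parse_args()

    df = offresonance_robustness(seed=args.seed, n_rep=20, df_hz=args.df_hz)
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "spen_vs_epi.csv", index=False, float_format="%.6g")
    frac = (df.spen_shift < df.epi_shift).mean()
    print(
        f"offset {args.df_hz:.0f} Hz: SPEN shift {df.spen_shift.mean():.2f} vox, "
        f"EPI shift {df.epi_shift.mean():.2f} vox "
        f"(analytic EPI prediction {df.epi_predicted.iloc[0]:.2f}); "
        f"SPEN less displaced in {frac:.0%} of {len(df)} replicates"
    )


if __name__ == "__main__":
    main()
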