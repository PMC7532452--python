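#!/usr/bin/env python
"""Steepest-slope DCE perfusion analysis.

Validates the estimator on single-voxel ground truth (native 7.68 s frame
time, then the bias as the frame time halves twice), then runs the
end-to-end phantom study: wildtype vs knockout placental-layer perfusion
and the fetal-liver/placenta ratio that separates an intact from a leaky
placental barrier.  Writes results/perfusion_summary.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from fetomri.experiments import steepest_slope_recovery

HERE = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=HERE / "results")
    args = ap.parse_args()

    res = steepest_slope_recovery(seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for model, r in res["ratios"].items():
        rows.append(dict(model_class=model, **r))
    pd.DataFrame(rows).to_csv(args.out / "perfusion_summary.csv", index=False,
                              float_format="%.6g")
    (args.out / "perfusion_estimator.json").write_text(
        json.dumps(dict(rel_err_native=res["rel_err_native"],
                        biases=res["biases"]), indent=1)
    )

    print(f"estimator error at 7.68 s frames: {100 * res['rel_err_native']:.1f}%")
    print("bias vs frame time:",
          {k: f"{100 * v:+.1f}%" for k, v in res["biases"].items()})
    for model, r in res["ratios"].items():
        print(f"  {model:10s} labyrinth {r['labyrinth']:.4f} s⁻¹, "
              f"decidua {r['decidua']:.4f} s⁻¹, "
              f"liver/placenta = {r['liver_over_placenta']:.3g}")


if __name__ == "__main__":
    main()
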