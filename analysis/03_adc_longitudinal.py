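#!/usr/bin/env python
"""Longitudinal ADC analysis of the simulated cohorts.

Runs the end-to-end recovery study (phantom → SPEN encode → reconstruct →
ADC fit → per-region Gaussian statistics), writes the cohort table,
model-contrast statistics and recovery errors under results/, and prints
the designed-ordering checks (knockout placentas slower than wildtype,
broadest l-NAME spread, fetal-brain diffusivity falling with age, wildtype
brain spread narrowing fastest).
"""

import argparse
from pathlib import Path

from fetomri.adc import compare_models, longitudinal_summary, per_animal_breakdown
from fetomri.experiments import adc_recovery_study

HERE = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=HERE / "results")
    args = ap.parse_args()

    res = adc_recovery_study(seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    res["table"].to_csv(args.out / "adc_cohort_table.csv", index=False,
                        float_format="%.8g")
    res["merged"].to_csv(args.out / "adc_recovery_errors.csv", index=False,
                         float_format="%.8g")
    per_animal_breakdown(res["fits"]).to_csv(
        args.out / "adc_per_animal.csv", index=False, float_format="%.8g"
    )

    table = res["table"]
    wt = table[table.model_class == "wildtype"]
    rows = []
    for model in ("enos_ko", "il10_ko", "lname"):
        other = table[table.model_class == model]
        try:
            rows.append(
                dict(model=model,
                     **compare_models(wt, other, "mu", 14.5, "placenta"))
            )
        except ValueError:
            continue
    import pandas as pd

    pd.DataFrame(rows).to_csv(args.out / "adc_model_contrasts.csv", index=False,
                              float_format="%.6g")

    print(f"worst cohort-mean ADC recovery error: "
          f"{100 * res['max_mu_rel_err']:.1f}%")
    for name, ok in res["orderings"].items():
        print(f"  {'PASS' if ok else 'FAIL'}  {name}")
    for r in rows:
        print(f"  wildtype vs {r['model']}: placental Δμ = "
              f"{r['difference']:.2e} mm²/s, p = {r['p_value']:.2g}")


if __name__ == "__main__":
    main()
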