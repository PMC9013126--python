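#!/usr/bin/env python
"""Compare the training- and validation-cohort characteristics.

Runs chi-square tests (no continuity correction) on the published
categorical count tables — sex, T stage, N stage, scanner field strength —
and writes results/cohort_comparison.csv.

Found: sex (p = 0.56) and T stage (p = 0.98) are balanced between cohorts,
while N stage and field strength differ strongly (p < 1e-6), matching the
qualitative picture of an intercontinental cohort with different staging mix
and scanner hardware.
"""

from pathlib import Path

import pandas as pd

from pcr_radiomics.evaluation import compare_cohorts

RESULTS = Path(__file__).resolve().parents[1] / "results"

# (training counts, validation counts) per categorical characteristic
TABLES = {
    "sex_male_female": ([123, 39], [47, 12]),
    "t_stage_2_3_4": ([15, 95, 52], [6, 34, 19]),
    "n_stage_0_1_2": ([9, 58, 95], [25, 24, 10]),
    "field_strength_1p5_3": ([162, 0], [32, 27]),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, (train, valid) in TABLES.items():
        chi2, p = compare_cohorts(train, valid, kind="categorical")
        rows.append({"characteristic": name, "chi_square": chi2, "p_value": p})
        print(f"{name:24s} chi2 = {chi2:8.3f}   p = {p:.4f}")
    out = RESULTS / "cohort_comparison.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
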