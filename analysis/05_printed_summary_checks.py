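"""Reproductions computable from the published summary statistics alone.

The imaging cluster tables derive from unshared patient MRI data; what is
reproducible at the desk is (a) the cohort descriptives from the packaged
demographics table and (b) the volumetric two-sample t-tests from the
printed group means/SDs (top / middle / bottom thirds and total S1).
"""

from pathlib import Path

import pandas as pd

from painhub.cohort import summarize_cohort
from painhub.stats import t_test_from_summary
from painhub.synthetic import load_table1_fixture

ROOT = Path(__file__).resolve().parents[1]

PRINTED = [
    # measure, patient mean/sd, control mean/sd
    ("top_third", 5416, 932, 4781, 783),
    ("middle_third", 5696, 946, 5554, 1080),
    ("bottom_third", 5863, 1029, 5863, 1198),
    ("total", 16977, 2868, 16198, 2739),
]


def main() -> None:
    summary = summarize_cohort(load_table1_fixture())
    pat = summary[summary["group"] == "patient"].iloc[0]
    print(f"patients: age {pat['age_mean']} +/- {pat['age_sd']}, "
          f"{pat['n_female']} F / {pat['n_male']} M, BDI {pat['bdi_mean']}, "
          f"duration {pat['duration_yrs_mean']} yrs, BPI {pat['bpi_avg_mean']}")

    rows = []
    for name, m1, s1, m2, s2 in PRINTED:
        t, df, p = t_test_from_summary(m1, s1, 18, m2, s2, 18)
        rows.append({"measure": name, "patient": f"{m1} +/- {s1}",
                     "control": f"{m2} +/- {s2}", "t": round(t, 3),
                     "df": df, "p": round(p, 4)})
    table = pd.DataFrame(rows)
    print(table.to_string(index=False))
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    summary.to_csv(results / "table1_descriptives.tsv", sep="\t", index=False)
    table.to_csv(results / "summary_volume_ttests.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
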