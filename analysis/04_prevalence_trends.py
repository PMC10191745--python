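"""Per-year prevalence of each utilisation group with 95% CIs.

Computes per-10,000 prevalence (exact Clopper-Pearson intervals) by
calendar year and overall from the classification table, plus the cohort
description (deliveries, maternal age, caesarean share) per year.
"""

from pathlib import Path

import pandas as pd

from pregclaims import cohort_summary, stratify_by_year

OUT = Path("results")

labels = pd.read_csv(OUT / "classification.csv")
prev = stratify_by_year(labels)
prev.to_csv(OUT / "prevalence_by_year.csv", index=False)

eps = pd.read_csv(OUT / "episodes.csv").rename(
    columns={"maternal_age_at_delivery": "maternal_age"}
)
summary = cohort_summary(eps)
summary.to_csv(OUT / "cohort_summary.csv", index=False)

overall = prev[prev.stratum == "overall"].set_index("group")
print("Overall prevalence per 10,000 enrolled pregnancies (95% CI):")
for g in ("pregestational_continuer", "pregestational_switcher", "gdm", "discontinuer"):
    if g in overall.index:
        r = overall.loc[g]
        print(f"  {g:28s} {r.rate_per_10k:7.1f}  ({r.ci_low_per_10k:.1f}-{r.ci_high_per_10k:.1f})")
print()
print("Cohort description:")
print(summary.to_string(index=False))
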