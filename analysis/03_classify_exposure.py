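"""Classify each episode's antidiabetic dispensation pattern.

Builds per-window exposure profiles from the dispensation table, assigns
the utilisation-group labels (pregestational continuer/switcher, GDM,
discontinuer, T1-only, unexposed), flags fertility comedication, and
tabulates prepregnancy substance shares among discontinuers.  Verifies
the labels against the simulator's ground truth.
"""

import datetime as dt
from pathlib import Path

import pandas as pd

from pregclaims import CodeConfig, GroupLabel, read_claims
from pregclaims.deliveries import DeliveryEvent
from pregclaims.exposure import classify_episodes, substance_distribution
from pregclaims.timing import build_episode

CLAIMS = Path("results/claims")
OUT = Path("results")

config = CodeConfig.default()
bundle = read_claims(CLAIMS / "services.csv", CLAIMS / "dispensations.csv",
                     CLAIMS / "enrollment.csv", config)
eps_df = pd.read_csv(OUT / "episodes.csv")
episodes = [
    build_episode(DeliveryEvent(str(r.person_id), dt.date.fromisoformat(r.delivery_date),
                                r.term_status, True, False, bool(r.caesarean), []))
    for r in eps_df.itertuples()
]
profiles, assignments, table = classify_episodes(episodes, bundle.dispensations, config)
table.to_csv(OUT / "classification.csv", index=False)

print("Utilisation groups among enrolled pregnancies:")
print(table.group.value_counts().to_string())

truth = pd.read_csv(CLAIMS / "ground_truth.csv")
truth["episode_id"] = truth.person_id + ":" + truth.delivery_date
j = truth[~truth.expected_dropped].merge(table[["episode_id", "group"]],
                                         on="episode_id", suffixes=("_true", "_pred"))
acc = 100 * (j.group_true == j.group_pred).mean()
print(f"Agreement with simulator ground truth: {acc:.1f}% of {len(j)} episodes.")

dist = substance_distribution(profiles, assignments, GroupLabel.DISCONTINUER,
                              "prepregnancy", config)
dist.to_csv(OUT / "discontinuer_prepregnancy_substances.csv", index=False)
print("Prepregnancy substance shares among discontinuers (within class):")
print(dist.to_string(index=False))
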