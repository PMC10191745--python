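"""Simulate a synthetic claims extract at the study-condition defaults.

Generates a ~6,500-delivery cohort (5,000 women, 2012-2019) with the
default utilisation-group prevalences, noise rates and pathology
injection, and writes the three claims tables plus ground truth under
results/claims/.
"""

from pathlib import Path

from pregclaims import SimulationConfig, generate_cohort, write_cohort

OUT = Path("results/claims")
SEED = 42

config = SimulationConfig(seed=SEED, n_women=5000)
cohort = generate_cohort(config)
paths = write_cohort(cohort, OUT)

n = len(cohort.truth)
print(f"Simulated {config.n_women} women -> {n} deliveries "
      f"({len(cohort.services)} service rows, {len(cohort.dispensations)} dispensations).")
print("Ground-truth group counts:")
print(cohort.truth.group.value_counts().to_string())
print("Injected pathologies:")
print(cohort.truth.pathology.value_counts().to_string())
print(f"Tables written to {OUT}/")
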