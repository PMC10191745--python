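"""Reconstruct pregnancy episodes from the simulated claims tables.

Reads results/claims/, collapses delivery codes into events (30-day
clustering, DRG priority, stray-code and relocation rules), imputes LMP
and the four analysis windows, and applies the continuous-enrollment
filter.  Writes the episode table and the audit log under results/.
"""

from pathlib import Path

import pandas as pd

from pregclaims import CodeConfig, read_claims
from pregclaims.deliveries import identify_deliveries, write_audit_log
from pregclaims.timing import build_episode, filter_continuous_enrollment, write_episode_table

CLAIMS = Path("results/claims")
OUT = Path("results")

config = CodeConfig.default()
bundle = read_claims(CLAIMS / "services.csv", CLAIMS / "dispensations.csv",
                     CLAIMS / "enrollment.csv", config)
persons = pd.read_csv(CLAIMS / "persons.csv")
birth_years = dict(zip(persons.person_id, persons.birth_year.astype(int)))

events, audit = identify_deliveries(bundle.services, config)
episodes = [build_episode(ev, birth_years.get(ev.person_id)) for ev in events]
kept, dropped = filter_continuous_enrollment(episodes, bundle.enrollment)

write_episode_table(kept, OUT / "episodes.csv")
write_audit_log(audit, OUT / "audit_log.csv")

print(f"Identified {len(events)} deliveries; kept {len(kept)} continuously "
      f"enrolled episodes, dropped {len(dropped)} with coverage gaps.")
rules = pd.Series([a.rule for a in audit]).value_counts()
print("Audit log:" if len(rules) else "Audit log empty.")
if len(rules):
    print(rules.to_string())
preterm = sum(ep.term_status == "preterm" for ep in kept)
print(f"Preterm share among kept episodes: {100 * preterm / len(kept):.1f}%")
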