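# Methods

## Problem and model

Insurance claims identify a delivery only through billing codes and carry
no gestational age. The pipeline therefore rests on three modelling
layers, each with explicit, testable rules.

**Delivery collapsing.** A birth typically produces several billing codes
(an inpatient DRG, outpatient TARMED items, occasional late re-billed
codes). Codes within 30 days of each other are treated as one pregnancy.
The 30-day radius is *anchor-based* by default — a code joins a cluster
when it falls within 30 days of the cluster's first code — which bounds a
pregnancy's code spread at 30 days and is order-independent for sorted
input; transitive chaining is available via `cluster_rule: chain` for
sensitivity analyses, since claims texts rarely say which reading was
used. The delivery date is the earliest code, except that a DRG code
(precisely dated hospital discharge billing) takes priority over TARMED.
A stray DRG code 31–300 days after a DRG-dated delivery is ignored; after
a TARMED-only delivery it instead relocates the delivery date, on the
view that the outpatient code was a miscoded or early-billed record of
the same birth. Only DRG codes trigger the stray rule by default
(`tarmed_triggers_ignore_rule` extends it). Distinct deliveries must be
at least 300 days apart; anything closer that the rules do not resolve is
merged into the earlier event defensively and logged. No code is silently
dropped: every ignore/relocate/merge decision is an audit-log row.

**Termination exclusion.** Pregnancies ending in miscarriage or
termination are out of scope. Since a termination code marks an episode
that did not end in delivery, any delivery event within 30 days (the
same-pregnancy radius) of a termination-coded service for the same woman
is excluded, with an audit entry.

**Gestational windows.** LMP = delivery − 270 days for full-term, − 245
days for preterm deliveries (term status from DRG codes; TARMED-only
events default to full term, the modal outcome). The LMP is day 0;
trimesters are closed 90-day intervals (T1 days 0–89, T2 90–179, T3 180
to delivery — 66 days inclusive for a preterm birth), and the
prepregnancy baseline is the 252 days (9 months) before the LMP. The
four windows tile [LMP − 252 d, delivery] exactly; this is asserted by a
day-membership property test. The continuous-enrollment requirement runs
from 9 months before the LMP to 9 months after delivery; the
post-delivery arm is implemented as 252 days for symmetry with the
explicit 252-day = 9-month baseline convention and is configurable
(`post_delivery_enrollment_days`), since sources differ on whether 252 or
a calendar 9 months was meant.

**Exposure and groups.** Exposure is ≥ 1 outpatient dispensation in a
window, intervals closed on both ends (a dispensation on the delivery
date counts toward T3; day LMP+90 belongs to T2). Drug classes come from
longest-prefix ATC matching (A10A insulin, A10B blood glucose-lowering,
other A10 products a residual class; everything else non-ADM).
"Continuing the same ADM group" is interpreted at the class level:
continuer = non-empty intersection of the prepregnancy and in/after-T2
class sets, switcher = disjoint sets. This reproduces the mixed-regimen
edge cases (insulin before and insulin + oral agent after → continuer;
insulin + oral agent before and insulin only after → continuer; oral
agent before and insulin only after → switcher). Episodes whose only or
first exposure is in T1 fit none of the three published groups; they get
a separate `t1_only` label with an only/first subtype rather than being
forced into GDM (whose definition requires first exposure in or after
T2). Prepregnancy exposure with T1-only continuation is a discontinuer
by the letter of the definition, but such episodes carry a
`t1_exposed_discontinuer` flag for sensitivity analyses. The six labels
partition every cohort; this and the switcher-disjointness invariant are
property-tested.

**Prevalence.** Rates are numerator/denominator per 10,000 enrolled
pregnancies. The CI method is exact Clopper–Pearson by default (its
zero-numerator upper bound is the closed form 1 − 0.025^(1/n), e.g.
14.2% at n = 24); Wilson is available via `ci_method`. All arithmetic is
at full precision; half-up rounding to one decimal is applied only at
presentation. Published group shares are conventionally quoted as ratios
of already-rounded per-10,000 rates, which can differ from raw-count
ratios in the last decimal; `proportion_pct` serves the presentation
convention, while pipeline tables always derive from raw counts.

## Synthetic generator

The generator emulates the structure of a real claims extract for women
with ≥ 1 delivery in 2012–2019: parity 1–3 (mean ≈ 1.30 deliveries per
woman), preterm probability 0.07, caesarean 0.319, maternal age
N(31.7, 4.5²) clipped to 14.2–51.8, group prevalences per 10,000 of 22.1
(continuers), 3.8 (switchers), 257.7 (GDM), 10.7 (discontinuers) and 5.0
(T1-only; not separately reported anywhere, chosen as a plausibly small
rate), with optional per-year trend multipliers. Class mixes within
groups: continuers 88.2% insulin-only / 5.2% oral-only / 6.6% combined
regimen; switchers all oral→insulin; discontinuers 75.7% oral / 23.3%
insulin / 1% both; GDM 98.7% insulin / 1.1% oral / 0.2% both. Substance
mixes: insulin aspart 42.3%, lispro 20.9%, detemir 20.0%, human insulin
16.8%; metformin 66.1%, GLP-1 21.0%, SGLT2 8.1%, DPP-4 4.8%. 32.1% of
oral-agent discontinuers also receive a fertility-treatment dispensation
in the baseline window. Non-ADM background dispensations (mean 2 per
pregnancy) exercise the classifier's negative path.

Three choices keep ground-truth labels exactly recoverable:

- ADM dispensations are drawn uniformly *strictly inside* their target
  window with a one-day margin from each boundary, so labels cannot hinge
  on endpoint conventions;
- successive deliveries are ≥ 540 days apart — below 522 days
  (270 gestation + 252 baseline) one pregnancy's T2/T3 could overlap the
  next one's baseline window and contaminate its label, and the extra
  margin keeps a relocation TARMED code (up to 60 days early) more than
  300 days from the previous delivery;
- at most one pathology is injected per episode (duplicate code within
  30 days, stray DRG 31–290 days after, TARMED-only delivery, TARMED
  code 31–60 days before its DRG, or a one-day enrollment hole), each
  recorded in ground truth with the audit entry or drop the pipeline
  must produce. TARMED-only deliveries are generated as full-term
  vaginal births only, matching the pipeline's full-term default for
  events without DRG term information. Enrollment gaps are restricted to
  single-pregnancy women so exactly one episode is affected.

Randomness comes from three deterministically spawned substreams
(demographics, exposure, noise) of one seed, so turning noise on or off
does not change the underlying cohort. The synthetic DRG ("O60A"/"O60C"
vaginal, "O01A"/"O01C" caesarean) and TARMED ("DEL01") values are
placeholders with the right shape — real national code lists are tariff
data and belong in the user-editable configuration.

What the simulator does **not** model: real national DRG tariff
structure, inpatient medication billing, dose/days-supply, seasonal
delivery patterns, exposure misclassification from irregular refill
behaviour near window boundaries, and within-woman correlation of groups
across pregnancies. Passing recovery tests therefore demonstrates that
the pipeline implements its rules exactly — not that the rules are free
of misclassification on real data, where LMP imputation error is known
to blur trimester edges.

## Problem sizes and numerics

Default driver/analysis runs use 5,000 women (~6,500 deliveries);
statistical-recovery checks use 15,400 women (~20,000 deliveries), at
which the programmed prevalences are recovered within 3 binomial
standard errors. Oracle-equivalence testing compares the collapsing
implementation with an independent naive reference on 200 random code
streams spanning all rules. Dates are calendar dates and all interval
arithmetic is in whole days; ties among same-day codes are broken
deterministically (DRG before TARMED, then code string). Zero
denominators raise explicit errors rather than returning NaN; empty
groups yield empty tables.

## Known limitations

- Term status is a dichotomy from DRG codes; no gestational-age
  diagnosis codes, ultrasound dates or birthweight refine the LMP.
- GDM and overt diabetes first treated in pregnancy cannot be separated
  with dispensation timing alone; the in/after-T2 first-exposure group
  deliberately pools them.
- The termination-exclusion window (30 days) is a design choice; real
  studies may exclude on episode linkage instead.
- Maternal age uses calendar-year difference when a birth year is
  supplied, not exact age at delivery.
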