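"""Seeded synthetic claims generator with per-episode ground truth.

Real Swiss claims extracts of this kind are proprietary, so the pipeline
ships a simulator that emits the same three tables (services,
dispensations, enrollment) together with a ground-truth table recording
what the pipeline is expected to reconstruct: the delivery date (after any
code pathology), term status, imputed LMP, utilisation-group label, and —
for injected pathologies — the audit-log entry or enrollment drop the
pipeline must produce.

Default parameters mirror the published Swiss cohort figures: utilisation
groups at 22.1 (continuers), 3.8 (switchers), 257.7 (GDM) and 10.7
(discontinuers) per 10,000 deliveries over 2012-2019, a 31.9% caesarean
share, mean maternal age 31.7, class mixes of 88.2/6.5/5.2% within
continuers, 75.7/23.3% within discontinuers and 98.7/1.1/0.2% within GDM,
and substance mixes led by insulin aspart (42.3%) and metformin (66.1%).

Antidiabetic dispensations are placed uniformly *strictly inside* their
target window (one-day margin from each boundary), so ground-truth labels
are unambiguous under any closed/open endpoint convention.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deliveries import DeliveryEvent
from .records import (
    CodeConfig,
    DispensationRecord,
    EnrollmentSpan,
    ServiceRecord,
    write_claims,
)
from .timing import (
    GESTATION_FULL_TERM_DAYS,
    GESTATION_PRETERM_DAYS,
    PREPREGNANCY_DAYS,
    build_episode,
)

DAY = dt.timedelta(days=1)

#: minimum spacing between a woman's successive deliveries; kept at 540
#: (not the 300-day identification floor) so that (i) consecutive
#: pregnancies' analysis windows never overlap — the next prepregnancy
#: baseline starts 522 days (270 gestation + 252 baseline) before the next
#: delivery, so any shorter spacing would let one pregnancy's T2/T3
#: dispensations leak into the next one's baseline and blur ground-truth
#: labels — and (ii) injected pathologies (a TARMED code up to 60 days
#: before its DRG) can never bring two pregnancies within 300 days.
MIN_SPACING_DAYS = 540
MAX_SPACING_DAYS = 900


class GenerationError(ValueError):
    """The simulation configuration is infeasible; the message names the
    violated constraint."""


@dataclass
class SimulationConfig:
    seed: int
    n_women: int = 1000
    start: dt.date = dt.date(2012, 1, 1)
    end: dt.date = dt.date(2019, 12, 31)
    parity_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.72, 2: 0.26, 3: 0.02}
    )
    preterm_probability: float = 0.07
    caesarean_probability: float = 0.319
    #: utilisation-group prevalences per 10,000 deliveries
    group_prevalence_per_10k: dict[str, float] = field(
        default_factory=lambda: {
            "pregestational_continuer": 22.1,
            "pregestational_switcher": 3.8,
            "gdm": 257.7,
            "discontinuer": 10.7,
            "t1_only": 5.0,
        }
    )
    #: optional per-year multiplier on a group's prevalence, e.g.
    #: {"gdm": {2012: 0.55, ...}}; missing years default to 1.0
    year_trend: dict[str, dict[int, float]] = field(default_factory=dict)
    continuer_regimen_mix: dict[str, float] = field(
        default_factory=lambda: {
            "insulin_only": 0.882,
            "bgld_only": 0.052,
            "both_pre_insulin_post": 0.066,
        }
    )
    discontinuer_class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "blood_glucose_lowering": 0.757,
            "insulin": 0.233,
            "both": 0.010,
        }
    )
    gdm_class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "insulin": 0.987,
            "blood_glucose_lowering": 0.011,
            "both": 0.002,
        }
    )
    insulin_substances: dict[str, float] = field(
        default_factory=lambda: {
            "A10AB05": 0.423,  # insulin aspart
            "A10AB04": 0.209,  # insulin lispro
            "A10AE05": 0.200,  # insulin detemir
            "A10AB01": 0.168,  # human insulin
        }
    )
    bgld_substances: dict[str, float] = field(
        default_factory=lambda: {
            "A10BA02": 0.661,  # metformin
            "A10BJ02": 0.210,  # liraglutide (GLP-1)
            "A10BK01": 0.081,  # dapagliflozin (SGLT2)
            "A10BH01": 0.048,  # sitagliptin (DPP-4)
        }
    )
    fertility_comedication_probability: float = 0.321
    fertility_substance: str = "G03GA04"
    background_dispensations_mean: float = 2.0
    background_atc: tuple[str, ...] = ("N02BE01", "B03AA07", "A11CC05")
    refill_max: int = 2  # extra dispensations per exposed window, 0..refill_max
    mean_maternal_age: float = 31.7
    sd_maternal_age: float = 4.5
    age_range: tuple[float, float] = (14.2, 51.8)
    # -- noise / pathology rates (mutually exclusive per episode) ----------
    duplicate_code_rate: float = 0.15
    stray_drg_rate: float = 0.02
    tarmed_only_rate: float = 0.03
    tarmed_relocation_rate: float = 0.02
    enrollment_gap_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.seed is None:
            raise GenerationError("seed is mandatory")
        if abs(sum(self.parity_distribution.values()) - 1.0) > 1e-9:
            raise GenerationError("parity_distribution must sum to 1")
        if sum(self.group_prevalence_per_10k.values()) > 10000:
            raise GenerationError("group prevalences exceed 10,000 per 10,000")
        for name in (
            "preterm_probability",
            "caesarean_probability",
            "fertility_comedication_probability",
            "duplicate_code_rate",
            "stray_drg_rate",
            "tarmed_only_rate",
            "tarmed_relocation_rate",
            "enrollment_gap_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name}={v} outside [0, 1]")
        if self.noise_total > 1.0:
            raise GenerationError("pathology rates sum to more than 1")
        range_days = (self.end - self.start).days
        max_parity = max(self.parity_distribution)
        if (max_parity - 1) * MIN_SPACING_DAYS > range_days:
            raise GenerationError(
                f"parity {max_parity} with {MIN_SPACING_DAYS}-day spacing does not "
                f"fit in the {range_days}-day year range"
            )

    @property
    def noise_total(self) -> float:
        return (
            self.duplicate_code_rate
            + self.stray_drg_rate
            + self.tarmed_only_rate
            + self.tarmed_relocation_rate
            + self.enrollment_gap_rate
        )

    def without_noise(self) -> "SimulationConfig":
        return dataclasses.replace(
            self,
            duplicate_code_rate=0.0,
            stray_drg_rate=0.0,
            tarmed_only_rate=0.0,
            tarmed_relocation_rate=0.0,
            enrollment_gap_rate=0.0,
        )


# synthetic placeholder billing codes (term x mode of delivery)
DRG_CODE = {
    ("full_term", False): "O60A",
    ("preterm", False): "O60C",
    ("full_term", True): "O01A",
    ("preterm", True): "O01C",
}
TARMED_CODE = "DEL01"


@dataclass
class SimulatedCohort:
    services: list[ServiceRecord]
    dispensations: list[DispensationRecord]
    enrollment: list[EnrollmentSpan]
    truth: pd.DataFrame
    persons: pd.DataFrame
    config: SimulationConfig


def _draw(rng: np.random.Generator, mix: dict) -> object:
    keys = list(mix)
    probs = np.asarray([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _uniform_day(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    """Uniform date in the closed interval [lo, hi]."""
    span = (hi - lo).days
    if span < 0:
        raise GenerationError(f"empty interval {lo}..{hi}")
    return lo + int(rng.integers(0, span + 1)) * DAY


def _window_dispensations(
    rng: np.random.Generator,
    person: str,
    window: tuple[dt.date, dt.date],
    substance: str,
    refill_max: int,
) -> list[DispensationRecord]:
    lo, hi = window
    lo, hi = lo + DAY, hi - DAY  # one-day margin keeps labels unambiguous
    n = 1 + int(rng.integers(0, refill_max + 1))
    return [DispensationRecord(person, _uniform_day(rng, lo, hi), substance) for _ in range(n)]


def generate_cohort(
    config: SimulationConfig, code_config: CodeConfig | None = None
) -> SimulatedCohort:
    """Generate the three claims tables plus ground truth.

    Deterministic given ``config.seed``; pathologies are injected by
    :func:`inject_pathologies` at the configured rates.
    """
    if code_config is None:
        code_config = CodeConfig.default()
    ss = np.random.SeedSequence(config.seed)
    demo_rng, expo_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    services: list[ServiceRecord] = []
    dispensations: list[DispensationRecord] = []
    enrollment: list[EnrollmentSpan] = []
    truth_rows: list[dict] = []
    person_rows: list[dict] = []

    range_days = (config.end - config.start).days

    for w in range(config.n_women):
        person = f"W{w:06d}"
        parity = int(_draw(demo_rng, config.parity_distribution))
        # spacing gaps first, then a feasible uniform start
        cap = range_days // max(parity - 1, 1)
        gaps = [
            int(demo_rng.integers(MIN_SPACING_DAYS, min(MAX_SPACING_DAYS, cap) + 1))
            for _ in range(parity - 1)
        ]
        total = sum(gaps)
        if total > range_days:
            raise GenerationError("delivery spacing exceeds the year range")
        first = _uniform_day(demo_rng, config.start, config.end - total * DAY)
        delivery_dates = [first]
        for g in gaps:
            delivery_dates.append(delivery_dates[-1] + g * DAY)

        age_first = float(
            np.clip(
                demo_rng.normal(config.mean_maternal_age, config.sd_maternal_age),
                *config.age_range,
            )
        )
        birth_year = first.year - int(round(age_first))
        person_rows.append({"person_id": person, "birth_year": birth_year})

        episode_windows: list[tuple[dt.date, dt.date]] = []
        for idx, d in enumerate(delivery_dates):
            preterm = demo_rng.random() < config.preterm_probability
            term = "preterm" if preterm else "full_term"
            caesarean = demo_rng.random() < config.caesarean_probability
            lmp = d - (GESTATION_PRETERM_DAYS if preterm else GESTATION_FULL_TERM_DAYS) * DAY
            ep = build_episode(
                DeliveryEvent(person, d, term, True, False, caesarean, []),
                birth_year=birth_year,
            )
            episode_windows.append((ep.prepregnancy[0], d + PREPREGNANCY_DAYS * DAY))

            services.append(ServiceRecord(person, d, "DRG", DRG_CODE[(term, caesarean)]))

            # -- utilisation group -----------------------------------------
            trend = {
                g: config.year_trend.get(g, {}).get(d.year, 1.0)
                for g in config.group_prevalence_per_10k
            }
            probs = {
                g: config.group_prevalence_per_10k[g] * trend[g] / 1e4
                for g in config.group_prevalence_per_10k
            }
            leftover = 1.0 - sum(probs.values())
            if leftover < 0:
                raise GenerationError("trended prevalences exceed 10,000 per 10,000")
            group = str(_draw(expo_rng, {**probs, "unexposed": leftover}))

            pre_classes: set[str] = set()
            t1_classes: set[str] = set()
            post_classes: set[str] = set()
            fertility = False
            t1_subtype = ""

            ins = str(_draw(expo_rng, config.insulin_substances))
            bgld = str(_draw(expo_rng, config.bgld_substances))
            post_window = ep.t2 if expo_rng.random() < 0.5 else ep.t3

            def place(window, substance):
                dispensations.extend(
                    _window_dispensations(expo_rng, person, window, substance, config.refill_max)
                )

            if group == "pregestational_continuer":
                regimen = _draw(expo_rng, config.continuer_regimen_mix)
                if regimen == "insulin_only":
                    pre_classes = post_classes = {"insulin"}
                    place(ep.prepregnancy, ins)
                    place(post_window, ins)
                elif regimen == "bgld_only":
                    pre_classes = post_classes = {"blood_glucose_lowering"}
                    place(ep.prepregnancy, bgld)
                    place(post_window, bgld)
                else:  # insulin + BGLD before pregnancy, insulin continued
                    pre_classes = {"insulin", "blood_glucose_lowering"}
                    post_classes = {"insulin"}
                    place(ep.prepregnancy, ins)
                    place(ep.prepregnancy, bgld)
                    place(post_window, ins)
            elif group == "pregestational_switcher":
                # all published switchers went BGLD -> insulin
                pre_classes = {"blood_glucose_lowering"}
                post_classes = {"insulin"}
                place(ep.prepregnancy, bgld)
                place(post_window, ins)
            elif group == "gdm":
                mix = str(_draw(expo_rng, config.gdm_class_mix))
                post_classes = (
                    {"insulin", "blood_glucose_lowering"} if mix == "both" else {mix}
                )
                if "insulin" in post_classes:
                    place(post_window, ins)
                if "blood_glucose_lowering" in post_classes:
                    place(post_window, bgld)
            elif group == "discontinuer":
                mix = str(_draw(expo_rng, config.discontinuer_class_mix))
                pre_classes = (
                    {"insulin", "blood_glucose_lowering"} if mix == "both" else {mix}
                )
                if "insulin" in pre_classes:
                    place(ep.prepregnancy, ins)
                if "blood_glucose_lowering" in pre_classes:
                    place(ep.prepregnancy, bgld)
                if (
                    "blood_glucose_lowering" in pre_classes
                    and expo_rng.random() < config.fertility_comedication_probability
                ):
                    fertility = True
                    place(ep.prepregnancy, config.fertility_substance)
            elif group == "t1_only":
                t1_subtype = "only"
                cls = "insulin" if expo_rng.random() < 0.5 else "blood_glucose_lowering"
                t1_classes = {cls}
                place(ep.t1, ins if cls == "insulin" else bgld)

            n_bg = int(expo_rng.poisson(config.background_dispensations_mean))
            for _ in range(n_bg):
                code = str(config.background_atc[int(expo_rng.integers(0, len(config.background_atc)))])
                dispensations.append(
                    DispensationRecord(person, _uniform_day(expo_rng, ep.prepregnancy[0], d), code)
                )

            truth_rows.append(
                {
                    "person_id": person,
                    "episode_index": idx,
                    "delivery_date": d,
                    "next_delivery_date": (
                        delivery_dates[idx + 1] if idx + 1 < parity else None
                    ),
                    "delivery_year": d.year,
                    "term_status": term,
                    "caesarean": caesarean,
                    "lmp": lmp,
                    "maternal_age": d.year - birth_year,
                    "group": group,
                    "t1_subtype": t1_subtype,
                    "pre_classes": "|".join(sorted(pre_classes)),
                    "t1_classes": "|".join(sorted(t1_classes)),
                    "post_classes": "|".join(sorted(post_classes)),
                    "fertility_comedication": fertility,
                    "parity": parity,
                    "pathology": "none",
                    "expected_audit_rule": "",
                    "expected_audit_date": None,
                    "expected_dropped": False,
                    "expected_first_uncovered_day": None,
                }
            )

        obs_start = min(w0 for w0, _ in episode_windows)
        obs_end = max(
            d + PREPREGNANCY_DAYS * DAY for d in delivery_dates
        )
        pad_before = int(demo_rng.integers(10, 201))
        pad_after = int(demo_rng.integers(10, 201))
        enrollment.append(
            EnrollmentSpan(person, obs_start - pad_before * DAY, obs_end + pad_after * DAY)
        )

    truth = pd.DataFrame(truth_rows)
    persons = pd.DataFrame(person_rows)
    cohort = SimulatedCohort(services, dispensations, enrollment, truth, persons, config)
    if config.noise_total > 0:
        cohort = inject_pathologies(cohort, config, noise_rng)
    _canonical_sort(cohort)
    return cohort


def _canonical_sort(cohort: SimulatedCohort) -> None:
    cohort.services.sort(key=lambda r: (r.person_id, r.date, r.code_system, r.code))
    cohort.dispensations.sort(key=lambda r: (r.person_id, r.date, r.atc_code))
    cohort.enrollment.sort(key=lambda r: (r.person_id, r.start, r.end))


def inject_pathologies(
    cohort: SimulatedCohort,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Inject code/enrollment pathologies, recording expected outcomes.

    Per episode at most one pathology is drawn:

    * ``duplicate`` — extra TARMED delivery code 1-25 days after the DRG;
      absorbed by 30-day collapsing, no expected audit entry;
    * ``stray`` — DRG delivery code 31-290 days after a DRG-dated
      delivery; expected to be ignored (audit rule ``ignored_stray_drg``);
    * ``tarmed_only`` — the DRG code is replaced by a TARMED code on the
      same date (full-term vaginal deliveries only, so the pipeline's
      full-term default keeps truth consistent);
    * ``relocation`` — a TARMED code 31-60 days *before* the DRG code;
      the TARMED-only event must be moved to the DRG date (audit rule
      ``relocated_to_drg``);
    * ``gap`` — a one-day enrollment hole inside the episode's
      continuous-coverage window (single-pregnancy women only); the
      episode must be dropped with that day as diagnostic.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])

    truth = cohort.truth
    services = cohort.services
    span_by_person = {s.person_id: s for s in cohort.enrollment}
    new_spans: dict[str, list[EnrollmentSpan]] = {}

    rates = np.array(
        [
            config.duplicate_code_rate,
            config.stray_drg_rate,
            config.tarmed_only_rate,
            config.tarmed_relocation_rate,
            config.enrollment_gap_rate,
        ]
    )
    names = ["duplicate", "stray", "tarmed_only", "relocation", "gap"]

    for i in truth.index:
        u = rng.random()
        cum = np.cumsum(rates)
        picked = None
        for name, edge in zip(names, cum):
            if u < edge:
                picked = name
                break
        if picked is None:
            continue
        row = truth.loc[i]
        person = row["person_id"]
        d: dt.date = row["delivery_date"]
        nxt = row["next_delivery_date"]

        if picked == "duplicate":
            services.append(
                ServiceRecord(person, d + int(rng.integers(1, 26)) * DAY, "TARMED", TARMED_CODE)
            )
            truth.loc[i, "pathology"] = "duplicate"
        elif picked == "stray":
            # keep the stray well clear (>=31 d) of the next pregnancy's
            # codes, including a relocation TARMED up to 60 d early
            hi = 290
            if nxt is not None:
                hi = min(hi, (nxt - d).days - 91)
            if hi < 31:
                continue
            stray_date = d + int(rng.integers(31, hi + 1)) * DAY
            services.append(ServiceRecord(person, stray_date, "DRG", "O60A"))
            truth.loc[i, "pathology"] = "stray"
            truth.loc[i, "expected_audit_rule"] = "ignored_stray_drg"
            truth.loc[i, "expected_audit_date"] = stray_date
        elif picked == "tarmed_only":
            if row["term_status"] != "full_term" or row["caesarean"]:
                continue
            for j, s in enumerate(services):
                if s.person_id == person and s.date == d and s.code_system == "DRG":
                    services[j] = ServiceRecord(person, d, "TARMED", TARMED_CODE)
                    truth.loc[i, "pathology"] = "tarmed_only"
                    break
        elif picked == "relocation":
            off = int(rng.integers(31, 61))
            services.append(ServiceRecord(person, d - off * DAY, "TARMED", TARMED_CODE))
            truth.loc[i, "pathology"] = "relocation"
            truth.loc[i, "expected_audit_rule"] = "relocated_to_drg"
            truth.loc[i, "expected_audit_date"] = d
        elif picked == "gap":
            if row["parity"] != 1 or person in new_spans:
                continue
            lmp: dt.date = row["lmp"]
            win_lo = lmp - PREPREGNANCY_DAYS * DAY
            win_hi = d + PREPREGNANCY_DAYS * DAY
            gap_day = _uniform_day(rng, win_lo, win_hi)
            span = span_by_person[person]
            new_spans[person] = [
                EnrollmentSpan(person, span.start, gap_day - DAY),
                EnrollmentSpan(person, gap_day + DAY, span.end),
            ]
            truth.loc[i, "pathology"] = "gap"
            truth.loc[i, "expected_dropped"] = True
            truth.loc[i, "expected_first_uncovered_day"] = gap_day

    if new_spans:
        enrollment: list[EnrollmentSpan] = []
        for s in cohort.enrollment:
            enrollment.extend(new_spans.get(s.person_id, [s]))
        cohort.enrollment = enrollment
    _canonical_sort(cohort)
    return cohort


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as CSV files; returns the path of each table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "services": outdir / "services.csv",
        "dispensations": outdir / "dispensations.csv",
        "enrollment": outdir / "enrollment.csv",
        "persons": outdir / "persons.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    write_claims(cohort.services, paths["services"], kind="services")
    write_claims(cohort.dispensations, paths["dispensations"], kind="dispensations")
    write_claims(cohort.enrollment, paths["enrollment"], kind="enrollment")
    cohort.persons.sort_values("person_id").to_csv(paths["persons"], index=False)
    truth = cohort.truth.copy()
    for col in ("delivery_date", "next_delivery_date", "lmp",
                "expected_audit_date", "expected_first_uncovered_day"):
        truth[col] = truth[col].map(lambda v: v.isoformat() if isinstance(v, dt.date) else "")
    truth.sort_values(["person_id", "episode_index"]).to_csv(paths["ground_truth"], index=False)
    return paths
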