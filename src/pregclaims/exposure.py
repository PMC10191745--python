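"""Per-window antidiabetic exposure profiles and utilisation-group labels.

Exposure is "at least one outpatient dispensation" of an antidiabetic
medication (ATC A10: insulins A10A, blood glucose-lowering drugs A10B)
inside a window.  Episodes are partitioned into six labels:

* ``pregestational_continuer`` — exposed in prepregnancy and in/after T2,
  with at least one drug class in common between the two periods;
* ``pregestational_switcher`` — exposed in both periods but with disjoint
  class sets (e.g., a blood glucose-lowering drug before pregnancy,
  insulin only from T2);
* ``gdm`` — first-ever exposure in or after T2 (proxy for
  pharmacologically treated gestational diabetes);
* ``discontinuer`` — prepregnancy exposure, nothing in or after T2;
* ``t1_only`` — exposure pattern involving T1 that none of the three
  published groups covers (first or only exposure in T1, no prepregnancy
  exposure), carried with a subtype flag;
* ``unexposed`` — no antidiabetic dispensation in any window.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .prevalence import round_half_up
from .records import CodeConfig, ConfigurationError, DispensationRecord, classify_atc
from .timing import PregnancyEpisode

WINDOWS = ("prepregnancy", "t1", "t2", "t3")


class GroupLabel(str, Enum):
    PREGESTATIONAL_CONTINUER = "pregestational_continuer"
    PREGESTATIONAL_SWITCHER = "pregestational_switcher"
    GDM = "gdm"
    DISCONTINUER = "discontinuer"
    T1_ONLY = "t1_only"
    UNEXPOSED = "unexposed"


@dataclass
class ExposureProfile:
    episode: PregnancyEpisode
    classes: Mapping[str, frozenset[str]]  # window -> ADM class labels
    substances: Mapping[str, frozenset[str]]  # window -> ATC codes as dispensed

    @property
    def exposed_prepregnancy(self) -> bool:
        return bool(self.classes["prepregnancy"])

    @property
    def exposed_t2_or_later(self) -> bool:
        return bool(self.classes["t2"] | self.classes["t3"])

    @property
    def post_t2_classes(self) -> frozenset[str]:
        return self.classes["t2"] | self.classes["t3"]

    @property
    def first_exposure_window(self) -> str | None:
        for w in WINDOWS:
            if self.classes[w]:
                return w
        return None


@dataclass(frozen=True)
class GroupAssignment:
    label: GroupLabel
    #: for t1_only: "only" (no later exposure) or "first" (T1 then later)
    t1_subtype: str | None = None
    #: discontinuers with a T1 dispensation, surfaced for sensitivity checks
    t1_exposed_discontinuer: bool = False


def build_exposure_profile(
    episode: PregnancyEpisode,
    dispensations: Sequence[DispensationRecord],
    config: CodeConfig,
) -> ExposureProfile:
    """Assign each antidiabetic dispensation of the episode's person to the
    analysis window containing its date (closed intervals; dispensations
    after the delivery date are out of scope).
    """
    classes: dict[str, set[str]] = {w: set() for w in WINDOWS}
    substances: dict[str, set[str]] = {w: set() for w in WINDOWS}
    for d in dispensations:
        if d.person_id != episode.person_id or d.date > episode.delivery_date:
            continue
        window = episode.window_of(d.date)
        if window is None:
            continue
        label = classify_atc(d.atc_code, config)
        if label == "non_adm":
            continue
        classes[window].add(label)
        substances[window].add(d.atc_code.upper())
    return ExposureProfile(
        episode=episode,
        classes={w: frozenset(s) for w, s in classes.items()},
        substances={w: frozenset(s) for w, s in substances.items()},
    )


def assign_group(profile: ExposureProfile) -> GroupAssignment:
    """Assign the episode to exactly one utilisation group."""
    pre = profile.classes["prepregnancy"]
    t1 = profile.classes["t1"]
    post = profile.post_t2_classes
    if not pre and not t1 and not post:
        return GroupAssignment(GroupLabel.UNEXPOSED)
    if pre and not post:
        return GroupAssignment(GroupLabel.DISCONTINUER, t1_exposed_discontinuer=bool(t1))
    if pre and post:
        if pre & post:
            return GroupAssignment(GroupLabel.PREGESTATIONAL_CONTINUER)
        return GroupAssignment(GroupLabel.PREGESTATIONAL_SWITCHER)
    # no prepregnancy exposure from here on
    if post and not t1:
        return GroupAssignment(GroupLabel.GDM)
    if post and t1:
        return GroupAssignment(GroupLabel.T1_ONLY, t1_subtype="first")
    return GroupAssignment(GroupLabel.T1_ONLY, t1_subtype="only")


def flag_fertility_comedication(
    profile: ExposureProfile,
    dispensations: Sequence[DispensationRecord],
    config: CodeConfig,
) -> bool:
    """True when any prepregnancy-window dispensation matches a configured
    fertility-treatment ATC prefix."""
    if not config.fertility_atc:
        raise ConfigurationError("fertility_atc list is empty")
    lo, hi = profile.episode.prepregnancy
    prefixes = tuple(p.upper() for p in config.fertility_atc)
    for d in dispensations:
        if d.person_id != profile.episode.person_id:
            continue
        if lo <= d.date <= hi and d.atc_code.upper().startswith(prefixes):
            return True
    return False


def substance_distribution(
    profiles: Sequence[ExposureProfile],
    assignments: Sequence[GroupAssignment],
    group: GroupLabel,
    window: str,
    config: CodeConfig,
) -> pd.DataFrame:
    """Share of each dispensed substance within its drug class, among a
    group's episodes, in one window.

    The share denominator is class-specific: episodes of the group with any
    substance of that class in the window.  Returns an empty frame for an
    empty group.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}")
    members = [p for p, a in zip(profiles, assignments) if a.label == group]
    if not members:
        return pd.DataFrame(columns=["substance", "adm_class", "n", "class_n", "share_pct"])
    subst_counts: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    for p in members:
        substances = p.substances[window]
        classes_present = {classify_atc(s, config) for s in substances}
        for cl in classes_present:
            class_counts[cl] = class_counts.get(cl, 0) + 1
        for s in substances:
            subst_counts[s] = subst_counts.get(s, 0) + 1
    rows = []
    for s in sorted(subst_counts):
        cl = classify_atc(s, config)
        denom = class_counts[cl]
        rows.append(
            {
                "substance": s,
                "adm_class": cl,
                "n": subst_counts[s],
                "class_n": denom,
                "share_pct": round_half_up(100.0 * subst_counts[s] / denom, 1),
            }
        )
    return pd.DataFrame(rows, columns=["substance", "adm_class", "n", "class_n", "share_pct"])


def classify_episodes(
    episodes: Sequence[PregnancyEpisode],
    dispensations: Sequence[DispensationRecord],
    config: CodeConfig,
) -> tuple[list[ExposureProfile], list[GroupAssignment], pd.DataFrame]:
    """Profile and label every episode; also return the classification table."""
    by_person: dict[str, list[DispensationRecord]] = {}
    for d in dispensations:
        by_person.setdefault(d.person_id, []).append(d)
    profiles: list[ExposureProfile] = []
    assignments: list[GroupAssignment] = []
    rows = []
    for ep in episodes:
        person_disp = by_person.get(ep.person_id, [])
        prof = build_exposure_profile(ep, person_disp, config)
        assignment = assign_group(prof)
        fertility = flag_fertility_comedication(prof, person_disp, config)
        profiles.append(prof)
        assignments.append(assignment)
        row = {
            "episode_id": ep.episode_id,
            "person_id": ep.person_id,
            "delivery_year": ep.delivery_year,
            "group": assignment.label.value,
            "t1_subtype": assignment.t1_subtype or "",
            "t1_exposed_discontinuer": assignment.t1_exposed_discontinuer,
            "fertility_comedication": fertility,
        }
        for w in WINDOWS:
            row[f"{w}_insulin"] = "insulin" in prof.classes[w]
            row[f"{w}_blood_glucose_lowering"] = "blood_glucose_lowering" in prof.classes[w]
            row[f"{w}_other_adm"] = "other_adm" in prof.classes[w]
        rows.append(row)
    table = pd.DataFrame(rows)
    return profiles, assignments, table


def write_classification_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
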