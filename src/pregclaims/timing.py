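"""Gestational-window imputation and the continuous-enrollment filter.

Claims carry no gestational age, so the last menstrual period (LMP) is
imputed from the delivery date: 270 days before delivery for full-term
births, 245 days for preterm births (identified through term-specific DRG
codes).  The LMP is day 0 of pregnancy; trimesters are consecutive 90-day
closed intervals (T1 days 0-89, T2 days 90-179, T3 day 180 to delivery,
hence shortened for preterm births), and the prepregnancy baseline covers
the 252 days (9 months) before the LMP.  Together the four windows tile
[LMP - 252 d, delivery] with no gaps or overlaps.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .deliveries import DeliveryEvent
from .records import EnrollmentSpan

GESTATION_FULL_TERM_DAYS = 270
GESTATION_PRETERM_DAYS = 245
TRIMESTER_DAYS = 90
PREPREGNANCY_DAYS = 252

DateInterval = tuple[dt.date, dt.date]  # closed on both ends


@dataclass
class PregnancyEpisode:
    person_id: str
    delivery_date: dt.date
    term_status: str
    lmp: dt.date
    prepregnancy: DateInterval
    t1: DateInterval
    t2: DateInterval
    t3: DateInterval
    delivery_year: int
    caesarean: bool = False
    maternal_age_at_delivery: int | None = None
    predates_data_period: bool = False

    @property
    def episode_id(self) -> str:
        return f"{self.person_id}:{self.delivery_date.isoformat()}"

    @property
    def observation_window(self) -> DateInterval:
        return (self.prepregnancy[0], self.delivery_date)

    def window_of(self, date: dt.date) -> str | None:
        """Name of the analysis window containing ``date``, if any."""
        for name in ("prepregnancy", "t1", "t2", "t3"):
            lo, hi = getattr(self, name)
            if lo <= date <= hi:
                return name
        return None


def estimate_lmp(event: DeliveryEvent) -> dt.date:
    """Impute the last menstrual period from the delivery date.

    270 days before delivery for a full-term birth, 245 for preterm.
    """
    if event.term_status == "full_term":
        return event.delivery_date - dt.timedelta(days=GESTATION_FULL_TERM_DAYS)
    if event.term_status == "preterm":
        return event.delivery_date - dt.timedelta(days=GESTATION_PRETERM_DAYS)
    raise ValueError(f"term_status {event.term_status!r}")


def build_episode(
    event: DeliveryEvent,
    birth_year: int | None = None,
    data_start: dt.date = dt.date(2012, 1, 1),
) -> PregnancyEpisode:
    """Construct a pregnancy episode with its four analysis windows."""
    lmp = estimate_lmp(event)
    day = dt.timedelta(days=1)
    t1 = (lmp, lmp + 89 * day)
    t2 = (lmp + 90 * day, lmp + 179 * day)
    t3 = (lmp + 180 * day, event.delivery_date)
    prepregnancy = (lmp - PREPREGNANCY_DAYS * day, lmp - day)
    return PregnancyEpisode(
        person_id=event.person_id,
        delivery_date=event.delivery_date,
        term_status=event.term_status,
        lmp=lmp,
        prepregnancy=prepregnancy,
        t1=t1,
        t2=t2,
        t3=t3,
        delivery_year=event.delivery_date.year,
        caesarean=event.caesarean,
        maternal_age_at_delivery=(
            event.delivery_date.year - birth_year if birth_year is not None else None
        ),
        predates_data_period=lmp < data_start,
    )


@dataclass(frozen=True)
class DroppedEpisode:
    episode: PregnancyEpisode
    first_uncovered_day: dt.date


def _merged_spans(spans: list[EnrollmentSpan]) -> list[DateInterval]:
    if not spans:
        return []
    spans = sorted(spans, key=lambda s: (s.start, s.end))
    merged = [(spans[0].start, spans[0].end)]
    for s in spans[1:]:
        lo, hi = merged[-1]
        if s.start <= hi + dt.timedelta(days=1):  # abutting spans form one cover
            merged[-1] = (lo, max(hi, s.end))
        else:
            merged.append((s.start, s.end))
    return merged


def first_uncovered_day(
    window: DateInterval, spans: list[EnrollmentSpan]
) -> dt.date | None:
    """First day of the closed ``window`` not covered by the span union."""
    lo, hi = window
    cursor = lo
    for s_lo, s_hi in _merged_spans(spans):
        if s_hi < cursor:
            continue
        if s_lo > cursor:
            return cursor
        cursor = s_hi + dt.timedelta(days=1)
        if cursor > hi:
            return None
    return cursor if cursor <= hi else None


def filter_continuous_enrollment(
    episodes: list[PregnancyEpisode],
    spans: list[EnrollmentSpan],
    post_delivery_days: int = PREPREGNANCY_DAYS,
) -> tuple[list[PregnancyEpisode], list[DroppedEpisode]]:
    """Keep episodes continuously enrolled from 9 months before the LMP
    to ``post_delivery_days`` (default 252 = 9 months) after delivery.
    """
    by_person: dict[str, list[EnrollmentSpan]] = {}
    for s in spans:
        by_person.setdefault(s.person_id, []).append(s)
    kept: list[PregnancyEpisode] = []
    dropped: list[DroppedEpisode] = []
    for ep in episodes:
        window = (
            ep.lmp - dt.timedelta(days=PREPREGNANCY_DAYS),
            ep.delivery_date + dt.timedelta(days=post_delivery_days),
        )
        gap = first_uncovered_day(window, by_person.get(ep.person_id, []))
        if gap is None:
            kept.append(ep)
        else:
            dropped.append(DroppedEpisode(ep, gap))
    return kept, dropped


def write_episode_table(episodes: Iterable[PregnancyEpisode], path: str | Path) -> None:
    cols = [
        "episode_id", "person_id", "delivery_date", "delivery_year", "term_status",
        "caesarean", "lmp", "prepregnancy_start", "prepregnancy_end",
        "t1_start", "t1_end", "t2_start", "t2_end", "t3_start", "t3_end",
        "maternal_age_at_delivery", "predates_data_period",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for ep in episodes:
            w.writerow([
                ep.episode_id, ep.person_id, ep.delivery_date.isoformat(),
                ep.delivery_year, ep.term_status, ep.caesarean, ep.lmp.isoformat(),
                ep.prepregnancy[0].isoformat(), ep.prepregnancy[1].isoformat(),
                ep.t1[0].isoformat(), ep.t1[1].isoformat(),
                ep.t2[0].isoformat(), ep.t2[1].isoformat(),
                ep.t3[0].isoformat(), ep.t3[1].isoformat(),
                "" if ep.maternal_age_at_delivery is None else ep.maternal_age_at_delivery,
                ep.predates_data_period,
            ])
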