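"""Delivery identification: raw billing codes -> collapsed delivery events.

Deliveries surface in claims through inpatient DRG codes and outpatient
TARMED codes, usually several codes per birth.  The collapsing rules are:

(a) codes within 30 days of each other belong to the same pregnancy
    (anchor-based clustering by default: within 30 days of the cluster's
    first code);
(b) the delivery date is the earliest code in the cluster, except that a
    DRG code takes priority over TARMED — the date becomes the earliest
    DRG code date;
(c) a DRG code recorded 31-300 days after an event's date is ignored when
    the event already rests on a DRG code, but when the event is
    TARMED-only the delivery date is *moved* to that DRG code (TARMED
    deliveries are imprecisely dated; the later inpatient DRG corrects
    them) and term status is re-derived;
(d) anything else landing closer than 300 days to an event is merged into
    it defensively and logged;
(e) separate deliveries of one person must be at least 300 days apart.

Every input code ends up either as a member of exactly one event or in the
audit log with the rule that discarded it.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .records import CodeConfig, ServiceRecord

#: days within which codes are collapsed into one pregnancy
SAME_PREGNANCY_DAYS = 30
#: minimum separation between distinct deliveries of one person
MIN_SEPARATION_DAYS = 300


class ContractViolation(ValueError):
    """Input violated a documented precondition (e.g., unsorted codes)."""


class RawDeliveryCode(NamedTuple):
    person_id: str
    date: dt.date
    code_system: str
    code: str
    term_status: str  # full_term | preterm | unspecified


@dataclass
class DeliveryEvent:
    person_id: str
    delivery_date: dt.date
    term_status: str  # full_term | preterm
    had_drg: bool
    had_tarmed: bool
    caesarean: bool
    member_codes: list[RawDeliveryCode]


@dataclass(frozen=True)
class AuditEntry:
    """One discarded, moved or excluded code/event with the rule applied."""

    person_id: str
    rule: str  # ignored_stray_drg | relocated_to_drg | merged_lt300 | termination_exclusion
    code_system: str
    code: str
    date: dt.date
    detail: str = ""


def write_audit_log(entries: Iterable[AuditEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "rule", "code_system", "code", "date", "detail"])
        for e in entries:
            writer.writerow([e.person_id, e.rule, e.code_system, e.code, e.date.isoformat(), e.detail])


def extract_delivery_codes(
    services: list[ServiceRecord], config: CodeConfig
) -> tuple[list[RawDeliveryCode], list[ServiceRecord]]:
    """Filter service records down to delivery codes (plus termination codes).

    Returns the delivery codes annotated with their configured term status,
    and separately the termination/miscarriage-coded records, which later
    exclude any delivery event they sit within 30 days of.
    """
    delivery: list[RawDeliveryCode] = []
    terminations: list[ServiceRecord] = []
    for rec in services:
        if config.is_delivery_code(rec.code_system, rec.code):
            delivery.append(
                RawDeliveryCode(
                    rec.person_id,
                    rec.date,
                    rec.code_system,
                    rec.code,
                    config.term_status_of(rec.code_system, rec.code),
                )
            )
        elif (rec.code_system, rec.code) in config.termination_codes:
            terminations.append(rec)
    return delivery, terminations


def _cluster(codes: list[RawDeliveryCode], rule: str) -> list[list[RawDeliveryCode]]:
    clusters: list[list[RawDeliveryCode]] = []
    current: list[RawDeliveryCode] = [codes[0]]
    anchor = codes[0].date
    for c in codes[1:]:
        ref = anchor if rule == "anchor" else current[-1].date
        if (c.date - ref).days <= SAME_PREGNANCY_DAYS:
            current.append(c)
        else:
            clusters.append(current)
            current = [c]
            anchor = c.date
    clusters.append(current)
    return clusters


def _event_from_cluster(cluster: list[RawDeliveryCode], config: CodeConfig) -> DeliveryEvent:
    drg = [c for c in cluster if c.code_system == "DRG"]
    date = min(c.date for c in drg) if drg else min(c.date for c in cluster)
    term = "preterm" if any(c.term_status == "preterm" for c in drg) else "full_term"
    return DeliveryEvent(
        person_id=cluster[0].person_id,
        delivery_date=date,
        term_status=term,
        had_drg=bool(drg),
        had_tarmed=any(c.code_system == "TARMED" for c in cluster),
        caesarean=any((c.code_system, c.code) in config.caesarean_codes for c in cluster),
        member_codes=list(cluster),
    )


def _rederive(event: DeliveryEvent, config: CodeConfig) -> None:
    drg = [c for c in event.member_codes if c.code_system == "DRG"]
    event.had_drg = bool(drg)
    event.had_tarmed = any(c.code_system == "TARMED" for c in event.member_codes)
    event.term_status = (
        "preterm" if any(c.term_status == "preterm" for c in drg) else "full_term"
    )
    event.caesarean = any(
        (c.code_system, c.code) in config.caesarean_codes for c in event.member_codes
    )


def collapse_delivery_events(
    codes: list[RawDeliveryCode],
    config: CodeConfig,
    audit: list[AuditEntry] | None = None,
) -> list[DeliveryEvent]:
    """Collapse one person's delivery codes into dated delivery events.

    Implements rules (a)-(e) above.  ``codes`` must belong to a single
    person and be sorted by date.  Discarded/merged codes are appended to
    ``audit`` when given.
    """
    if not codes:
        return []
    if len({c.person_id for c in codes}) > 1:
        raise ContractViolation("codes from more than one person")
    if any(codes[i].date > codes[i + 1].date for i in range(len(codes) - 1)):
        raise ContractViolation("codes not sorted by date")
    if audit is None:
        audit = []

    clusters = _cluster(codes, config.cluster_rule)
    events = [_event_from_cluster(cl, config) for cl in clusters]

    accepted: list[DeliveryEvent] = []
    current = events[0]
    for nxt in events[1:]:
        gap = (nxt.delivery_date - current.delivery_date).days
        if gap >= MIN_SEPARATION_DAYS:
            accepted.append(current)
            current = nxt
            continue
        # Within 300 days of the current event: apply the stray-code rules.
        stray_systems = ("DRG", "TARMED") if config.tarmed_triggers_ignore_rule else ("DRG",)
        if not current.had_drg:
            drg_members = [c for c in nxt.member_codes if c.code_system == "DRG"]
        else:
            drg_members = []
        if drg_members:
            # TARMED-only event later confirmed by a DRG: relocate.
            new_date = min(c.date for c in drg_members)
            audit.append(
                AuditEntry(
                    current.person_id,
                    "relocated_to_drg",
                    drg_members[0].code_system,
                    drg_members[0].code,
                    new_date,
                    f"moved from {current.delivery_date.isoformat()}",
                )
            )
            current.member_codes.extend(nxt.member_codes)
            current.delivery_date = new_date
            _rederive(current, config)
        else:
            for c in nxt.member_codes:
                delta = (c.date - current.delivery_date).days
                if (
                    c.code_system in stray_systems
                    and current.had_drg
                    and SAME_PREGNANCY_DAYS < delta < MIN_SEPARATION_DAYS
                ):
                    audit.append(
                        AuditEntry(
                            c.person_id,
                            "ignored_stray_drg",
                            c.code_system,
                            c.code,
                            c.date,
                            f"{delta} days after {current.delivery_date.isoformat()}",
                        )
                    )
                else:
                    audit.append(
                        AuditEntry(
                            c.person_id,
                            "merged_lt300",
                            c.code_system,
                            c.code,
                            c.date,
                            f"merged into event {current.delivery_date.isoformat()}",
                        )
                    )
                    current.member_codes.append(c)
            _rederive_keep_date(current, config)
    accepted.append(current)
    return accepted


def _rederive_keep_date(event: DeliveryEvent, config: CodeConfig) -> None:
    # merging extra codes never shifts an established delivery date
    date = event.delivery_date
    _rederive(event, config)
    event.delivery_date = date


def identify_deliveries(
    services: list[ServiceRecord], config: CodeConfig
) -> tuple[list[DeliveryEvent], list[AuditEntry]]:
    """Full delivery identification over a sorted multi-person service table.

    Applies code extraction, per-person collapsing, and the termination /
    miscarriage exclusion: an event within 30 days of a termination-coded
    service for the same person is removed (with an audit entry), because
    such an episode does not end in a delivery.
    """
    codes, terminations = extract_delivery_codes(services, config)
    term_by_person: dict[str, list[ServiceRecord]] = {}
    for t in terminations:
        term_by_person.setdefault(t.person_id, []).append(t)

    audit: list[AuditEntry] = []
    events: list[DeliveryEvent] = []
    by_person: dict[str, list[RawDeliveryCode]] = {}
    for c in codes:
        by_person.setdefault(c.person_id, []).append(c)
    for person in sorted(by_person):
        person_codes = sorted(by_person[person], key=lambda c: (c.date, c.code_system, c.code))
        for ev in collapse_delivery_events(person_codes, config, audit):
            near_termination = any(
                abs((t.date - ev.delivery_date).days) <= SAME_PREGNANCY_DAYS
                for t in term_by_person.get(person, ())
            )
            if near_termination:
                audit.append(
                    AuditEntry(
                        person,
                        "termination_exclusion",
                        "-",
                        "-",
                        ev.delivery_date,
                        "termination/miscarriage code within 30 days",
                    )
                )
            else:
                events.append(ev)
    return events, audit
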