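"""Delivery-code collapsing rules against examples and a brute-force oracle."""

import datetime as dt
import random

import pytest

from pregclaims import CodeConfig, ServiceRecord
from pregclaims.deliveries import (
    ContractViolation,
    RawDeliveryCode,
    collapse_delivery_events,
    extract_delivery_codes,
    identify_deliveries,
)

from conftest import drg, tarmed

BASE = dt.date(2015, 1, 1)


# ---------------------------------------------------------------------------
# Independent brute-force reference: a deliberately naive, O(n^2),
# step-at-a-time transcription of the collapsing rules, kept free of the
# production code's cluster/event machinery.
# ---------------------------------------------------------------------------

def brute_force_collapse(codes, caesarean_codes=frozenset()):
    """Return [(date, term, had_drg, had_tarmed, member_count)] per event."""
    codes = sorted(codes, key=lambda c: (c.date, c.code_system, c.code))
    unassigned = list(codes)
    clusters = []
    while unassigned:
        anchor = unassigned[0]
        cluster = [c for c in unassigned if (c.date - anchor.date).days <= 30]
        unassigned = [c for c in unassigned if (c.date - anchor.date).days > 30]
        clusters.append(cluster)

    def date_of(cluster):
        drgs = [c for c in cluster if c.code_system == "DRG"]
        if drgs:
            return min(c.date for c in drgs)
        return min(c.date for c in cluster)

    events = []  # mutable [members, date]
    for cluster in clusters:
        if not events:
            events.append([list(cluster), date_of(cluster)])
            continue
        members, cur_date = events[-1]
        gap = (date_of(cluster) - cur_date).days
        if gap >= 300:
            events.append([list(cluster), date_of(cluster)])
            continue
        cur_has_drg = any(c.code_system == "DRG" for c in members)
        cluster_drgs = [c for c in cluster if c.code_system == "DRG"]
        if not cur_has_drg and cluster_drgs:
            # relocation: TARMED-only event corrected by a later DRG
            members.extend(cluster)
            events[-1][1] = min(c.date for c in cluster_drgs)
        else:
            for c in cluster:
                delta = (c.date - cur_date).days
                if c.code_system == "DRG" and cur_has_drg and 30 < delta < 300:
                    continue  # ignored stray
                members.append(c)

    out = []
    for members, date in events:
        drgs = [c for c in members if c.code_system == "DRG"]
        term = "preterm" if any(c.term_status == "preterm" for c in drgs) else "full_term"
        out.append(
            (
                date,
                term,
                bool(drgs),
                any(c.code_system == "TARMED" for c in members),
                len(members),
            )
        )
    return out


def summarize(events):
    return [
        (e.delivery_date, e.term_status, e.had_drg, e.had_tarmed, len(e.member_codes))
        for e in events
    ]


class TestExtraction:
    def test_filters_to_configured_delivery_codes(self, config):
        services = [
            ServiceRecord("W1", BASE, "DRG", "O60A"),
            ServiceRecord("W1", BASE, "DRG", "X99Z"),
            ServiceRecord("W1", BASE + dt.timedelta(days=400), "TARMED", "DEL01"),
            ServiceRecord("W1", BASE, "TARMED", "00.123"),
            ServiceRecord("W1", BASE, "DRG", "O40Z"),  # termination
        ]
        codes, terminations = extract_delivery_codes(services, config)
        assert len(codes) == 2
        assert len(terminations) == 1
        assert codes[0].term_status == "full_term"

    def test_no_matches_gives_empty_list(self, config):
        codes, _ = extract_delivery_codes([ServiceRecord("W1", BASE, "DRG", "Z99")], config)
        assert codes == []

    def test_brute_force_membership_count(self, config):
        rng = random.Random(7)
        all_codes = ["O60A", "O60C", "DEL01", "X99", "00.12", "O40Z"]
        services = [
            ServiceRecord(
                f"W{rng.randrange(10)}",
                BASE + dt.timedelta(days=rng.randrange(2000)),
                rng.choice(["DRG", "TARMED"]),
                rng.choice(all_codes),
            )
            for _ in range(1000)
        ]
        codes, _ = extract_delivery_codes(services, config)
        expected = sum(
            1
            for s in services
            if s.code in config.delivery_codes.get(s.code_system, {})
        )
        assert len(codes) == expected


class TestCollapseExamples:
    def test_drg_priority_sets_delivery_date(self, config):
        events = collapse_delivery_events([tarmed("W1", 95), drg("W1", 100)], config)
        assert summarize(events) == [(BASE + dt.timedelta(days=100), "full_term", True, True, 2)]

    def test_tarmed_only_event_relocated_to_later_drg(self, config):
        events = collapse_delivery_events([tarmed("W1", 0), drg("W1", 120)], config)
        assert len(events) == 1
        assert events[0].delivery_date == BASE + dt.timedelta(days=120)
        assert events[0].had_drg and events[0].had_tarmed

    def test_stray_drg_within_300_days_ignored(self, config):
        audit = []
        events = collapse_delivery_events([drg("W1", 0), drg("W1", 150)], config, audit)
        assert summarize(events) == [(BASE, "full_term", True, False, 1)]
        assert [a.rule for a in audit] == ["ignored_stray_drg"]

    def test_separate_deliveries_310_days_apart(self, config):
        events = collapse_delivery_events([drg("W1", 0), drg("W1", 310)], config)
        assert len(events) == 2

    def test_exactly_300_days_is_a_new_delivery(self, config):
        events = collapse_delivery_events([drg("W1", 0), drg("W1", 300)], config)
        assert len(events) == 2

    def test_preterm_from_any_member_drg(self, config):
        events = collapse_delivery_events([drg("W1", 0, "O60A"), drg("W1", 10, "O60C")], config)
        assert events[0].term_status == "preterm"

    def test_relocation_rederives_term_status(self, config):
        events = collapse_delivery_events([tarmed("W1", 0), drg("W1", 60, "O60C")], config)
        assert events[0].term_status == "preterm"

    def test_caesarean_flag_from_member_codes(self, config):
        events = collapse_delivery_events([drg("W1", 0, "O01A")], config)
        assert events[0].caesarean

    def test_unsorted_input_rejected(self, config):
        with pytest.raises(ContractViolation):
            collapse_delivery_events([drg("W1", 10), drg("W1", 0)], config)

    def test_mixed_persons_rejected(self, config):
        with pytest.raises(ContractViolation):
            collapse_delivery_events([drg("W1", 0), drg("W2", 0)], config)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_streams(self, config):
        """200 random synthetic code streams covering the 30-day collapse,
        the 31-300-day ignore/relocate rules and the 300-day separation
        produce identical event lists to the naive reference."""
        rng = random.Random(20240601)
        for _ in range(200):
            n = rng.randrange(1, 12)
            days = sorted(
                rng.choices(
                    # mixture of short and long gaps to hit every rule
                    range(0, 1200),
                    k=n,
                )
            )
            codes = sorted(
                (
                    drg("W1", d, rng.choice(["O60A", "O60C"]))
                    if rng.random() < 0.6
                    else tarmed("W1", d)
                    for d in days
                ),
                key=lambda c: (c.date, c.code_system, c.code),
            )
            got = summarize(collapse_delivery_events(codes, config))
            expected = brute_force_collapse(codes)
            assert got == expected, f"stream {[(c.date, c.code_system) for c in codes]}"

    def test_events_at_least_300_days_apart_property(self, config):
        rng = random.Random(99)
        for _ in range(100):
            days = sorted(rng.randrange(0, 2000) for _ in range(rng.randrange(1, 15)))
            codes = sorted(
                (drg("W1", d) if rng.random() < 0.5 else tarmed("W1", d) for d in days),
                key=lambda c: (c.date, c.code_system, c.code),
            )
            events = collapse_delivery_events(codes, config)
            gaps = [
                (b.delivery_date - a.delivery_date).days
                for a, b in zip(events, events[1:])
            ]
            assert all(g >= 300 for g in gaps)

    def test_conservation_every_code_member_or_audited(self, config):
        rng = random.Random(5)
        for _ in range(100):
            days = sorted(rng.randrange(0, 1500) for _ in range(rng.randrange(1, 12)))
            codes = sorted(
                (drg("W1", d) if rng.random() < 0.5 else tarmed("W1", d) for d in days),
                key=lambda c: (c.date, c.code_system, c.code),
            )
            audit = []
            events = collapse_delivery_events(codes, config, audit)
            member_total = sum(len(e.member_codes) for e in events)
            discarded = sum(1 for a in audit if a.rule == "ignored_stray_drg")
            assert member_total + discarded == len(codes)

    def test_idempotent_on_own_output(self, config):
        rng = random.Random(17)
        for _ in range(50):
            days = sorted(rng.randrange(0, 1500) for _ in range(rng.randrange(1, 10)))
            codes = sorted(
                (drg("W1", d) if rng.random() < 0.5 else tarmed("W1", d) for d in days),
                key=lambda c: (c.date, c.code_system, c.code),
            )
            events = collapse_delivery_events(codes, config)
            members = sorted(
                (c for e in events for c in e.member_codes),
                key=lambda c: (c.date, c.code_system, c.code),
            )
            again = collapse_delivery_events(members, config)
            assert summarize(again) == summarize(events)


class TestTerminationExclusion:
    def test_event_near_termination_code_excluded(self, config):
        services = [
            ServiceRecord("W1", BASE, "DRG", "O60A"),
            ServiceRecord("W1", BASE + dt.timedelta(days=10), "DRG", "O40Z"),
            ServiceRecord("W2", BASE, "DRG", "O60A"),
        ]
        events, audit = identify_deliveries(services, config)
        assert [e.person_id for e in events] == ["W2"]
        assert any(a.rule == "termination_exclusion" for a in audit)
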