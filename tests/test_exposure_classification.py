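"""Exposure windows, utilisation-group assignment, fertility flag, shares."""

import datetime as dt
import random

import pytest

from pregclaims import (
    DispensationRecord,
    GroupLabel,
    assign_group,
    build_episode,
    build_exposure_profile,
    flag_fertility_comedication,
    substance_distribution,
)
from pregclaims.deliveries import DeliveryEvent
from pregclaims.exposure import WINDOWS, GroupAssignment, classify_episodes

DELIVERY = dt.date(2015, 10, 1)


def episode(term="full_term", person="W1"):
    return build_episode(DeliveryEvent(person, DELIVERY, term, True, False, False, []))


def disp(date, atc="A10AB05", person="W1"):
    return DispensationRecord(person, date, atc)


def profile_from(ep, window_to_codes):
    """Build a profile by placing one dispensation per (window, ATC) pair."""
    records = []
    for window, codes in window_to_codes.items():
        lo, hi = getattr(ep, window)
        mid = lo + (hi - lo) / 2
        for atc in codes:
            records.append(disp(mid, atc, ep.person_id))
    from pregclaims import CodeConfig

    return build_exposure_profile(ep, records, CodeConfig.default())


class TestWindowAssignment:
    def test_day_90_boundary_belongs_to_t2(self, config):
        ep = episode()
        d = [disp(ep.lmp + dt.timedelta(days=90), "A10BA02")]
        prof = build_exposure_profile(ep, d, config)
        assert "blood_glucose_lowering" in prof.classes["t2"]
        assert not prof.classes["t1"]

    def test_prepregnancy_start_day_inclusive(self, config):
        ep = episode()
        d = [disp(ep.lmp - dt.timedelta(days=252))]
        prof = build_exposure_profile(ep, d, config)
        assert "insulin" in prof.classes["prepregnancy"]

    def test_delivery_day_counts_toward_t3(self, config):
        ep = episode()
        prof = build_exposure_profile(ep, [disp(DELIVERY)], config)
        assert "insulin" in prof.classes["t3"]

    def test_post_delivery_and_non_adm_ignored(self, config):
        ep = episode()
        d = [disp(DELIVERY + dt.timedelta(days=5)), disp(ep.lmp, "N02BE01")]
        prof = build_exposure_profile(ep, d, config)
        assert all(not prof.classes[w] for w in WINDOWS)

    def test_matches_brute_force_day_assignment(self, config):
        """Random dispensation streams land in the same window as an
        explicit day-by-day interval scan."""
        rng = random.Random(123)
        ep = episode()
        lo = ep.prepregnancy[0] - dt.timedelta(days=30)
        for _ in range(300):
            date = lo + dt.timedelta(days=rng.randrange(0, 680))
            atc = rng.choice(["A10AB05", "A10BA02", "N02BE01"])
            prof = build_exposure_profile(ep, [disp(date, atc)], config)
            hit = [w for w in WINDOWS if prof.substances[w]]
            expected = []
            if atc != "N02BE01" and date <= ep.delivery_date:
                for w in WINDOWS:
                    wlo, whi = getattr(ep, w)
                    if wlo <= date <= whi:
                        expected.append(w)
            assert hit == expected


class TestGroupAssignment:
    def p(self, **window_to_codes):
        return profile_from(episode(), window_to_codes)

    def test_continuer_insulin_then_insulin_plus_bgld(self):
        prof = self.p(prepregnancy=["A10AB05"], t2=["A10AB05", "A10BA02"])
        assert assign_group(prof).label is GroupLabel.PREGESTATIONAL_CONTINUER

    def test_continuer_both_before_insulin_after(self):
        prof = self.p(prepregnancy=["A10AB05", "A10BA02"], t3=["A10AB05"])
        assert assign_group(prof).label is GroupLabel.PREGESTATIONAL_CONTINUER

    def test_switcher_bgld_to_insulin(self):
        prof = self.p(prepregnancy=["A10BA02"], t2=["A10AB05"])
        assert assign_group(prof).label is GroupLabel.PREGESTATIONAL_SWITCHER

    def test_switcher_class_sets_disjoint_invariant(self):
        prof = self.p(prepregnancy=["A10BA02"], t3=["A10AE05"])
        a = assign_group(prof)
        if a.label is GroupLabel.PREGESTATIONAL_SWITCHER:
            assert not (prof.classes["prepregnancy"] & prof.post_t2_classes)

    def test_discontinuer_metformin_prepregnancy_only(self):
        prof = self.p(prepregnancy=["A10BA02"])
        assert assign_group(prof).label is GroupLabel.DISCONTINUER

    def test_discontinuer_despite_t1_exposure_flagged(self):
        prof = self.p(prepregnancy=["A10BA02"], t1=["A10BA02"])
        a = assign_group(prof)
        assert a.label is GroupLabel.DISCONTINUER and a.t1_exposed_discontinuer

    def test_gdm_first_exposure_in_t3(self):
        prof = self.p(t3=["A10AB05"])
        assert assign_group(prof).label is GroupLabel.GDM

    def test_t1_then_later_is_not_gdm(self):
        prof = self.p(t1=["A10AB05"], t2=["A10AB05"])
        a = assign_group(prof)
        assert a.label is GroupLabel.T1_ONLY and a.t1_subtype == "first"

    def test_t1_only_exposure(self):
        prof = self.p(t1=["A10BA02"])
        a = assign_group(prof)
        assert a.label is GroupLabel.T1_ONLY and a.t1_subtype == "only"

    def test_unexposed(self):
        prof = self.p()
        assert assign_group(prof).label is GroupLabel.UNEXPOSED

    def test_labels_partition_random_profiles(self):
        """Exactly one label per episode over random exposure patterns."""
        rng = random.Random(7)
        codes = ["A10AB05", "A10BA02", "A10XA01"]
        for _ in range(500):
            placement = {
                w: [c for c in codes if rng.random() < 0.25] for w in WINDOWS
            }
            prof = profile_from(episode(), placement)
            a = assign_group(prof)
            assert isinstance(a, GroupAssignment)
            assert a.label in GroupLabel


class TestFertilityFlag:
    def test_fertility_prefix_in_prepregnancy(self, config):
        ep = episode()
        d = [disp(ep.prepregnancy[0] + dt.timedelta(days=5), "G03GA04")]
        prof = build_exposure_profile(ep, d, config)
        assert flag_fertility_comedication(prof, d, config)

    def test_same_code_in_t3_only_is_false(self, config):
        ep = episode()
        d = [disp(ep.t3[0] + dt.timedelta(days=5), "G03GA04")]
        prof = build_exposure_profile(ep, d, config)
        assert not flag_fertility_comedication(prof, d, config)

    def test_matches_brute_force_prefix_scan(self, config):
        rng = random.Random(31)
        ep = episode()
        pool = ["G03GA04", "G03GB02", "H01CC01", "A10AB05", "N02BE01"]
        for _ in range(200):
            records = [
                disp(
                    ep.prepregnancy[0] + dt.timedelta(days=rng.randrange(-40, 700)),
                    rng.choice(pool),
                )
                for _ in range(rng.randrange(0, 6))
            ]
            prof = build_exposure_profile(ep, records, config)
            got = flag_fertility_comedication(prof, records, config)
            lo, hi = ep.prepregnancy
            expected = any(
                lo <= r.date <= hi
                and any(r.atc_code.startswith(p) for p in config.fertility_atc)
                for r in records
            )
            assert got == expected


class TestSubstanceDistribution:
    def _cohort(self, config, n_metformin, n_sitagliptin):
        profiles, assignments = [], []
        for i in range(n_metformin + n_sitagliptin):
            atc = "A10BA02" if i < n_metformin else "A10BH01"
            ep = episode(person=f"W{i}")
            prof = profile_from(ep, {"prepregnancy": [atc]})
            profiles.append(prof)
            assignments.append(assign_group(prof))
        return profiles, assignments

    def test_single_substance_is_100_pct(self, config):
        profiles, assignments = self._cohort(config, 2, 0)
        table = substance_distribution(
            profiles, assignments, GroupLabel.DISCONTINUER, "prepregnancy", config
        )
        assert table.share_pct.tolist() == [100.0]

    def test_empty_group_gives_empty_table(self, config):
        table = substance_distribution([], [], GroupLabel.GDM, "t2", config)
        assert table.empty

    def test_programmed_60_40_mix_recovered(self, config):
        profiles, assignments = self._cohort(config, 60, 40)
        table = substance_distribution(
            profiles, assignments, GroupLabel.DISCONTINUER, "prepregnancy", config
        ).set_index("substance")
        assert table.loc["A10BA02", "share_pct"] == 60.0
        assert table.loc["A10BH01", "share_pct"] == 40.0


class TestClassifyEpisodes:
    def test_table_has_one_row_per_episode(self, config):
        eps = [episode(person=f"W{i}") for i in range(3)]
        d = [disp(eps[0].prepregnancy[0] + dt.timedelta(days=3), "A10BA02", "W0")]
        profiles, assignments, table = classify_episodes(eps, d, config)
        assert len(table) == 3
        assert set(table.group) == {"discontinuer", "unexposed"}
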