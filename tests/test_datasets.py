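"""Analysis-table construction: breeder-days, pair-days, dyads, dispersal."""

import numpy as np
import pandas as pd
import pytest

from boxvisits.datasets import (
    build_dispersal_dyads,
    build_dispersal_records,
    build_epp_dyads,
    build_individual_day_table,
    build_pair_day_table,
    build_territory_visit_dyads,
    eligible_members,
    mark_extrapair,
)
from boxvisits.territories import build_territories
from boxvisits.visits import (
    apply_inclusion_rules,
    classify_visits,
    collapse_readings,
    occupied_only_filter,
    retained_visits,
)
from tests.conftest import make_attempts, make_boxes, make_individuals


@pytest.fixture
def season():
    boxes = make_boxes([(0, 0), (100, 0), (0, 100), (100, 100), (20, 30)])
    attempts = make_attempts(["B00", "B01", "B02", "B03"])
    individuals = make_individuals(attempts)
    tm = build_territories(boxes, attempts)
    return boxes, attempts, individuals, tm


def visits_from(times_boxes, individual, setup):
    boxes, attempts, individuals, tm = setup
    frames = [
        pd.DataFrame({"individual_id": [individual], "box_id": [b], "timestamp": [t]})
        for t, b in times_boxes
    ]
    v = classify_visits(collapse_readings(pd.concat(frames)), tm, attempts, individuals)
    return retained_visits(apply_inclusion_rules(v, attempts, individuals))


class TestIndividualDays:
    def test_row_count_is_inclusive_day_span(self, season):
        boxes, attempts, individuals, tm = season
        idt = build_individual_day_table(
            visits_from([], "M0", season) if False else pd.DataFrame(),
            attempts, individuals, 2020,
        )
        # Apr 1 .. May 28 inclusive = 58 days, for each of 8 members
        assert len(idt) == 58 * 8
        assert not idt["made_visit"].any()
        # relative-date anchors
        one = idt[idt["individual_id"] == "M0"].set_index("day")
        assert one.loc["2020-04-15", "rel_laying"] == 0
        assert one.loc["2020-05-08", "rel_hatch"] == 0

    def test_made_visit_flags_match_day_sets(self, season):
        ret = visits_from(
            [("2020-04-10 08:00:00", "B01"), ("2020-04-10 17:00:00", "B01"),
             ("2020-04-20 09:00:00", "B02")],
            "M0", season,
        )
        boxes, attempts, individuals, tm = season
        idt = build_individual_day_table(ret, attempts, individuals, 2020)
        m0 = idt[idt["individual_id"] == "M0"]
        flagged = set(m0.loc[m0["made_visit"], "day"].dt.strftime("%m-%d"))
        assert flagged == {"04-10", "04-20"}

    def test_attempt_with_missing_dates_skipped(self, season):
        boxes, attempts, individuals, tm = season
        attempts = attempts.copy()
        attempts.loc[attempts["attempt_id"] == "A0", "date_fledge"] = pd.NaT
        idt = build_individual_day_table(pd.DataFrame(), attempts, individuals, 2020)
        assert "M0" not in set(idt["individual_id"])
        assert len(idt) == 58 * 6


class TestPairDays:
    def test_received_flags(self, season):
        boxes, attempts, individuals, tm = season
        # M0 visits B01's territory; F0 visits B02's breeding box
        ret = pd.concat(
            [
                visits_from([("2020-04-18 08:00:00", "B01")], "M0", season),
                visits_from([("2020-04-19 08:00:00", "B02")], "F0", season),
            ]
        )
        pdt = build_pair_day_table(ret, attempts, individuals, tm)
        host1 = pdt[(pdt["host_territory"] == "B01")].set_index("day")
        assert bool(host1.loc["2020-04-18", "received_from_male"])
        assert not host1.loc["2020-04-18", "received_from_female"]
        assert host1.loc["2020-04-18", "rel_laying"] == 3
        host2 = pdt[(pdt["host_territory"] == "B02")].set_index("day")
        assert bool(host2.loc["2020-04-19", "received_from_female"])
        assert host1["received_from_male"].sum() == 1
        # no incoming visits anywhere else
        others = pdt[~pdt["host_territory"].isin(["B01", "B02"])]
        assert not others[["received_from_male", "received_from_female"]].any().any()

    def test_breeding_box_only_variant_is_stricter(self, season):
        boxes, attempts, individuals, tm = season
        # B04 is in B00's territory but is not the breeding box
        ret = visits_from([("2020-04-18 08:00:00", "B04")], "M1", season)
        wide = build_pair_day_table(ret, attempts, individuals, tm, territory_wide=True)
        strict = build_pair_day_table(ret, attempts, individuals, tm, territory_wide=False)
        assert wide["received_from_male"].sum() == 1
        assert strict["received_from_male"].sum() == 0


class TestTerritoryDyads:
    def test_rows_orders_and_visit_aggregation(self, season):
        boxes, attempts, individuals, tm = season
        ret = visits_from(
            [("2020-04-10 08:00:00", "B01"), ("2020-04-11 09:00:00", "B01"),
             ("2020-04-11 10:00:00", "B01")],
            "M0", season,
        )
        dy = build_territory_visit_dyads(ret, tm, attempts, individuals, boxes)
        m0 = dy[dy["focal_id"] == "M0"]
        # every box outside B00's territory is a candidate (B04 is inside it)
        assert set(m0["target_id"]) == {"B01", "B02", "B03"}
        row = m0.set_index("target_id").loc["B01"]
        assert row["visited"] and row["n_visit_days"] == 2  # two distinct days
        assert m0.set_index("target_id").loc["B02", "visited"] == False  # noqa: E712
        assert (m0["neighbor_order"] >= 1).all()
        # distance check against coordinates
        assert row["distance"] == pytest.approx(100.0)

    def test_zero_visits_all_false(self, season):
        boxes, attempts, individuals, tm = season
        dy = build_territory_visit_dyads(pd.DataFrame(), tm, attempts, individuals, boxes)
        assert len(dy) > 0 and not dy["visited"].any() and (dy["n_visit_days"] == 0).all()

    def test_occupied_only_is_monotone_restriction(self, small_bundle):
        b = small_bundle
        tm = b.territory_maps[2015]
        v = classify_visits(collapse_readings(b.readings), tm, b.attempts, b.individuals)
        ret = retained_visits(apply_inclusion_rules(v, b.attempts, b.individuals))
        full = build_territory_visit_dyads(ret, tm, b.attempts, b.individuals, b.boxes)
        occ = build_territory_visit_dyads(
            occupied_only_filter(ret), tm, b.attempts, b.individuals, b.boxes,
            occupied_only=True,
        )
        merged = occ.merge(
            full, on=["focal_id", "target_id"], suffixes=("_occ", "_full")
        )
        assert len(merged) == len(occ)
        assert (merged["n_visit_days_occ"] <= merged["n_visit_days_full"]).all()
        assert not (merged["visited_occ"] & ~merged["visited_full"]).any()


class TestEppDyads:
    def _parentage(self, rows):
        return pd.DataFrame(
            rows,
            columns=["offspring_id", "attempt_id", "genetic_mother_id",
                     "genetic_sire_id", "is_extrapair"],
        )

    def test_single_epo_dyad(self, season):
        boxes, attempts, individuals, tm = season
        # M1 sired one chick in A0's brood (F0); M1 visited B00's territory
        par = self._parentage(
            [("c1", "A0", "F0", "M1", True), ("c2", "A0", "F0", "M0", False)]
        )
        ret = visits_from([("2020-04-10 08:00:00", "B00")], "M1", season)
        dy = build_epp_dyads(par, tm, attempts, individuals, ret, boxes)
        m1 = dy[(dy["sex"] == "male") & (dy["focal_id"] == "M1")]
        assert m1["outcome"].sum() == 1
        hit = m1[m1["outcome"]].iloc[0]
        assert hit["target_id"] == "F0" and hit["visited"]
        # F0 is also a focal (extrapair young in her brood)
        f0 = dy[(dy["sex"] == "female") & (dy["focal_id"] == "F0")]
        assert f0["outcome"].sum() == 1
        assert f0[f0["outcome"]].iloc[0]["target_id"] == "M1"

    def test_focal_without_epo_contributes_no_rows(self, season):
        boxes, attempts, individuals, tm = season
        par = self._parentage([("c1", "A0", "F0", "M0", False)])
        dy = build_epp_dyads(par, tm, attempts, individuals, pd.DataFrame(), boxes)
        assert len(dy) == 0

    def test_outcome_flags_match_bruteforce_join(self, small_bundle):
        b = small_bundle
        tm = b.territory_maps[2015]
        v = classify_visits(collapse_readings(b.readings), tm, b.attempts, b.individuals)
        ret = retained_visits(apply_inclusion_rules(v, b.attempts, b.individuals))
        dy = build_epp_dyads(b.parentage, tm, b.attempts, b.individuals, ret, b.boxes)
        par = mark_extrapair(b.parentage, b.attempts)
        mother = b.attempts.set_index("attempt_id")["female_id"]
        epo_pairs = {
            (s, mother[a])
            for s, a in zip(par.loc[par["is_extrapair"], "genetic_sire_id"],
                            par.loc[par["is_extrapair"], "attempt_id"])
        }
        for row in dy.sample(min(300, len(dy)), random_state=1).itertuples():
            pair = (
                (row.focal_id, row.target_id)
                if row.sex == "male"
                else (row.target_id, row.focal_id)
            )
            assert row.outcome == (pair in epo_pairs)
        assert (dy["neighbor_order"] <= 2).all()


class TestDispersal:
    def _setup(self):
        # elongated layout: own Voronoi cell extends ~150 m, so a >70 m move
        # can stay inside the previous territory
        boxes = make_boxes([(0, 0), (300, 0), (600, 0), (100, 0), (340, 0)])
        att_x = make_attempts(["B00", "B01", "B02"], year=2020)
        att_x1 = make_attempts(["B00", "B01", "B02"], year=2021).assign(year=2021)
        individuals = make_individuals(att_x)
        tm = build_territories(boxes, att_x, year=2020)
        return boxes, att_x, att_x1, individuals, tm

    @pytest.mark.parametrize(
        "new_box,expect_dispersed,why",
        [
            ("B03", False, "moved 100 m but still inside own polygon"),
            ("B04", True, "moved 340 m into another territory"),
        ],
    )
    def test_conjunctive_rule(self, new_box, expect_dispersed, why):
        boxes, att_x, att_x1, individuals, tm = self._setup()
        att_x1 = att_x1.copy()
        att_x1.loc[att_x1["attempt_id"] == "A0", "box_id"] = new_box
        rec = build_dispersal_records(att_x, att_x1, tm, individuals, boxes)
        row = rec[rec["individual_id"] == "M0"].iloc[0]
        assert bool(row["dispersed"]) == expect_dispersed, why
        if new_box == "B03":
            assert row["moved_distance"] == pytest.approx(100.0)
            assert not row["outside_previous_territory"]

    def test_short_move_across_border_not_dispersed(self):
        # 50 m move into a different territory fails the distance criterion
        boxes = make_boxes([(0, 0), (80, 0), (30, 0)])
        att_x = make_attempts(["B00", "B01"], year=2020)
        att_x1 = make_attempts(["B00", "B01"], year=2021).assign(year=2021)
        att_x1.loc[att_x1["attempt_id"] == "A0", "box_id"] = "B02"
        individuals = make_individuals(att_x)
        tm = build_territories(boxes, att_x, year=2020)
        rec = build_dispersal_records(att_x, att_x1, tm, individuals, boxes)
        row = rec[rec["individual_id"] == "M0"].iloc[0]
        assert not row["dispersed"]

    def test_dispersal_dyads_exactly_one_destination(self, two_year_bundle):
        b = two_year_bundle
        tm = b.territory_maps[2015]
        att_x = b.attempts[b.attempts["year"] == 2015]
        att_x1 = b.attempts[b.attempts["year"] == 2016]
        rec = build_dispersal_records(att_x, att_x1, tm, b.individuals, b.boxes)
        v = classify_visits(
            collapse_readings(b.readings[b.readings["timestamp"].dt.year == 2015]),
            tm, b.attempts, b.individuals,
        )
        ret = retained_visits(apply_inclusion_rules(v, b.attempts, b.individuals))
        dy = build_dispersal_dyads(rec, tm, ret)
        if len(dy):
            per_focal = dy.groupby("focal_id")["outcome"].sum()
            assert (per_focal == 1).all()
            assert (dy["neighbor_order"].between(1, 3)).all()
        n_retained = dy["focal_id"].nunique() if len(dy) else 0
        assert n_retained + dy.attrs["n_beyond_max_order"] == int(rec["dispersed"].sum())


def test_eligible_members_excludes_late_tagged_and_failed(season):
    boxes, attempts, individuals, tm = season
    attempts = attempts.copy()
    attempts.loc[attempts["attempt_id"] == "A1", "fate"] = "failed"
    individuals = individuals.copy()
    individuals.loc[individuals["individual_id"] == "M2", "tag_date"] = pd.Timestamp(
        "2020-04-10"
    )
    mem = eligible_members(attempts, individuals, 2020)
    ids = set(mem["individual_id"])
    assert "M1" not in ids and "F1" not in ids  # failed attempt
    assert "M2" not in ids and "F2" in ids  # late-tagged male only
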