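"""Analysis tables: breeder-days, pair-days, and dyads.

Builds the tables the mixed models run on, from filtered visits plus the
season's breeding attempts, territory map and parentage assignments:

* one row per breeder per day of its attempt (foray models),
* one row per host pair per day (received-visit models),
* focal x territory-box dyads within three neighborhood orders (visit
  decay models),
* focal x opposite-sex-breeder dyads within two orders for breeders
  with extrapair offspring (extrapair-paternity models),
* between-year records and disperser x candidate-territory dyads
  (dispersal models).

Relative-date covariates use the focal bird's own attempt in the foray
tables and the host pair's attempt in the received-visit tables (what
matters for a visitor is the visited female's breeding stage).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.geometry import Point

from boxvisits.territories import TerritoryMap

logger = logging.getLogger(__name__)

#: Breeding-dispersal distance criterion, meters: a bird dispersed iff it
#: moved further than this AND settled outside its previous territory.
DISPERSAL_DISTANCE_M = 70.0


def individuals_for_year(individuals: pd.DataFrame, year: int) -> pd.DataFrame:
    """Season-specific individual attributes (age class changes between
    years); falls back to unique rows when the table has no year column."""
    if "year" in individuals.columns:
        sub = individuals[individuals["year"] == year]
        if len(sub):
            return sub.drop_duplicates("individual_id")
    return individuals.drop_duplicates("individual_id")


def eligible_members(attempts: pd.DataFrame, individuals: pd.DataFrame, year: int) -> pd.DataFrame:
    """Breeders entering the analyses: pair members of fledged attempts of
    one season, tagged on or before the start of nest building, with
    complete phenology dates.  One row per member."""
    individuals = individuals_for_year(individuals, year)
    att = attempts[(attempts["year"] == year) & (attempts["fate"] == "fledged")].copy()
    missing = att["date_nest_start"].isna() | att["date_fledge"].isna()
    if missing.any():
        logger.warning(
            "skipping %d fledged attempt(s) with missing phenology dates", int(missing.sum())
        )
        att = att[~missing]
    ind = individuals.set_index("individual_id")
    rows = []
    for sex_col in ("male_id", "female_id"):
        sub = att.dropna(subset=[sex_col]).copy()
        sub["individual_id"] = sub[sex_col]
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    out = out[out["individual_id"].isin(ind.index)]
    out["sex"] = out["individual_id"].map(ind["sex"])
    out["age_class"] = out["individual_id"].map(ind["age_class"])
    tag = pd.to_datetime(out["individual_id"].map(ind["tag_date"]))
    on_time = tag.isna() | (tag <= pd.to_datetime(out["date_nest_start"]))
    out = out[on_time]
    cols = [
        "individual_id",
        "sex",
        "age_class",
        "attempt_id",
        "box_id",
        "year",
        "date_nest_start",
        "date_first_egg",
        "date_hatch",
        "date_fledge",
    ]
    return out[cols].reset_index(drop=True)


def _visit_days(visits: pd.DataFrame) -> pd.DataFrame:
    """Distinct (individual, day) combinations among retained visits."""
    if len(visits) == 0:
        return pd.DataFrame(columns=["individual_id", "day"])
    return visits[["individual_id", "day"]].drop_duplicates()


def build_individual_day_table(
    visits: pd.DataFrame,
    attempts: pd.DataFrame,
    individuals: pd.DataFrame,
    year: int,
) -> pd.DataFrame:
    """One row per eligible breeder per day between nest start and fledging.

    ``made_visit`` is true on days with at least one retained
    extra-territorial visit.  ``rel_laying`` / ``rel_hatch`` count days from
    the focal's first-egg and hatch dates.
    """
    members = eligible_members(attempts, individuals, year)
    recs = []
    for row in members.itertuples(index=False):
        days = pd.date_range(row.date_nest_start, row.date_fledge, freq="D")
        rel_egg = (days - pd.Timestamp(row.date_first_egg)).days
        rel_hatch = (days - pd.Timestamp(row.date_hatch)).days
        recs.append(
            pd.DataFrame(
                {
                    "individual_id": row.individual_id,
                    "sex": row.sex,
                    "age_class": row.age_class,
                    "day": days,
                    "rel_laying": rel_egg,
                    "rel_hatch": rel_hatch,
                    "year": row.year,
                    "attempt_id": row.attempt_id,
                }
            )
        )
    if not recs:
        return pd.DataFrame(
            columns=[
                "individual_id", "sex", "age_class", "day", "rel_laying",
                "rel_hatch", "year", "attempt_id", "made_visit",
            ]
        )
    table = pd.concat(recs, ignore_index=True)
    vd = _visit_days(visits)
    vd = vd.assign(made_visit=True)
    table = table.merge(vd, on=["individual_id", "day"], how="left")
    table["made_visit"] = table["made_visit"].eq(True)
    return table


def build_pair_day_table(
    visits: pd.DataFrame,
    attempts: pd.DataFrame,
    individuals: pd.DataFrame,
    tm: TerritoryMap,
    territory_wide: bool = True,
) -> pd.DataFrame:
    """One row per host pair per active day with received-visit flags.

    A visit counts as received by the host pair whose territory contains
    the visited box (default) or, with ``territory_wide=False``, only
    visits to the host's breeding box itself.  Received flags are split by
    visitor sex; relative dates use the host's phenology.
    """
    att = attempts[(attempts["year"] == tm.year) & (attempts["fate"] == "fledged")].copy()
    att = att[att["date_nest_start"].notna() & att["date_fledge"].notna()]
    ind = individuals_for_year(individuals, tm.year).set_index("individual_id")

    v = visits.copy()
    if len(v):
        if territory_wide:
            v["host_territory"] = v["box_id"].astype(str).map(tm.box_assignment)
        else:
            v["host_territory"] = v["box_id"].astype(str).where(
                v["box_id"].astype(str).isin(tm.territory_ids)
            )
        v["visitor_sex"] = v["individual_id"].map(ind["sex"])
        v = v.dropna(subset=["host_territory"])

    recs = []
    for row in att.itertuples(index=False):
        days = pd.date_range(row.date_nest_start, row.date_fledge, freq="D")
        recs.append(
            pd.DataFrame(
                {
                    "attempt_id": row.attempt_id,
                    "host_territory": str(row.box_id),
                    "day": days,
                    "rel_laying": (days - pd.Timestamp(row.date_first_egg)).days,
                    "rel_hatch": (days - pd.Timestamp(row.date_hatch)).days,
                    "year": row.year,
                }
            )
        )
    if not recs:
        return pd.DataFrame(
            columns=[
                "attempt_id", "host_territory", "day", "rel_laying", "rel_hatch",
                "year", "received_from_male", "received_from_female",
            ]
        )
    table = pd.concat(recs, ignore_index=True)
    for sex in ("male", "female"):
        if len(v):
            inc = (
                v[v["visitor_sex"] == sex][["host_territory", "day"]]
                .drop_duplicates()
                .assign(**{f"received_from_{sex}": True})
            )
            table = table.merge(inc, on=["host_territory", "day"], how="left")
            table[f"received_from_{sex}"] = table[f"received_from_{sex}"].eq(True)
        else:
            table[f"received_from_{sex}"] = False
    return table


def _box_coords(boxes: pd.DataFrame) -> pd.DataFrame:
    df = boxes.copy()
    if "x_m" in df.columns:
        df = df.rename(columns={"x_m": "x", "y_m": "y"})
    df["box_id"] = df["box_id"].astype(str)
    return df.set_index("box_id")[["x", "y"]]


def build_territory_visit_dyads(
    visits: pd.DataFrame,
    tm: TerritoryMap,
    attempts: pd.DataFrame,
    individuals: pd.DataFrame,
    boxes: pd.DataFrame,
    max_order: int = 3,
    occupied_only: bool = False,
) -> pd.DataFrame:
    """Focal breeder x box dyads for boxes in other territories within
    ``max_order`` neighborhood orders.

    ``visited`` / ``n_visit_days`` aggregate the focal's retained visits to
    that box over its inclusion window.  With ``occupied_only`` both the
    candidate boxes and the counted visits are restricted to breeding
    boxes of active pairs.
    """
    members = eligible_members(attempts, individuals, tm.year)
    coords = _box_coords(boxes)

    v = visits.copy()
    if occupied_only and len(v):
        v = v[v["target_occupied"]]
    per_box = (
        v.groupby(["individual_id", "box_id"])["day"].nunique().rename("n_visit_days")
        if len(v)
        else pd.Series(dtype=int, name="n_visit_days")
    )

    # candidate boxes grouped by territory
    terr_boxes: dict[str, list[str]] = {}
    for bid, tid in tm.box_assignment.items():
        if occupied_only and bid not in tm.territory_ids:
            continue
        terr_boxes.setdefault(tid, []).append(bid)

    rows = []
    for row in members.itertuples(index=False):
        own_tid = tm.box_assignment[str(row.box_id)]
        orders = tm.orders_from(own_tid)
        fx, fy = coords.loc[str(row.box_id)]
        for tid, order in orders.items():
            if order < 1 or order > max_order:
                continue
            for bid in terr_boxes.get(tid, []):
                bx, by = coords.loc[bid]
                n_days = int(per_box.get((row.individual_id, bid), 0))
                rows.append(
                    {
                        "focal_id": row.individual_id,
                        "sex": row.sex,
                        "target_id": bid,
                        "target_territory": tid,
                        "neighbor_order": order,
                        "distance": float(np.hypot(bx - fx, by - fy)),
                        "visited": n_days > 0,
                        "n_visit_days": n_days,
                        "target_occupied": bid in tm.territory_ids,
                        "year": row.year,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "focal_id", "sex", "target_id", "target_territory", "neighbor_order",
            "distance", "visited", "n_visit_days", "target_occupied", "year",
        ],
    )


def mark_extrapair(parentage: pd.DataFrame, attempts: pd.DataFrame) -> pd.DataFrame:
    """Fill/verify ``is_extrapair`` against the broods' social males."""
    out = parentage.copy()
    social_male = out["attempt_id"].map(attempts.set_index("attempt_id")["male_id"])
    out["is_extrapair"] = out["genetic_sire_id"].notna() & (
        out["genetic_sire_id"] != social_male
    )
    return out


def build_breeder_epp_table(
    parentage: pd.DataFrame,
    attempts: pd.DataFrame,
    individuals: pd.DataFrame,
    visits: pd.DataFrame,
    year: int,
) -> pd.DataFrame:
    """Per eligible breeder: produced >=1 extrapair offspring, plus the
    visit covariates (any visit, number of visit days)."""
    members = eligible_members(attempts, individuals, year)
    par = mark_extrapair(parentage, attempts)
    epo = par[par["is_extrapair"]]
    brood_mother = attempts.set_index("attempt_id")["female_id"]
    epo_mothers = set(epo["attempt_id"].map(brood_mother).dropna())
    epo_sires = set(epo["genetic_sire_id"].dropna())

    per_ind = (
        visits.groupby("individual_id")["day"].nunique()
        if len(visits)
        else pd.Series(dtype=int)
    )
    out = members[["individual_id", "sex", "age_class", "year", "attempt_id", "box_id"]].copy()
    out["any_epo"] = np.where(
        out["sex"] == "male",
        out["individual_id"].isin(epo_sires),
        out["individual_id"].isin(epo_mothers),
    )
    out["n_visit_days"] = out["individual_id"].map(per_ind).fillna(0).astype(int)
    out["visited_any"] = out["n_visit_days"] > 0
    return out


def build_epp_dyads(
    parentage: pd.DataFrame,
    tm: TerritoryMap,
    attempts: pd.DataFrame,
    individuals: pd.DataFrame,
    visits: pd.DataFrame,
    boxes: pd.DataFrame,
    max_order: int = 2,
    occupied_only: bool = False,
) -> pd.DataFrame:
    """Focal x opposite-sex-breeder dyads for extrapair-paternity models.

    Focals are eligible breeders with at least one extrapair offspring;
    partners are opposite-sex eligible breeders within ``max_order``
    territories.  ``outcome`` marks dyads sharing an extrapair offspring;
    ``visited`` marks focals that visited the partner's territory (or,
    with ``occupied_only``, the partner's breeding box).
    """
    members = eligible_members(attempts, individuals, tm.year)
    coords = _box_coords(boxes)
    breeders = build_breeder_epp_table(parentage, attempts, individuals, visits, tm.year)
    focals = breeders[breeders["any_epo"]]

    par = mark_extrapair(parentage, attempts)
    epo = par[par["is_extrapair"]].copy()
    brood_mother = attempts.set_index("attempt_id")["female_id"]
    epo["mother_id"] = epo["attempt_id"].map(brood_mother)
    shared = set(zip(epo["genetic_sire_id"], epo["mother_id"]))

    v = visits.copy()
    if occupied_only and len(v):
        v = v[v["target_occupied"]]
    if len(v):
        v["target_territory"] = v["box_id"].astype(str).map(tm.box_assignment)
        per_terr = v.groupby(["individual_id", "target_territory"])["day"].nunique()
    else:
        per_terr = pd.Series(dtype=int)

    by_sex = {s: members[members["sex"] == s] for s in ("male", "female")}
    rows = []
    n_skipped = 0
    for focal in focals.itertuples(index=False):
        own_tid = tm.box_assignment.get(str(focal.box_id))
        if own_tid is None:
            n_skipped += 1
            continue
        orders = tm.orders_from(own_tid)
        fx, fy = coords.loc[str(focal.box_id)]
        partner_sex = "female" if focal.sex == "male" else "male"
        for partner in by_sex[partner_sex].itertuples(index=False):
            p_tid = tm.box_assignment[str(partner.box_id)]
            order = orders.get(p_tid)
            if order is None or order < 1 or order > max_order:
                continue
            pair = (
                (focal.individual_id, partner.individual_id)
                if focal.sex == "male"
                else (partner.individual_id, focal.individual_id)
            )
            n_days = int(per_terr.get((focal.individual_id, p_tid), 0))
            px, py = coords.loc[str(partner.box_id)]
            rows.append(
                {
                    "focal_id": focal.individual_id,
                    "sex": focal.sex,
                    "target_id": partner.individual_id,
                    "neighbor_order": order,
                    "distance": float(np.hypot(px - fx, py - fy)),
                    "visited": n_days > 0,
                    "n_visit_days": n_days,
                    "outcome": pair in shared,
                    "year": tm.year,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "focal_id", "sex", "target_id", "neighbor_order", "distance",
            "visited", "n_visit_days", "outcome", "year",
        ],
    )
    out.attrs["n_focals_skipped"] = n_skipped
    return out


def build_dispersal_records(
    attempts_x: pd.DataFrame,
    attempts_x1: pd.DataFrame,
    tm_x: TerritoryMap,
    individuals: pd.DataFrame,
    boxes: pd.DataFrame,
    threshold_m: float = DISPERSAL_DISTANCE_M,
) -> pd.DataFrame:
    """Between-year records for birds breeding in two consecutive seasons.

    ``dispersed`` applies the conjunctive rule: moved more than
    ``threshold_m`` AND the new box lies outside the bird's previous
    territory polygon.  Both criteria are reported separately.
    """
    coords = _box_coords(boxes)

    def member_boxes(att: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for sex_col, sex in (("male_id", "male"), ("female_id", "female")):
            sub = att.dropna(subset=[sex_col])
            rows.append(
                pd.DataFrame(
                    {
                        "individual_id": sub[sex_col],
                        "sex": sex,
                        "box_id": sub["box_id"].astype(str),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True).drop_duplicates("individual_id")

    bx = member_boxes(attempts_x[attempts_x["year"] == tm_x.year])
    bx1 = member_boxes(attempts_x1).rename(columns={"box_id": "box_id_next"})[
        ["individual_id", "box_id_next"]
    ]
    both = bx.merge(bx1, on="individual_id", how="inner")

    rows = []
    for row in both.itertuples(index=False):
        x0, y0 = coords.loc[row.box_id]
        x1, y1 = coords.loc[row.box_id_next]
        dist = float(np.hypot(x1 - x0, y1 - y0))
        own_tid = tm_x.box_assignment[row.box_id]
        outside = not tm_x.polygon(own_tid).covers(Point(x1, y1))
        rows.append(
            {
                "individual_id": row.individual_id,
                "sex": row.sex,
                "box_id": row.box_id,
                "box_id_next": row.box_id_next,
                "moved_distance": dist,
                "outside_previous_territory": outside,
                "dispersed": (dist > threshold_m) and outside,
                "year": tm_x.year,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id", "sex", "box_id", "box_id_next", "moved_distance",
            "outside_previous_territory", "dispersed", "year",
        ],
    )


def build_dispersal_dyads(
    dispersal: pd.DataFrame,
    tm_x: TerritoryMap,
    visits_x: pd.DataFrame,
    max_order: int = 3,
) -> pd.DataFrame:
    """Disperser x candidate-territory dyads within ``max_order`` orders.

    Exactly one outcome-true row (the destination territory) per retained
    disperser; dispersers whose destination lies beyond ``max_order`` are
    dropped and counted in ``attrs['n_beyond_max_order']``.
    """
    v = visits_x.copy()
    if len(v):
        v["target_territory"] = v["box_id"].astype(str).map(tm_x.box_assignment)
        per_terr = v.groupby(["individual_id", "target_territory"])["day"].nunique()
    else:
        per_terr = pd.Series(dtype=int)

    gen = tm_x.generators.set_index("territory_id")
    rows = []
    n_far = 0
    for row in dispersal[dispersal["dispersed"]].itertuples(index=False):
        own_tid = tm_x.box_assignment[row.box_id]
        dest_tid = tm_x.box_assignment[row.box_id_next]
        orders = tm_x.orders_from(own_tid)
        dest_order = orders.get(dest_tid)
        if dest_order is None or dest_order > max_order:
            n_far += 1
            continue
        x0 = gen.loc[own_tid, ["x", "y"]].to_numpy(float)
        for tid, order in orders.items():
            if order < 1 or order > max_order:
                continue
            x1 = gen.loc[tid, ["x", "y"]].to_numpy(float)
            n_days = int(per_terr.get((row.individual_id, tid), 0))
            rows.append(
                {
                    "focal_id": row.individual_id,
                    "sex": row.sex,
                    "target_id": tid,
                    "neighbor_order": order,
                    "distance": float(np.hypot(*(x1 - x0))),
                    "visited": n_days > 0,
                    "n_visit_days": n_days,
                    "outcome": tid == dest_tid,
                    "year": row.year,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "focal_id", "sex", "target_id", "neighbor_order", "distance",
            "visited", "n_visit_days", "outcome", "year",
        ],
    )
    out.attrs["n_beyond_max_order"] = n_far
    return out
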