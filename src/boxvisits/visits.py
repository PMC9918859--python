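"""From raw RFID readings to classified, filtered visits.

A transponder reading only shows that a tagged bird was at a nest-box
entrance at one instant; detections seconds or minutes apart are not
independent events.  Readings by the same bird at the same box are
therefore merged into a single *visit* whenever consecutive readings are
no more than a merge window apart (10 minutes by default) — standard
gap-based sessionization.  Visits are then classified against the
season's territory map (own box / own territory / extra-territorial,
occupied vs unoccupied target) and run through the inclusion rules that
restrict analyses to active, successful, timely-tagged breeders.
"""

from __future__ import annotations

import logging

import pandas as pd

from boxvisits.territories import TerritoryMap

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = pd.Timedelta(minutes=10)

VISIT_COLUMNS = [
    "individual_id",
    "box_id",
    "start",
    "end",
    "n_readings",
    "day",
]

#: Inclusion rules, applied jointly (a visit may fail several); the order
#: here is only used for stable column output, never for the outcome.
EXCLUSION_RULES = [
    "non_breeder",
    "not_extra_territorial",
    "failed_attempt",
    "missing_dates",
    "outside_window",
    "tagged_late",
]


def collapse_readings(readings: pd.DataFrame, window: pd.Timedelta = DEFAULT_WINDOW) -> pd.DataFrame:
    """Merge readings into visits with the inter-reading gap rule.

    A reading joins the current visit of its (individual, box) stream iff
    its gap to the previous reading is <= ``window``; otherwise it starts a
    new visit.  Identical (individual, box, timestamp) rows are first
    deduplicated; unparseable timestamps are rejected and logged.  The sum
    of ``n_readings`` over the output equals the number of valid readings.
    """
    window = pd.Timedelta(window)
    if window <= pd.Timedelta(0):
        raise ValueError("merge window must be positive")
    df = readings.loc[:, ["individual_id", "box_id", "timestamp"]].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce")
    n_bad = int(df["timestamp"].isna().sum())
    if n_bad:
        logger.warning("rejected %d reading(s) with unparseable timestamps", n_bad)
        df = df.dropna(subset=["timestamp"])
    df = df.drop_duplicates(subset=["individual_id", "box_id", "timestamp"])
    if df.empty:
        return pd.DataFrame(columns=VISIT_COLUMNS)

    df = df.sort_values(["individual_id", "box_id", "timestamp"], kind="mergesort")
    same_stream = (
        df["individual_id"].eq(df["individual_id"].shift())
        & df["box_id"].eq(df["box_id"].shift())
    )
    gap = df["timestamp"].diff()
    new_visit = ~(same_stream & (gap <= window))
    visit_id = new_visit.cumsum()

    out = (
        df.groupby(visit_id)
        .agg(
            individual_id=("individual_id", "first"),
            box_id=("box_id", "first"),
            start=("timestamp", "min"),
            end=("timestamp", "max"),
            n_readings=("timestamp", "size"),
        )
        .reset_index(drop=True)
    )
    out["day"] = out["start"].dt.normalize()
    return out.sort_values(["start", "individual_id", "box_id"], kind="mergesort").reset_index(
        drop=True
    )


def _focal_attempts(attempts: pd.DataFrame, year: int) -> pd.DataFrame:
    """Long table: one row per tagged pair member of each attempt of ``year``."""
    att = attempts[attempts["year"] == year]
    rows = []
    for sex_col in ("male_id", "female_id"):
        sub = att.dropna(subset=[sex_col])
        rows.append(
            sub[[sex_col, "attempt_id", "box_id", "fate", "date_nest_start", "date_fledge"]]
            .rename(columns={sex_col: "individual_id"})
        )
    out = pd.concat(rows, ignore_index=True)
    dup = out["individual_id"].duplicated()
    if dup.any():
        # replacement clutches: keep the first attempt per individual (by nest start)
        out = out.sort_values("date_nest_start").drop_duplicates("individual_id")
    return out


def classify_visits(
    visits: pd.DataFrame,
    tm: TerritoryMap,
    attempts: pd.DataFrame,
    individuals: pd.DataFrame,
) -> pd.DataFrame:
    """Attach spatial classification and target occupancy to each visit.

    ``classification`` is ``own_box`` when the visited box is the focal's
    breeding box, ``own_territory`` when it is another box assigned to the
    focal's territory, ``extra_territorial`` otherwise, and ``non_breeder``
    when the focal has no breeding attempt in the map's season (such visits
    are excluded downstream).  ``target_occupied`` flags boxes that are the
    breeding box of an attempt active that season.
    """
    out = visits.copy()
    focal = _focal_attempts(attempts, tm.year).set_index("individual_id")
    occupied_boxes = set(attempts.loc[attempts["year"] == tm.year, "box_id"].astype(str))

    own_box = out["individual_id"].map(focal["box_id"])
    out["attempt_id"] = out["individual_id"].map(focal["attempt_id"])
    box_terr = out["box_id"].astype(str).map(tm.box_assignment)
    own_terr = own_box.astype("string").map(tm.box_assignment)

    cls = pd.Series("extra_territorial", index=out.index, dtype=object)
    cls[box_terr.eq(own_terr).fillna(False)] = "own_territory"
    cls[out["box_id"].astype(str).eq(own_box.astype("string")).fillna(False)] = "own_box"
    cls[own_box.isna()] = "non_breeder"
    out["classification"] = cls
    out["target_occupied"] = out["box_id"].astype(str).isin(occupied_boxes)
    return out


def apply_inclusion_rules(
    visits: pd.DataFrame,
    attempts: pd.DataFrame,
    individuals: pd.DataFrame,
) -> pd.DataFrame:
    """Flag every visit with the inclusion rules it violates.

    Retained visits (empty ``excluded_by``) are extra-territorial visits by
    breeders whose attempt fledged, made between the start of nest building
    and fledging (both inclusive), by birds tagged on or before the start
    of nest building.  Failed breeders contribute no visits at all.  Each
    rule is evaluated independently, so the outcome cannot depend on rule
    order; per-rule counts are stored in ``result.attrs["exclusion_counts"]``.
    """
    out = visits.copy()
    att = attempts.set_index("attempt_id")
    # tag dates are individual-constant, so any season's row will do
    ind = individuals.drop_duplicates("individual_id").set_index("individual_id")

    fate = out["attempt_id"].map(att["fate"])
    nest_start = pd.to_datetime(out["attempt_id"].map(att["date_nest_start"]))
    fledge = pd.to_datetime(out["attempt_id"].map(att["date_fledge"]))
    tag_date = pd.to_datetime(out["individual_id"].map(ind["tag_date"]))
    day = pd.to_datetime(out["day"])

    fails = {
        "non_breeder": out["classification"].eq("non_breeder"),
        "not_extra_territorial": out["classification"].isin(["own_box", "own_territory"]),
        "failed_attempt": fate.ne("fledged") & fate.notna(),
        "missing_dates": fate.eq("fledged") & (nest_start.isna() | fledge.isna()),
        "outside_window": (day < nest_start) | (day > fledge),
        "tagged_late": tag_date.notna() & (tag_date > nest_start),
    }
    excluded_by = pd.Series("", index=out.index, dtype=object)
    counts_all: dict[str, int] = {}
    first_rule = pd.Series("", index=out.index, dtype=object)
    for rule in EXCLUSION_RULES:
        mask = fails[rule].fillna(False)
        counts_all[rule] = int(mask.sum())
        excluded_by = excluded_by.where(~mask, excluded_by + rule + ";")
        first_rule = first_rule.where(~(mask & first_rule.eq("")), rule)
    out["excluded_by"] = excluded_by.str.rstrip(";")
    # partition counts (first failing rule) sum to the number excluded;
    # counts_all counts each rule independently (rules can overlap)
    counts = {r: int(first_rule.eq(r).sum()) for r in EXCLUSION_RULES}
    counts["retained"] = int(out["excluded_by"].eq("").sum())
    out.attrs["exclusion_counts"] = counts
    out.attrs["exclusion_counts_all"] = counts_all
    for rule, n in counts.items():
        logger.info("inclusion rule %s: %d visit(s)", rule, n)
    return out


def retained_visits(visits: pd.DataFrame) -> pd.DataFrame:
    """Subset of visits passing all inclusion rules."""
    if "excluded_by" not in visits.columns:
        raise ValueError("run apply_inclusion_rules first")
    return visits[visits["excluded_by"].eq("")].copy()


def occupied_only_filter(visits: pd.DataFrame) -> pd.DataFrame:
    """Restrict to visits whose target box hosts an active breeding attempt."""
    return visits[visits["target_occupied"]].copy()
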