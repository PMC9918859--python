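"""Synthetic study populations with known ground truth.

Generates everything the pipeline consumes — nest-box layout, breeding
calendars, RFID reading streams, parentage and between-year dispersal —
with the statistical structure the analyses assume, so that every
pipeline summary has a computable expectation:

* boxes sit on a jittered rectangular grid with ~39 m spacing between a
  box and its four nearest neighbors;
* each occupied box hosts a pair; phenology follows the usual blue-tit
  calendar (nest building, one egg per day, ~14 d incubation, ~20 d
  nestling period);
* each breeder-day is a Bernoulli foray trial on the logit scale, with a
  male/female baseline gap, a seasonal trend, a female decline starting
  a few days before egg laying, and a sharp male drop at hatching;
* foray destinations are sampled with exponential distance decay, an
  occupied-box multiplier, and extra attraction of males to boxes whose
  female is in her fertile window;
* reading times follow a bimodal diel mixture (mid-morning and
  pre-sunset peaks over a daylight floor, day length from a sinusoidal
  approximation at ~48 deg N);
* extrapair sires are drawn dyadically with configurable effects of
  "visited" and neighborhood order, with the intercept calibrated by
  bisection so the expected share of broods with extrapair young hits a
  target (about half, as typical for the study system);
* breeding dispersal is generated independently of visit history — the
  built-in null that the dispersal analyses are expected to recover.

All randomness flows from one seed through per-component child
sequences, so a fixed seed reproduces the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from boxvisits.territories import StudyArea, TerritoryMap, build_territories

SECONDS_PER_DAY = 86400


@dataclass
class SimulationConfig:
    """All generator knobs; defaults emulate the study system's regime."""

    seed: int = 1
    n_years: int = 2
    start_year: int = 2015

    # layout
    grid_nx: int = 16
    grid_ny: int = 16
    spacing_m: float = 39.0
    jitter_sd_m: float = 5.0

    # population / calendars
    occupancy_prob: float = 0.55
    adult_fraction: float = 0.5
    nest_start_mean_doy: float = 91.0
    nest_start_sd_days: float = 5.0
    nest_to_egg_lag_mean: float = 14.0
    nest_to_egg_lag_sd: float = 3.0
    clutch_min: int = 7
    clutch_poisson_mean: float = 3.5
    incubation_days: int = 14
    nestling_days: int = 20
    failure_prob: float = 0.10
    tag_late_fraction: float = 0.10

    # foray hazards, logit scale; baselines and individual SD calibrated
    # jointly so that about 11% of breeder-days carry a visit, about 62%
    # of breeders ever visit, and males visit >3x as often as females —
    # the descriptive regime of the emulated system
    male_base_logit: float = -2.30
    female_base_logit: float = -3.25
    foray_individual_sd: float = 2.7
    season_trend_per_day: float = -0.015
    female_decline_onset: float = -3.0
    female_decline_slope: float = -0.25
    male_hatch_drop: float = -2.5

    # destination choice; occupied_weight set so that roughly a third of
    # extra-territorial visits target an active breeding box, the share
    # reported for the emulated system
    distance_decay_m: float = 30.0
    occupied_weight: float = 0.35
    fertility_window: tuple[int, int] = (0, 5)
    fertility_weight: float = 2.5

    # bout structure
    visits_per_day_geom_p: float = 0.5
    readings_per_visit_geom_p: float = 0.5
    within_visit_gap_s: float = 40.0
    own_box_readings_per_day: float = 8.0

    # diel mixture
    morning_weight: float = 0.45
    evening_weight: float = 0.25
    morning_offset_h: float = 3.5
    morning_sd_h: float = 1.5
    evening_offset_h: float = 0.75
    evening_sd_h: float = 0.75
    daylength_amplitude_h: float = 4.4

    # extrapair paternity (dyadic siring model)
    epp_beta_visited: float = 0.65
    epp_beta_order: float = -1.5
    epp_max_order: int = 2
    epp_brood_incidence: float = 0.5

    # dispersal — independent of visit history by construction
    return_prob: float = 0.5
    female_move_prob: float = 0.35
    male_move_prob: float = 0.08
    dispersal_kernel_m: float = 60.0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["fertility_window"] = list(self.fertility_window)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        d = yaml.safe_load(text)
        if "fertility_window" in d:
            d["fertility_window"] = tuple(d["fertility_window"])
        return cls(**d)


@dataclass
class SimulationBundle:
    """Everything one simulation produced, plus its ground truth."""

    config: SimulationConfig
    boxes: pd.DataFrame
    area: StudyArea
    individuals: pd.DataFrame
    attempts: pd.DataFrame
    readings: pd.DataFrame
    parentage: pd.DataFrame
    visit_events: pd.DataFrame  # generator's own record of realized forays
    dispersal_moves: pd.DataFrame
    territory_maps: dict[int, TerritoryMap]
    ground_truth: dict

    def write_csvs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.boxes.rename(columns={"x": "x_m", "y": "y_m"}).to_csv(
            out / "boxes.csv", index=False
        )
        self.individuals.to_csv(out / "individuals.csv", index=False)
        self.attempts.to_csv(out / "attempts.csv", index=False)
        self.readings.to_csv(out / "readings.csv", index=False)
        self.parentage.to_csv(out / "parentage.csv", index=False)
        self.dispersal_moves.to_csv(out / "dispersal_moves.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(self.ground_truth, indent=2))


# ------------------------------------------------------------------ layout


def generate_layout(config: SimulationConfig, rng: np.random.Generator):
    """Jittered rectangular grid of nest-boxes plus the study area."""
    n = config.grid_nx * config.grid_ny
    if n < 4:
        raise ValueError("need at least 4 boxes")
    ii, jj = np.meshgrid(np.arange(config.grid_nx), np.arange(config.grid_ny), indexing="ij")
    x = ii.ravel() * config.spacing_m + rng.normal(0, config.jitter_sd_m, n)
    y = jj.ravel() * config.spacing_m + rng.normal(0, config.jitter_sd_m, n)
    boxes = pd.DataFrame(
        {"box_id": [f"B{k:03d}" for k in range(n)], "x": x, "y": y}
    )
    area = StudyArea.from_boxes(boxes)
    return boxes, area


# ------------------------------------------------- population and calendars


def _phenology(config: SimulationConfig, rng: np.random.Generator, year: int):
    doy = int(round(rng.normal(config.nest_start_mean_doy, config.nest_start_sd_days)))
    nest_start = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=doy - 1)
    lag = max(5, int(round(rng.normal(config.nest_to_egg_lag_mean, config.nest_to_egg_lag_sd))))
    first_egg = nest_start + pd.Timedelta(days=lag)
    clutch = config.clutch_min + rng.poisson(config.clutch_poisson_mean)
    # one egg per day; incubation starts at clutch completion
    hatch = first_egg + pd.Timedelta(days=int(clutch) - 1 + config.incubation_days)
    fledge = hatch + pd.Timedelta(days=config.nestling_days)
    return nest_start, first_egg, int(clutch), hatch, fledge


def generate_population_and_calendars(
    config: SimulationConfig,
    rng: np.random.Generator,
    boxes: pd.DataFrame,
    year: int,
    carryover: pd.DataFrame | None = None,
    id_offset: int = 0,
):
    """Pairs, individual attributes and breeding calendars for one season.

    ``carryover`` rows (returning breeders with their chosen box) claim
    their boxes first; remaining occupancy is filled with new pairs.
    """
    n_boxes = len(boxes)
    target = rng.binomial(n_boxes, config.occupancy_prob)
    claimed: dict[str, dict[str, str]] = {}
    if carryover is not None and len(carryover):
        for row in carryover.itertuples(index=False):
            slot = claimed.setdefault(row.box_id, {})
            if row.sex not in slot:
                slot[row.sex] = row.individual_id

    free = [b for b in boxes["box_id"] if b not in claimed]
    rng.shuffle(free)
    while len(claimed) < target and free:
        claimed[free.pop()] = {}

    inds, atts = [], []
    next_id = id_offset
    known = (
        carryover.set_index("individual_id")
        if carryover is not None and len(carryover)
        else pd.DataFrame()
    )
    for box_id in sorted(claimed):
        nest_start, first_egg, clutch, hatch, fledge = _phenology(config, rng, year)
        pair = {}
        for sex in ("male", "female"):
            if sex in claimed[box_id]:
                iid = claimed[box_id][sex]
                prev = known.loc[iid]
                inds.append(
                    {
                        "individual_id": iid,
                        "sex": sex,
                        "age_class": "adult",
                        "tag_date": prev["tag_date"],
                        "year": year,
                    }
                )
            else:
                iid = f"{'M' if sex == 'male' else 'F'}{next_id:04d}"
                next_id += 1
                age = "adult" if rng.random() < config.adult_fraction else "yearling"
                if rng.random() < config.tag_late_fraction:
                    tag = nest_start + pd.Timedelta(days=int(rng.integers(1, 15)))
                else:
                    tag = nest_start - pd.Timedelta(days=int(rng.integers(30, 180)))
                inds.append(
                    {
                        "individual_id": iid,
                        "sex": sex,
                        "age_class": age,
                        "tag_date": tag,
                        "year": year,
                    }
                )
            pair[sex] = iid
        failed = rng.random() < config.failure_prob
        if failed:
            # failure during incubation or the nestling period
            if rng.random() < 0.5:
                hatch_out, fledge_out = pd.NaT, pd.NaT
            else:
                hatch_out, fledge_out = hatch, pd.NaT
        else:
            hatch_out, fledge_out = hatch, fledge
        atts.append(
            {
                "attempt_id": f"Y{year}_{box_id}",
                "year": year,
                "box_id": box_id,
                "male_id": pair["male"],
                "female_id": pair["female"],
                "date_nest_start": nest_start,
                "date_first_egg": first_egg,
                "clutch_size": clutch,
                "date_hatch": hatch_out,
                "date_fledge": fledge_out,
                "fate": "failed" if failed else "fledged",
                "is_replacement": False,
            }
        )
    return pd.DataFrame(inds), pd.DataFrame(atts), next_id


# ------------------------------------------------------------ diel timing


def day_length_hours(doy: np.ndarray, amplitude: float = 4.4) -> np.ndarray:
    """Sinusoidal day-length approximation (hours) for a mid-latitude site."""
    return 12.0 + amplitude * np.sin(2 * np.pi * (np.asarray(doy, float) - 80.0) / 365.0)


def sun_times(doy: np.ndarray, amplitude: float = 4.4) -> tuple[np.ndarray, np.ndarray]:
    """(sunrise, sunset) in hours of solar time."""
    L = day_length_hours(doy, amplitude)
    return 12.0 - L / 2.0, 12.0 + L / 2.0


def _sample_times_of_day(
    config: SimulationConfig, rng: np.random.Generator, doy: np.ndarray
) -> np.ndarray:
    """Seconds-of-day for visit starts from the bimodal diel mixture."""
    n = len(doy)
    rise, sset = sun_times(doy, config.daylength_amplitude_h)
    u = rng.random(n)
    hours = np.empty(n)
    m_w = config.morning_weight
    e_w = config.evening_weight
    morning = u < m_w
    evening = (u >= m_w) & (u < m_w + e_w)
    flat = ~morning & ~evening
    hours[morning] = rng.normal(rise[morning] + config.morning_offset_h, config.morning_sd_h,
                                morning.sum())
    hours[evening] = rng.normal(sset[evening] - config.evening_offset_h, config.evening_sd_h,
                                evening.sum())
    hours[flat] = rng.uniform(rise[flat] - 0.4, sset[flat] + 0.2, flat.sum())
    return np.clip(hours, 0.0, 23.999) * 3600.0


# ------------------------------------------------------- reading streams


def foray_hazard_logit(
    config: SimulationConfig, sex: str, rel_laying: np.ndarray, rel_hatch: np.ndarray
) -> np.ndarray:
    """Per-day latent foray hazard on the logit scale."""
    rel_laying = np.asarray(rel_laying, float)
    rel_hatch = np.asarray(rel_hatch, float)
    h = np.full_like(rel_laying, config.season_trend_per_day) * rel_laying
    if sex == "female":
        h += config.female_base_logit
        h += config.female_decline_slope * np.maximum(
            0.0, rel_laying - config.female_decline_onset
        )
    else:
        h += config.male_base_logit
        h += np.where(rel_hatch >= 0, config.male_hatch_drop, 0.0)
    return h


def generate_reading_stream(
    config: SimulationConfig,
    rng: np.random.Generator,
    individuals: pd.DataFrame,
    attempts: pd.DataFrame,
    tm: TerritoryMap,
    boxes: pd.DataFrame,
    individual_intercepts: dict[str, float] | None = None,
):
    """RFID readings for one season, plus the realized foray events.

    Returns (readings, visit_events, expected_visit_days) where
    ``visit_events`` is the generator's own record of each realized foray
    (individual, box, day) and ``expected_visit_days`` the analytic sum of
    daily hazards per individual.  ``individual_intercepts`` carries the
    latent per-individual foray intercepts across seasons (consistent
    individual differences); new individuals get a fresh draw.
    """
    coords = boxes.set_index("box_id")[["x", "y"]]
    box_ids = list(boxes["box_id"].astype(str))
    box_xy = coords.loc[box_ids].to_numpy(float)
    n_box = len(box_ids)
    box_index = {b: i for i, b in enumerate(box_ids)}

    att = attempts.set_index("attempt_id")
    occupied = np.zeros(n_box, bool)
    first_egg_doy = np.full(n_box, np.nan)
    for a in attempts.itertuples(index=False):
        i = box_index[str(a.box_id)]
        occupied[i] = True
        first_egg_doy[i] = pd.Timestamp(a.date_first_egg).day_of_year

    terr_of_box = np.array([tm.box_assignment[b] for b in box_ids])

    ind = individuals.set_index("individual_id")
    members = []
    for a in attempts.itertuples(index=False):
        end = a.date_fledge
        if pd.isna(end):
            end = a.date_hatch if pd.notna(a.date_hatch) else a.date_first_egg + pd.Timedelta(
                days=10
            )
        for col, sex in (("male_id", "male"), ("female_id", "female")):
            iid = getattr(a, col)
            if pd.isna(iid):
                continue
            members.append((iid, sex, str(a.box_id), a.attempt_id, a.date_nest_start,
                            a.date_first_egg, a.date_hatch, end))

    rec_ind, rec_box, rec_ts = [], [], []
    events = []
    expected_days: dict[str, float] = {}

    for iid, sex, own_box, attempt_id, nest_start, first_egg, hatch, end in members:
        days = pd.date_range(nest_start, end, freq="D")
        doy = days.day_of_year.to_numpy()
        rel_lay = (days - first_egg).days.to_numpy(float)
        rel_hatch = (
            (days - hatch).days.to_numpy(float) if pd.notna(hatch) else np.full(len(days), -99.0)
        )
        if individual_intercepts is None:
            u_ind = rng.normal(0.0, config.foray_individual_sd)
        elif iid in individual_intercepts:
            u_ind = individual_intercepts[iid]
        else:
            u_ind = individual_intercepts.setdefault(
                iid, rng.normal(0.0, config.foray_individual_sd)
            )
        p = expit(foray_hazard_logit(config, sex, rel_lay, rel_hatch) + u_ind)
        expected_days[iid] = float(p.sum())
        foray = rng.random(len(days)) < p

        own_i = box_index[own_box]
        own_terr = terr_of_box[own_i]
        static_w = np.exp(
            -np.hypot(box_xy[:, 0] - box_xy[own_i, 0], box_xy[:, 1] - box_xy[own_i, 1])
            / config.distance_decay_m
        )
        static_w[own_i] = 0.0
        static_w = static_w * np.where(occupied, config.occupied_weight, 1.0)

        for k in np.flatnonzero(foray):
            w = static_w.copy()
            if sex == "male":
                rel_host = doy[k] - first_egg_doy
                lo, hi = config.fertility_window
                fert = occupied & (rel_host >= lo) & (rel_host <= hi)
                w[fert] *= config.fertility_weight
            w_sum = w.sum()
            if w_sum <= 0:
                continue
            n_visits = int(rng.geometric(config.visits_per_day_geom_p))
            dest = rng.choice(n_box, size=n_visits, p=w / w_sum)
            starts = _sample_times_of_day(config, rng, np.full(n_visits, doy[k]))
            for v in range(n_visits):
                bi = int(dest[v])
                n_read = int(rng.geometric(config.readings_per_visit_geom_p))
                gaps = rng.exponential(config.within_visit_gap_s, n_read - 1) if n_read > 1 else []
                secs = starts[v] + np.concatenate([[0.0], np.cumsum(gaps)])
                secs = np.clip(secs, 0, SECONDS_PER_DAY - 1)
                for s in secs:
                    rec_ind.append(iid)
                    rec_box.append(box_ids[bi])
                    rec_ts.append(days[k] + pd.Timedelta(seconds=round(float(s))))
                events.append(
                    {
                        "individual_id": iid,
                        "sex": sex,
                        "box_id": box_ids[bi],
                        "territory_id": terr_of_box[bi],
                        "day": days[k],
                        "extra_territorial": terr_of_box[bi] != own_terr,
                    }
                )

        # own-box reading traffic (realism noise; excluded by classification)
        n_per_day = rng.poisson(config.own_box_readings_per_day, len(days))
        tot = int(n_per_day.sum())
        if tot:
            day_idx = np.repeat(np.arange(len(days)), n_per_day)
            secs = _sample_times_of_day(config, rng, doy[day_idx])
            ts = days.values[day_idx] + np.round(secs).astype("timedelta64[s]")
            rec_ind.extend([iid] * tot)
            rec_box.extend([own_box] * tot)
            rec_ts.extend(ts)

    readings = pd.DataFrame(
        {"individual_id": rec_ind, "box_id": rec_box,
         "timestamp": pd.to_datetime(rec_ts)}
    ).sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    visit_events = pd.DataFrame(
        events,
        columns=["individual_id", "sex", "box_id", "territory_id", "day", "extra_territorial"],
    )
    return readings, visit_events, expected_days


# ------------------------------------------------------------- parentage


def _epp_candidate_table(
    config: SimulationConfig,
    attempts: pd.DataFrame,
    tm: TerritoryMap,
    visit_events: pd.DataFrame,
) -> pd.DataFrame:
    """One row per (brood, candidate sire) with covariates for the siring model.

    ``visited`` records whether either member of the dyad visited the
    other's territory; the two directions also enter separately so that
    both the male-focal and female-focal analyses estimate the configured
    dyadic effect.
    """
    ev = visit_events[visit_events["extra_territorial"]]
    visited_pairs = set(zip(ev["individual_id"], ev["territory_id"]))

    males = attempts.dropna(subset=["male_id"])[["male_id", "box_id"]].copy()
    males["territory_id"] = males["box_id"].astype(str).map(tm.box_assignment)
    rows = []
    for brood in attempts[attempts["fate"] == "fledged"].itertuples(index=False):
        if pd.isna(brood.female_id):
            continue
        b_tid = tm.box_assignment[str(brood.box_id)]
        orders = tm.orders_from(b_tid)
        for cand in males.itertuples(index=False):
            if cand.male_id == brood.male_id:
                continue
            order = orders.get(cand.territory_id)
            if order is None or order < 1 or order > config.epp_max_order:
                continue
            vis_m = (cand.male_id, b_tid) in visited_pairs
            vis_f = (brood.female_id, cand.territory_id) in visited_pairs
            rows.append(
                {
                    "attempt_id": brood.attempt_id,
                    "female_id": brood.female_id,
                    "male_id": cand.male_id,
                    "neighbor_order": order,
                    "visited_m": vis_m,
                    "visited_f": vis_f,
                    "visited": vis_m or vis_f,
                    "clutch_size": brood.clutch_size,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["attempt_id", "female_id", "male_id", "neighbor_order",
                 "visited_m", "visited_f", "visited", "clutch_size"],
    )


def _dyad_success_prob(config: SimulationConfig, cands: pd.DataFrame, c: float) -> np.ndarray:
    return expit(
        c
        + config.epp_beta_visited * cands["visited_m"].to_numpy(float)
        + config.epp_beta_visited * cands["visited_f"].to_numpy(float)
        + config.epp_beta_order * cands["neighbor_order"].to_numpy(float)
    )


def calibrate_epp_intercept(
    config: SimulationConfig, cands: pd.DataFrame, tol: float = 1e-6
) -> float:
    """Bisection on the intercept so the expected share of broods with at
    least one extrapair offspring matches the configured target.

    The dyadic outcome (candidate sires >=1 young in the brood) is itself
    Bernoulli on the configured logit, so the brood-level no-extrapair
    probability is the product of the dyads' complements."""
    if len(cands) == 0:
        raise ValueError("no candidate sires: cannot calibrate")

    def incidence(c: float) -> float:
        p = _dyad_success_prob(config, cands, c)
        no_claim = pd.Series(np.log1p(-p), index=cands["attempt_id"]).groupby(level=0).sum()
        return float(np.mean(1.0 - np.exp(no_claim.to_numpy())))

    lo, hi = -12.0, 4.0
    target = config.epp_brood_incidence
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if incidence(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def generate_parentage(
    config: SimulationConfig,
    rng: np.random.Generator,
    attempts: pd.DataFrame,
    tm: TerritoryMap,
    visit_events: pd.DataFrame,
):
    """Offspring-level parentage with dyadic, visit-linked extrapair siring.

    Each (brood, candidate-sire) dyad independently succeeds with the
    configured dyadic logit, so the dyad-level "shared extrapair young"
    outcome follows exactly the logistic model the analyses fit; winning
    sires are then allocated one or a few offspring within the clutch, the
    remainder staying within-pair.
    """
    cands = _epp_candidate_table(config, attempts, tm, visit_events)
    intercept = calibrate_epp_intercept(config, cands) if len(cands) else 0.0
    if len(cands):
        cands = cands.assign(p=_dyad_success_prob(config, cands, intercept))
        by_brood = dict(tuple(cands.groupby("attempt_id")))
    else:
        by_brood = {}

    rows = []
    for brood in attempts[attempts["fate"] == "fledged"].itertuples(index=False):
        c = by_brood.get(brood.attempt_id)
        clutch = int(brood.clutch_size)
        sires = [brood.male_id] * clutch
        if c is not None and len(c):
            winners = c["male_id"].to_numpy()[rng.random(len(c)) < c["p"].to_numpy()]
            rng.shuffle(winners)
            slot = 0
            for w in winners:
                if slot >= clutch:
                    break  # clutch exhausted; in practice winners are few
                n_young = 1 + rng.poisson(0.5)
                for _ in range(min(n_young, clutch - slot)):
                    sires[slot] = w
                    slot += 1
        for j in range(clutch):
            rows.append(
                {
                    "offspring_id": f"{brood.attempt_id}_chick{j:02d}",
                    "attempt_id": brood.attempt_id,
                    "genetic_mother_id": brood.female_id,
                    "genetic_sire_id": sires[j],
                    "is_extrapair": sires[j] != brood.male_id,
                }
            )
    parentage = pd.DataFrame(
        rows,
        columns=["offspring_id", "attempt_id", "genetic_mother_id", "genetic_sire_id",
                 "is_extrapair"],
    )
    truth = {
        "epp_intercept": intercept,
        "epp_beta_visited": config.epp_beta_visited,
        "epp_beta_order": config.epp_beta_order,
        "n_candidate_dyads": int(len(cands)),
    }
    return parentage, truth


# -------------------------------------------------------------- dispersal


def generate_dispersal(
    config: SimulationConfig,
    rng: np.random.Generator,
    attempts: pd.DataFrame,
    individuals: pd.DataFrame,
    boxes: pd.DataFrame,
):
    """Survivors' box choices for the next season (visit-independent).

    Returns a carryover frame (individual_id, sex, tag_date, box_id of the
    chosen next-season box) plus a truth record of movers.
    """
    coords = boxes.set_index("box_id")[["x", "y"]]
    box_ids = list(boxes["box_id"].astype(str))
    box_xy = coords.loc[box_ids].to_numpy(float)
    ind = individuals.set_index("individual_id")

    members = []
    for a in attempts.itertuples(index=False):
        for col, sex in (("male_id", "male"), ("female_id", "female")):
            iid = getattr(a, col)
            if pd.notna(iid):
                members.append((iid, sex, str(a.box_id)))

    taken: set[str] = set()
    carry, moves = [], []
    for iid, sex, box in members:
        if rng.random() >= config.return_prob:
            continue
        move_p = config.female_move_prob if sex == "female" else config.male_move_prob
        moved = rng.random() < move_p
        if moved:
            i0 = box_ids.index(box)
            d = np.hypot(box_xy[:, 0] - box_xy[i0, 0], box_xy[:, 1] - box_xy[i0, 1])
            w = np.exp(-d / config.dispersal_kernel_m)
            w[i0] = 0.0
            for b in taken:
                w[box_ids.index(b)] = 0.0
            if w.sum() <= 0:
                new_box = box
                moved = False
            else:
                new_box = box_ids[int(rng.choice(len(box_ids), p=w / w.sum()))]
        else:
            new_box = box
        carry.append(
            {
                "individual_id": iid,
                "sex": sex,
                "tag_date": ind.loc[iid, "tag_date"],
                "box_id": new_box,
            }
        )
        if moved:
            taken.add(new_box)
            moves.append(
                {"individual_id": iid, "sex": sex, "from_box": box, "to_box": new_box}
            )
    return (
        pd.DataFrame(carry, columns=["individual_id", "sex", "tag_date", "box_id"]),
        pd.DataFrame(moves, columns=["individual_id", "sex", "from_box", "to_box"]),
    )


# ------------------------------------------------------------ orchestration


def simulate(config: SimulationConfig) -> SimulationBundle:
    """Run the full generator for ``config.n_years`` consecutive seasons."""
    ss = np.random.SeedSequence(config.seed)
    keys = ["layout", "population", "readings", "parentage", "dispersal"]
    child = dict(zip(keys, ss.spawn(len(keys))))
    rngs = {k: np.random.default_rng(s) for k, s in child.items()}

    boxes, area = generate_layout(config, rngs["layout"])

    all_ind, all_att, all_read, all_par, all_ev = [], [], [], [], []
    all_moves = []
    tms: dict[int, TerritoryMap] = {}
    truth: dict = {
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "years": {},
    }
    carryover = None
    id_offset = 0
    intercepts: dict[str, float] = {}
    for y in range(config.n_years):
        year = config.start_year + y
        inds, atts, id_offset = generate_population_and_calendars(
            config, rngs["population"], boxes, year, carryover, id_offset
        )
        tm = build_territories(boxes, atts, area=area, year=year)
        tms[year] = tm
        readings, events, expected_days = generate_reading_stream(
            config, rngs["readings"], inds, atts, tm, boxes, individual_intercepts=intercepts
        )
        parentage, epp_truth = generate_parentage(
            config, rngs["parentage"], atts, tm, events
        )
        events["year"] = year
        truth["years"][str(year)] = {
            "n_pairs": int(len(atts)),
            "expected_visit_days": expected_days,
            **epp_truth,
        }
        all_ind.append(inds)
        all_att.append(atts)
        all_read.append(readings)
        all_par.append(parentage)
        all_ev.append(events)
        if y < config.n_years - 1:
            carryover, moves = generate_dispersal(
                config, rngs["dispersal"], atts, inds, boxes
            )
            moves["year"] = year
            all_moves.append(moves)

    return SimulationBundle(
        config=config,
        boxes=boxes,
        area=area,
        individuals=pd.concat(all_ind, ignore_index=True),
        attempts=pd.concat(all_att, ignore_index=True),
        readings=pd.concat(all_read, ignore_index=True),
        parentage=pd.concat(all_par, ignore_index=True),
        visit_events=pd.concat(all_ev, ignore_index=True),
        dispersal_moves=(
            pd.concat(all_moves, ignore_index=True)
            if all_moves
            else pd.DataFrame(columns=["individual_id", "sex", "from_box", "to_box", "year"])
        ),
        territory_maps=tms,
        ground_truth=truth,
    )
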