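"""End-to-end orchestration: simulate or load, process, analyze, report.

``run_pipeline`` runs every stage on a configuration and writes the full
artifact bundle (dataset CSVs, model fits, summaries, figures and a
manifest with per-rule exclusion counts and model diagnostics) under the
output directory.  Every stage is deterministic given the configuration
and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from boxvisits import datasets as ds
from boxvisits import models as md
from boxvisits import reporting as rp
from boxvisits.simulate import SimulationBundle, SimulationConfig, simulate
from boxvisits.territories import StudyArea, build_territories
from boxvisits.visits import (
    apply_inclusion_rules,
    classify_visits,
    collapse_readings,
    occupied_only_filter,
    retained_visits,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run-level knobs consolidating the processing constants."""

    out_dir: str = "results/pipeline"
    seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_dir: str | None = None  # read CSV bundle instead of simulating
    merge_window_min: float = 10.0
    occupied_only: bool = False
    date_basis: str = "rel_laying"
    max_order_visits: int = 3
    max_order_epp: int = 2
    max_order_dispersal: int = 3
    dispersal_threshold_m: float = 70.0
    make_figures: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if self.merge_window_min <= 0 or self.dispersal_threshold_m <= 0:
            raise ValueError("thresholds must be positive")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["simulation"]["fertility_window"] = list(self.simulation.fertility_window)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        sim = d.pop("simulation", {})
        if "fertility_window" in sim:
            sim["fertility_window"] = tuple(sim["fertility_window"])
        return cls(simulation=SimulationConfig(**sim), **d)


def load_bundle(input_dir: str | Path) -> SimulationBundle:
    """Read a CSV input bundle (the same layout ``simulate`` writes)."""
    p = Path(input_dir)
    boxes = pd.read_csv(p / "boxes.csv").rename(columns={"x_m": "x", "y_m": "y"})
    individuals = pd.read_csv(p / "individuals.csv", parse_dates=["tag_date"])
    attempts = pd.read_csv(
        p / "attempts.csv",
        parse_dates=["date_nest_start", "date_first_egg", "date_hatch", "date_fledge"],
    )
    readings = pd.read_csv(p / "readings.csv", parse_dates=["timestamp"])
    parentage = pd.read_csv(p / "parentage.csv")
    area = StudyArea.from_boxes(boxes)
    tms = {
        int(y): build_territories(boxes, att, area=area, year=int(y))
        for y, att in attempts.groupby("year")
    }
    return SimulationBundle(
        config=SimulationConfig(),
        boxes=boxes,
        area=area,
        individuals=individuals,
        attempts=attempts,
        readings=readings,
        parentage=parentage,
        visit_events=pd.DataFrame(),
        dispersal_moves=pd.DataFrame(),
        territory_maps=tms,
        ground_truth={},
    )


def process_visits(bundle: SimulationBundle, config: PipelineConfig) -> dict[int, pd.DataFrame]:
    """Collapse, classify and filter readings season by season."""
    window = pd.Timedelta(minutes=config.merge_window_min)
    out: dict[int, pd.DataFrame] = {}
    for year, tm in sorted(bundle.territory_maps.items()):
        rd = bundle.readings[bundle.readings["timestamp"].dt.year == year]
        v = collapse_readings(rd, window=window)
        v = classify_visits(v, tm, bundle.attempts, bundle.individuals)
        v = apply_inclusion_rules(v, bundle.attempts, bundle.individuals)
        out[year] = v
    return out


def build_all_datasets(
    bundle: SimulationBundle, visits_by_year: dict[int, pd.DataFrame], config: PipelineConfig
) -> dict[str, pd.DataFrame]:
    """Assemble the analysis tables over all seasons."""
    idt, pdt, tvd, brd, epd = [], [], [], [], []
    disp, dd = [], []
    years = sorted(bundle.territory_maps)
    for year in years:
        tm = bundle.territory_maps[year]
        ret = retained_visits(visits_by_year[year])
        if config.occupied_only:
            ret = occupied_only_filter(ret)
        idt.append(ds.build_individual_day_table(ret, bundle.attempts, bundle.individuals, year))
        pdt.append(
            ds.build_pair_day_table(ret, bundle.attempts, bundle.individuals, tm,
                                    territory_wide=not config.occupied_only)
        )
        tvd.append(
            ds.build_territory_visit_dyads(
                ret, tm, bundle.attempts, bundle.individuals, bundle.boxes,
                max_order=config.max_order_visits, occupied_only=config.occupied_only,
            )
        )
        if len(bundle.parentage):
            par = bundle.parentage[
                bundle.parentage["attempt_id"].isin(
                    bundle.attempts.loc[bundle.attempts["year"] == year, "attempt_id"]
                )
            ]
            brd.append(
                ds.build_breeder_epp_table(par, bundle.attempts, bundle.individuals, ret, year)
            )
            epd.append(
                ds.build_epp_dyads(
                    par, tm, bundle.attempts, bundle.individuals, ret, bundle.boxes,
                    max_order=config.max_order_epp, occupied_only=config.occupied_only,
                )
            )
    for year in years[:-1]:
        tm = bundle.territory_maps[year]
        att_x = bundle.attempts[bundle.attempts["year"] == year]
        att_x1 = bundle.attempts[bundle.attempts["year"] == year + 1]
        if len(att_x1) == 0:
            continue
        rec = ds.build_dispersal_records(
            att_x, att_x1, tm, bundle.individuals, bundle.boxes,
            threshold_m=config.dispersal_threshold_m,
        )
        ret = retained_visits(visits_by_year[year])
        if config.occupied_only:
            ret = occupied_only_filter(ret)
        rec = md.attach_visit_covariates(rec, ret)
        disp.append(rec)
        dd.append(
            ds.build_dispersal_dyads(rec, tm, ret, max_order=config.max_order_dispersal)
        )

    def cat(frames):
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    return {
        "individual_days": cat(idt),
        "pair_days": cat(pdt),
        "territory_dyads": cat(tvd),
        "breeders": cat(brd),
        "epp_dyads": cat(epd),
        "dispersal": cat(disp),
        "dispersal_dyads": cat(dd),
    }


def fit_all_models(tables: dict[str, pd.DataFrame], config: PipelineConfig) -> dict[str, md.GlmmFit]:
    """Fit the full model battery; stage names label any failure."""
    fits: dict[str, md.GlmmFit] = {}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"model stage '{name}' failed: {e}") from e

    fits["foray"] = stage("foray", md.run_table1_model, tables["individual_days"],
                          config.date_basis)
    for sex, f in stage("received", md.run_received_models, tables["pair_days"],
                        config.date_basis).items():
        fits[f"received_from_{sex}"] = f
    for sex in ("male", "female"):
        fits[f"territory_visits_{sex}"] = stage(
            f"territory_visits_{sex}", md.run_table2_model, tables["territory_dyads"], sex
        )
    if len(tables.get("breeders", ())) and len(tables.get("epp_dyads", ())):
        fits.update(stage("epp", md.run_epp_models, tables["breeders"], tables["epp_dyads"]))
    if len(tables.get("dispersal", ())):
        fits.update(
            stage("dispersal", md.run_dispersal_models, tables["dispersal"],
                  tables["dispersal_dyads"])
        )
    return fits


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate (or load), process, analyze and export; returns the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)

    if config.input_dir:
        bundle = load_bundle(config.input_dir)
    else:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        bundle = simulate(sim_cfg)
        bundle.write_csvs(out / "inputs")

    visits_by_year = process_visits(bundle, config)
    all_visits = pd.concat(
        [v.assign(year=y) for y, v in visits_by_year.items()], ignore_index=True
    )
    all_visits.to_csv(out / "visits.csv", index=False)

    tables = build_all_datasets(bundle, visits_by_year, config)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)

    fits = fit_all_models(tables, config)
    diagnostics = {}
    for name, fit in fits.items():
        md.save_fit(fit, out / "models" / f"{name}.csv")
        diagnostics[name] = {
            "converged": fit.converged,
            "separation": fit.separation,
            "n_obs": fit.n_obs,
            "re_variance": fit.re_variance,
        }

    # descriptive summaries for the latest season with data
    year = max(bundle.territory_maps)
    ret = retained_visits(visits_by_year[year])
    summary = rp.summarize_visit_distributions(
        ret, bundle.attempts, bundle.individuals, bundle.territory_maps[year]
    )
    tod = rp.summarize_time_of_day(ret)
    for key in ("visits_per_box_day", "visit_days_per_visitor", "territories_per_visitor"):
        summary[key].to_csv(out / f"summary_{key}.csv", index=False)
    tod["histogram"].to_csv(out / "summary_time_of_day.csv", index=False)

    if config.make_figures:
        rp.fig_visit_distributions(summary, out / "figures" / "visit_distributions.png")
        rp.fig_time_of_day(tod, out / "figures" / "time_of_day.png")
        if len(tables["territory_dyads"]):
            rp.fig_order_distance(tables["territory_dyads"],
                                  out / "figures" / "order_distance.png")
        if len(tables.get("epp_dyads", ())):
            rp.fig_epp_contrast(tables["epp_dyads"], out / "figures" / "epp_contrast.png")

    exclusions = {
        int(y): v.attrs.get("exclusion_counts", {}) for y, v in visits_by_year.items()
    }
    manifest = {
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "seed": config.seed,
        "n_raw_visits": {int(y): int(len(v)) for y, v in visits_by_year.items()},
        "exclusion_counts": exclusions,
        "table_rows": {k: int(len(v)) for k, v in tables.items()},
        "model_diagnostics": diagnostics,
        "scalar_summaries": {
            k: summary[k]
            for k in (
                "pct_breeders_with_visit",
                "median_visit_days",
                "pct_breeder_days_with_visit",
                "pct_single_visit_cases",
            )
        },
        "time_of_day_proportions": tod["proportions"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
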