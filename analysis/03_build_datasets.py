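#!/usr/bin/env python
"""Assemble the analysis tables from processed visits.

Builds the breeder-day, pair-day, territory-dyad, extrapair-paternity and
dispersal tables under results/tables/ and prints their sizes, mirroring
the units of analysis of the study's models.
"""

from pathlib import Path

import pandas as pd

from boxvisits import datasets as ds
from boxvisits.models import attach_visit_covariates
from boxvisits.pipeline import load_bundle

OUT = Path("results")


def main() -> None:
    bundle = load_bundle(OUT / "sim")
    visits = pd.read_csv(OUT / "visits.csv", parse_dates=["start", "end", "day"])
    retained = visits[visits["excluded_by"].isna() | visits["excluded_by"].eq("")]
    (OUT / "tables").mkdir(exist_ok=True)

    pieces = {k: [] for k in
              ("individual_days", "pair_days", "territory_dyads", "breeders", "epp_dyads")}
    years = sorted(bundle.territory_maps)
    for y in years:
        tm = bundle.territory_maps[y]
        ret = retained[retained["year"] == y]
        pieces["individual_days"].append(
            ds.build_individual_day_table(ret, bundle.attempts, bundle.individuals, y))
        pieces["pair_days"].append(
            ds.build_pair_day_table(ret, bundle.attempts, bundle.individuals, tm))
        pieces["territory_dyads"].append(
            ds.build_territory_visit_dyads(ret, tm, bundle.attempts, bundle.individuals,
                                           bundle.boxes))
        pieces["breeders"].append(
            ds.build_breeder_epp_table(bundle.parentage, bundle.attempts,
                                       bundle.individuals, ret, y))
        pieces["epp_dyads"].append(
            ds.build_epp_dyads(bundle.parentage, tm, bundle.attempts,
                               bundle.individuals, ret, bundle.boxes))

    tm_x = bundle.territory_maps[years[0]]
    ret_x = retained[retained["year"] == years[0]]
    disp = ds.build_dispersal_records(
        bundle.attempts[bundle.attempts["year"] == years[0]],
        bundle.attempts[bundle.attempts["year"] == years[1]],
        tm_x, bundle.individuals, bundle.boxes)
    disp = attach_visit_covariates(disp, ret_x)
    disp_dyads = ds.build_dispersal_dyads(disp, tm_x, ret_x)

    for name, frames in pieces.items():
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(OUT / "tables" / f"{name}.csv", index=False)
        print(f"{name}: {len(df):,} rows")
    disp.to_csv(OUT / "tables" / "dispersal.csv", index=False)
    disp_dyads.to_csv(OUT / "tables" / "dispersal_dyads.csv", index=False)
    print(f"dispersal: {len(disp):,} returnees, {int(disp['dispersed'].sum())} dispersed; "
          f"{len(disp_dyads):,} destination dyads")


if __name__ == "__main__":
    main()
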