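#!/usr/bin/env python
"""Descriptive summaries and diagnostic figures.

Visit-count distributions, share of breeders that foray, diel timing
relative to sunrise/sunset, daily visit-probability profiles by sex, and
the order/distance decay curves; tables under results/, figures under
results/figures/.
"""

from pathlib import Path

import pandas as pd

from boxvisits import reporting as rp
from boxvisits.models import daily_probability_profile
from boxvisits.pipeline import load_bundle

OUT = Path("results")


def main() -> None:
    bundle = load_bundle(OUT / "sim")
    visits = pd.read_csv(OUT / "visits.csv", parse_dates=["start", "end", "day"])
    retained = visits[visits["excluded_by"].isna() | visits["excluded_by"].eq("")]
    (OUT / "figures").mkdir(exist_ok=True)

    year = min(bundle.territory_maps)
    ret_y = retained[retained["year"] == year]
    s = rp.summarize_visit_distributions(
        ret_y, bundle.attempts, bundle.individuals, bundle.territory_maps[year]
    )
    for key in ("visits_per_box_day", "visit_days_per_visitor", "territories_per_visitor"):
        s[key].to_csv(OUT / f"summary_{key}.csv", index=False)
    print(f"{year}: {s['pct_breeders_with_visit']:.0f}% of {s['n_breeders']} breeders "
          f"made >=1 extra-territorial visit; median {s['median_visit_days']:.0f} "
          f"visit days among visitors; a visit on "
          f"{s['pct_breeder_days_with_visit']:.1f}% of breeder-days")

    tod = rp.summarize_time_of_day(retained)
    tod["histogram"].to_csv(OUT / "summary_time_of_day.csv", index=False)
    p = tod["proportions"]
    print(f"diel timing: {100 * p['daylight']:.1f}% of visits in daylight, "
          f"{100 * p['before_sunrise']:.1f}% before sunrise, "
          f"{100 * p['after_sunset']:.1f}% after sunset")

    idt = pd.read_csv(OUT / "tables" / "individual_days.csv")
    profiles = {
        sex: daily_probability_profile(idt[idt["sex"] == sex], "made_visit")
        for sex in ("male", "female")
    }
    for sex, prof in profiles.items():
        prof.to_csv(OUT / f"daily_profile_{sex}.csv", index=False)

    rp.fig_visit_distributions(s, OUT / "figures" / "visit_distributions.png")
    rp.fig_daily_profile(profiles, OUT / "figures" / "daily_profiles.png",
                         xlabel="days relative to first egg")
    rp.fig_time_of_day(tod, OUT / "figures" / "time_of_day.png")
    dyads = pd.read_csv(OUT / "tables" / "territory_dyads.csv")
    rp.fig_order_distance(dyads, OUT / "figures" / "order_distance.png")
    epp = pd.read_csv(OUT / "tables" / "epp_dyads.csv")
    rp.fig_epp_contrast(epp, OUT / "figures" / "epp_contrast.png")
    print(f"figures -> {OUT}/figures/")


if __name__ == "__main__":
    main()
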