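#!/usr/bin/env python
"""Fit the study's binomial mixed models on the assembled tables.

Writes one CSV per fit (term, estimate, SE, z, p) plus a diagnostics JSON
under results/models/ and prints a compact summary with the directions
that matter: the sex gap and seasonal decline in foraying, the
order/distance decay of territory visits, the dyadic visit effect on
extrapair paternity, and the (null) visit effect on dispersal.
"""

import json
from pathlib import Path

import pandas as pd

from boxvisits.models import (
    run_dispersal_models,
    run_epp_models,
    run_received_models,
    run_table1_model,
    run_table2_model,
    save_fit,
)

OUT = Path("results")


def main() -> None:
    t = {
        name: pd.read_csv(OUT / "tables" / f"{name}.csv")
        for name in ("individual_days", "pair_days", "territory_dyads", "breeders",
                     "epp_dyads", "dispersal", "dispersal_dyads")
    }
    (OUT / "models").mkdir(exist_ok=True)

    fits = {"foray": run_table1_model(t["individual_days"])}
    fits.update(
        {f"received_from_{s}": f for s, f in run_received_models(t["pair_days"]).items()}
    )
    for sex in ("male", "female"):
        fits[f"territory_visits_{sex}"] = run_table2_model(t["territory_dyads"], sex)
    fits.update(run_epp_models(t["breeders"], t["epp_dyads"]))
    fits.update(run_dispersal_models(t["dispersal"], t["dispersal_dyads"]))

    diag = {}
    for name, fit in fits.items():
        save_fit(fit, OUT / "models" / f"{name}.csv")
        diag[name] = {"converged": fit.converged, "separation": fit.separation,
                      "n_obs": fit.n_obs, "re_variance": fit.re_variance}
    (OUT / "models" / "diagnostics.json").write_text(json.dumps(diag, indent=2))

    f = fits["foray"]
    print("foray model: female effect %.2f (z=%.1f), seasonal decline z=%.1f"
          % (f.coef("sex[female]"), f.zvalue("sex[female]"), f.zvalue("rel_laying")))
    m = fits["territory_visits_male"]
    print("territory visits (males): distance z=%.1f, order z=%.1f"
          % (m.zvalue("distance"), m.zvalue("neighbor_order")))
    for sex in ("male", "female"):
        d = fits[f"dyadic_epp_{sex}"]
        print("dyadic EPP (%s): visited %.2f (p=%.3f), order %.2f (p=%.1e)"
              % (sex, d.coef("visited"), d.pvalue("visited"),
                 d.coef("neighbor_order"), d.pvalue("neighbor_order")))
    for sex in ("male", "female"):
        key = f"dispersed_{sex}"
        if key in fits:
            d = fits[key]
            note = " [separation]" if d.separation else ""
            print("dispersal (%s): visited %.2f (p=%.2f)%s"
                  % (sex, d.coef("visited_any"), d.pvalue("visited_any"), note))
    print(f"wrote {len(fits)} fits -> {OUT}/models/")


if __name__ == "__main__":
    main()
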