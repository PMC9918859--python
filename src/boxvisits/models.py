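"""The study's binomial mixed models, as ready-to-run wrappers.

Each wrapper pins one analysis:

* foray model — daily probability that a breeder makes at least one
  extra-territorial visit, with sex, age, an orthonormal quadratic in
  relative date, and sex x date / sex x age interactions;
* received-visit models — daily probability that a pair receives a
  visit, separately by visitor sex;
* territory-visit models — probability of visiting a particular box,
  against neighborhood order and distance (quadratics, per sex);
* extrapair-paternity models — any-extrapair-offspring per breeder, and
  dyadic sharing against "visited" and neighborhood order (per sex);
* dispersal models — dispersed yes/no against "visited", and dyadic
  destination choice against "visited" and neighborhood order (per sex).

Sex enters dummy-coded with ``male`` as reference and age with
``yearling`` as reference (matching the reported tables); date and the
order/distance covariates use unit-norm orthonormal polynomial bases
computed on the observed values, which is why quadratic-term estimates
live on a very different scale from raw-unit linear terms.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from boxvisits.glmm import GlmmFit, ModelSpec, fit_binomial_glmm

logger = logging.getLogger(__name__)


def _reference_coding(df: pd.DataFrame) -> pd.DataFrame:
    """Male and yearling as reference levels, as in the reported tables."""
    out = df.copy()
    if "sex" in out.columns:
        out["sex"] = pd.Categorical(out["sex"], categories=["male", "female"])
    if "age_class" in out.columns:
        out["age_class"] = pd.Categorical(out["age_class"], categories=["yearling", "adult"])
    return out


def run_table1_model(
    individual_days: pd.DataFrame,
    date_basis: str = "rel_laying",
    use_n_days: bool = False,
) -> GlmmFit:
    """Foray GLMM: made_visit ~ sex + age + date + date^2 + sex:date + sex:age."""
    if date_basis not in ("rel_laying", "rel_hatch"):
        raise ValueError("date_basis must be 'rel_laying' or 'rel_hatch'")
    df = _reference_coding(individual_days)
    df["made_visit"] = df["made_visit"].astype(int)
    spec = ModelSpec(
        response="made_visit",
        fixed_terms=(
            "sex",
            "age_class",
            f"poly({date_basis},2)",
            f"sex:poly({date_basis},1)",
            "sex:age_class",
        ),
        random_intercepts=("individual_id", "year"),
    )
    return fit_binomial_glmm(df, spec)


def run_received_models(
    pair_days: pd.DataFrame, date_basis: str = "rel_laying"
) -> dict[str, GlmmFit]:
    """Received-visit GLMMs, one per visitor sex (pair and year intercepts)."""
    fits = {}
    for sex in ("male", "female"):
        df = pair_days.copy()
        resp = f"received_from_{sex}"
        df[resp] = df[resp].astype(int)
        spec = ModelSpec(
            response=resp,
            fixed_terms=(f"poly({date_basis},2)",),
            random_intercepts=("attempt_id", "year"),
        )
        fits[sex] = fit_binomial_glmm(df, spec)
    return fits


def run_table2_model(territory_dyads: pd.DataFrame, sex: str) -> GlmmFit:
    """Territory-visit GLMM per sex: visited ~ order + order^2 + dist + dist^2."""
    df = territory_dyads[territory_dyads["sex"] == sex].copy()
    df["visited"] = df["visited"].astype(int)
    spec = ModelSpec(
        response="visited",
        fixed_terms=("poly(neighbor_order,2)", "poly(distance,2)"),
        random_intercepts=("focal_id", "year"),
    )
    return fit_binomial_glmm(df, spec)


def run_epp_models(
    breeders: pd.DataFrame,
    epp_dyads: pd.DataFrame,
    use_n_days: bool = False,
) -> dict[str, GlmmFit]:
    """Extrapair-paternity GLMMs: individual-level any-EPO models and
    dyadic shared-EPO models, one of each per sex.

    ``use_n_days`` swaps the binary "visited" covariate for the number of
    visit days (the sensitivity variant).
    """
    visit_term = "n_visit_days" if use_n_days else ("visited_any", "visited")
    fits: dict[str, GlmmFit] = {}
    for sex in ("male", "female"):
        ind = _reference_coding(breeders[breeders["sex"] == sex])
        if ind["any_epo"].sum() == 0:
            raise ValueError(f"no {sex} breeders with extrapair offspring: empty focal set")
        ind["any_epo"] = ind["any_epo"].astype(int)
        term = "n_visit_days" if use_n_days else "visited_any"
        ind[term] = ind[term].astype(float)
        fits[f"any_epo_{sex}"] = fit_binomial_glmm(
            ind,
            ModelSpec(
                response="any_epo",
                fixed_terms=(term, "age_class"),
                random_intercepts=("individual_id", "year"),
            ),
        )
        dy = epp_dyads[epp_dyads["sex"] == sex].copy()
        if len(dy) == 0:
            raise ValueError(f"no {sex} extrapair dyads: empty focal set")
        dy["outcome"] = dy["outcome"].astype(int)
        dterm = "n_visit_days" if use_n_days else "visited"
        dy[dterm] = dy[dterm].astype(float)
        fits[f"dyadic_epp_{sex}"] = fit_binomial_glmm(
            dy,
            ModelSpec(
                response="outcome",
                fixed_terms=(dterm, "neighbor_order"),
                random_intercepts=("focal_id", "year"),
            ),
        )
    return fits


def run_dispersal_models(
    dispersal: pd.DataFrame,
    dispersal_dyads: pd.DataFrame,
    use_n_days: bool = False,
) -> dict[str, GlmmFit]:
    """Dispersal GLMMs: dispersed yes/no per sex, and dyadic destination
    choice per sex.  ``dispersal`` must carry the visit covariates
    (``visited_any`` / ``n_visit_days`` from the year-x visit data)."""
    fits: dict[str, GlmmFit] = {}
    term = "n_visit_days" if use_n_days else "visited_any"
    dterm = "n_visit_days" if use_n_days else "visited"
    def try_fit(name, df, spec):
        try:
            fits[name] = fit_binomial_glmm(df, spec)
        except ValueError as e:
            # tiny disperser samples can leave a covariate constant; the
            # study-scale male models sit at exactly this edge
            logger.warning("skipping %s: %s", name, e)

    for sex in ("male", "female"):
        ind = dispersal[dispersal["sex"] == sex].copy()
        if len(ind):
            ind["dispersed"] = ind["dispersed"].astype(int)
            ind[term] = ind[term].astype(float)
            try_fit(
                f"dispersed_{sex}",
                ind,
                ModelSpec(
                    response="dispersed",
                    fixed_terms=(term,),
                    random_intercepts=("individual_id", "year"),
                ),
            )
        dy = (
            dispersal_dyads[dispersal_dyads["sex"] == sex].copy()
            if len(dispersal_dyads)
            else pd.DataFrame()
        )
        if len(dy):
            dy["outcome"] = dy["outcome"].astype(int)
            dy[dterm] = dy[dterm].astype(float)
            try_fit(
                f"destination_{sex}",
                dy,
                ModelSpec(
                    response="outcome",
                    fixed_terms=(dterm, "neighbor_order"),
                    random_intercepts=("focal_id", "year"),
                ),
            )
    return fits


def attach_visit_covariates(table: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Add ``visited_any`` / ``n_visit_days`` per individual from retained visits."""
    out = table.copy()
    per_ind = (
        visits.groupby("individual_id")["day"].nunique() if len(visits) else pd.Series(dtype=int)
    )
    out["n_visit_days"] = out["individual_id"].map(per_ind).fillna(0).astype(int)
    out["visited_any"] = out["n_visit_days"] > 0
    return out


def daily_probability_profile(
    table: pd.DataFrame,
    response: str,
    day_col: str = "rel_laying",
    random_intercepts: tuple[str, ...] = ("individual_id", "year"),
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-day predicted visit probability with Wald CI.

    Date enters as a factor so each day gets its own logit-scale estimate
    (one saturated level per day); estimates are back-transformed to the
    probability scale.  Days on which the response never (or always)
    occurred have no finite logit estimate and are dropped with a warning.
    """
    df = table.copy()
    df["_resp"] = df[response].astype(int)
    rate = df.groupby(day_col)["_resp"].mean()
    degenerate = rate[(rate == 0) | (rate == 1)].index
    if len(degenerate):
        logger.warning(
            "dropping %d day level(s) with all-zero or all-one response", len(degenerate)
        )
        df = df[~df[day_col].isin(degenerate)]
    if df.empty:
        return pd.DataFrame(columns=["day", "p", "lo", "hi", "n_obs"])
    # zero-padded labels keep factor levels in numeric day order
    shift = int(df[day_col].min())
    df["_day"] = (df[day_col] - shift).astype(int).map("{:04d}".format)
    spec = ModelSpec(
        response="_resp",
        fixed_terms=("factor(_day)",),
        random_intercepts=random_intercepts,
        intercept=False,
    )
    fit = fit_binomial_glmm(df, spec)
    q = norm.ppf(0.5 + level / 2)
    rows = []
    counts = df.groupby("_day").size()
    for _, r in fit.terms.iterrows():
        lab = r["term"].split("[")[1].rstrip("]")
        rows.append(
            {
                "day": int(lab) + shift,
                "p": expit(r["estimate"]),
                "lo": expit(r["estimate"] - q * r["se"]),
                "hi": expit(r["estimate"] + q * r["se"]),
                "n_obs": int(counts[lab]),
            }
        )
    return pd.DataFrame(rows).sort_values("day").reset_index(drop=True)


# ---------------------------------------------------------------- export


def spec_to_yaml(spec: ModelSpec) -> str:
    return yaml.safe_dump(
        {
            "response": spec.response,
            "fixed_terms": list(spec.fixed_terms),
            "random_intercepts": list(spec.random_intercepts),
            "family": spec.family,
            "data_filter": spec.data_filter,
            "intercept": spec.intercept,
        },
        sort_keys=False,
    )


def spec_from_yaml(text: str) -> ModelSpec:
    d = yaml.safe_load(text)
    return ModelSpec(
        response=d["response"],
        fixed_terms=tuple(d["fixed_terms"]),
        random_intercepts=tuple(d.get("random_intercepts", ())),
        family=d.get("family", "binomial"),
        data_filter=d.get("data_filter"),
        intercept=d.get("intercept", True),
    )


def save_fit(fit: GlmmFit, csv_path: str | Path, diagnostics_path: str | Path | None = None):
    """Write a fit as a table-layout CSV plus a diagnostics JSON."""
    fit.terms.to_csv(csv_path, index=False)
    if diagnostics_path is not None:
        diag = {
            "response": fit.spec.response,
            "fixed_terms": list(fit.spec.fixed_terms),
            "random_intercepts": list(fit.spec.random_intercepts),
            "re_variance": fit.re_variance,
            "converged": fit.converged,
            "separation": fit.separation,
            "n_obs": fit.n_obs,
            "n_groups": fit.n_groups,
            "loglik": fit.loglik,
        }
        Path(diagnostics_path).write_text(json.dumps(diag, indent=2))
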