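"""Descriptive summaries and diagnostic figures.

Summaries mirror the descriptive results of the visit dataset: how many
visits individuals make per box and day, on how many days they foray, how
many different territories they reach, and how visits distribute over the
day relative to sunrise and sunset.
"""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from boxvisits.datasets import eligible_members
from boxvisits.simulate import sun_times
from boxvisits.territories import TerritoryMap

logger = logging.getLogger(__name__)


def summarize_visit_distributions(
    visits: pd.DataFrame,
    attempts: pd.DataFrame,
    individuals: pd.DataFrame,
    tm: TerritoryMap,
) -> dict:
    """Visit-frequency distributions and headline shares for one season.

    Returns a dict with three frequency tables (visits per individual-box-
    day, foray days per visitor, territories visited per visitor) and the
    scalar summaries built on the eligible-breeder denominator.
    """
    members = eligible_members(attempts, individuals, tm.year)
    n_breeders = len(members)
    out: dict = {"year": tm.year, "n_breeders": n_breeders}

    if len(visits) == 0:
        empty = pd.DataFrame(columns=["value", "count"])
        out.update(
            visits_per_box_day=empty,
            visit_days_per_visitor=empty,
            territories_per_visitor=empty,
            pct_breeders_with_visit=0.0,
            median_visit_days=0.0,
            pct_breeder_days_with_visit=0.0,
            pct_single_visit_cases=0.0,
        )
        return out

    per_case = visits.groupby(["individual_id", "box_id", "day"]).size()
    per_ind_days = visits.groupby("individual_id")["day"].nunique()
    terr = visits.assign(
        territory=visits["box_id"].astype(str).map(tm.box_assignment)
    )
    per_ind_terr = terr.groupby("individual_id")["territory"].nunique()

    def freq(s: pd.Series) -> pd.DataFrame:
        c = s.value_counts().sort_index()
        return pd.DataFrame({"value": c.index, "count": c.to_numpy()})

    total_days = int(
        (
            pd.to_datetime(members["date_fledge"]) - pd.to_datetime(members["date_nest_start"])
        ).dt.days.add(1).sum()
    )
    visitors = set(per_ind_days.index) & set(members["individual_id"])
    day_pairs = visits[["individual_id", "day"]].drop_duplicates()

    out.update(
        visits_per_box_day=freq(per_case),
        visit_days_per_visitor=freq(per_ind_days),
        territories_per_visitor=freq(per_ind_terr),
        pct_breeders_with_visit=100.0 * len(visitors) / max(n_breeders, 1),
        median_visit_days=float(per_ind_days.loc[sorted(visitors)].median()) if visitors else 0.0,
        pct_breeder_days_with_visit=100.0 * len(day_pairs) / max(total_days, 1),
        pct_single_visit_cases=100.0 * float((per_case == 1).mean()),
    )
    return out


def summarize_time_of_day(
    visits: pd.DataFrame, daylength_amplitude_h: float | None = 4.4
) -> dict:
    """Hourly histogram of visit starts plus sunrise/sunset proportions.

    Without a day-length model (``daylength_amplitude_h=None``) the
    daylight proportions are omitted with a warning.
    """
    if len(visits) == 0:
        return {
            "histogram": pd.DataFrame(columns=["hour", "count"]),
            "proportions": {},
        }
    start = pd.to_datetime(visits["start"])
    hour = start.dt.hour + start.dt.minute / 60.0 + start.dt.second / 3600.0
    hist = (
        pd.DataFrame({"hour": start.dt.hour})
        .groupby("hour")
        .size()
        .reindex(range(24), fill_value=0)
        .rename("count")
        .reset_index()
    )
    out = {"histogram": hist}
    if daylength_amplitude_h is None:
        logger.warning("no day-length model supplied; daylight proportions omitted")
        out["proportions"] = {}
        return out
    doy = start.dt.day_of_year.to_numpy()
    rise, sset = sun_times(doy, daylength_amplitude_h)
    h = hour.to_numpy()
    before = float(np.mean(h < rise))
    after = float(np.mean(h > sset))
    out["proportions"] = {
        "before_sunrise": before,
        "daylight": 1.0 - before - after,
        "after_sunset": after,
    }
    return out


# ------------------------------------------------------------------ figures


def fig_visit_distributions(summary: dict, path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, key, title in zip(
        axes,
        ["visits_per_box_day", "visit_days_per_visitor", "territories_per_visitor"],
        ["visits per box-day", "foray days per visitor", "territories visited"],
    ):
        d = summary[key]
        if len(d):
            ax.bar(d["value"], d["count"], color="steelblue")
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("n")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def fig_daily_profile(profiles: dict[str, pd.DataFrame], path, xlabel: str = "day") -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    colors = {"male": "tab:blue", "female": "tab:red"}
    for label, prof in profiles.items():
        if len(prof) == 0:
            continue
        ax.errorbar(
            prof["day"], prof["p"],
            yerr=[prof["p"] - prof["lo"], prof["hi"] - prof["p"]],
            fmt="o", ms=3, lw=1, label=label, color=colors.get(label),
        )
    ax.set_xlabel(xlabel)
    ax.set_ylabel("daily visit probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def fig_order_distance(dyads: pd.DataFrame, path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    for sex, color in (("male", "tab:blue"), ("female", "tab:red")):
        d = dyads[dyads["sex"] == sex]
        if len(d) == 0:
            continue
        by_order = d.groupby("neighbor_order")["visited"].mean()
        axes[0].plot(by_order.index, by_order.to_numpy(), "o-", color=color, label=sex)
        bins = pd.cut(d["distance"], bins=np.arange(0, d["distance"].max() + 25, 25))
        by_dist = d.groupby(bins, observed=True)["visited"].mean()
        mid = [iv.mid for iv in by_dist.index]
        axes[1].plot(mid, by_dist.to_numpy(), "o-", color=color, label=sex)
    axes[0].set_xlabel("neighborhood order")
    axes[0].set_ylabel("P(visited)")
    axes[1].set_xlabel("distance (m)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def fig_time_of_day(tod: dict, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    h = tod["histogram"]
    if len(h):
        ax.bar(h["hour"], h["count"], color="darkorange")
    ax.set_xlabel("hour of day")
    ax.set_ylabel("visits")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def fig_epp_contrast(epp_dyads: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    w = 0.35
    for i, sex in enumerate(("male", "female")):
        d = epp_dyads[epp_dyads["sex"] == sex]
        if len(d) == 0:
            continue
        rates = d.groupby("visited")["outcome"].mean()
        xs = np.array([0, 1]) + (i - 0.5) * w
        ax.bar(xs, [rates.get(False, 0), rates.get(True, 0)], width=w, label=sex)
    ax.set_xticks([0, 1], ["not visited", "visited"])
    ax.set_ylabel("P(shared extrapair offspring)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
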