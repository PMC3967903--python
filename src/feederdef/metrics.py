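"""Space-use indices, control variables, and the bird-feeder-day table.

The response modeled downstream is NVC — the number of visits made by
competitors at a feeder on a day, relative to a focal individual.  This
module computes, from the sessionized visit table:

* spatial concentration — the share of a focal's daily visits made at a
  given feeder;
* seasonal spatial concentration — the same share over the individual's
  whole followed period (one field season);
* spatial stability — the Pearson correlation between daily and seasonal
  concentration across (feeder, day) combinations, an index of fidelity
  in grid usage (requires >= 3 followed days);
* grid usage — the mean daily visit total across individuals active that
  day, a day-level control for weather and natural-food availability;
* feeder rank — feeders ranked by how many distinct competitor-sex
  individuals were ever detected there in a season (rank 1 = most);

and assembles the analysis table: one row per (focal, feeder, day) for
adult focals of the focal sex followed on >= 3 distinct days, with NVC
counting visits by *other* adults of the competitor sex, and rows with
no competitor-sex visits (including focal-only feeder-days) excluded —
there is no variation in NVC to model when nobody else shows up.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .simdata import LOW_SUCROSE


class JoinError(ValueError):
    """Visits refer to tags or feeders missing from the metadata."""


# ---------------------------------------------------------------------------
# Visit-count helpers
# ---------------------------------------------------------------------------

def visit_counts(visits: pd.DataFrame) -> pd.DataFrame:
    """Per (tag, date, feeder) visit counts with a ``year`` column."""
    out = (visits.groupby(["tag_id", "date", "feeder_id"])
           .size().rename("n_visits").reset_index())
    out["year"] = pd.to_datetime(out["date"]).dt.year
    return out


def filter_visits(visits: pd.DataFrame, individuals: pd.DataFrame,
                  sex: str | None = None,
                  age_class: str | None = "adult") -> pd.DataFrame:
    """Restrict a visit table to individuals of a given sex/age class."""
    meta = individuals.set_index("tag")
    unknown = set(visits["tag_id"]) - set(meta.index)
    if unknown:
        raise JoinError(f"tags missing from individual metadata: "
                        f"{sorted(unknown)[:10]}")
    keep = pd.Series(True, index=meta.index)
    if sex is not None:
        keep &= meta["sex"] == sex
    if age_class is not None:
        keep &= meta["age_class"] == age_class
    return visits[visits["tag_id"].map(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Space-use indices
# ---------------------------------------------------------------------------

def spatial_concentration(visits: pd.DataFrame) -> pd.DataFrame:
    """Daily spatial concentration for every (tag, date, feeder).

    The ratio of an individual's visits to a feeder on a day to its total
    visits on the grid that day; sums to 1 over feeders within each
    active bird-day.
    """
    counts = visit_counts(visits)
    totals = counts.groupby(["tag_id", "date"])["n_visits"].transform("sum")
    counts["spatial_concentration"] = counts["n_visits"] / totals
    return counts


def seasonal_concentration(visits: pd.DataFrame) -> pd.DataFrame:
    """Seasonal spatial concentration per (tag, year, feeder).

    Same ratio as the daily index but over the individual's entire
    followed period within a season (one calendar year).
    """
    counts = visit_counts(visits)
    agg = (counts.groupby(["tag_id", "year", "feeder_id"])["n_visits"]
           .sum().reset_index())
    totals = agg.groupby(["tag_id", "year"])["n_visits"].transform("sum")
    agg["seasonal_concentration"] = agg["n_visits"] / totals
    return agg.drop(columns="n_visits")


def days_followed(visits: pd.DataFrame) -> pd.Series:
    """Distinct detection days per (tag, year)."""
    counts = visit_counts(visits)
    return counts.groupby(["tag_id", "year"])["date"].nunique()


def spatial_stability(visits: pd.DataFrame) -> pd.DataFrame:
    """Spatial stability per (tag, year).

    Pearson correlation between daily and seasonal concentration, paired
    over every (feeder, day) combination where the feeder is one the
    individual visited at least once that season — days on which it
    skipped a feeder contribute a daily concentration of 0 for it.
    Requires >= 3 followed days; with fewer the individual is not a
    focal.  Individuals whose pairing has zero variance on either side
    (e.g. a single feeder used all season) get ``stability = NaN`` and
    ``defined = False`` and are excluded from modeling.

    Values are reported as computed: the correlation can in principle be
    negative and is not clamped to [0, 1].
    """
    daily = spatial_concentration(visits)
    seas = seasonal_concentration(visits)
    out = []
    for (tag, year), grp in daily.groupby(["tag_id", "year"]):
        days = sorted(grp["date"].unique())
        if len(days) < 3:
            continue
        sub = seas[(seas["tag_id"] == tag) & (seas["year"] == year)]
        feeders = sub["feeder_id"].to_numpy()
        svec = sub["seasonal_concentration"].to_numpy()
        mat = (grp.pivot_table(index="date", columns="feeder_id",
                               values="spatial_concentration", fill_value=0.0)
               .reindex(index=days, columns=feeders, fill_value=0.0))
        x = mat.to_numpy().ravel()                      # daily, by (day, feeder)
        y = np.tile(svec, len(days))                    # seasonal, matched
        if x.std() == 0 or y.std() == 0:
            stab, defined = np.nan, False
        else:
            stab = float(np.corrcoef(x, y)[0, 1])
            defined = True
        out.append({"tag_id": tag, "year": year, "stability": stab,
                    "n_days_followed": len(days), "defined": defined})
    return pd.DataFrame(out, columns=["tag_id", "year", "stability",
                                      "n_days_followed", "defined"])


# ---------------------------------------------------------------------------
# Control variables
# ---------------------------------------------------------------------------

def grid_usage(visits: pd.DataFrame) -> pd.DataFrame:
    """Mean daily visit total across individuals that used the grid.

    One row per date; individuals with zero visits that day are not part
    of the mean (they did not use the grid).
    """
    counts = visit_counts(visits)
    per_bird = counts.groupby(["date", "tag_id"])["n_visits"].sum()
    out = per_bird.groupby("date").mean().rename("grid_usage").reset_index()
    return out


def feeder_rank(visits: pd.DataFrame, feeder_ids,
                individuals: pd.DataFrame | None = None,
                competitor_sex: str | None = None) -> pd.DataFrame:
    """Rank feeders by distinct individuals detected over each season.

    Ascending ranks: the feeder where the most distinct individuals (of
    the competitor sex, adults) were detected at least once gets rank 1;
    ties get the average of the tied ranks; feeders never visited count
    zero individuals and rank last.  Returns one row per (year, feeder).
    """
    v = visits
    if competitor_sex is not None:
        if individuals is None:
            raise ValueError("individual metadata required to restrict "
                             "ranks by sex")
        v = filter_visits(v, individuals, sex=competitor_sex)
    counts = visit_counts(v)
    out = []
    feeder_ids = list(feeder_ids)
    years = sorted(counts["year"].unique())
    for year in years:
        sub = counts[counts["year"] == year]
        n_ind = (sub.groupby("feeder_id")["tag_id"].nunique()
                 .reindex(feeder_ids, fill_value=0))
        ranks = rankdata(-n_ind.to_numpy(), method="average")
        out.append(pd.DataFrame({"year": year, "feeder_id": feeder_ids,
                                 "n_individuals": n_ind.to_numpy(),
                                 "feeder_rank": ranks}))
    if not out:
        return pd.DataFrame(columns=["year", "feeder_id", "n_individuals",
                                     "feeder_rank"])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Treatment join
# ---------------------------------------------------------------------------

def sucrose_for(schedule: pd.DataFrame, dates: pd.Series,
                feeders: pd.Series) -> pd.Series:
    """Sucrose level for each (date, feeder) pair; low outside treatment."""
    sched = schedule.copy()
    sched["week_start"] = pd.to_datetime(sched["week_start"]).dt.date
    sched["week_end"] = pd.to_datetime(sched["week_end"]).dt.date
    lookup: dict[tuple, str] = {}
    for row in sched.itertuples(index=False):
        d = row.week_start
        while d <= row.week_end:
            lookup[(d, row.feeder_id)] = row.sucrose
            d += _dt.timedelta(days=1)
    keys = list(zip(pd.to_datetime(dates).dt.date, feeders))
    return pd.Series([lookup.get(k, LOW_SUCROSE) for k in keys],
                     index=dates.index)


# ---------------------------------------------------------------------------
# Analysis table
# ---------------------------------------------------------------------------

ANALYSIS_COLUMNS = [
    "tag_id", "feeder_id", "date", "year", "nvc", "spatial_concentration",
    "spatial_stability", "daily_visits", "n_competitors", "grid_usage",
    "feeder_rank", "sucrose", "openness", "lateral_visibility_m",
    "focal_sex", "competitor_sex",
]


def assemble_analysis_table(visits: pd.DataFrame, individuals: pd.DataFrame,
                            feeders: pd.DataFrame, schedule: pd.DataFrame,
                            focal_sex: str = "M", competitor_sex: str = "M",
                            min_days: int = 3,
                            ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Build the bird-feeder-day analysis table.

    Every adult of ``focal_sex`` followed on at least ``min_days``
    distinct days in a season is considered in turn as the focal
    (potential defender) at each feeder-day it visited.  For each such
    row, NVC is the total number of visits made that day at that feeder
    by *other* adults of ``competitor_sex`` (all adults count as
    competitors regardless of how long they were followed; juveniles
    never do).  Rows with NVC = 0 — in particular feeder-days where the
    focal was the only individual detected — are excluded: a feeder
    nobody else visits more likely reflects low attractiveness than
    perfect defense, and log(NVC) requires NVC >= 1.  Focals whose
    spatial stability is undefined (zero variance) are also dropped.

    Returns ``(table, dropped)`` where ``dropped`` reconciles row counts
    per exclusion reason.
    """
    meta = individuals.set_index("tag")
    unknown_tags = set(visits["tag_id"]) - set(meta.index)
    if unknown_tags:
        raise JoinError(f"tags missing from individual metadata: "
                        f"{sorted(unknown_tags)[:10]}")
    unknown_feeders = set(visits["feeder_id"]) - set(feeders["feeder_id"])
    if unknown_feeders:
        raise JoinError(f"feeders missing from feeder metadata: "
                        f"{sorted(unknown_feeders)[:10]}")

    adults = filter_visits(visits, individuals, age_class="adult")
    focal_visits = filter_visits(adults, individuals, sex=focal_sex)
    comp_visits = filter_visits(adults, individuals, sex=competitor_sex)

    followed = days_followed(focal_visits)
    stab = spatial_stability(focal_visits).set_index(["tag_id", "year"])
    daily_conc = spatial_concentration(focal_visits)
    gusage = grid_usage(visits).set_index("date")["grid_usage"]
    ranks = feeder_rank(visits, feeders["feeder_id"], individuals,
                        competitor_sex=competitor_sex)
    ranks = ranks.set_index(["year", "feeder_id"])["feeder_rank"]

    comp_counts = visit_counts(comp_visits)

    dropped = {"under_min_days": 0, "undefined_stability": 0,
               "no_competitor_visits": 0}

    rows = daily_conc.copy()  # one candidate row per focal bird-feeder-day
    dropped["candidate_rows"] = len(rows)
    key = list(zip(rows["tag_id"], rows["year"]))
    nd = np.array([followed.get(k, 0) for k in key])
    keep = nd >= min_days
    dropped["under_min_days"] = int((~keep).sum())
    rows = rows[keep]

    key = list(zip(rows["tag_id"], rows["year"]))
    stab_defined = np.array(
        [bool(stab["defined"].get(k, False)) for k in key])
    stab_val = np.array(
        [float(stab["stability"].get(k, np.nan)) for k in key])
    dropped["undefined_stability"] = int((~stab_defined).sum())
    rows = rows[stab_defined]
    rows = rows.assign(spatial_stability=stab_val[stab_defined])

    # Competitor visits and distinct competitors at each feeder-day,
    # excluding the focal itself.
    cc = comp_counts.set_index(["date", "feeder_id", "tag_id"])["n_visits"]
    fd_tot = comp_counts.groupby(["date", "feeder_id"])["n_visits"].sum()
    fd_n = comp_counts.groupby(["date", "feeder_id"])["tag_id"].nunique()

    nvc = []
    ncomp = []
    for r in rows.itertuples(index=False):
        k = (r.date, r.feeder_id)
        own = cc.get((r.date, r.feeder_id, r.tag_id), 0)
        own_present = 1 if own > 0 else 0
        nvc.append(int(fd_tot.get(k, 0) - own))
        ncomp.append(int(fd_n.get(k, 0) - own_present))
    rows = rows.assign(nvc=nvc, n_competitors=ncomp)
    keep = rows["nvc"] >= 1
    dropped["no_competitor_visits"] = int((~keep).sum())
    rows = rows[keep]

    daily_tot = (focal_visits.groupby(["tag_id", "date"]).size()
                 .rename("daily_visits"))
    rows = rows.join(daily_tot, on=["tag_id", "date"])
    rows["grid_usage"] = rows["date"].map(gusage)
    rows["feeder_rank"] = [
        ranks.get((y, f), np.nan)
        for y, f in zip(rows["year"], rows["feeder_id"])]
    rows["sucrose"] = sucrose_for(schedule, rows["date"],
                                  rows["feeder_id"]).to_numpy()
    fmeta = feeders.set_index("feeder_id")
    rows["openness"] = rows["feeder_id"].map(fmeta["openness"])
    rows["lateral_visibility_m"] = rows["feeder_id"].map(
        fmeta["lateral_visibility_m"])
    rows["focal_sex"] = focal_sex
    rows["competitor_sex"] = competitor_sex

    table = rows[ANALYSIS_COLUMNS].reset_index(drop=True)
    table["log_nvc"] = np.log(table["nvc"].astype(float))
    return table, dropped
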