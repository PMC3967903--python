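"""Synthetic study system: feeder grid, sucrose treatment, detection streams.

The field system this module emulates is a 44-ha systematic grid of 45
nectar feeders (rows of 12, 12, 7, 7, 7 at 100 m spacing) spanning
hayfield, fallow and forest habitat, each feeder fitted with an RFID
antenna that logs, once per second, every PIT-tagged hummingbird perched
at it.  No field dataset is distributed with the package, so everything
downstream (sessionization, space-use indices, permutation nulls, mixed
models) is exercised on streams generated here from a known ground truth.

Two generators are provided:

* :func:`simulate_detection_stream` — an individual-based simulator that
  produces the raw per-second detection log from per-individual daily
  visit rates, home-feeder fidelity and defense-driven exclusion of
  competitors.
* :func:`simulate_nvc_table` — the generative twin of the analysis-stage
  linear mixed model: it draws log competitor-visit counts directly from
  the fitted model's form (fixed effects + feeder intercept + correlated
  individual intercept and concentration slope + residual) so that the
  inference machinery can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Sequence

import numpy as np
import pandas as pd

HABITATS = ("hayfield", "fallow", "forest")

#: Row lengths of the systematic grid, north to south.
GRID_ROWS = (12, 12, 7, 7, 7)
GRID_SPACING_M = 100.0

#: Field-season bounds (month, day) used for schedules and tenures.
SEASON_START = (5, 20)
SEASON_END = (8, 30)
#: Sucrose manipulation window in the treatment year: 9 weeks from 10 June.
TREATMENT_START = (6, 10)
TREATMENT_YEAR = 2009
STUDY_YEARS = (2007, 2008, 2009)

LOW_SUCROSE = "low"
HIGH_SUCROSE = "high"


class InvalidConfigError(ValueError):
    """Raised when simulator parameters are outside their valid domain."""


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

def make_grid(seed: int = 0,
              visibility_ranges: dict[str, tuple[float, float]] | None = None,
              ) -> pd.DataFrame:
    """Build the 45-feeder study grid.

    Feeders are laid out in rows of 12, 12, 7, 7, 7 spaced 100 m apart.
    Habitat follows the field gradient: the first row crosses hayfield
    (8 feeders) into fallow, the second finishes the fallows (6 total)
    and enters forest, and the remaining rows are forest (31 feeders).
    Every hayfield/fallow feeder sits in the open; exactly 14 of the 31
    forest feeders fall in a canopy gap (>50 m^2) and are coded open.
    Lateral visibility (m) is drawn uniformly from per-habitat ranges:
    by default [1, 15] m in forest and [10, 30] m in open habitat.

    Parameters
    ----------
    seed
        Seeds the choice of open forest feeders and the visibility draws.
    visibility_ranges
        Optional override mapping ``{"forest": (lo, hi), "open": (lo, hi)}``.

    Returns
    -------
    DataFrame with columns ``feeder_id, x, y, habitat, openness,
    lateral_visibility_m``, one row per feeder.
    """
    rng = np.random.default_rng(seed)
    ranges = {"forest": (1.0, 15.0), "open": (10.0, 30.0)}
    if visibility_ranges:
        ranges.update(visibility_ranges)

    rows = []
    idx = 0
    for r, length in enumerate(GRID_ROWS):
        for c in range(length):
            idx += 1
            rows.append({"feeder_id": f"F{idx:02d}",
                         "x": c * GRID_SPACING_M,
                         "y": r * GRID_SPACING_M})
    grid = pd.DataFrame(rows)

    habitat = np.array(["forest"] * len(grid), dtype=object)
    habitat[:8] = "hayfield"          # row 1, west side
    habitat[8:12] = "fallow"          # row 1, east side
    habitat[12:14] = "fallow"         # row 2 start
    grid["habitat"] = habitat

    openness = np.where(grid["habitat"] != "forest", "open", "closed")
    forest_idx = np.flatnonzero(grid["habitat"].to_numpy() == "forest")
    open_forest = rng.choice(forest_idx, size=14, replace=False)
    openness[open_forest] = "open"
    grid["openness"] = openness

    vis = np.empty(len(grid))
    is_forest = grid["habitat"].to_numpy() == "forest"
    lo, hi = ranges["forest"]
    vis[is_forest] = rng.uniform(lo, hi, is_forest.sum())
    lo, hi = ranges["open"]
    vis[~is_forest] = rng.uniform(lo, hi, (~is_forest).sum())
    grid["lateral_visibility_m"] = np.round(vis, 1)
    return grid


# ---------------------------------------------------------------------------
# Treatment schedule
# ---------------------------------------------------------------------------

def make_treatment_schedule(year: int, seed: int = 0,
                            feeder_ids: Sequence[str] | None = None,
                            ) -> pd.DataFrame:
    """Weekly sucrose treatment table for one field season.

    In the treatment year the manipulation runs 9 weeks in 3 blocks of 3
    weeks; each week 15 of the 45 feeders are randomly assigned the high
    (35%) concentration under the constraint that within each block every
    feeder is high exactly once.  In the other study years every feeder
    carries the standard low (20%) concentration all season.

    Returns a table with columns ``year, block, week, feeder_id, sucrose,
    week_start, week_end`` (dates inclusive); non-treatment years get a
    single all-season "week" 0 per feeder.
    """
    if year not in STUDY_YEARS:
        raise InvalidConfigError(f"year {year} outside configured study years "
                                 f"{STUDY_YEARS}")
    if feeder_ids is None:
        feeder_ids = [f"F{i:02d}" for i in range(1, 46)]
    feeder_ids = list(feeder_ids)
    n = len(feeder_ids)

    if year != TREATMENT_YEAR:
        start = _dt.date(year, *SEASON_START)
        end = _dt.date(year, *SEASON_END)
        return pd.DataFrame({
            "year": year, "block": 0, "week": 0, "feeder_id": feeder_ids,
            "sucrose": LOW_SUCROSE, "week_start": start, "week_end": end,
        })

    if n % 3:
        raise InvalidConfigError("feeder count must be divisible by 3 for "
                                 "the 3-week block design")
    per_week = n // 3
    rng = np.random.default_rng(seed)
    t0 = _dt.date(year, *TREATMENT_START)
    records = []
    week_no = 0
    for block in (1, 2, 3):
        # A random partition of the feeders into 3 groups of equal size:
        # each feeder is high exactly once per block, 15 feeders per week.
        perm = rng.permutation(n)
        for wk_in_block in range(3):
            week_no += 1
            high = set(perm[wk_in_block * per_week:(wk_in_block + 1) * per_week])
            ws = t0 + _dt.timedelta(days=7 * (week_no - 1))
            we = ws + _dt.timedelta(days=6)
            for i, fid in enumerate(feeder_ids):
                records.append({
                    "year": year, "block": block, "week": week_no,
                    "feeder_id": fid,
                    "sucrose": HIGH_SUCROSE if i in high else LOW_SUCROSE,
                    "week_start": ws, "week_end": we,
                })
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Population ground truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimConfig:
    """Simulator knobs; the seed fully determines the output stream.

    Attributes
    ----------
    dropout_prob
        Per-second probability that a reading inside a visit is skipped by
        the detector (first and last second of a visit are never dropped,
        and runs of consecutive drops are capped below the sessionization
        gap so visit boundaries stay identifiable).
    visit_duration_median_s, visit_duration_sigma
        Median (s) and log-scale shape of the log-normal visit duration.
    habitat_attractiveness
        Multiplier per habitat applied to feeder choice weights and to the
        daily visit rate (via the home feeder's habitat).
    sucrose_attractiveness
        Multiplier applied to high-sucrose feeders.
    allocation_concentration
        Total Dirichlet mass of an optional per-day Dirichlet layer over
        the feeder-choice weights; ``None`` (default) is the multinomial
        limit, i.e. visits are allocated by a plain multinomial draw.
    home_radius_m
        Feeders beyond this distance from an individual's home feeder get
        zero choice weight (``None`` disables the restriction).
    day_start_hour, day_end_hour
        Daily activity window; detectors run around the clock but birds do
        not.
    """
    seed: int = 0
    dropout_prob: float = 0.05
    visit_duration_median_s: float = 8.0
    visit_duration_sigma: float = 0.6
    habitat_attractiveness: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"hayfield": 1.0, "fallow": 1.0, "forest": 1.0})
    sucrose_attractiveness: float = 1.5
    allocation_concentration: float | None = None
    home_radius_m: float | None = 150.0
    day_start_hour: int = 5
    day_end_hour: int = 21

    def validate(self) -> None:
        if not 0.0 <= self.dropout_prob < 1.0:
            raise InvalidConfigError("dropout_prob must be in [0, 1)")
        if any(v < 0 for v in self.habitat_attractiveness.values()):
            raise InvalidConfigError("habitat attractiveness multipliers "
                                     "must be non-negative")
        if self.sucrose_attractiveness < 0:
            raise InvalidConfigError("sucrose_attractiveness must be "
                                     "non-negative")
        if (self.allocation_concentration is not None
                and self.allocation_concentration <= 0):
            raise InvalidConfigError("allocation_concentration must be "
                                     "positive or None")
        if not 0 <= self.day_start_hour < self.day_end_hour <= 24:
            raise InvalidConfigError("activity window must satisfy "
                                     "0 <= start < end <= 24")


def make_population(n_individuals: int, grid: pd.DataFrame, year: int,
                    seed: int = 0, *,
                    sex_ratio_male: float = 0.6,
                    juvenile_fraction: float = 0.15,
                    mean_daily_rate: float = 35.0,
                    fidelity_mean: float = 8.0,
                    defense_mean: float = 2.0,
                    ) -> pd.DataFrame:
    """Draw a ground-truth population table.

    Each individual gets a tag, sex, age class, a home feeder on the grid,
    an expected daily visit count ``lambda`` (gamma-distributed around
    ``mean_daily_rate``; the default of 35 visits/day matches the
    magnitude implied by reported per-feeder visit counts and daily
    concentrations of territorial males), a fidelity ``kappa``
    (weight placed on the home feeder when choosing where to visit), a
    defense strength ``beta`` (how sharply the top user of a feeder-day
    excludes competitor visits), and a tenure (first/last active day
    within the season).  Juveniles appear only in August, mirroring the
    late-season influx of young birds.
    """
    rng = np.random.default_rng(seed)
    season_start = _dt.date(year, *SEASON_START)
    season_end = _dt.date(year, *SEASON_END)
    n_days = (season_end - season_start).days + 1

    recs = []
    for i in range(n_individuals):
        sex = "M" if rng.random() < sex_ratio_male else "F"
        juvenile = rng.random() < juvenile_fraction
        if juvenile:
            first = (_dt.date(year, 8, 1)
                     - season_start).days + int(rng.integers(0, 10))
            last = min(first + int(rng.integers(3, 15)), n_days - 1)
            age = "juvenile"
        else:
            first = int(rng.integers(0, n_days // 3))
            last = int(rng.integers(max(first + 1, n_days // 2), n_days))
            last = min(last, n_days - 1)
            age = "adult"
        recs.append({
            "tag": f"T{i + 1:03d}",
            "sex": sex,
            "age_class": age,
            "home_feeder": grid["feeder_id"].iloc[int(rng.integers(len(grid)))],
            "daily_rate": float(rng.gamma(4.0, mean_daily_rate / 4.0)),
            "fidelity": float(rng.gamma(2.0, fidelity_mean / 2.0)),
            "defense": float(rng.gamma(2.0, defense_mean / 2.0)),
            "first_day": season_start + _dt.timedelta(days=first),
            "last_day": season_start + _dt.timedelta(days=last),
        })
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Detection stream
# ---------------------------------------------------------------------------

def _choice_weights(grid: pd.DataFrame, schedule_day: pd.Series,
                    cfg: SimConfig) -> np.ndarray:
    """Per-feeder attractiveness for one day (habitat x sucrose)."""
    w = grid["habitat"].map(cfg.habitat_attractiveness).to_numpy(float)
    w = w * np.where(schedule_day.to_numpy() == HIGH_SUCROSE,
                     cfg.sucrose_attractiveness, 1.0)
    return w


def _sucrose_by_day(schedule: pd.DataFrame, grid: pd.DataFrame,
                    days: Sequence[_dt.date]) -> dict[_dt.date, pd.Series]:
    out = {}
    fid = grid["feeder_id"]
    for day in days:
        mask = (schedule["week_start"] <= day) & (day <= schedule["week_end"])
        sub = schedule.loc[mask].set_index("feeder_id")["sucrose"]
        out[day] = fid.map(sub).fillna(LOW_SUCROSE)
    return out


def kept_seconds(rng: np.random.Generator, duration: int,
                 dropout_prob: float) -> np.ndarray:
    """Second offsets of a visit's readings that survive detector dropout.

    Each interior second is dropped independently with probability
    ``dropout_prob``; the first and last second are never dropped (visit
    boundaries stay identifiable) and runs of consecutive drops are
    capped at 20 s so every internal gap stays strictly below the 21-s
    sessionization threshold.
    """
    seconds = np.arange(duration)
    if duration <= 2 or dropout_prob <= 0:
        return seconds
    drop = rng.random(duration) < dropout_prob
    drop[0] = drop[-1] = False
    run = 0
    for j in range(1, duration - 1):
        if drop[j]:
            run += 1
            if run >= 20:
                drop[j] = False
                run = 0
        else:
            run = 0
    return seconds[~drop]


def simulate_detection_stream(population: pd.DataFrame, grid: pd.DataFrame,
                              schedule: pd.DataFrame, cfg: SimConfig,
                              ) -> pd.DataFrame:
    """Generate the per-second detection log for one season.

    For every individual-day inside the individual's tenure, a visit count
    is drawn from a Poisson with mean ``daily_rate`` scaled by the home
    feeder's habitat/sucrose attractiveness, and the visits are allocated
    across feeders with weights proportional to feeder attractiveness
    times ``(1 + fidelity)`` at the home feeder (optionally through a
    Dirichlet layer, and restricted to feeders within ``home_radius_m`` of
    home).  Defense then thins the stream: at each feeder-day the top user
    (most realized visits, pre-thinning) with defense ``beta`` and daily
    concentration ``C`` there retains each competitor visit with
    probability ``exp(-beta * C)``.  Surviving visits are expanded into
    consecutive one-second readings with independent dropout; the first
    and last second are never dropped and consecutive drops are capped at
    20 s so the sessionizer's 21-s rule recovers the generated visits.

    Returns the stream sorted by timestamp with columns
    ``timestamp, tag_id, feeder_id`` (second resolution).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if population.empty:
        return pd.DataFrame(columns=["timestamp", "tag_id", "feeder_id"])

    year = int(schedule["year"].iloc[0])
    season_start = _dt.date(year, *SEASON_START)
    season_end = _dt.date(year, *SEASON_END)
    days = [season_start + _dt.timedelta(days=d)
            for d in range((season_end - season_start).days + 1)]
    sucrose_day = _sucrose_by_day(schedule, grid, days)

    fids = grid["feeder_id"].to_numpy()
    fid_index = {f: i for i, f in enumerate(fids)}
    xy = grid[["x", "y"]].to_numpy(float)
    unknown = set(population["home_feeder"]) - set(fids)
    if unknown:
        raise InvalidConfigError(f"home feeders not on the grid: "
                                 f"{sorted(unknown)}")

    # Per-individual reachable-feeder mask around home.
    reach = {}
    for tag, home in zip(population["tag"], population["home_feeder"]):
        hi = fid_index[home]
        if cfg.home_radius_m is None:
            reach[tag] = np.ones(len(fids), bool)
        else:
            d = np.hypot(*(xy - xy[hi]).T)
            reach[tag] = d <= cfg.home_radius_m

    pop = population.set_index("tag")
    visit_rows = []  # (day, tag, feeder_idx)
    for day in days:
        day_sucrose = sucrose_day[day]
        attract = _choice_weights(grid, day_sucrose, cfg)
        active = pop[(pop["first_day"] <= day) & (day <= pop["last_day"])]
        for tag, ind in active.iterrows():
            hi = fid_index[ind["home_feeder"]]
            rate = ind["daily_rate"] * attract[hi] / max(attract.mean(), 1e-12)
            n_visits = rng.poisson(rate)
            if n_visits == 0:
                continue
            w = attract * reach[tag]
            w = w * (1.0 + ind["fidelity"] * (np.arange(len(fids)) == hi))
            if w.sum() <= 0:
                continue
            p = w / w.sum()
            if cfg.allocation_concentration is not None:
                p = rng.dirichlet(cfg.allocation_concentration * p + 1e-9)
            counts = rng.multinomial(n_visits, p)
            for fi in np.flatnonzero(counts):
                visit_rows.extend((day, tag, fi) for _ in range(counts[fi]))

    if not visit_rows:
        return pd.DataFrame(columns=["timestamp", "tag_id", "feeder_id"])
    visits = pd.DataFrame(visit_rows, columns=["day", "tag", "feeder_idx"])

    # Defense thinning: per feeder-day, the top user's realized (pre-thin)
    # concentration there sets competitors' retention probability.
    keep = np.ones(len(visits), bool)
    totals = visits.groupby(["day", "tag"]).size()
    for (day, fi), grp in visits.groupby(["day", "feeder_idx"]):
        counts = grp.groupby("tag").size()
        if len(counts) < 2:
            continue
        top = counts.idxmax()
        conc = counts[top] / totals[(day, top)]
        beta = pop.loc[top, "defense"]
        p_keep = np.exp(-beta * conc)
        if p_keep >= 1.0:
            continue
        comp_idx = grp.index[grp["tag"] != top]
        keep[comp_idx] = rng.random(len(comp_idx)) < p_keep
    visits = visits[keep]

    # Expand retained visits into second-resolution readings.
    records = []
    window_s = (cfg.day_end_hour - cfg.day_start_hour) * 3600
    mu = np.log(cfg.visit_duration_median_s)
    for (day, tag), grp in visits.groupby(["day", "tag"]):
        n = len(grp)
        durs = np.maximum(
            1, np.round(rng.lognormal(mu, cfg.visit_duration_sigma, n))
        ).astype(int)
        # Random start offsets, then push apart so one bird's visits never
        # overlap and same-feeder visits stay >= 21 s apart (sessionizer
        # must not merge distinct generated visits).
        offsets = np.sort(rng.integers(0, window_s, n))
        t = -(10 ** 9)
        starts = np.empty(n, int)
        for k in range(n):
            starts[k] = max(offsets[k], t + 25)
            t = starts[k] + durs[k] - 1
        day_origin = _dt.datetime.combine(
            day, _dt.time(cfg.day_start_hour, 0, 0))
        for (fi, dur, st) in zip(grp["feeder_idx"], durs, starts):
            seconds = kept_seconds(rng, int(dur), cfg.dropout_prob)
            base = day_origin + _dt.timedelta(seconds=int(st))
            fid = fids[fi]
            records.extend(
                (base + _dt.timedelta(seconds=int(s)), tag, fid)
                for s in seconds)

    stream = pd.DataFrame(records, columns=["timestamp", "tag_id",
                                            "feeder_id"])
    stream = stream.sort_values(
        ["timestamp", "tag_id", "feeder_id"]).reset_index(drop=True)
    return stream


# ---------------------------------------------------------------------------
# Generative twin of the analysis model
# ---------------------------------------------------------------------------

def make_nvc_design(n_rows: int = 15000, n_individuals: int = 88,
                    n_feeders: int = 45, seed: int = 0,
                    years: Sequence[int] = STUDY_YEARS) -> pd.DataFrame:
    """Draw a covariate table shaped like the bird-feeder-day analysis table.

    Produces ``n_rows`` rows over ``n_individuals`` focal individuals and
    ``n_feeders`` feeders with covariates on realistic raw scales:
    spatial concentration in [0, 1], per-individual spatial stability,
    daily visit totals, day-level grid usage, competitor counts, a fixed
    feeder rank permutation, per-feeder openness/lateral visibility, and
    the sucrose treatment active only in the final year.  Used as the
    design for :func:`simulate_nvc_table` in parameter-recovery studies.
    """
    rng = np.random.default_rng(seed)
    tags = np.array([f"T{i + 1:03d}" for i in range(n_individuals)])
    feeders = np.array([f"F{i + 1:02d}" for i in range(n_feeders)])

    stab = np.clip(rng.beta(5, 2, n_individuals) * 1.2 - 0.1, -1, 1)
    rank = rng.permutation(n_feeders) + 1.0
    openness = np.where(rng.random(n_feeders) < 0.6, "closed", "open")
    latvis = np.where(openness == "closed",
                      rng.uniform(1, 15, n_feeders),
                      rng.uniform(10, 30, n_feeders))

    ti = rng.integers(0, n_individuals, n_rows)
    fi = rng.integers(0, n_feeders, n_rows)
    yr = np.asarray(years)[rng.integers(0, len(years), n_rows)]
    conc = rng.beta(0.9, 1.6, n_rows)
    table = pd.DataFrame({
        "tag_id": tags[ti],
        "feeder_id": feeders[fi],
        "year": yr,
        "spatial_concentration": conc,
        "spatial_stability": stab[ti],
        "daily_visits": rng.poisson(55, n_rows) + 1,
        "grid_usage": np.round(rng.gamma(16, 1.5, n_rows), 2),
        "n_competitors": 1 + rng.poisson(2.0, n_rows),
        "feeder_rank": rank[fi],
        "sucrose": np.where((yr == TREATMENT_YEAR)
                            & (rng.random(n_rows) < 1 / 3),
                            HIGH_SUCROSE, LOW_SUCROSE),
        "openness": openness[fi],
        "lateral_visibility_m": np.round(latvis[fi], 1),
        "focal_sex": "M",
        "competitor_sex": "M",
    })
    return table


def simulate_nvc_table(coefs: dict[str, float],
                       variance_components: dict[str, float],
                       design: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Draw log competitor-visit counts from the mixed model's generative form.

    ``log_nvc = X @ beta + b_feeder + u0_ind + u1_ind * concentration + eps``
    with ``b_feeder ~ N(0, var_feeder)``, ``(u0, u1) ~ N(0, Psi)`` where
    ``Psi = [[var_ind_intercept, cov_ind], [cov_ind, var_ind_slope]]``, and
    ``eps ~ N(0, var_residual)``.

    Parameters
    ----------
    coefs
        Named fixed-effect coefficients over the full-model term set (see
        :mod:`feederdef.inference`); missing terms default to 0, unknown
        names raise.
    variance_components
        Keys ``var_feeder, var_ind_intercept, var_ind_slope, cov_ind,
        var_residual``; the implied individual-level covariance must be
        positive semi-definite.
    design
        Covariate table (e.g. from :func:`make_nvc_design`).

    Returns a copy of ``design`` with ``log_nvc`` and ``nvc`` columns and
    ground-truth random-effect columns (``true_b_feeder``, ``true_u0``,
    ``true_u1``) for recovery tests.
    """
    from .inference import FULL_TERMS, build_design_matrix

    X, names = build_design_matrix(design, FULL_TERMS)
    unknown = set(coefs) - set(names)
    if unknown:
        raise InvalidConfigError(f"unknown coefficient names: "
                                 f"{sorted(unknown)}")
    vc = {"var_feeder": 0.0, "var_ind_intercept": 0.0,
          "var_ind_slope": 0.0, "cov_ind": 0.0, "var_residual": 0.0}
    vc.update(variance_components)
    psi = np.array([[vc["var_ind_intercept"], vc["cov_ind"]],
                    [vc["cov_ind"], vc["var_ind_slope"]]])
    if vc["var_feeder"] < 0 or vc["var_residual"] < 0:
        raise InvalidConfigError("variances must be non-negative")
    if np.min(np.linalg.eigvalsh(psi)) < -1e-12:
        raise InvalidConfigError("individual random-effect covariance is "
                                 "not positive semi-definite")

    rng = np.random.default_rng(seed)
    beta = np.array([coefs.get(nm, 0.0) for nm in names])
    eta = X @ beta

    feeders, f_inv = np.unique(design["feeder_id"], return_inverse=True)
    tags, t_inv = np.unique(design["tag_id"], return_inverse=True)
    b_feeder = rng.normal(0, np.sqrt(vc["var_feeder"]), len(feeders))
    # Draw (u0, u1) via the Cholesky-like square root of Psi (PSD-safe).
    evals, evecs = np.linalg.eigh(psi)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))
    u = rng.standard_normal((len(tags), 2)) @ root.T
    eps = rng.normal(0, np.sqrt(vc["var_residual"]), len(design))

    conc = design["spatial_concentration"].to_numpy(float)
    log_nvc = (eta + b_feeder[f_inv] + u[t_inv, 0] + u[t_inv, 1] * conc + eps)

    out = design.copy()
    out["log_nvc"] = log_nvc
    out["nvc"] = np.exp(log_nvc)
    out["true_b_feeder"] = b_feeder[f_inv]
    out["true_u0"] = u[t_inv, 0]
    out["true_u1"] = u[t_inv, 1]
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_stream(stream: pd.DataFrame, path) -> None:
    """Write a detection stream as CSV with ISO-8601 second timestamps."""
    out = stream.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
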