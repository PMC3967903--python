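"""Multimodel inference on the competitor-visit response.

Ten linear mixed models with a fixed random structure (feeder intercept,
plus a correlated intercept and spatial-concentration slope per focal
individual) and nested fixed-effect structures are put in competition by
AICc.  All models share five control main effects (year, grid usage,
number of competitors, feeder rank, sucrose concentration); the richer
models add the focal's space-use terms and their interactions with
spatial concentration, which carry the resource-defense hypotheses.

Selection uses maximum-likelihood fits (fixed-effect structures differ);
model-averaged coefficients and their unconditional standard errors are
computed from REML fits, substituting zero for terms a model omits.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .lmm import LMMResult, fit_mixed

log = logging.getLogger(__name__)

CONTROL_TERMS = ("year", "grid_usage", "n_competitors", "feeder_rank",
                 "sucrose")
FULL_TERMS = CONTROL_TERMS + (
    "spatial_concentration", "daily_visits", "spatial_stability",
    "openness", "lateral_visibility",
    "spatial_concentration:daily_visits",
    "spatial_concentration:n_competitors",
    "spatial_concentration:spatial_stability",
    "spatial_concentration:openness:lateral_visibility",
    "spatial_concentration:sucrose",
)

_HABITAT_TERMS = ("openness", "lateral_visibility")
_MODEL_TERMS: dict[int, tuple[str, ...]] = {
    1: CONTROL_TERMS,
    2: CONTROL_TERMS + _HABITAT_TERMS,
    3: CONTROL_TERMS + ("spatial_concentration", "daily_visits",
                        "spatial_stability") + _HABITAT_TERMS,
    4: CONTROL_TERMS + ("spatial_concentration", "spatial_stability")
       + _HABITAT_TERMS
       + ("spatial_concentration:n_competitors",
          "spatial_concentration:spatial_stability",
          "spatial_concentration:openness:lateral_visibility"),
    5: CONTROL_TERMS + ("spatial_concentration", "daily_visits")
       + _HABITAT_TERMS
       + ("spatial_concentration:daily_visits",
          "spatial_concentration:n_competitors",
          "spatial_concentration:openness:lateral_visibility"),
    6: CONTROL_TERMS + ("spatial_concentration", "daily_visits",
                        "spatial_stability") + _HABITAT_TERMS
       + ("spatial_concentration:daily_visits",
          "spatial_concentration:spatial_stability",
          "spatial_concentration:openness:lateral_visibility"),
    7: CONTROL_TERMS + ("spatial_concentration", "daily_visits",
                        "spatial_stability")
       + ("spatial_concentration:daily_visits",
          "spatial_concentration:n_competitors",
          "spatial_concentration:spatial_stability"),
    8: CONTROL_TERMS + ("spatial_concentration", "daily_visits",
                        "spatial_stability") + _HABITAT_TERMS
       + ("spatial_concentration:daily_visits",
          "spatial_concentration:n_competitors",
          "spatial_concentration:spatial_stability"),
    9: tuple(t for t in FULL_TERMS if t != "spatial_concentration:sucrose"),
    10: FULL_TERMS,
}


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One fixed-effect structure from the candidate set."""
    model_id: int
    fixed_terms: tuple[str, ...]

    def __contains__(self, term: str) -> bool:
        return term in self.fixed_terms


def build_model_set() -> list[ModelSpec]:
    """The ten candidate fixed-effect structures.

    Models 1-2 omit spatial concentration entirely (no-defense
    baselines); models 3-9 drop single space-use or habitat terms and/or
    their concentration interactions; model 10 carries every term
    including the concentration x sucrose interaction, which appears in
    no other model.
    """
    return [ModelSpec(mid, tuple(terms))
            for mid, terms in sorted(_MODEL_TERMS.items())]


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def _term_columns(table: pd.DataFrame, term: str) -> dict[str, np.ndarray]:
    """Expand one model term into named design columns.

    Categorical references: year 2007, sucrose low, openness closed.
    The three-way interaction is parameterized as separate
    concentration x lateral-visibility slopes within each openness
    level, matching how averaged coefficients are reported.
    """
    conc = table["spatial_concentration"].to_numpy(float)
    if term == "year":
        yr = table["year"].to_numpy(int)
        levels = sorted(np.unique(yr))
        # Reference level: the earliest year present (2007 in the full
        # three-season design).
        return {f"year_{lv}": (yr == lv).astype(float)
                for lv in levels[1:]}
    if term == "sucrose":
        return {"sucrose_high":
                (table["sucrose"].to_numpy() == "high").astype(float)}
    if term == "openness":
        return {"openness_open":
                (table["openness"].to_numpy() == "open").astype(float)}
    if term == "lateral_visibility":
        return {"lateral_visibility":
                table["lateral_visibility_m"].to_numpy(float)}
    if term in ("grid_usage", "n_competitors", "feeder_rank",
                "spatial_concentration", "daily_visits",
                "spatial_stability"):
        return {term: table[term].to_numpy(float)}
    if term == "spatial_concentration:daily_visits":
        return {term: conc * table["daily_visits"].to_numpy(float)}
    if term == "spatial_concentration:n_competitors":
        return {term: conc * table["n_competitors"].to_numpy(float)}
    if term == "spatial_concentration:spatial_stability":
        return {term: conc * table["spatial_stability"].to_numpy(float)}
    if term == "spatial_concentration:sucrose":
        high = (table["sucrose"].to_numpy() == "high").astype(float)
        return {"spatial_concentration:sucrose_high": conc * high}
    if term == "spatial_concentration:openness:lateral_visibility":
        is_open = (table["openness"].to_numpy() == "open").astype(float)
        lv = table["lateral_visibility_m"].to_numpy(float)
        return {
            "spatial_concentration:openness_closed:lateral_visibility":
                conc * (1.0 - is_open) * lv,
            "spatial_concentration:openness_open:lateral_visibility":
                conc * is_open * lv,
        }
    raise KeyError(f"unknown model term: {term}")


def build_design_matrix(table: pd.DataFrame, terms,
                        ) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix (with intercept) for a term list.

    Numeric covariates enter on their raw scales; coefficients are
    therefore directly comparable to reported effect sizes.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(table))}
    for term in terms:
        for nm, col in _term_columns(table, term).items():
            # Constant columns (e.g. sucrose_high in a season without the
            # treatment) are aliased with the intercept and dropped.
            if np.ptp(col) == 0:
                log.debug("dropping constant design column %s", nm)
                continue
            cols[nm] = col
    names = list(cols)
    X = np.column_stack([cols[nm] for nm in names])
    # Prune linearly dependent columns (e.g. concentration x competitors
    # when every feeder-day happens to have exactly one competitor, as
    # can occur in very small datasets).
    keep = [0]
    for j in range(1, X.shape[1]):
        Xk = X[:, keep]
        beta, *_ = np.linalg.lstsq(Xk, X[:, j], rcond=None)
        resid = X[:, j] - Xk @ beta
        if np.linalg.norm(resid) <= 1e-8 * max(np.linalg.norm(X[:, j]), 1.0):
            log.debug("dropping aliased design column %s", names[j])
            continue
        keep.append(j)
    names = [names[j] for j in keep]
    return X[:, keep], names


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_lmm(spec: ModelSpec, table: pd.DataFrame, method: str = "REML",
            random_slope: bool = True,
            fixed_theta: np.ndarray | None = None) -> LMMResult:
    """Fit one candidate model to the bird-feeder-day table.

    The response is the natural log of NVC; the random structure (feeder
    intercept + correlated individual intercept/concentration slope) is
    the same for every candidate.
    """
    if table.empty:
        raise ValueError("analysis table is empty")
    y = (table["log_nvc"].to_numpy(float) if "log_nvc" in table
         else np.log(table["nvc"].to_numpy(float)))
    X, names = build_design_matrix(table, spec.fixed_terms)
    fit = fit_mixed(y, X, names,
                    table["feeder_id"].to_numpy(),
                    table["tag_id"].to_numpy(),
                    conc=table["spatial_concentration"].to_numpy(float),
                    method=method, random_slope=random_slope,
                    fixed_theta=fixed_theta)
    if not fit.converged:
        log.warning("model %d (%s) did not converge", spec.model_id, method)
    return fit


def fit_model_set(table: pd.DataFrame,
                  ) -> tuple[list[LMMResult], list[LMMResult]]:
    """ML and REML fits of all ten candidates, in model order."""
    specs = build_model_set()
    ml = [fit_lmm(s, table, method="ML") for s in specs]
    reml = [fit_lmm(s, table, method="REML") for s in specs]
    return ml, reml


# ---------------------------------------------------------------------------
# Information criteria
# ---------------------------------------------------------------------------

def aicc(fit: LMMResult) -> float:
    """Small-sample corrected AIC: -2 loglik + 2K + 2K(K+1)/(n-K-1).

    Requires an ML fit (likelihoods of REML fits with different fixed
    effects are not comparable).  K counts fixed effects, the
    random-effect (co)variance parameters, and the residual variance.
    """
    if fit.method != "ML":
        raise ValueError("AICc requires a maximum-likelihood fit")
    k, n = fit.k_params, fit.n
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n={n} <= K+1={k + 1}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)."""
    v = np.asarray(aicc_values, float)
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("AICc values must be a non-empty finite sequence")
    delta = v - v.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def selection_table(ml_fits: list[LMMResult]) -> pd.DataFrame:
    """Model-selection summary: K, AICc, delta, Akaike weight per model."""
    ics = np.array([aicc(f) for f in ml_fits])
    w = akaike_weights(ics)
    return pd.DataFrame({
        "model_id": np.arange(1, len(ml_fits) + 1),
        "K": [f.k_params for f in ml_fits],
        "loglik_ml": [f.loglik for f in ml_fits],
        "aicc": ics,
        "delta_aicc": ics - ics.min(),
        "weight": w,
    })


# ---------------------------------------------------------------------------
# Model averaging
# ---------------------------------------------------------------------------

def model_average(reml_fits: list[LMMResult], weights,
                  method: str = "zero") -> pd.DataFrame:
    """Average coefficients across the candidate set.

    ``method="zero"`` (default) substitutes 0 for terms a model omits
    and averages over the full set; ``method="natural"`` averages each
    term only over the models containing it, renormalizing the weights.
    The unconditional standard error combines within-model sampling
    variance with between-model coefficient spread:
    ``SE = sum_i w_i sqrt(se_i^2 + (theta_i - theta_bar)^2)``;
    95% CIs use a normal 1.96 multiplier.

    Non-converged fits are dropped with a warning and weights
    renormalized.
    """
    w = np.asarray(weights, float)
    if len(w) != len(reml_fits):
        raise ValueError("weights must align with fits")
    ok = np.array([f.converged for f in reml_fits])
    if not ok.all():
        log.warning("dropping %d non-converged fit(s) from averaging",
                    int((~ok).sum()))
    fits = [f for f, o in zip(reml_fits, ok) if o]
    w = w[ok]
    w = w / w.sum()

    names: list[str] = []
    for f in fits:
        for nm in f.coefficients.index:
            if nm not in names and nm != "Intercept":
                names.append(nm)

    rows = []
    for nm in names:
        theta = np.array([f.coefficients.get(nm, 0.0) for f in fits])
        se = np.array([f.se.get(nm, 0.0) for f in fits])
        present = np.array([nm in f.coefficients.index for f in fits])
        if method == "natural":
            wn = w * present
            if wn.sum() == 0:
                continue
            wn = wn / wn.sum()
        elif method == "zero":
            wn = w
        else:
            raise ValueError("method must be 'zero' or 'natural'")
        coef = float(wn @ theta)
        unc_se = float(wn @ np.sqrt(se ** 2 + (theta - coef) ** 2))
        rows.append({"term": nm, "coef": coef, "unconditional_se": unc_se,
                     "ci_lower": coef - 1.96 * unc_se,
                     "ci_upper": coef + 1.96 * unc_se,
                     "n_models": int(present.sum())})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Individual-level defense (BLUP slopes)
# ---------------------------------------------------------------------------

_CONC_INTERACTIONS = {
    "spatial_concentration:daily_visits": "daily_visits",
    "spatial_concentration:n_competitors": "n_competitors",
    "spatial_concentration:spatial_stability": "spatial_stability",
    # at reference levels: openness = closed, sucrose = low
    "spatial_concentration:openness_closed:lateral_visibility":
        "lateral_visibility_m",
}


def _fixed_conc_effect(fit: LMMResult, table: pd.DataFrame) -> float:
    """Population-level concentration slope with numeric covariates at
    their means and factors at reference levels."""
    eff = float(fit.coefficients.get("spatial_concentration", 0.0))
    for term, covar in _CONC_INTERACTIONS.items():
        if term in fit.coefficients.index:
            eff += float(fit.coefficients[term]) * float(
                table[covar].mean())
    return eff


def blup_slopes(reml_fits: list[LMMResult], weights,
                table: pd.DataFrame) -> pd.DataFrame:
    """Model-averaged per-individual concentration slopes.

    For each individual, the total slope is the model-averaged fixed
    concentration effect (other numeric covariates at their means,
    factors at reference) plus the model-averaged BLUP of its random
    slope.  The slope is also expressed as the predicted percent
    reduction in NVC when spatial concentration goes from 0 to 1,
    ``100 * (1 - exp(slope))``.
    """
    w = np.asarray(weights, float)
    ok = np.array([f.converged and f.random_slope for f in reml_fits])
    fits = [f for f, o in zip(reml_fits, ok) if o]
    if not fits:
        raise ValueError("no converged random-slope fits to average")
    w = w[ok]
    w = w / w.sum()

    tags = fits[0].blups["tag_id"].to_numpy()
    total = np.zeros(len(tags))
    for f, wi in zip(fits, w):
        fixed = _fixed_conc_effect(f, table)
        b = f.blups.set_index("tag_id")["slope"].reindex(tags).to_numpy()
        total += wi * (fixed + b)
    return pd.DataFrame({
        "tag_id": tags,
        "total_slope": total,
        "nvc_reduction_pct": 100.0 * (1.0 - np.exp(total)),
    })


# ---------------------------------------------------------------------------
# Random-slope support
# ---------------------------------------------------------------------------

def random_slope_support(table: pd.DataFrame) -> float:
    """AICc difference between full models without vs with the random
    concentration slope; positive values favor the random slope."""
    spec = build_model_set()[-1]
    with_slope = fit_lmm(spec, table, method="ML", random_slope=True)
    without = fit_lmm(spec, table, method="ML", random_slope=False)
    if not (with_slope.converged and without.converged):
        raise RuntimeError("random-slope comparison did not converge")
    return aicc(without) - aicc(with_slope)
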