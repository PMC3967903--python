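"""Permutation null models for concentration and feeder dominance.

Two randomization procedures ask whether the observed visit patterns
could arise from birds spreading visits at random:

* concentration null — is an individual more concentrated at its
  most-visited feeder on a day than expected?  Each replicate reassigns
  every visit of each bird-day independently and uniformly among the
  feeders that bird visited that day (visit totals conserved), then
  recomputes the mean, over bird-days, of the visit share at the
  bird-day's top feeder.
* dominance null — does a single individual dominate a feeder-day in
  visit counts?  Each replicate reassigns every visit of each feeder-day
  independently and uniformly among the individuals that visited it,
  then recomputes the mean, over feeder-days, of the top individual's
  visit count.

A uniform multinomial redraw (rather than a permutation of the fixed
count vector, which would leave both statistics unchanged) is the only
reading under which the null differs from the data.  One-sided p-values
for observed > null use the add-one convention
``(1 + #{null >= observed}) / (n_rep + 1)``, so they are never zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .metrics import visit_counts
from .simdata import InvalidConfigError


@dataclasses.dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    n_rep: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))

    @property
    def p_value(self) -> float:
        b = int(np.sum(self.null_values >= self.observed))
        return (1 + b) / (self.n_rep + 1)


def _null_run(groups: list[tuple[int, int]], n_rep: int,
              rng: np.random.Generator, as_share: bool) -> np.ndarray:
    """Mean of per-group max counts (or shares) under uniform reassignment.

    ``groups`` holds (total visits n, number of options k) per group.
    """
    out = np.empty(n_rep)
    sizes = np.array([n for n, _ in groups], float)
    for r in range(n_rep):
        tops = np.empty(len(groups))
        for g, (n, k) in enumerate(groups):
            if k == 1:
                tops[g] = n
            else:
                counts = rng.multinomial(n, np.full(k, 1.0 / k))
                tops[g] = counts.max()
        if as_share:
            tops = tops / sizes
        out[r] = tops.mean()
    return out


def null_concentration(visits: pd.DataFrame, n_rep: int = 100,
                       seed: int = 0) -> PermutationResult:
    """Test whether birds concentrate visits beyond random feeder choice.

    Observed statistic: mean over bird-days of the spatial concentration
    at each bird-day's most-visited feeder.
    """
    if n_rep < 1:
        raise InvalidConfigError("n_rep must be >= 1")
    if visits.empty:
        raise ValueError("visits table is empty")
    counts = visit_counts(visits)
    per = counts.groupby(["tag_id", "date"])["n_visits"]
    totals = per.sum()
    maxima = per.max()
    observed = float((maxima / totals).mean())
    k = per.count()
    groups = list(zip(totals.astype(int), k.astype(int)))
    rng = np.random.default_rng(seed)
    nulls = _null_run(groups, n_rep, rng, as_share=True)
    return PermutationResult(observed, nulls, n_rep)


def null_dominance(visits: pd.DataFrame, n_rep: int = 100,
                   seed: int = 0) -> PermutationResult:
    """Test whether one individual dominates feeder-days in visit counts.

    Observed statistic: mean over feeder-days of the visit count of the
    individual that made the most visits there.
    """
    if n_rep < 1:
        raise InvalidConfigError("n_rep must be >= 1")
    if visits.empty:
        raise ValueError("visits table is empty")
    counts = visit_counts(visits)
    per = counts.groupby(["feeder_id", "date"])["n_visits"]
    totals = per.sum()
    maxima = per.max()
    observed = float(maxima.mean())
    m = per.count()
    groups = list(zip(totals.astype(int), m.astype(int)))
    rng = np.random.default_rng(seed)
    nulls = _null_run(groups, n_rep, rng, as_share=False)
    return PermutationResult(observed, nulls, n_rep)


def summary_frame(results: dict[str, PermutationResult]) -> pd.DataFrame:
    """One-row-per-test summary (observed, null mean/sd, p)."""
    rows = [{"test": name, "observed": r.observed, "null_mean": r.null_mean,
             "null_sd": r.null_sd, "n_rep": r.n_rep, "p_value": r.p_value}
            for name, r in results.items()]
    return pd.DataFrame(rows)
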