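"""Pearson and age-adjusted partial correlations among EF measures.

Raw correlations use pairwise-complete observations.  The age-adjusted
partial correlation of two measures is the Pearson correlation of their
residuals after each measure is regressed on its own best-fitting orthogonal
age polynomial (linear, quadratic or cubic, with intercept).  Because the
adjustment consumes degrees of freedom, partial-correlation p-values use
df = n - 2 - (number of age terms partialled); for a pair adjusted with
different degrees the larger of the two is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .basis import OrthogonalPolynomialBasis
from .trajectories import residualize

DEFAULT_MEASURES = (
    "stroop_effect",
    "ospan_partial",
    "switch_cost",
    "mixing_cost",
    "toh_score",
)


@dataclass(frozen=True)
class CorrelationMatrix:
    measures: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    partial_r: pd.DataFrame
    partial_p: pd.DataFrame


def _r_and_p(x: np.ndarray, y: np.ndarray, df: int) -> tuple[float, float]:
    r = float(np.corrcoef(x, y)[0, 1])
    if df <= 0 or abs(r) >= 1.0:
        return r, 0.0 if abs(r) >= 1.0 else np.nan
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df))


def age_residuals(
    scores: pd.DataFrame, measure: str, degree: int, age_col: str = "age_years"
) -> pd.Series:
    """Residuals of one measure after removing its best-fitting age
    polynomial, indexed like ``scores`` (NaN where incomplete)."""
    sub = scores[[age_col, measure]].dropna()
    basis = OrthogonalPolynomialBasis(degree=degree).fit(sub[age_col])
    resid = residualize(sub[measure].to_numpy(), basis.columns_)
    return pd.Series(resid, index=sub.index).reindex(scores.index)


def ef_correlations(
    scores: pd.DataFrame,
    best_degrees: dict[str, int],
    measures: tuple[str, ...] = DEFAULT_MEASURES,
    age_col: str = "age_years",
    min_n: int = 3,
) -> CorrelationMatrix:
    """Correlation matrix of EF measures with age-adjusted partial
    correlations.

    ``best_degrees`` maps each measure name to the polynomial degree chosen
    by the trajectory model selection; it controls how many age terms are
    partialled out of each measure.
    """
    k = len(measures)
    resid = {m: age_residuals(scores, m, best_degrees[m], age_col) for m in measures}
    shape = (k, k)
    r = np.ones(shape)
    p = np.zeros(shape)
    n = np.zeros(shape, dtype=int)
    pr = np.ones(shape)
    pp = np.zeros(shape)
    for i in range(k):
        n[i, i] = scores[measures[i]].notna().sum()
        for j in range(i + 1, k):
            a, b = measures[i], measures[j]
            pair = scores[[a, b]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < min_n:
                r[i, j] = r[j, i] = p[i, j] = p[j, i] = np.nan
                pr[i, j] = pr[j, i] = pp[i, j] = pp[j, i] = np.nan
                continue
            rij, pij = _r_and_p(
                pair[a].to_numpy(), pair[b].to_numpy(), len(pair) - 2
            )
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            rpair = pd.concat([resid[a], resid[b]], axis=1).dropna()
            n_terms = max(best_degrees[a], best_degrees[b])
            prij, ppij = _r_and_p(
                rpair.iloc[:, 0].to_numpy(),
                rpair.iloc[:, 1].to_numpy(),
                len(rpair) - 2 - n_terms,
            )
            pr[i, j] = pr[j, i] = prij
            pp[i, j] = pp[j, i] = ppij

    def frame(a, dtype=float):
        return pd.DataFrame(a, index=list(measures), columns=list(measures)).astype(dtype)

    return CorrelationMatrix(
        measures=tuple(measures),
        r=frame(r),
        p=frame(p),
        n=frame(n, int),
        partial_r=frame(pr),
        partial_p=frame(pp),
    )


def significance_stars(p: float) -> str:
    """Star tiers: * p<.05, ** p<.01, *** p<.001."""
    if np.isnan(p):
        return ""
    for stars, cut in (("***", 0.001), ("**", 0.01), ("*", 0.05)):
        if p < cut:
            return stars
    return ""
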