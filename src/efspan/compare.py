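"""Trajectory-equality testing between two executive-function measures.

Two measures whose best-fitting age models share the same polynomial degree
are compared by stacking their z-scored values, rebuilding the orthonormal
age basis on the stacked age vector, and testing whether freeing the age
terms per measure improves fit:

    model 1:  z ~ age terms (shared slopes)
    model 2:  z ~ age terms + group x each age term

Because each measure is z-scored within its own sample, both groups have
mean exactly zero and a group main effect is identically redundant; the
interaction model therefore frees only the age terms (df1 = degree), which
keeps the nested F test calibrated at its nominal level.  A significant
nested F (p < .05) means the two developmental trajectories differ.
Measures selected with different polynomial degrees are refused rather than
compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .basis import OrthogonalPolynomialBasis


class DegreeMismatchError(ValueError):
    """Raised when two measures' best models have different polynomial
    degrees and therefore cannot be compared slope-for-slope."""


@dataclass(frozen=True)
class TrajectoryEqualityResult:
    rss_delta: float
    f_change: float
    df1: int
    df2: int
    p: float
    verdict: str  # "different" | "not_different"

    @property
    def different(self) -> bool:
        return self.verdict == "different"


def _zscore(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std(ddof=1)


def compare_trajectories(
    ages_a, scores_a, ages_b, scores_b, degree: int, alpha: float = 0.05
) -> TrajectoryEqualityResult:
    """Test whether two measures share a developmental trajectory.

    Each score vector is z-scored within its own sample, the samples are
    stacked with a grouping dummy (measure A = 1, measure B = 2), and the
    shared-slope model is tested against the model with group x age-term
    interactions by a nested F test.
    """
    a_age = np.asarray(ages_a, dtype=float)
    b_age = np.asarray(ages_b, dtype=float)
    ya = np.asarray(scores_a, dtype=float)
    yb = np.asarray(scores_b, dtype=float)
    keep_a = ~(np.isnan(a_age) | np.isnan(ya))
    keep_b = ~(np.isnan(b_age) | np.isnan(yb))
    a_age, ya = a_age[keep_a], ya[keep_a]
    b_age, yb = b_age[keep_b], yb[keep_b]

    z = np.concatenate([_zscore(ya), _zscore(yb)])
    ages = np.concatenate([a_age, b_age])
    group = np.concatenate([np.ones(ya.size), np.full(yb.size, 2.0)])

    poly = OrthogonalPolynomialBasis(degree=degree).fit(ages).columns_
    n = z.size
    X1 = sm.add_constant(poly)
    X2 = np.column_stack([X1, poly * group[:, None]])

    fit1 = sm.OLS(z, X1).fit()
    fit2 = sm.OLS(z, X2).fit()
    rss1, rss2 = float(fit1.ssr), float(fit2.ssr)
    df1 = degree  # one freed slope per age term
    k2 = X2.shape[1]
    df2 = n - k2
    f_change = max(((rss1 - rss2) / df1) / (rss2 / df2), 0.0)
    p = float(stats.f.sf(f_change, df1, df2))
    return TrajectoryEqualityResult(
        rss_delta=float(rss1 - rss2),
        f_change=float(f_change),
        df1=df1,
        df2=df2,
        p=p,
        verdict="different" if p < alpha else "not_different",
    )


def compare_measures(
    scores, measure_a: str, measure_b: str, degrees: dict[str, int], age_col: str = "age_years"
) -> TrajectoryEqualityResult:
    """Compare two measures out of a scores table, refusing on degree
    mismatch (measures with different best-fitting degrees already have
    demonstrably different trajectories)."""
    da, db = degrees[measure_a], degrees[measure_b]
    if da != db:
        raise DegreeMismatchError(
            f"{measure_a} (degree {da}) and {measure_b} (degree {db}) were "
            "selected with different polynomial degrees; their trajectories "
            "already differ in form and are not directly compared"
        )
    return compare_trajectories(
        scores[age_col], scores[measure_a], scores[age_col], scores[measure_b], degree=da
    )
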