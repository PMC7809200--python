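"""Curvilinear age-trajectory models with covariates and model selection.

Each executive-function score is regressed on orthonormal polynomial scores
of age (degree 1-3) plus IQ and SES covariates.  All variables (outcome and
every predictor column) are z-scored before fitting, so the reported
coefficients are standardized betas and the fit indices (RSS, -2LL, AIC,
BIC) are on the standardized outcome scale.  The Gaussian log-likelihood is
``-n/2 (ln 2π + ln(RSS/n) + 1)`` and the information criteria count the
residual variance as a free parameter: ``k = n_coefficients + 1``, so
``AIC = 2k - 2LL`` and ``BIC = k ln n - 2LL`` (the R convention).

The best polynomial degree is chosen hierarchically: degree 1 vs 2, then the
winner vs degree 3, each comparison decided by a majority of four
goodness-of-fit indices (nested-F p, likelihood-ratio p, AIC, BIC); 2-2 ties
go to the simpler model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .basis import OrthogonalPolynomialBasis

AGE_TERM_NAMES = ("age_linear", "age_quadratic", "age_cubic")
ALPHA = 0.05


@dataclass(frozen=True)
class FTest:
    statistic: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class FitResult:
    """One OLS trajectory fit on standardized variables."""

    degree: int
    n: int
    coefficients: dict[str, float]
    r_squared: float
    f_overall: FTest
    rss: float
    loglik: float
    aic: float
    bic: float
    k_params: int  # coefficients incl. intercept, plus residual variance

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ModelComparison:
    """Nested comparison of a simpler vs a more complex trajectory fit."""

    f_change: FTest
    lr_chisq: tuple[float, int, float]  # (statistic, df, p)
    delta_aic: float
    delta_bic: float


@dataclass(frozen=True)
class SelectionResult:
    chosen_degree: int
    votes: dict[str, dict[str, int]]
    audit_trail: list[str] = field(default_factory=list)


class RankDeficientDesign(ValueError):
    pass


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        running_rank = 0
        for j in range(X.shape[1]):
            r = np.linalg.matrix_rank(X[:, : j + 1])
            if r == running_rank:
                bad.append(names[j])
            running_rank = r
        raise RankDeficientDesign(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def _zscore(a: np.ndarray, name: str) -> np.ndarray:
    sd = a.std(ddof=1)
    if sd == 0:
        raise RankDeficientDesign(f"column {name!r} has zero variance")
    return (a - a.mean()) / sd


class TrajectoryModel(RegressorMixin, BaseEstimator):
    """OLS age-trajectory regression with standardized coefficients.

    ``X`` is an array or DataFrame whose first column is age in years and
    whose remaining columns are covariates (IQ, SES).  ``fit`` builds a
    degree-``degree`` orthonormal polynomial basis on the sample ages,
    z-scores outcome and predictors, and fits ordinary least squares with an
    intercept.  Rows must be complete (no NaN); model-wise complete-case
    handling lives in :func:`fit_trajectory`.

    Parameters
    ----------
    degree : int
        Polynomial degree of the age trend (1-3).
    include_covariates : bool
        If False, covariate columns in ``X`` are ignored and the model is
        age-only (the paper-style covariate-removed refit).
    """

    def __init__(self, degree: int = 1, include_covariates: bool = True):
        self.degree = degree
        self.include_covariates = include_covariates

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y) -> "TrajectoryModel":
        X_df = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if X_df.isna().any().any() or np.isnan(y).any():
            raise ValueError("fit requires complete rows; drop NaN first")
        n = len(X_df)
        ages = X_df.iloc[:, 0].to_numpy(dtype=float)
        if self.include_covariates:
            cov = X_df.iloc[:, 1:]
            cov_names = [str(c) for c in cov.columns]
        else:
            cov = X_df.iloc[:, :0]
            cov_names = []
        self.basis_ = OrthogonalPolynomialBasis(degree=self.degree).fit(ages)
        poly = self.basis_.columns_
        names = list(AGE_TERM_NAMES[: self.degree]) + cov_names
        raw_cols = np.column_stack([poly, cov.to_numpy(dtype=float)]) if cov_names else poly

        self.col_means_ = raw_cols.mean(axis=0)
        self.col_sds_ = raw_cols.std(axis=0, ddof=1)
        self.y_mean_, self.y_sd_ = y.mean(), y.std(ddof=1)
        if self.y_sd_ == 0:
            # degenerate constant outcome: the trajectory is flat and the
            # likelihood is unbounded, so fit indices are undefined
            warnings.warn("outcome has zero variance; fitting a flat curve", stacklevel=2)
            k_coef = raw_cols.shape[1] + 1
            self.y_sd_ = 1.0
            self.n_ = n
            self.term_names_ = names
            self.coef_ = np.zeros(raw_cols.shape[1])
            self.intercept_ = 0.0
            self.result_ = FitResult(
                degree=int(self.degree),
                n=n,
                coefficients={nm: 0.0 for nm in names},
                r_squared=0.0,
                f_overall=FTest(np.nan, float(raw_cols.shape[1]), float(n - k_coef), np.nan),
                rss=0.0,
                loglik=np.nan,
                aic=np.nan,
                bic=np.nan,
                k_params=k_coef + 1,
            )
            self.pvalues_ = {nm: np.nan for nm in names}
            return self
        Z = np.column_stack(
            [_zscore(raw_cols[:, j], names[j]) for j in range(raw_cols.shape[1])]
        )
        _check_rank(np.column_stack([np.ones(n), Z]), ["intercept"] + names)
        yz = (y - self.y_mean_) / self.y_sd_

        ols = sm.OLS(yz, sm.add_constant(Z)).fit()
        rss = float(ols.ssr)
        k_coef = raw_cols.shape[1] + 1  # + intercept
        loglik = -n / 2.0 * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
        k = k_coef + 1  # + residual variance
        coefs = dict(zip(names, (float(b) for b in ols.params[1:])))
        self.n_ = n
        self.term_names_ = names
        self.coef_ = np.asarray(ols.params[1:], dtype=float)
        self.intercept_ = float(ols.params[0])
        self.result_ = FitResult(
            degree=int(self.degree),
            n=n,
            coefficients=coefs,
            r_squared=float(ols.rsquared),
            f_overall=FTest(
                float(ols.fvalue),
                float(ols.df_model),
                float(ols.df_resid),
                float(ols.f_pvalue),
            ),
            rss=rss,
            loglik=float(loglik),
            aic=float(2 * k - 2 * loglik),
            bic=float(k * np.log(n) - 2 * loglik),
            k_params=k,
        )
        self.pvalues_ = dict(zip(names, (float(p) for p in ols.pvalues[1:])))
        self.ols_ = ols
        return self

    # -- prediction --------------------------------------------------------
    def _design_z(self, ages: np.ndarray, cov_values: np.ndarray) -> np.ndarray:
        poly = self.basis_.transform(ages)
        cols = np.column_stack([poly, cov_values]) if cov_values.size else poly
        return (cols - self.col_means_) / self.col_sds_

    def predict(self, X) -> np.ndarray:
        X_df = pd.DataFrame(X)
        ages = X_df.iloc[:, 0].to_numpy(dtype=float)
        if self.include_covariates and len(self.term_names_) > self.degree:
            cov = X_df.iloc[:, 1:].to_numpy(dtype=float)
        else:
            cov = np.empty((len(X_df), 0))
        Z = self._design_z(ages, cov)
        yz = self.intercept_ + Z @ self.coef_
        return self.y_mean_ + self.y_sd_ * yz

    def predict_curve(self, new_ages, covariate_values=None) -> np.ndarray:
        """Fitted trajectory at ``new_ages`` with covariates held at their
        sample means (or at ``covariate_values``).  Warns on extrapolation
        beyond the anchor age range."""
        new_ages = np.asarray(new_ages, dtype=float)
        lo, hi = self.basis_.anchor_ages_.min(), self.basis_.anchor_ages_.max()
        if (new_ages < lo).any() or (new_ages > hi).any():
            warnings.warn(
                f"ages outside the fitted range [{lo:g}, {hi:g}]; extrapolating",
                stacklevel=2,
            )
        n_cov = len(self.term_names_) - self.degree
        if covariate_values is None:
            # column means of the raw covariates equal col_means_ beyond the
            # polynomial block
            cov_vals = self.col_means_[self.degree :]
        else:
            cov_vals = np.asarray(covariate_values, dtype=float)
        cov = np.tile(cov_vals, (new_ages.size, 1)) if n_cov else np.empty((new_ages.size, 0))
        Z = self._design_z(new_ages, cov)
        return self.y_mean_ + self.y_sd_ * (self.intercept_ + Z @ self.coef_)


# ---------------------------------------------------------------------------
# nested comparison and selection

def compare_nested(simple: FitResult, complex_: FitResult) -> ModelComparison:
    """F-change, likelihood-ratio and information-criterion deltas for a
    nested pair of trajectory fits on the same rows."""
    if simple.n != complex_.n:
        raise ValueError(f"fits use different samples (n={simple.n} vs {complex_.n})")
    dk = (complex_.k_params) - (simple.k_params)
    if dk <= 0:
        raise ValueError("complex model must add parameters")
    k_c_coef = complex_.k_params - 1
    n = complex_.n
    num = (simple.rss - complex_.rss) / dk
    den = complex_.rss / (n - k_c_coef)
    f_stat = max(num / den, 0.0)
    f_p = float(stats.f.sf(f_stat, dk, n - k_c_coef))
    lr = max(2.0 * (complex_.loglik - simple.loglik), 0.0)
    lr_p = float(stats.chi2.sf(lr, dk))
    return ModelComparison(
        f_change=FTest(float(f_stat), float(dk), float(n - k_c_coef), f_p),
        lr_chisq=(float(lr), int(dk), lr_p),
        delta_aic=float(complex_.aic - simple.aic),
        delta_bic=float(complex_.bic - simple.bic),
    )


def tally_votes(
    f_p: float, lr_p: float, delta_aic: float, delta_bic: float, alpha: float = ALPHA
) -> dict[str, int]:
    """Per-index verdicts for one nested comparison: 1 favours the complex
    model, 0 the simpler.  RSS never votes (it always favours complexity)."""
    return {
        "f_change_p": int(f_p < alpha),
        "lr_p": int(lr_p < alpha),
        "aic": int(delta_aic < 0),
        "bic": int(delta_bic < 0),
    }


def _majority_complex(votes: dict[str, int]) -> bool:
    # 2-2 ties go to the simpler model (parsimony)
    return sum(votes.values()) >= 3


class TrajectoryDegreeSelector(BaseEstimator):
    """Fit degree 1-3 trajectory models and select the best degree.

    Hierarchical majority vote: degree 1 vs 2 over the four indices
    (F-change p < .05, LR p < .05, lower AIC, lower BIC); the winner is then
    compared against degree 3 the same way.

    Attributes
    ----------
    models_ : dict[int, TrajectoryModel]
    comparisons_ : dict[str, ModelComparison]
    best_degree_ : int
    best_model_ : TrajectoryModel
    selection_result_ : SelectionResult
    """

    def __init__(self, include_covariates: bool = True, degrees=(1, 2, 3)):
        self.include_covariates = include_covariates
        self.degrees = degrees

    def fit(self, X, y) -> "TrajectoryDegreeSelector":
        degrees = sorted(self.degrees)
        self.models_ = {
            d: TrajectoryModel(degree=d, include_covariates=self.include_covariates).fit(X, y)
            for d in degrees
        }
        self.comparisons_ = {}
        votes: dict[str, dict[str, int]] = {}
        audit: list[str] = []
        current = degrees[0]
        for d in degrees[1:]:
            comp = compare_nested(self.models_[current].result_, self.models_[d].result_)
            key = f"{current}v{d}"
            self.comparisons_[key] = comp
            v = tally_votes(
                comp.f_change.p, comp.lr_chisq[2], comp.delta_aic, comp.delta_bic
            )
            votes[key] = v
            winner = d if _majority_complex(v) else current
            audit.append(
                f"degree {current} vs {d}: votes for complex = {sum(v.values())}/4 "
                f"({v}); winner degree {winner}"
            )
            current = winner
        self.best_degree_ = current
        self.best_model_ = self.models_[current]
        self.selection_result_ = SelectionResult(current, votes, audit)
        return self


# ---------------------------------------------------------------------------
# residualization

def residualize(outcome, predictors) -> np.ndarray:
    """OLS residuals of ``outcome`` on ``predictors`` plus an intercept.

    The residuals are orthogonal to every predictor column and sum to zero.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(pd.DataFrame(predictors), dtype=float)
    design = sm.add_constant(X, has_constant="add")
    _check_rank(design, ["intercept"] + [f"x{j}" for j in range(X.shape[1])])
    return np.asarray(sm.OLS(y, design).fit().resid)


# ---------------------------------------------------------------------------
# module-level wrappers (complete-case handling)

def _complete(outcome, ages, covariates):
    df = pd.DataFrame({"y": np.asarray(outcome, dtype=float), "age": np.asarray(ages, dtype=float)})
    cov_names: list[str] = []
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        cov_names = [str(c) for c in cov.columns]
        for c in cov_names:
            df[c] = cov[c].to_numpy(dtype=float)
    df = df.dropna()
    return df["y"].to_numpy(), df[["age"] + cov_names], cov_names


def fit_trajectory(outcome, ages, covariates=None, degree: int = 1) -> FitResult:
    """Fit one trajectory model on model-wise complete rows; returns the
    :class:`FitResult`."""
    y, X, cov_names = _complete(outcome, ages, covariates)
    model = TrajectoryModel(degree=degree, include_covariates=bool(cov_names))
    return model.fit(X, y).result_


def select_best_model(outcome, ages, covariates=None) -> SelectionResult:
    """Run the degree 1-3 selection on model-wise complete rows."""
    y, X, cov_names = _complete(outcome, ages, covariates)
    sel = TrajectoryDegreeSelector(include_covariates=bool(cov_names)).fit(X, y)
    return sel.selection_result_


def predict_curve(fit_model: TrajectoryModel, new_ages, covariate_values=None) -> np.ndarray:
    """Module-level alias of :meth:`TrajectoryModel.predict_curve`."""
    return fit_model.predict_curve(new_ages, covariate_values)
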