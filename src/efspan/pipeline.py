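"""End-to-end orchestration: simulate/load -> score -> model -> compare ->
correlate, with report tables and a reproducible run log."""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .compare import DegreeMismatchError, compare_measures
from .correlations import DEFAULT_MEASURES, ef_correlations, significance_stars
from .scoring import score_participants
from .simulate import CohortSpec, age_band, simulate_cohort
from .trajectories import (
    TrajectoryDegreeSelector,
    compare_nested,
)

log = logging.getLogger("efspan")

MEASURES = list(DEFAULT_MEASURES)


@dataclass
class RunConfig:
    mode: str = "simulate"  # "simulate" | "analyze"
    input_dir: str | None = None  # analyze mode: directory with the 5 tables
    out_dir: str = "efspan_run"
    seed: int = 0
    n_participants: int = 350
    log_transform: bool = True  # False reproduces the untransformed analysis
    covariates: bool = True


def _fit_all_measures(scores: pd.DataFrame, covariates: bool):
    """Degree selection per measure on model-wise complete rows."""
    selectors: dict[str, TrajectoryDegreeSelector] = {}
    ns: dict[str, int] = {}
    cov_cols = ["fsiq", "ses_index"] if covariates else []
    for m in MEASURES:
        cols = ["age_years", m] + cov_cols
        sub = scores[cols].dropna()
        X = sub[["age_years"] + cov_cols]
        sel = TrajectoryDegreeSelector(include_covariates=covariates).fit(X, sub[m])
        selectors[m] = sel
        ns[m] = len(sub)
    return selectors, ns


def make_table3(scores: pd.DataFrame) -> pd.DataFrame:
    """Descriptives (N, mean, SD) per EF measure, overall and by age band."""
    bands = age_band(scores["age_years"])
    rows = []
    for m in MEASURES:
        row = {"measure": m, "n": int(scores[m].notna().sum())}
        row["all_mean"] = scores[m].mean()
        row["all_sd"] = scores[m].std()
        for label, grp in scores.groupby(bands, observed=False):
            row[f"band_{label}_mean"] = grp[m].mean()
            row[f"band_{label}_sd"] = grp[m].std()
        rows.append(row)
    return pd.DataFrame(rows).round(4)


def make_table4(selectors: dict) -> pd.DataFrame:
    """Goodness-of-fit indices per measure x degree with the best-model flag."""
    rows = []
    for m, sel in selectors.items():
        results = {d: mod.result_ for d, mod in sel.models_.items()}
        for d in sorted(results):
            r = results[d]
            row = {
                "measure": m,
                "degree": d,
                "n": r.n,
                "rss": r.rss,
                "r_squared": r.r_squared,
                "minus_2ll": -2 * r.loglik,
                "aic": r.aic,
                "bic": r.bic,
                "f_change": np.nan,
                "f_change_p": np.nan,
                "lr_chisq": np.nan,
                "lr_p": np.nan,
                "best": d == sel.best_degree_,
            }
            if d > 1:
                comp = compare_nested(results[d - 1], results[d])
                row["f_change"] = comp.f_change.statistic
                row["f_change_p"] = comp.f_change.p
                row["lr_chisq"] = comp.lr_chisq[0]
                row["lr_p"] = comp.lr_chisq[2]
            rows.append(row)
    return pd.DataFrame(rows).round(6)


def make_table5(scores: pd.DataFrame, degrees: dict[str, int]) -> tuple[pd.DataFrame, object]:
    """Correlation matrix with age-adjusted partial correlations in
    parentheses, star-tiered as *p<.05 **p<.01 ***p<.001."""
    cm = ef_correlations(scores, degrees)
    k = len(cm.measures)
    cells = []
    for i, a in enumerate(cm.measures):
        row = {"measure": a}
        for j, b in enumerate(cm.measures):
            if i == j:
                row[b] = "-"
            elif j > i:
                row[b] = ""
            else:
                r, p = cm.r.iloc[i, j], cm.p.iloc[i, j]
                pr, pp = cm.partial_r.iloc[i, j], cm.partial_p.iloc[i, j]
                row[b] = (
                    f"{r:.2f}{significance_stars(p)} "
                    f"({pr:.2f}{significance_stars(pp)})"
                )
        cells.append(row)
    return pd.DataFrame(cells), cm


def make_comparisons(scores: pd.DataFrame, degrees: dict[str, int]) -> pd.DataFrame:
    """Trajectory-equality tests for every measure pair sharing a degree."""
    rows = []
    for a, b in itertools.combinations(MEASURES, 2):
        row = {"measure_a": a, "measure_b": b, "degree": degrees[a]}
        try:
            res = compare_measures(scores, a, b, degrees)
            row.update(
                rss_delta=res.rss_delta,
                f=res.f_change,
                df1=res.df1,
                df2=res.df2,
                p=res.p,
                verdict=res.verdict,
            )
        except DegreeMismatchError:
            row.update(
                degree=np.nan,
                rss_delta=np.nan,
                f=np.nan,
                df1=np.nan,
                df2=np.nan,
                p=np.nan,
                verdict=f"not_compared (degrees {degrees[a]} vs {degrees[b]})",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _fits_json(selectors_cov, selectors_nocov, ns) -> dict:
    out = {}
    for m in MEASURES:
        entry = {"n": ns[m]}
        for label, sel in (("with_covariates", selectors_cov), ("age_only", selectors_nocov)):
            block = {}
            for d, mod in sel[m].models_.items():
                r = mod.result_
                block[f"degree_{d}"] = {
                    "betas": r.coefficients,
                    "r_squared": r.r_squared,
                    "f": r.f_overall.statistic,
                    "df1": r.f_overall.df1,
                    "df2": r.f_overall.df2,
                    "p": r.f_overall.p,
                    "aic": r.aic,
                    "bic": r.bic,
                }
            block["best_degree"] = sel[m].best_degree_
            entry[label] = block
        out[m] = entry
    return out


def run(config: RunConfig) -> dict:
    """Execute a full pipeline run and write all artifacts to
    ``config.out_dir``.  Returns the in-memory results."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config: %s", json.dumps(asdict(config)))
        if config.mode == "simulate":
            spec = CohortSpec(
                n_participants=config.n_participants, master_seed=config.seed
            )
            tables = simulate_cohort(spec)
            io.write_tables(tables, out_dir)
            tables["truth"].to_csv(out_dir / "cohort_truth.csv", index=False)
            with open(out_dir / "cohort_truth.json", "w") as fh:
                json.dump(
                    {
                        "master_seed": spec.master_seed,
                        "n_participants": spec.n_participants,
                        "trajectories": {
                            m: {"degree": t.degree, "coeffs": list(t.coeffs)}
                            for m, t in spec.trajectories.items()
                        },
                        "person_sd": spec.person_sd,
                        "iq_effect": spec.iq_effect,
                    },
                    fh,
                    indent=2,
                )
        else:
            if not config.input_dir:
                raise ValueError("analyze mode requires input_dir")
            tables = io.load_tables(config.input_dir)
        log.info("scoring %d participants", len(tables["participants"]))
        scores = score_participants(
            tables["participants"],
            stroop=tables.get("stroop"),
            switching=tables.get("switching"),
            ospan=tables.get("ospan"),
            toh=tables.get("toh"),
            log_transform=config.log_transform,
        )
        scores.to_csv(out_dir / "scores.csv", index=False)

        selectors, ns = _fit_all_measures(scores, covariates=config.covariates)
        selectors_nocov, _ = _fit_all_measures(scores, covariates=False)
        degrees = {m: selectors[m].best_degree_ for m in MEASURES}
        log.info("selected degrees: %s", degrees)

        table3 = make_table3(scores)
        table3.to_csv(out_dir / "table3.csv", index=False)
        table4 = make_table4(selectors)
        table4.to_csv(out_dir / "table4.csv", index=False)
        table5, corr = make_table5(scores, degrees)
        table5.to_csv(out_dir / "table5.csv", index=False)
        comparisons = make_comparisons(scores, degrees)
        comparisons.to_csv(out_dir / "trajectory_comparisons.csv", index=False)
        fits = _fits_json(selectors, {m: selectors_nocov[m] for m in MEASURES}, ns)
        with open(out_dir / "fits.json", "w") as fh:
            json.dump(fits, fh, indent=2)
        log.info("artifacts written to %s", out_dir)
        return {
            "scores": scores,
            "selectors": selectors,
            "degrees": degrees,
            "table3": table3,
            "table4": table4,
            "table5": table5,
            "correlations": corr,
            "comparisons": comparisons,
            "fits": fits,
        }
    finally:
        log.removeHandler(handler)
        handler.close()
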