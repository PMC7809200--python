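"""Trial-level scoring of the four executive-function tasks.

Converts trial tables (Stroop colour-word, alternating-runs task switching,
operation span, Tower of Hanoi) into one derived score per participant per
task:

* Stroop congruency effect (incongruent minus congruent mean log RT, reversed)
* operation-span absolute and partial scores
* task-switching switch cost and mixing cost (log RT differences, reversed)
* Tower of Hanoi absolute score (sum of step counts of perfect trials)

RT measures are computed on accurate responses slower than 200 ms and within
2.5 SD of the participant's overall task mean, log-transformed (natural log)
at the trial level, and reverse scored so that higher always means better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

BLANK = "-"

#: letters used by the operation-span task
OSPAN_LETTER_POOL = frozenset("FHJKLNPQRSTY")

#: maximum Tower of Hanoi absolute score for the 16-trial design
#: (two trials at each step count 3..10)
TOH_MAX_SCORE = 2 * sum(range(3, 11))


# ---------------------------------------------------------------------------
# RT filtering

def filter_rt_trials(
    trials: pd.DataFrame,
    min_rt_ms: float = 200.0,
    sd_mult: float = 2.5,
    trim_on_log: bool = False,
) -> pd.DataFrame:
    """Retain accurate, non-timed-out trials within the RT trimming window.

    Eligible trials are accurate, not timed out, and slower than
    ``min_rt_ms``.  The trimming mean and SD are computed once over all
    eligible trials of the participant's task (pooled across conditions,
    single pass), and trials farther than ``sd_mult`` SDs from that mean are
    dropped.  ``trim_on_log`` switches the mean/SD computation to the log-ms
    scale (the default trims on raw milliseconds).

    The input must hold one participant's trials for one task.  With fewer
    than two eligible trials the SD is undefined; the eligible trials are
    returned untrimmed and a warning is emitted.
    """
    if trials.empty:
        return trials
    ok = trials["accurate"].astype(bool) & (trials["rt_ms"] > min_rt_ms)
    if "timed_out" in trials.columns:
        ok &= ~trials["timed_out"].fillna(False).astype(bool)
    eligible = trials.loc[ok]
    if len(eligible) < 2:
        warnings.warn(
            "fewer than 2 eligible trials; SD trimming skipped", stacklevel=2
        )
        return eligible
    rt = eligible["rt_ms"].to_numpy(dtype=float)
    vals = np.log(rt) if trim_on_log else rt
    m, s = vals.mean(), vals.std(ddof=1)
    return eligible.loc[np.abs(vals - m) <= sd_mult * s]


def _condition_mean(trials: pd.DataFrame, condition: str, log_transform: bool) -> float:
    rt = trials.loc[trials["condition"] == condition, "rt_ms"].to_numpy(dtype=float)
    if rt.size == 0:
        return np.nan
    return float(np.mean(np.log(rt)) if log_transform else np.mean(rt))


# ---------------------------------------------------------------------------
# Stroop

def stroop_congruency_effect(trials: pd.DataFrame, log_transform: bool = True) -> float:
    """Reverse-scored Stroop congruency effect for one (filtered) participant.

    ``-(mean RT incongruent - mean RT congruent)`` on the trial-level log
    scale (or raw ms with ``log_transform=False``); NaN if either condition
    is absent.
    """
    inc = _condition_mean(trials, "incongruent", log_transform)
    con = _condition_mean(trials, "congruent", log_transform)
    return -(inc - con)


# ---------------------------------------------------------------------------
# Operation span

def ospan_scores(trials: pd.DataFrame) -> tuple[int, int]:
    """Absolute and partial operation-span scores for one participant.

    The absolute score sums the span lengths of perfectly recalled sets
    (recalled sequence identical to the presented sequence, position by
    position, no extra or missing entries).  The partial score counts every
    letter recalled in its correct serial position; blank markers (``-``)
    never match.  ``partial >= absolute`` always holds.
    """
    absolute = 0
    partial = 0
    for row in trials.itertuples(index=False):
        presented = str(row.presented)
        recalled = "" if pd.isna(row.recalled) else str(row.recalled)
        span = len(presented)
        hits = sum(
            1
            for i in range(min(span, len(recalled)))
            if recalled[i] != BLANK and recalled[i] == presented[i]
        )
        partial += hits
        if recalled == presented:
            absolute += span
    return absolute, partial


# ---------------------------------------------------------------------------
# Task switching

def switching_costs(
    single_trials: pd.DataFrame,
    mixed_trials: pd.DataFrame,
    log_transform: bool = True,
) -> tuple[float, float]:
    """Reverse-scored switch and mixing costs for one (filtered) participant.

    switch cost  = -(mean log RT switch  - mean log RT non-switch), mixed task
    mixing cost  = -(mean log RT non-switch, mixed - mean log RT single task)

    Block-initial mixed-task trials have no preceding task and are excluded
    from both condition means.  Any required condition set being empty makes
    the dependent cost(s) NaN.
    """
    if "trial_index" in mixed_trials.columns:
        mixed_trials = mixed_trials.loc[mixed_trials["trial_index"] > 0]
    single_rt = single_trials["rt_ms"].to_numpy(dtype=float)
    single = (
        float(np.mean(np.log(single_rt)) if log_transform else np.mean(single_rt))
        if single_rt.size
        else np.nan
    )
    nonswitch = _condition_mean(mixed_trials, "nonswitch", log_transform)
    switch = _condition_mean(mixed_trials, "switch", log_transform)
    switch_cost = -(switch - nonswitch)
    mixing_cost = -(nonswitch - single)
    return switch_cost, mixing_cost


# ---------------------------------------------------------------------------
# Tower of Hanoi

def toh_absolute_score(trials: pd.DataFrame) -> int:
    """Sum of required step counts over perfectly completed trials.

    A trial solved in exactly its minimum number of moves with no errors
    contributes its step count (e.g. 5 points for a perfect 5-step trial).
    """
    if trials.empty:
        return 0
    perfect = trials["perfect"].astype(bool)
    return int(trials.loc[perfect, "required_steps"].sum())


# ---------------------------------------------------------------------------
# SES

def ses_index(education_code, income_code, occupation_code) -> float:
    """Socio-economic status index: education (1-6) + income (1-7) +
    occupational class (1-7), range 3-20.  Any missing component makes the
    index missing; out-of-range codes are rejected."""
    codes = (education_code, income_code, occupation_code)
    if any(c is None or (isinstance(c, float) and np.isnan(c)) for c in codes):
        return np.nan
    edu, inc, occ = (int(c) for c in codes)
    for name, val, hi in (("education", edu, 6), ("income", inc, 7), ("occupation", occ, 7)):
        if not 1 <= val <= hi:
            raise ValueError(f"{name} code {val} outside 1-{hi}")
    return float(edu + inc + occ)


# ---------------------------------------------------------------------------
# Reliability

@dataclass(frozen=True)
class ReliabilityReport:
    cronbach_alpha: float
    avg_inter_item_r: float
    n_items: int
    standardized: bool


def standardized_alpha(n_items: int, avg_r: float) -> float:
    """Standardized Cronbach's alpha from the Spearman-Brown style identity
    ``k * r / (1 + (k - 1) * r)``."""
    if n_items < 2:
        raise ValueError("need at least 2 items")
    return n_items * avg_r / (1.0 + (n_items - 1) * avg_r)


def reliability(item_matrix, standardized: bool = False) -> ReliabilityReport:
    """Internal-consistency statistics for a participants x items matrix.

    Rows with any missing item are dropped (listwise deletion).  The raw
    alpha is ``k/(k-1) * (1 - sum(item variances)/variance(total))``; the
    standardized alpha is derived from the mean pairwise inter-item Pearson
    correlation.  Zero total variance makes alpha undefined (NaN).
    """
    m = np.asarray(pd.DataFrame(item_matrix).dropna(), dtype=float)
    if m.shape[1] < 2:
        raise ValueError("need at least 2 items")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 complete participant rows")
    k = m.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(m, rowvar=False)
    iu = np.triu_indices(k, 1)
    avg_r = float(np.nanmean(corr[iu]))
    if standardized:
        alpha = standardized_alpha(k, avg_r)
    else:
        total_var = m.sum(axis=1).var(ddof=1)
        if total_var == 0:
            alpha = np.nan
        else:
            alpha = k / (k - 1) * (1.0 - m.var(axis=0, ddof=1).sum() / total_var)
    return ReliabilityReport(float(alpha), avg_r, k, standardized)


# ---------------------------------------------------------------------------
# Cohort-level scoring

SCORE_COLUMNS = [
    "stroop_effect",
    "ospan_absolute",
    "ospan_partial",
    "switch_cost",
    "mixing_cost",
    "toh_score",
]


def _score_stroop(trials: pd.DataFrame, log_transform: bool) -> pd.Series:
    out = {}
    for pid, grp in trials.groupby("participant_id", sort=False):
        exp = grp.loc[grp["condition"].isin(["congruent", "incongruent", "filler"])]
        out[pid] = stroop_congruency_effect(filter_rt_trials(exp), log_transform)
    return pd.Series(out, name="stroop_effect", dtype=float)


def _score_switching(trials: pd.DataFrame, log_transform: bool) -> pd.DataFrame:
    rows = {}
    for pid, grp in trials.groupby("participant_id", sort=False):
        single = filter_rt_trials(grp.loc[grp["phase"].str.startswith("single")])
        mixed = filter_rt_trials(grp.loc[grp["phase"] == "mixed"])
        rows[pid] = switching_costs(single, mixed, log_transform)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["switch_cost", "mixing_cost"]
    ).astype(float)


def score_participants(
    participants: pd.DataFrame,
    stroop: pd.DataFrame | None = None,
    switching: pd.DataFrame | None = None,
    ospan: pd.DataFrame | None = None,
    toh: pd.DataFrame | None = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Derive per-participant EF scores and demographics from trial tables.

    Returns one row per participant in ``participants`` with age, IQ, the
    SES index, and the EF scores; a score is missing when the participant has
    no trials for that task.
    """
    df = participants.set_index("participant_id").copy()
    ses = [
        ses_index(r.education_code, r.income_code, r.occupation_code)
        if not any(
            pd.isna(v) for v in (r.education_code, r.income_code, r.occupation_code)
        )
        else np.nan
        for r in df.itertuples()
    ]
    df["ses_index"] = ses
    for col in SCORE_COLUMNS:
        df[col] = np.nan
    if stroop is not None and len(stroop):
        df["stroop_effect"] = _score_stroop(stroop, log_transform)
    if switching is not None and len(switching):
        costs = _score_switching(switching, log_transform)
        df["switch_cost"] = costs["switch_cost"]
        df["mixing_cost"] = costs["mixing_cost"]
    if ospan is not None and len(ospan):
        for pid, grp in ospan.groupby("participant_id", sort=False):
            absolute, partial = ospan_scores(grp)
            df.loc[pid, "ospan_absolute"] = absolute
            df.loc[pid, "ospan_partial"] = partial
    if toh is not None and len(toh):
        for pid, grp in toh.groupby("participant_id", sort=False):
            df.loc[pid, "toh_score"] = toh_absolute_score(grp)
    keep = ["age_years", "fsiq", "viq", "piq", "ses_index"] + SCORE_COLUMNS
    keep = [c for c in keep if c in df.columns]
    return df[keep].reset_index()


def toh_item_matrix(toh: pd.DataFrame) -> pd.DataFrame:
    """Participants x trials matrix of per-trial Tower of Hanoi scores
    (step count if perfect, else 0), for reliability analysis."""
    t = toh.copy()
    t["item_score"] = t["required_steps"].where(t["perfect"].astype(bool), 0)
    return t.pivot_table(
        index="participant_id", columns="trial_index", values="item_score"
    )
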