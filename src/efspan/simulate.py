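"""Synthetic lifespan cohort with the EF battery's task designs.

Generates trial-level data for a cohort of 10-86 year-olds so that every
pipeline stage (scoring, trajectory modelling, selection, correlation) can be
exercised without any external data.  The generator reproduces the task
designs exactly — Stroop 50/50/50 trials under adjacency constraints,
alternating-runs task switching with clockwise quadrant rotation, operation
span with three trials at each span 2-7 from the 12-letter pool, Tower of
Hanoi problems at 3-10 steps verified by shortest-path search — and draws
performance from latent abilities with configurable linear/quadratic/cubic
age trajectories.

The statistical structure: response times are log-normal with an
age-dependent baseline (general slowing); condition effects (Stroop
interference, switch and mixing shifts) are reduced by the participant's
latent ability; operation-span recall is per-letter Bernoulli with a
logistic link in working-memory ability and span; Tower of Hanoi success is
Bernoulli with a logistic link in planning ability and step count.  IQ
feeds the inhibition, working-memory and planning abilities; SES is
generated but (as in the data this emulates) carries no EF effect.  Default
trajectory shapes and amplitudes follow the study conditions: quadratic
peaks near age 30 for inhibition and working memory, opposite-signed linear
trends for switch and mixing costs, and a cubic (rise-fall-rise) shape for
planning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .toh import generate_toh_problem_set

# ---------------------------------------------------------------------------
# design constants

STROOP_COLOR_WORDS = ("RED", "GREEN", "BLUE", "YELLOW")
STROOP_FILLER_WORDS = ("TAX", "CHIEF", "MEET", "PLENTY")
STROOP_COLORS = ("red", "green", "blue", "yellow")
STROOP_TRIALS_PER_CONDITION = 50

QUADRANTS = ("UL", "UR", "LR", "LL")
#: task switches when the stimulus crosses the horizontal midline
#: (top quadrants = shape task, bottom = colour task): UR->LR and LL->UL
SWITCH_QUADRANTS = frozenset({"UL", "LR"})
SHAPES = ("circle", "triangle")
COLORS = ("blue", "yellow")
SINGLE_BLOCK_TRIALS = 32
MIXED_BLOCKS = 4
MIXED_BLOCK_TRIALS = 32
SWITCH_TIMEOUT_MS = 5000.0

OSPAN_LETTERS = "FHJKLNPQRSTY"
OSPAN_SPANS = tuple(s for s in range(2, 8) for _ in range(3))  # 3 trials each

AGE_BANDS = ((10, 18), (18, 30), (30, 50), (50, 65), (65, 87))
BAND_LABELS = ("10-17", "18-29", "30-49", "50-64", "65-86")
BAND_NS = (62, 60, 76, 74, 78)


@dataclass(frozen=True)
class Trajectory:
    """Polynomial age trajectory on age rescaled to [0, 1]."""

    degree: int
    coeffs: tuple[float, ...]  # power basis, ascending, length degree + 1

    def __call__(self, u) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(u, dtype=float), self.coeffs)


#: default latent trajectories (units: log-ms for RT tasks, logits otherwise)
DEFAULT_TRAJECTORIES: dict[str, Trajectory] = {
    # inhibition: quadratic, peak near age 32
    "stroop": Trajectory(2, (0.009, 0.145, -0.25)),
    # working memory: quadratic, peak near age 30
    "ospan": Trajectory(2, (0.1134, 1.82, -3.5)),
    # switch-cost ability improves linearly with age (cost shrinks)
    "switch": Trajectory(1, (-0.055, 0.10)),
    # mixing-cost ability declines linearly with age (cost grows)
    "mixing": Trajectory(1, (0.028, -0.15)),
    # planning: cubic, peak ~33, trough ~75, slight late rise
    "toh": Trajectory(3, (-0.77, 10.216, -23.0, 13.333)),
}

DEFAULT_PERSON_SD = {
    "stroop": 0.06,
    "ospan": 0.9,
    "switch": 0.13,
    "mixing": 0.16,
    "toh": 0.8,
}

#: latent-ability shift per SD of full-scale IQ
DEFAULT_IQ_EFFECT = {
    "stroop": 0.015,
    "ospan": 0.45,
    "switch": 0.0,
    "mixing": 0.0,
    "toh": 0.4,
}

# Table-1-style band demographics
FSIQ_BAND_MEANS = (107.35, 107.45, 104.70, 110.18, 120.65)
FSIQ_BAND_SDS = (11.07, 10.75, 9.81, 11.83, 10.43)


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for one synthetic cohort.

    The defaults encode the emulated study's conditions: n = 350 split over
    five age bands (62/60/76/74/78), band-specific IQ distributions,
    log-normal RTs whose baseline rises linearly with age (general slowing,
    placing single-task log-RT band means in the 6.27-6.59 range), condition
    effects around 0.14 (Stroop), 0.33 (switch) and 0.41 (mixing) log-ms,
    and per-task missingness of roughly 3/350, 17/350, 16/350 and 2/350.
    """

    n_participants: int = 350
    age_distribution: str = "bands"  # or "uniform"
    trajectories: dict[str, Trajectory] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES)
    )
    person_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PERSON_SD))
    iq_effect: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_IQ_EFFECT))

    # general slowing: baseline log RT = intercept + slope * age_years
    stroop_base: tuple[float, float] = (6.57, 0.0048)
    switching_base: tuple[float, float] = (6.20, 0.0048)
    stroop_trial_sd: float = 0.18
    switching_trial_sd: float = 0.22
    stroop_interference: float = 0.15  # log-ms shift of incongruent trials
    filler_shift: float = 0.025
    switch_shift: float = 0.33
    mixing_shift: float = 0.41

    stroop_accuracy: float = 0.97
    incongruent_accuracy_penalty: float = 0.02
    switching_accuracy: float = 0.95
    switch_accuracy_penalty: float = 0.03

    ospan_intercept: float = 1.7
    ospan_span_slope: float = 0.35
    ospan_trial_sd: float = 1.2
    math_accuracy: float = 0.93  # generation floor is the task's 85% criterion

    toh_intercept: float = 1.8
    toh_step_slope: float = 0.45

    missingness: dict[str, float] = field(
        default_factory=lambda: {
            "stroop": 3 / 350,
            "ospan": 16 / 350,
            "switching": 17 / 350,
            "toh": 2 / 350,
        }
    )
    ses_component_missing_rate: float = 0.01

    master_seed: int = 0

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, master_seed=int(seed))


# ---------------------------------------------------------------------------
# sequence generators


def generate_stroop_sequence(
    seed: int | np.random.Generator, n_per_condition: int = STROOP_TRIALS_PER_CONDITION
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pseudo-randomised Stroop trial sequence.

    Returns ``(practice, experimental)``: 20 practice trials (10 filler, 10
    congruent) and 50 congruent + 50 incongruent + 50 filler experimental
    trials in which no two consecutive trials share a colour word, a printed
    colour, or the word/colour pair.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def build(conditions: list[str], max_attempts: int = 200) -> pd.DataFrame:
        for _ in range(max_attempts):
            order = list(conditions)
            rng.shuffle(order)
            rows = []
            prev_word = prev_color = None
            ok = True
            for cond in order:
                if cond == "congruent":
                    options = [
                        (w, c)
                        for w, c in zip(STROOP_COLOR_WORDS, STROOP_COLORS)
                        if w != prev_word and c != prev_color
                    ]
                elif cond == "incongruent":
                    options = [
                        (w, c)
                        for w in STROOP_COLOR_WORDS
                        for c in STROOP_COLORS
                        if w.lower() != c and w != prev_word and c != prev_color
                    ]
                else:
                    options = [
                        (w, c)
                        for w in STROOP_FILLER_WORDS
                        for c in STROOP_COLORS
                        if w != prev_word and c != prev_color
                    ]
                if not options:
                    ok = False
                    break
                prev_word, prev_color = options[int(rng.integers(len(options)))]
                rows.append((cond, prev_word, prev_color))
            if ok:
                df = pd.DataFrame(rows, columns=["condition", "word", "print_color"])
                df.insert(0, "trial_index", np.arange(len(df)))
                return df
        raise RuntimeError("Stroop sequence constraint satisfaction failed")

    practice = build(["filler"] * 10 + ["congruent"] * 10)
    experimental = build(
        ["congruent"] * n_per_condition
        + ["incongruent"] * n_per_condition
        + ["filler"] * n_per_condition
    )
    return practice, experimental


def generate_switching_sequence(
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Alternating-runs task-switching sequence.

    Two single-task blocks (shape, colour) of 32 trials and four mixed
    blocks of 32 trials.  Stimuli rotate clockwise through the quadrants
    starting upper-left; in mixed blocks the top quadrants require the shape
    task and the bottom quadrants the colour task, so UR->LR and LL->UL
    transitions are switches.  The same coloured shape never repeats on
    consecutive trials.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    prev_combo = None

    def stimulus():
        nonlocal prev_combo
        while True:
            combo = (
                SHAPES[int(rng.integers(2))],
                COLORS[int(rng.integers(2))],
            )
            if combo != prev_combo:
                prev_combo = combo
                return combo

    for phase, block in (("single_shape", 0), ("single_color", 0)):
        for t in range(SINGLE_BLOCK_TRIALS):
            shape, color = stimulus()
            rows.append((phase, block, t, QUADRANTS[t % 4], "single", shape, color))
    for block in range(MIXED_BLOCKS):
        for t in range(MIXED_BLOCK_TRIALS):
            quadrant = QUADRANTS[t % 4]
            cond = "switch" if quadrant in SWITCH_QUADRANTS else "nonswitch"
            shape, color = stimulus()
            rows.append(("mixed", block, t, quadrant, cond, shape, color))
    return pd.DataFrame(
        rows,
        columns=["phase", "block", "trial_index", "quadrant", "condition", "shape", "color"],
    )


# ---------------------------------------------------------------------------
# participant simulation


def _draw_demographics(spec: CohortSpec, rng: np.random.Generator) -> dict:
    if spec.age_distribution == "uniform":
        age = float(rng.uniform(10.0, 86.0))
        band = next(i for i, (lo, hi) in enumerate(AGE_BANDS) if lo <= age < hi)
    else:
        weights = np.asarray(BAND_NS, dtype=float)
        band = int(rng.choice(len(AGE_BANDS), p=weights / weights.sum()))
        lo, hi = AGE_BANDS[band]
        age = float(rng.uniform(lo, min(hi, 86.0)))
    fsiq = float(max(rng.normal(FSIQ_BAND_MEANS[band], FSIQ_BAND_SDS[band]), 70.0))
    viq = float(fsiq + rng.normal(0.0, 5.0))
    piq = float(fsiq + rng.normal(0.0, 5.0))

    def code(mean, sd, hi):
        if rng.random() < spec.ses_component_missing_rate:
            return np.nan
        return float(np.clip(np.round(rng.normal(mean, sd)), 1, hi))

    return {
        "age_years": round(age, 2),
        "band": band,
        "fsiq": round(fsiq, 1),
        "viq": round(viq, 1),
        "piq": round(piq, 1),
        "education_code": code(4.0, 1.2, 6),
        "income_code": code(4.7, 1.7, 7),
        "occupation_code": code(4.6, 1.5, 7),
    }


def _abilities(spec: CohortSpec, u: float, z_iq: float, rng: np.random.Generator) -> dict:
    out = {}
    for m, traj in spec.trajectories.items():
        out[m] = float(
            traj(u) + spec.iq_effect[m] * z_iq + rng.normal(0.0, spec.person_sd[m])
        )
    return out


def simulate_participant(
    spec: CohortSpec, participant_id: str, seed
) -> dict[str, object]:
    """Simulate one participant's full trial-level record set.

    Returns a dict with the participant row, per-task trial DataFrames
    (absent tasks dropped by the missingness model), and the latent truth.
    """
    rng = np.random.default_rng(seed)
    demo = _draw_demographics(spec, rng)
    u = (demo["age_years"] - 10.0) / 76.0
    z_iq = (demo["fsiq"] - 110.0) / 12.0
    ability = _abilities(spec, u, z_iq, rng)
    missing = {task: bool(rng.random() < p) for task, p in spec.missingness.items()}

    out: dict[str, object] = {
        "participant": {"participant_id": participant_id, **demo},
        "truth": {
            "participant_id": participant_id,
            "u": u,
            "z_iq": z_iq,
            **{f"ability_{m}": v for m, v in ability.items()},
            **{f"missing_{t}": v for t, v in missing.items()},
        },
    }

    # Stroop
    if not missing["stroop"]:
        _, seq = generate_stroop_sequence(rng)
        base = spec.stroop_base[0] + spec.stroop_base[1] * demo["age_years"]
        interference = spec.stroop_interference - ability["stroop"]
        shift = np.where(
            seq["condition"] == "incongruent",
            interference,
            np.where(seq["condition"] == "filler", spec.filler_shift, 0.0),
        )
        log_rt = base + shift + rng.normal(0.0, spec.stroop_trial_sd, len(seq))
        acc_p = np.where(
            seq["condition"] == "incongruent",
            spec.stroop_accuracy - spec.incongruent_accuracy_penalty,
            spec.stroop_accuracy,
        )
        df = seq.copy()
        df.insert(0, "participant_id", participant_id)
        df["rt_ms"] = np.round(np.exp(log_rt), 1)
        df["accurate"] = rng.random(len(seq)) < acc_p
        out["stroop"] = df
    # Task switching
    if not missing["switching"]:
        seq = generate_switching_sequence(rng)
        base = spec.switching_base[0] + spec.switching_base[1] * demo["age_years"]
        mixing = spec.mixing_shift - ability["mixing"]
        switching = spec.switch_shift - ability["switch"]
        shift = np.where(
            seq["condition"] == "switch",
            mixing + switching,
            np.where(seq["condition"] == "nonswitch", mixing, 0.0),
        )
        log_rt = base + shift + rng.normal(0.0, spec.switching_trial_sd, len(seq))
        rt = np.exp(log_rt)
        timed_out = rt >= SWITCH_TIMEOUT_MS
        rt = np.minimum(rt, SWITCH_TIMEOUT_MS)
        acc_p = np.where(
            seq["condition"] == "switch",
            spec.switching_accuracy - spec.switch_accuracy_penalty,
            spec.switching_accuracy,
        )
        df = seq.drop(columns=["shape", "color"]).copy()
        df.insert(0, "participant_id", participant_id)
        df["rt_ms"] = np.round(rt, 1)
        df["accurate"] = (rng.random(len(seq)) < acc_p) & ~timed_out
        df["timed_out"] = timed_out
        out["switching"] = df
    # Operation span
    if not missing["ospan"]:
        spans = list(OSPAN_SPANS)
        rng.shuffle(spans)
        letters = np.array(list(OSPAN_LETTERS))
        rows = []
        for t, span in enumerate(spans):
            presented = letters[rng.choice(len(letters), size=span, replace=False)]
            trial_ability = ability["ospan"] + rng.normal(0.0, spec.ospan_trial_sd)
            p = expit(
                spec.ospan_intercept + trial_ability - spec.ospan_span_slope * (span - 4.5)
            )
            recalled = []
            for letter in presented:
                if rng.random() < p:
                    recalled.append(letter)
                elif rng.random() < 0.5:
                    recalled.append("-")
                else:
                    wrong = letter
                    while wrong == letter:
                        wrong = letters[int(rng.integers(len(letters)))]
                    recalled.append(wrong)
            math_correct = int(
                rng.binomial(span, max(spec.math_accuracy, 0.85))
            )
            rows.append(
                (participant_id, t, span, "".join(presented), "".join(recalled), math_correct, span)
            )
        out["ospan"] = pd.DataFrame(
            rows,
            columns=[
                "participant_id",
                "trial_index",
                "span",
                "presented",
                "recalled",
                "math_correct",
                "math_total",
            ],
        )
    # Tower of Hanoi
    if not missing["toh"]:
        _, problems = generate_toh_problem_set(rng)
        rows = []
        for t, prob in enumerate(problems):
            p = expit(
                spec.toh_intercept
                + ability["toh"]
                - spec.toh_step_slope * (prob.min_steps - 3)
            )
            perfect = bool(rng.random() < p)
            errors = 0 if perfect else int(rng.integers(1, 5))
            rows.append((participant_id, t, prob.min_steps, perfect, errors))
        out["toh"] = pd.DataFrame(
            rows,
            columns=["participant_id", "trial_index", "required_steps", "perfect", "error_moves"],
        )
    return out


def simulate_cohort(spec: CohortSpec) -> dict[str, pd.DataFrame]:
    """Simulate a full cohort; the master seed fully determines the output.

    Returns DataFrames keyed ``participants``, ``stroop``, ``switching``,
    ``ospan``, ``toh`` and ``truth`` (the latent parameters, for recovery
    tests).
    """
    seeds = np.random.SeedSequence(spec.master_seed).spawn(spec.n_participants)
    width = len(str(spec.n_participants))
    participants, truth = [], []
    tasks: dict[str, list[pd.DataFrame]] = {k: [] for k in ("stroop", "switching", "ospan", "toh")}
    for i, child in enumerate(seeds):
        pid = f"P{i + 1:0{width}d}"
        rec = simulate_participant(spec, pid, child)
        participants.append(rec["participant"])
        truth.append(rec["truth"])
        for task in tasks:
            if task in rec:
                tasks[task].append(rec[task])
    out = {
        "participants": pd.DataFrame(participants).drop(columns=["band"]),
        "truth": pd.DataFrame(truth),
    }
    for task, frames in tasks.items():
        out[task] = pd.concat(frames, ignore_index=True)
    return out


def age_band(ages) -> pd.Series:
    """Map ages to the five descriptive band labels."""
    ages = pd.Series(ages, dtype=float)
    bins = [lo for lo, _ in AGE_BANDS] + [AGE_BANDS[-1][1]]
    return pd.cut(ages, bins=bins, right=False, labels=BAND_LABELS)
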