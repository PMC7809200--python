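"""CSV schemas and validated loading for the trial and participant tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = {
    "participants": [
        "participant_id",
        "age_years",
        "fsiq",
        "viq",
        "piq",
        "education_code",
        "income_code",
        "occupation_code",
    ],
    "stroop": ["participant_id", "trial_index", "condition", "word", "print_color", "rt_ms", "accurate"],
    "switching": [
        "participant_id",
        "phase",
        "block",
        "trial_index",
        "quadrant",
        "condition",
        "rt_ms",
        "accurate",
        "timed_out",
    ],
    "ospan": ["participant_id", "trial_index", "span", "presented", "recalled"],
    "toh": ["participant_id", "trial_index", "required_steps", "perfect", "error_moves"],
}

TABLE_FILENAMES = {
    "participants": "participants.csv",
    "stroop": "trials_stroop.csv",
    "switching": "trials_switching.csv",
    "ospan": "trials_ospan.csv",
    "toh": "trials_toh.csv",
}


class SchemaError(ValueError):
    """Input table fails schema validation; message itemizes the problems."""


def validate_table(df: pd.DataFrame, kind: str, source: str = "<table>") -> list[str]:
    problems = []
    missing = [c for c in REQUIRED_COLUMNS[kind] if c not in df.columns]
    if missing:
        problems.append(f"{source}: missing columns {missing}")
        return problems
    if kind in ("stroop", "switching") and len(df):
        rt = pd.to_numeric(df["rt_ms"], errors="coerce")
        if rt.isna().any():
            problems.append(f"{source}: non-numeric rt_ms values")
        elif (rt <= 0).any():
            problems.append(f"{source}: rt_ms must be positive")
    if kind == "stroop" and len(df):
        bad = set(df["condition"]) - {"congruent", "incongruent", "filler"}
        if bad:
            problems.append(f"{source}: illegal stroop conditions {sorted(bad)}")
    if kind == "switching" and len(df):
        bad = set(df["condition"]) - {"single", "nonswitch", "switch"}
        if bad:
            problems.append(f"{source}: illegal switching conditions {sorted(bad)}")
    if kind == "toh" and len(df):
        steps = pd.to_numeric(df["required_steps"], errors="coerce")
        if steps.isna().any() or not steps.between(1, 15).all():
            problems.append(f"{source}: required_steps outside 1-15")
    return problems


def load_tables(input_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Load and validate the five input tables from a directory.

    Raises :class:`SchemaError` with an itemized message if any table is
    missing or malformed.
    """
    input_dir = Path(input_dir)
    tables = {}
    problems = []
    for kind, fname in TABLE_FILENAMES.items():
        path = input_dir / fname
        if not path.exists():
            problems.append(f"missing input file: {path}")
            continue
        df = pd.read_csv(path)
        problems.extend(validate_table(df, kind, fname))
        tables[kind] = df
    if problems:
        raise SchemaError("input validation failed:\n  " + "\n  ".join(problems))
    return tables


def write_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for kind, fname in TABLE_FILENAMES.items():
        if kind in tables:
            tables[kind].to_csv(out_dir / fname, index=False)
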