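import numpy as np
import pandas as pd
import pytest

from efspan.scoring import score_participants
from efspan.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant simulated cohort shared across tests."""
    spec = CohortSpec(n_participants=60, master_seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    return score_participants(
        small_cohort["participants"],
        stroop=small_cohort["stroop"],
        switching=small_cohort["switching"],
        ospan=small_cohort["ospan"],
        toh=small_cohort["toh"],
    )


def rt_frame(rts, condition="congruent", accurate=True, **extra):
    """Build a minimal RT trial table."""
    rts = np.asarray(rts, dtype=float)
    df = pd.DataFrame(
        {
            "participant_id": "p1",
            "trial_index": np.arange(1, rts.size + 1),
            "condition": condition,
            "rt_ms": rts,
            "accurate": accurate,
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df
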