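import numpy as np
import pandas as pd
import pytest

from sr2kit import Condition, TrackSpec, TrialRecord, build_tmr_sequence


@pytest.fixture
def default_spec() -> TrackSpec:
    return TrackSpec(condition=Condition("SR2", 0))


def make_track(spec: TrackSpec, correct_mask) -> list[TrialRecord]:
    """Build a trial list with a prescribed correctness pattern.

    Correct trials echo the target; incorrect ones answer a wrong color.
    """
    trials = []
    for idx, (tmr, ok) in enumerate(zip(build_tmr_sequence(spec), correct_mask)):
        trials.append(
            TrialRecord(
                trial_index=idx,
                tmr_db=tmr,
                target_color="blue",
                target_number=2,
                response_color="blue" if ok else "red",
                response_number=2,
            )
        )
    return trials


@pytest.fixture
def mini_session():
    """5-listener × 2-run headphone mini-study, deterministic."""
    from sr2kit import CohortModel, sample_cohort, simulate_study

    model = CohortModel.experiment2(n=5)
    cohort = sample_cohort(model, 11)
    schedule = [(Condition("SR2", sep), run) for run in (1, 2) for sep in (0, 45)]
    return simulate_study(cohort, schedule, seed=12)
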