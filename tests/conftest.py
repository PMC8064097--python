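import numpy as np
import pandas as pd
import pytest

from breathflow import pipeline, synthetic
from breathflow.tracer import RawTraceSession


def make_session(co2, cps=None, phase=None, participant="P1",
                 timepoint="Day0", trigger=None):
    """Minimal 1 Hz session from a CO2 series and optional cps columns."""
    co2 = np.asarray(co2, dtype=float)
    n = len(co2)
    if cps is None:
        cps = {"mz59.05": np.ones(n)}
    frame = pd.DataFrame({k: np.asarray(v, dtype=float)
                          for k, v in cps.items()})
    if phase is None:
        phase = np.where(co2 >= 1.0, "breath", "flush").astype(object)
    if trigger is None:
        trigger = (co2 >= 4.0).astype(int)
    return RawTraceSession(participant_id=participant, timepoint=timepoint,
                           time_s=np.arange(n), co2_pct=co2,
                           trigger=np.asarray(trigger),
                           cps=frame, phase=np.asarray(phase, dtype=object))


@pytest.fixture(scope="session")
def small_study():
    design = synthetic.StudyDesignSpec(n_per_group=(4, 3, 3), seed=11)
    sessions, dtab, truth = synthetic.simulate_study(
        design, synthetic.default_effects())
    return design, sessions, dtab, truth


@pytest.fixture(scope="session")
def small_analysis(small_study):
    _, sessions, dtab, _ = small_study
    return pipeline.analyze_study(sessions, dtab)


@pytest.fixture(scope="session")
def full_study():
    """Default campaign: 62 participants, 5 timepoints, duplicates."""
    design = synthetic.StudyDesignSpec(seed=42)
    sessions, dtab, truth = synthetic.simulate_study(
        design, synthetic.default_effects())
    return design, sessions, dtab, truth


@pytest.fixture(scope="session")
def full_analysis(full_study):
    _, sessions, dtab, _ = full_study
    return pipeline.analyze_study(sessions, dtab)
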