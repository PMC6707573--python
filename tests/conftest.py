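import pytest
from hypothesis import settings

import trialcea as t

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_costs():
    return t.UnitCostTable()


@pytest.fixture(scope="session")
def small_records():
    """Small synthetic trial (20/arm, seed 11) with default dropout."""
    return t.generate_trial(t.GeneratorConfig(n_per_arm=20), seed=11)


@pytest.fixture(scope="session")
def small_frame(small_records, unit_costs):
    return t.build_analysis_frame(small_records, unit_costs)


@pytest.fixture(scope="session")
def completed_frames(small_frame):
    cfg = t.ImputationConfig(m_outcome=2, seed=5)
    frame = t.impute_costs(small_frame, cfg)
    return t.impute_outcomes(frame, cfg)


@pytest.fixture(scope="session")
def big_records():
    """Large trial (2000/arm, no dropout) for parameter-recovery checks."""
    cfg = t.GeneratorConfig(
        n_per_arm=2000,
        effects={
            "ISMI": t.synthetic_trial.ArmEffects(9.75, 0.8, 0.015, 0.025, 0.003, 0.006, 0.0),
            "WLC": t.synthetic_trial.ArmEffects(3.0, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0),
        },
    )
    return cfg, t.generate_trial(cfg, seed=21)
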