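import numpy as np
import pytest

from hetfx import TrialData, ScenarioSpec, generate_trial


@pytest.fixture
def tiny_trial() -> TrialData:
    """Hand-computable 6-unit trial: arms {0,1,2} and {0,2,4}."""
    return TrialData(
        outcome=np.array([0.0, 1.0, 2.0, 0.0, 2.0, 4.0]),
        treatment=np.array([0, 0, 0, 1, 1, 1]),
    )


@pytest.fixture
def normal_trial() -> TrialData:
    """A moderately sized null trial (both arms standard normal)."""
    return generate_trial(ScenarioSpec(n_per_group=40, seed=123), 0)


@pytest.fixture
def covariate_trial() -> TrialData:
    """Null trial with one covariate influencing the outcome."""
    return generate_trial(
        ScenarioSpec(n_per_group=40, with_covariate=True, seed=321), 0
    )
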