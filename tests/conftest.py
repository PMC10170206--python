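"""Shared fixtures: one fast synthetic survey reused across test modules.

The survey fixtures use a coarsened vertical simulation (fewer particles,
larger step) purely to keep the suite quick; the physics and the
observation model are identical to the defaults.
"""

import numpy as np
import pytest

from eggdrift.inference import EggDispersalModel, ModelSpec
from eggdrift.synthetic import SyntheticConfig, simulate_survey
from eggdrift.vertical import VerticalParams, simulate_vertical_concentration

FAST_VERTICAL = VerticalParams(n_particles=2000, dt=30.0, seed=7)


@pytest.fixture(scope="session")
def vertical_field():
    """C(z, t) over 15 h from a coarsened particle simulation."""
    return simulate_vertical_concentration(FAST_VERTICAL, duration=15.0)


@pytest.fixture(scope="session")
def survey(vertical_field):
    """One full synthetic survey at the study-condition truth."""
    cfg = SyntheticConfig(vertical=FAST_VERTICAL, seed=42)
    return simulate_survey(cfg, vertical_field=vertical_field)


@pytest.fixture(scope="session")
def fitted(survey):
    """Full-model ML fit on the session survey."""
    model = EggDispersalModel(survey.observations, survey.vertical, ModelSpec.full())
    return model.fit(seed=0)
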