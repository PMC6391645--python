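import pandas as pd
import pytest

from motech_cea import synth
from motech_cea.costing import expand_rollout
from motech_cea.reference import (
    REFERENCE_BASELINE_COVERAGE,
    REFERENCE_EFFECTS,
)


@pytest.fixture(scope="session")
def registry() -> pd.DataFrame:
    """Reference-size synthetic district registry (170 districts)."""
    return synth.generate_districts(170, seed=7)


@pytest.fixture(scope="session")
def schedule(registry):
    """Reference rollout schedule expanded on the session registry."""
    return expand_rollout(None, registry)


@pytest.fixture(scope="session")
def effects_points() -> dict[str, float]:
    return dict(REFERENCE_EFFECTS)


@pytest.fixture(scope="session")
def baselines() -> dict[str, float]:
    return dict(REFERENCE_BASELINE_COVERAGE)
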