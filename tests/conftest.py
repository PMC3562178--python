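import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture()
def small_items():
    """4 respondents x 3 items; alpha = 27/29 by hand (see test)."""
    from dyadstat.scales import LikertItemMatrix

    df = pd.DataFrame(
        [[1, 1, 1], [2, 2, 1], [3, 3, 2], [4, 4, 2]],
        index=pd.Index([1, 2, 3, 4], name="respondent_id"),
        columns=["i1", "i2", "i3"],
        dtype=float,
    )
    return LikertItemMatrix("toy", df, 1, 4)


@pytest.fixture(scope="session")
def study_table():
    """One deterministic 148-dyad replicate at study-like magnitudes."""
    from dyadstat.synthetic import SCENARIO_PRESETS, generate_dyads

    return generate_dyads(SCENARIO_PRESETS["paper_magnitude"], seed=424242)


@pytest.fixture(scope="session")
def big_table():
    """A large single-outcome table for asymptotic checks."""
    from dyadstat.synthetic import DyadScenario, OutcomeSpec, generate_dyads

    scn = DyadScenario(
        n_dyads=10_000,
        outcomes={
            "qol": OutcomeSpec(-0.15, -0.02, -0.17, -0.05, (11.8, 14.5), (3.0, 2.2))
        },
    )
    return generate_dyads(scn, seed=77)
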