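import pytest

from ceakit import pipeline, synthetic
from ceakit.markov import LifeTable


@pytest.fixture(scope="session")
def value_set():
    return synthetic.generate_value_set("crosswalk", seed=12345)


@pytest.fixture(scope="session")
def prices():
    return synthetic.default_unit_cost_table()


@pytest.fixture(scope="session")
def trial(value_set):
    """Default synthetic trial (n=777, seed 1) plus ground truth."""
    frame, truth = synthetic.generate_trial(
        synthetic.SynthConfig(), seed=1, value_set=value_set
    )
    return frame, truth


@pytest.fixture(scope="session")
def work_df(trial, value_set, prices):
    """Trial table with derived utility and period-cost columns."""
    frame, _ = trial
    out = pipeline.attach_utilities(frame, value_set)
    return pipeline.attach_period_costs(out, prices)


@pytest.fixture(scope="session")
def life_table():
    return LifeTable(synthetic.generate_life_table())
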