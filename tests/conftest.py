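import io

import pytest

from driftlab.io import read_observations
from driftlab.noise_model import fit_noise_model
from driftlab.synthetic_data import (
    SyntheticExperimentSpec,
    SyntheticNoiseSpec,
    generate_experiment_table,
    generate_noise_table,
)


def table_to_observations(df, require_time=False):
    """Round-trip a generated table through the CSV reader (adds the cv column)."""
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_observations(buf, require_time=require_time)


@pytest.fixture(scope="session")
def noise_table():
    return generate_noise_table(SyntheticNoiseSpec(seed=7))


@pytest.fixture(scope="session")
def noise_model(noise_table):
    return fit_noise_model(noise_table, seed=7)


@pytest.fixture(scope="session")
def experiment_observations():
    """Main-experiment table with default injected drift, reader-processed."""
    df = generate_experiment_table(SyntheticExperimentSpec(seed=2))
    return table_to_observations(df, require_time=True)


@pytest.fixture(scope="session")
def nodrift_observations():
    """Main-experiment table with measurement noise only (no drift)."""
    df = generate_experiment_table(SyntheticExperimentSpec(seed=8, injected_drift=None))
    return table_to_observations(df, require_time=True)
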