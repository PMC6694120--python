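import numpy as np
import pandas as pd
import pytest

from galswitch import synthetic
from galswitch.pipeline import RunConfig, run_pipeline

SMALL_COUNTS = {
    "GAL3": {"Inducible": 6, "Uninducible": 4},
    "GAL80": {"Inducible": 4, "Constitutive": 2, "Uninducible": 2,
              "Leaky": 2},
    "GAL4": {"Inducible": 5, "Constitutive": 2, "Uninducible": 2,
             "WeakExpression": 2},
}


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(seed=11, n_events=2000, class_counts=SMALL_COUNTS,
                     stages=("simulate", "preprocess", "classify",
                             "predict", "sensors"))


@pytest.fixture(scope="session")
def small_run(small_config):
    """One reduced-scale end-to-end run shared across the suite.

    31 alleles -> ~350 genotypes x 2 conditions x 2 replicates at 2000
    events/sample: small enough to run in seconds, large enough that every
    expression class and model key is populated.
    """
    return run_pipeline(small_config)


@pytest.fixture(scope="session")
def small_truth(small_run):
    return small_run["artifacts"]["truth"]


@pytest.fixture(scope="session")
def small_records(small_run):
    return small_run["artifacts"]["records"]


@pytest.fixture(scope="session")
def small_assignments(small_run):
    return small_run["artifacts"]["assignments"]


@pytest.fixture(scope="session")
def small_doubles(small_run):
    return small_run["artifacts"]["doubles"]


@pytest.fixture(scope="session")
def sensor_panel():
    return synthetic.simulate_sensor_panel(seed=5)


def make_uniform_events(n=10000, seed=0, rate=0.5):
    """A featureless uniform scatter cloud with constant event rate."""
    from galswitch.cytometry import EventTable
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "FSC-A": rng.uniform(0, 1e5, n),
        "SSC-A": rng.uniform(0, 1e5, n),
        "FITC-A": rng.uniform(0, 1e3, n),
        "PE-A": rng.uniform(1, 1e3, n),
        "time_ms": np.sort(rng.uniform(0, 1e5, n)),
    })
    return EventTable(data=df, sample_id="uniform", sampling_rate=rate)
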