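"""Shared fixtures: schemes, study-design parameter sets, dataset builders."""
import numpy as np
import pytest

from tecfit import (
    Conditions,
    Dataset,
    GeneratorSpec,
    Observation,
    ObservableMap,
    RateParameterSet,
    build_three_step_scheme,
)
from tecfit.synthetic_data import (
    TABLE1_MINUS_NUSG,
    generate_quench_flow,
    generate_stopped_flow_trace,
)

PRODUCT_STATES = frozenset({"TEC17_pre", "TEC17_post"})


@pytest.fixture(scope="session")
def three_step_scheme():
    return build_three_step_scheme()


@pytest.fixture(scope="session")
def table1_params():
    return TABLE1_MINUS_NUSG


def make_three_step_dataset(seed: int) -> Dataset:
    """The dual-observable experiment: quench-flow product points over
    0.004-10 s (2% noise) plus a stopped-flow translocation trace (1% noise,
    500 points to 1 s after a 1.5 ms dead time)."""
    qf_spec = GeneratorSpec(
        scheme="three_step",
        params=TABLE1_MINUS_NUSG,
        assay="quench_flow",
        seed=seed,
        noise=0.02,
        n_points=12,
    )
    sf_obs = ObservableMap(
        kind="fluorescence", coefficients={"TEC17_post": 1.0}, scale=0.8, offset=0.2
    )
    sf_spec = GeneratorSpec(
        scheme="three_step",
        params=TABLE1_MINUS_NUSG,
        assay="stopped_flow",
        seed=seed + 1000,
        noise=0.01,
        n_points=500,
        duration=1.0,
        observable=sf_obs,
    )
    qf = generate_quench_flow(qf_spec)
    sf = generate_stopped_flow_trace(sf_spec)
    return Dataset(
        (
            Observation(qf, ObservableMap(kind="state_sum", product_states=PRODUCT_STATES), label="qf"),
            Observation(sf, sf_obs, label="sf"),
        )
    )


GENERIC_INITIAL = RateParameterSet(
    {"k_add": 10.0, "k_tr": 10.0, "k_rec": 0.1, "k_inact": 0.1}, slow_fraction=0.1
)
THREE_STEP_FREE = ("k_add", "k_tr", "k_rec", "k_inact", "slow_fraction")


@pytest.fixture(scope="session")
def three_step_dataset():
    return make_three_step_dataset(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
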