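import numpy as np
import pytest

from splicekin import correlation as corr
from splicekin import kinetic_models as km
from splicekin import trace_simulator as ts


@pytest.fixture(scope="session")
def layout():
    return km.default_reporter_layout()


@pytest.fixture(scope="session")
def control_model():
    """Model II.4 at the control-condition parameters."""
    return km.make_model("II.4", v=2.60, splice_mean=267.0,
                         release_mean=116.1, k_init=0.02)


@pytest.fixture(scope="session")
def control_traces(control_model, layout):
    """The experimental-scale synthetic dataset: 21 traces x 500 frames."""
    return ts.simulate_dataset(control_model, layout, n_traces=21,
                               duration=5000.0, dt=10.0,
                               noise=ts.NoiseSpec(additive_sd=0.3),
                               rng_seed=1)


@pytest.fixture(scope="session")
def control_sets(control_traces):
    return [corr.correlate_trace(t) for t in control_traces]


@pytest.fixture(scope="session")
def control_avg(control_sets):
    return corr.average_correlations(control_sets, n_boot=300, rng_seed=2)
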