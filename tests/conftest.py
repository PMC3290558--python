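import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import collmove as cm

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: fixed base seed for every stochastic fixture in the suite
SUITE_SEED = 20120229


@pytest.fixture(scope="session")
def canonical():
    return cm.make_canonical_networks()


@pytest.fixture(scope="session")
def star(canonical):
    return canonical["star"]


@pytest.fixture(scope="session")
def equal(canonical):
    return canonical["equal"]


@pytest.fixture(scope="session")
def star_calibration():
    """Kernel calibration on the star network, 10,000 replicates per kernel."""
    return cm.calibrate_kernel(
        config=cm.SimulationConfig(replicates=10_000, seed=SUITE_SEED)
    )


@pytest.fixture(scope="session")
def continuum_batches(canonical):
    """Reference-kernel batches on the six continuum networks.

    4,000 replicates per network keep Monte-Carlo error on class means
    small while the whole fixture builds in well under a minute.
    """
    out = {}
    for i, name in enumerate(cm.CONTINUUM_NAMES):
        net = canonical[name]
        cfg = cm.SimulationConfig(
            kernel=cm.REFERENCE_KERNEL, replicates=4_000, seed=SUITE_SEED + 1 + i
        )
        records = cm.run_batch(net, cfg)
        focal = net.central or "C"
        out[name] = {
            "records": records,
            "focal": focal,
            "summary": cm.summarize(records, central=focal),
            "index_exact": cm.centrality_index(
                cm.eigenvector_centrality(net), focal
            )[0],
        }
    return out


def mean_se(values):
    """Mean and its Monte-Carlo standard error."""
    values = np.asarray(values, dtype=float)
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))
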