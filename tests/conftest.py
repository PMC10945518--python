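import numpy as np
import pytest

from pioneertf.dyads import call_dyads
from pioneertf.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """The standard study conditions: 1 Mb, 40 TFs, 25% pioneers."""
    return simulate_bundle(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_dyads(default_bundle):
    b = default_bundle
    return call_dyads(b.fragments["A"], b.genome)


@pytest.fixture(scope="session")
def shl_bundle():
    """12 TFs planted at the nucleosomal DNA ends (6) or the dyad (6),
    signal:background 3:1 within nucleosome regions."""
    shl = {
        f"TF{i:03d}": ((5.5, 7.0) if i < 6 else (0.0, 1.5)) for i in range(12)
    }
    cfg = SimulationConfig(
        seed=13,
        n_tfs=12,
        pioneer_fraction=1.0,
        pioneer_nr_bias=1.0,
        pioneer_host_regions="any",
        shl_target=shl,
        low_expression_fraction=0.0,
    )
    return simulate_bundle(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
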