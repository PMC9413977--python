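import pytest
from hypothesis import settings

import bcrflow as bf

settings.register_profile("default", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def igh_library():
    return bf.build_germline_library(seed=11, n_v=4, n_j=2, chain="IGH")


@pytest.fixture(scope="session")
def sc_libraries():
    return {ch: bf.build_germline_library(11, 3, 2, ch) for ch in ("IGH", "IGK", "IGL")}


@pytest.fixture(scope="session")
def small_repertoire(igh_library):
    cfg = bf.SimulationConfig(seed=5, n_clones=12, n_sequences=60, shm_rate=0.0)
    return cfg, bf.simulate_repertoire(cfg, igh_library)
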