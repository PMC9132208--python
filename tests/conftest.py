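import numpy as np
import pytest

from svaduplicon import synthetic_genome as sg


@pytest.fixture(scope="session")
def library():
    return sg.make_element_library(seed=42, n_subfamilies=2, n_diagnostic_sites=24)


@pytest.fixture(scope="session")
def demo_sim():
    """Small mu=0 simulation shared by detector tests."""
    conf = sg.SimulationConfig(
        seed=1,
        n_contigs=2,
        contig_length=330_000,
        core_duplicon_length=12_000,
        mu=0.0,
        n_l1_insertions=6,
        n_duplication_copies=6,
        n_bp5_clusters=3,
        n_bp3_clusters=3,
        n_circular_cassettes=1,
        n_direct_repeat_sds=2,
        tsd_length_range=(8, 16),
        min_event_spacing=36_000,
    )
    return sg.simulate(conf)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
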