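import pytest

import srna_deblock as sd


@pytest.fixture(scope="session")
def refs():
    """Scaled-down reference set shared by read-only tests."""
    return sd.make_references(seed=7)


@pytest.fixture(scope="session")
def simulated(refs):
    """A default-composition, zero-error simulated library with ground truth."""
    config = sd.SimulationConfig(seed=7, n_reads=5000, error_rate=0.0)
    reads, truth = sd.simulate_library(config, refs)
    return config, reads, truth


@pytest.fixture(scope="session")
def preprocessed(simulated):
    _, reads, _ = simulated
    lib, report = sd.preprocess_reads([r.sequence for r in reads])
    return lib, report
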