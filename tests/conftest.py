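import pytest

from specfx import annotation, synthetic_data


@pytest.fixture(scope="session")
def library():
    return annotation.load_library()


@pytest.fixture(scope="session")
def default_config():
    return synthetic_data.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def fingerprint_matrix(default_config):
    return synthetic_data.generate_fingerprints(default_config)


@pytest.fixture(scope="session")
def efficacy_table(default_config):
    return synthetic_data.generate_efficacy(default_config)


@pytest.fixture(scope="session")
def decoy_peak_lists():
    """Deterministic peak lists: all library peaks in every sample plus five
    decoys per ion mode, each absent from at least one sample."""
    cfg = synthetic_data.GeneratorConfig(seed=20, n_decoy_peaks=5)
    return synthetic_data.generate_sample_peak_lists(cfg)
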