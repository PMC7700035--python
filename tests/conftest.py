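import pytest

from netpharm import SynthConfig, fxhj_docking_affinity, generate_dataset


@pytest.fixture(scope="session")
def fxhj_affinity():
    """Bundled 16-compound x 5-target FXHJ docking-affinity table."""
    return fxhj_docking_affinity()


@pytest.fixture(scope="session")
def synth():
    """One default synthetic study, shared across tests (seed 1)."""
    return generate_dataset(SynthConfig(seed=1))
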