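import pytest
from hypothesis import settings

from mdachimera import SimConfig, detect, simulate

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """The default planted-truth simulation: 100 of each chimera class,
    700 normal pairs, 200 kb reference, seed 42."""
    return simulate(SimConfig(seed=42))


@pytest.fixture(scope="session")
def sim_paths(default_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return default_dataset.emit(out / "sim")


@pytest.fixture(scope="session")
def detect_result(sim_paths, tmp_path_factory):
    """Full pipeline run on the default simulation via the truth SAM."""
    out = tmp_path_factory.mktemp("detect")
    return detect(sim_paths["sam"], sim_paths["fasta"], str(out / "run"))
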