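import pytest

from codyn import interactions
from codyn.config import PipelineConfig
from codyn.pipeline import fit_dataset
from codyn.simulate import emit_dataset, neutral_scenario, species_block_scenario


@pytest.fixture(scope="session")
def neutral_dir(tmp_path_factory):
    """Full neutral-scenario dataset written to disk (shared across tests)."""
    outdir = tmp_path_factory.mktemp("neutral_data")
    emit_dataset(neutral_scenario(seed=1), outdir)
    return outdir


@pytest.fixture(scope="session")
def neutral_dataset():
    """In-memory neutral-scenario dataset (same seed as neutral_dir)."""
    return emit_dataset(neutral_scenario(seed=1))


@pytest.fixture(scope="session")
def neutral_params(neutral_dataset):
    """Fitted kinetic parameters for every well of the neutral dataset."""
    joined = [(neutral_dataset.layout[c.culture_id], c) for c in neutral_dataset.curves]
    return fit_dataset(joined, PipelineConfig())


@pytest.fixture(scope="session")
def neutral_records(neutral_params):
    return interactions.analyze_all(neutral_params)


@pytest.fixture(scope="session")
def block_dataset():
    """Species-block scenario with planted interactions."""
    return emit_dataset(species_block_scenario(seed=2))


@pytest.fixture(scope="session")
def block_params(block_dataset):
    joined = [(block_dataset.layout[c.culture_id], c) for c in block_dataset.curves]
    return fit_dataset(joined, PipelineConfig())


@pytest.fixture(scope="session")
def block_records(block_params):
    return interactions.analyze_all(block_params)
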