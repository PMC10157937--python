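import pytest

from cgimeth.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The reference simulated dataset (defaults, seed 1), in memory."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def dataset_dir(default_dataset, tmp_path_factory):
    """The reference dataset written out as files."""
    from cgimeth.simulate import write_dataset

    outdir = tmp_path_factory.mktemp("simdata")
    write_dataset(default_dataset, outdir)
    return outdir


@pytest.fixture(scope="session")
def truth(default_dataset):
    return default_dataset.annotation.truth.set_index("gene_id")
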