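import pytest

from agroprior.config import default_config
from agroprior.io import load_inputs
from agroprior.synthetic import GeneratorSpec, generate, write_dataset


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory):
    """A 60-species fixture dataset with no missingness, written and reloaded
    through the CSV layer, together with its ground truth and config."""
    spec = GeneratorSpec(n_species=60, seed=11, missingness_economic=0.0,
                         missingness_food=0.0)
    tables, truth, gcfg = generate(spec)
    d = tmp_path_factory.mktemp("clean")
    write_dataset(tables, truth, gcfg, d)
    return load_inputs(d), truth, gcfg, d
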