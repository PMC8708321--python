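import warnings

import numpy as np
import pytest

from bbbp.data_io import MoleculeRecord, curate_free_form
from bbbp.descriptors import compute_panel
from bbbp.scaffold_split import fixed_scaffold_split
from bbbp.synthetic_data import GeneratorConfig, generate

warnings.filterwarnings("ignore", message="Stochastic Optimizer")


def make_records(rows):
    """Build MoleculeRecords from (num, name, label, smiles) tuples."""
    return [MoleculeRecord(str(n), name, int(p), s) for n, name, p, s in rows]


@pytest.fixture(scope="session")
def synth_records():
    """Medium synthetic dataset shared by read-only tests."""
    return generate(GeneratorConfig(n_molecules=600, seed=7))


@pytest.fixture(scope="session")
def curated_synth(synth_records):
    kept, _ = curate_free_form(synth_records)
    return kept


@pytest.fixture(scope="session")
def synth_panel(curated_synth):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_panel(curated_synth)


@pytest.fixture(scope="session")
def synth_labels(curated_synth):
    return np.array([r.p_np for r in curated_synth])


@pytest.fixture(scope="session")
def synth_split(curated_synth):
    return fixed_scaffold_split(curated_synth)
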