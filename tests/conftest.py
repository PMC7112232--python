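import numpy as np
import pytest
from hypothesis import settings

from ssikit.chemlib import MoleculeRecord
from ssikit.synthdata import PlantedDescriptorSpec, gen_descriptor_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_small():
    """A small planted learning set (fast to model) with its ground truth."""
    spec = PlantedDescriptorSpec(
        n_actives=20, n_inactives=1000, n_noise_descriptors=8, seed=11
    )
    table, truth = gen_descriptor_dataset(spec)
    return table, truth


@pytest.fixture(scope="session")
def planted_default():
    """The default study-condition learning set (30 actives : 6000 inactives)."""
    spec = PlantedDescriptorSpec(seed=5)
    return gen_descriptor_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def record_with_descriptors(mol_id: str, **descriptors) -> MoleculeRecord:
    """A MoleculeRecord with a hand-set descriptor vector (no chemistry needed)."""
    rec = MoleculeRecord(id=mol_id, smiles="C")
    rec.descriptors = {k: float(v) for k, v in descriptors.items()}
    return rec
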