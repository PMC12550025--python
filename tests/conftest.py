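import numpy as np
import pytest

from catgen.fixtures import FixtureSpec, make_reaction_dataset
from catgen.model import CatalystCVAE, TrainingConfig
from catgen.vocab import AtomBondVocabulary, build_vocabulary


@pytest.fixture(scope="session")
def small_vocab():
    """Node budget 20, organic + Pd palette."""
    return build_vocabulary(
        ["CCO", "c1ccccc1", "CC(=O)O", "CN", "CS", "CCl", "CF", "CP(C)C",
         "c1ccncc1", "[Pd]", "[Ni]", "[Pt]", "C#N", "C1CCNC1"],
        max_atom_types=16, max_nodes=20)


@pytest.fixture(scope="session")
def fixture_dataset():
    return make_reaction_dataset(FixtureSpec(n_records=120, seed=42))


@pytest.fixture(scope="session")
def trained_results(fixture_dataset):
    """A small fitted CVAE shared across generation/optimization tests."""
    cfg = TrainingConfig.desk(epochs=12, augment_orders=2,
                              split_ratios=(80, 10, 10))
    model = CatalystCVAE(fixture_dataset.records, config=cfg)
    return model.fit(seed=0)
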