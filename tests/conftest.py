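import numpy as np
import pytest

from cmomo.chem import parse_smiles
from cmomo.constraints import AlertLibrary
from cmomo.fixtures import load_toy_pool


@pytest.fixture(scope="session")
def pool():
    """The packaged SMILES pool (validated drug-like molecules + violators)."""
    return load_toy_pool()


@pytest.fixture(scope="session")
def pool_molecules(pool):
    return [parse_smiles(s) for s in pool]


@pytest.fixture(scope="session")
def alerts():
    return AlertLibrary.packaged()


@pytest.fixture(scope="session")
def random_smiles_1000(pool):
    """1000 valid SMILES strings: randomized (non-canonical) renderings of
    pool molecules, a deterministic stand-in for an external fixture list."""
    from rdkit import Chem

    rng = np.random.default_rng(20240917)
    out = []
    mols = [Chem.MolFromSmiles(s) for s in pool]
    while len(out) < 1000:
        m = mols[int(rng.integers(len(mols)))]
        out.append(
            Chem.MolToSmiles(m, canonical=False, doRandom=True)
        )
    return out
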