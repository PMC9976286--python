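import sys
from pathlib import Path

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from phore.molio import ConformerSet
from phore.synthdata import example_model, plant_template


def mol3d(smiles: str, mol_id: str = "mol", seed: int = 0) -> ConformerSet:
    """Small helper: one ETKDG-embedded conformer from SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    molH = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMolecule(molH, params)
    return ConformerSet(mol_id, Chem.RemoveHs(molH))


@pytest.fixture(scope="session")
def planted_model():
    return example_model()


@pytest.fixture(scope="session")
def planted_template(planted_model):
    return plant_template(planted_model)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
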