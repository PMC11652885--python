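import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from orcoscreen.registry import Compound, load_fixture


@pytest.fixture(scope="session")
def t1_records():
    return load_fixture("T1")


@pytest.fixture(scope="session")
def t3_records():
    return load_fixture("T3")


@pytest.fixture(scope="session")
def t5_records():
    return load_fixture("T5")


@pytest.fixture(scope="session")
def t6_records():
    return load_fixture("T6")


@pytest.fixture
def hexanoic_acid():
    return Compound(id="8892", name="Hexanoic acid", smiles="CCCCCC(O)=O")


def embed_3d(smiles: str, seed: int = 7) -> Chem.Mol:
    """Single embedded 3D conformer with explicit hydrogens."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    AllChem.MMFFOptimizeMolecule(mol)
    return mol


def all_anti_chain_mol(smiles: str) -> Chem.Mol:
    """Embed and force every heavy-atom torsion along the main chain to anti."""
    from rdkit.Chem import rdMolTransforms

    mol = embed_3d(smiles)
    heavy = Chem.RemoveHs(mol)
    # longest simple path torsions: set every rotatable heavy dihedral to 180
    conf = mol.GetConformer()
    for bond in mol.GetBonds():
        a2, a3 = bond.GetBeginAtom(), bond.GetEndAtom()
        if a2.GetAtomicNum() <= 1 or a3.GetAtomicNum() <= 1:
            continue
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        n2 = [n for n in a2.GetNeighbors()
              if n.GetIdx() != a3.GetIdx() and n.GetAtomicNum() > 1]
        n3 = [n for n in a3.GetNeighbors()
              if n.GetIdx() != a2.GetIdx() and n.GetAtomicNum() > 1]
        if not n2 or not n3:
            continue
        rdMolTransforms.SetDihedralDeg(
            conf, n2[0].GetIdx(), a2.GetIdx(), a3.GetIdx(), n3[0].GetIdx(), 180.0
        )
    return mol
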