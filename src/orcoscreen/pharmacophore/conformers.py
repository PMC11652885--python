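"""Seeded conformer ensemble generation (ETKDG + MMFF, RMSD dedup)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ..registry import Compound

DEFAULT_N_CONFORMERS = 100
DEFAULT_SEED = 2024
DEFAULT_DEDUP_RMSD = 0.5  # A, heavy atoms


@dataclass
class ConformerEnsemble:
    compound_id: str
    mol: Chem.Mol  # with explicit hydrogens; one RDKit conformer per member
    seed: int

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    def conformer_ids(self) -> list[int]:
        return [c.GetId() for c in self.mol.GetConformers()]

    def heavy_coords(self, conf_id: int) -> np.ndarray:
        conf = self.mol.GetConformer(conf_id)
        return np.array([
            list(conf.GetAtomPosition(a.GetIdx()))
            for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1
        ])


def _heavy_rmsd(mol: Chem.Mol, i: int, j: int, heavy: list[int]) -> float:
    return AllChem.AlignMol(mol, mol, prbCid=i, refCid=j, atomMap=[(a, a) for a in heavy])


def extended_all_anti(
    molecule: Compound | Chem.Mol | str,
    seed: int = DEFAULT_SEED,
) -> Chem.Mol:
    """Single conformer with every acyclic heavy-atom torsion set to anti
    (the fully extended zig-zag for unbranched chains)."""
    from rdkit.Chem import rdMolTransforms

    if isinstance(molecule, Compound):
        mol = molecule.to_mol()
    elif isinstance(molecule, Chem.Mol):
        mol = molecule
    else:
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"invalid SMILES {molecule!r}")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise RuntimeError("embedding failed")
    AllChem.MMFFOptimizeMolecule(molh, maxIters=500)
    conf = molh.GetConformer()
    for bond in molh.GetBonds():
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
    return molh


def max_hydrophobe_separation(mol_with_conf: Chem.Mol, conf_id: int = 0) -> float:
    """Largest pairwise distance (A) between atom-centred hydrophobic points."""
    from .features import annotate_features

    pts = [p.xyz for p in annotate_features(mol_with_conf, conf_id=conf_id)
           if p.kind == "HydA"]
    if len(pts) < 2:
        raise ValueError("fewer than two hydrophobic atoms")
    arr = np.asarray(pts)
    d = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=2)
    return float(d.max())


def generate_conformers(
    molecule: Compound | Chem.Mol | str,
    n: int = DEFAULT_N_CONFORMERS,
    seed: int = DEFAULT_SEED,
    dedup_rmsd: float = DEFAULT_DEDUP_RMSD,
    optimize: bool = True,
) -> ConformerEnsemble:
    """Generate up to ``n`` distinct conformers, reproducible for fixed seed."""
    if isinstance(molecule, Compound):
        cid, mol = molecule.id, molecule.to_mol()
    elif isinstance(molecule, Chem.Mol):
        cid, mol = molecule.GetProp("_Name") if molecule.HasProp("_Name") else "mol", molecule
    else:
        cid = molecule
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"invalid SMILES {molecule!r}")
    Chem.SanitizeMol(mol)
    molh = Chem.AddHs(mol)

    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    params.pruneRmsThresh = dedup_rmsd
    params.useRandomCoords = False
    conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
    if len(conf_ids) == 0:
        params.useRandomCoords = True
        params.randomSeed = seed + 1000
        conf_ids = AllChem.EmbedMultipleConfs(molh, numConfs=n, params=params)
    if len(conf_ids) == 0:
        raise RuntimeError(f"conformer embedding failed for compound {cid!r}")

    if optimize:
        try:
            AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
        except Exception:
            AllChem.UFFOptimizeMoleculeConfs(molh, maxIters=500)

    # greedy dedup on heavy-atom RMSD after optimization
    heavy = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() > 1]
    kept: list[int] = []
    for i in [c.GetId() for c in molh.GetConformers()]:
        if all(_heavy_rmsd(molh, i, j, heavy) > dedup_rmsd for j in kept):
            kept.append(i)
    out = Chem.Mol(molh)
    out.RemoveAllConformers()
    for new_id, i in enumerate(kept):
        conf = Chem.Conformer(molh.GetConformer(i))
        conf.SetId(new_id)
        out.AddConformer(conf, assignId=False)

    coords = np.array([
        list(out.GetConformer(c.GetId()).GetAtomPosition(0))
        for c in out.GetConformers()
    ])
    if not np.all(np.isfinite(coords)):
        raise RuntimeError(f"non-finite conformer coordinates for {cid!r}")
    return ConformerEnsemble(compound_id=cid, mol=out, seed=seed)
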