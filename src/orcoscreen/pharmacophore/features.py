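"""Deterministic feature annotation of 3D conformers.

Annotation scheme (documented SMARTS/rules):

* hydrophobic atoms: neutral carbons with fewer than 3 attached N/O
  (``[#6;!$([#6](~[#7,#8])(~[#7,#8])~[#7,#8]);+0]``); every such atom emits
  an atom-centred ``HydA`` point, and every connected group of two or more
  emits a centroid ``Hyd`` point.  Carbonyl carbons qualify — this keeps the
  extended-chain geometry consistent with the calibrated model.
* acceptors (``Acc``): any oxygen ``[#8]``, nitrile nitrogen ``[#7X1]``, or
  aromatic nitrogen without hydrogen ``[n;H0]``.
* donors (``Don``): ``[O,N;!H0]``.
* each ``Acc`` also emits projected ``Acc2`` points at ``proj_distance``
  (default 2.8 A) along idealized lone-pair directions derived from the
  acceptor's hybridization and bonded geometry.
"""

from __future__ import annotations

import math

import numpy as np
from rdkit import Chem

from .model import FeaturePoint

HYDROPHOBE_SMARTS = "[#6;+0;!$([#6](~[#7,#8])(~[#7,#8])~[#7,#8])]"
ACCEPTOR_SMARTS = ("[#8]", "[#7X1]", "[n;H0]")
DONOR_SMARTS = "[O,N;!H0]"

ACC2_PROJECTION_DISTANCE = 2.8  # A; typical heavy-atom--donor H-bond length
_TETRAHEDRAL_HALF = math.radians(109.47 / 2.0)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry: zero-length direction vector")
    return v / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    return (v * math.cos(angle)
            + np.cross(axis, v) * math.sin(angle)
            + axis * np.dot(axis, v) * (1.0 - math.cos(angle)))


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


def lone_pair_directions(mol: Chem.Mol, atom_idx: int, conf_id: int = 0) -> list[np.ndarray]:
    """Idealized lone-pair unit vectors for an acceptor atom."""
    conf = mol.GetConformer(conf_id)
    atom = mol.GetAtomWithIdx(atom_idx)
    pos = np.asarray(conf.GetAtomPosition(atom_idx))
    nbr_vecs = [
        _unit(np.asarray(conf.GetAtomPosition(n.GetIdx())) - pos)
        for n in atom.GetNeighbors()
    ]
    hyb = atom.GetHybridization()
    aromatic = atom.GetIsAromatic()

    if len(nbr_vecs) == 0:
        return []
    if len(nbr_vecs) == 1:
        u = nbr_vecs[0]
        if hyb == Chem.HybridizationType.SP:
            return [-u]  # nitrile: single axial lone pair
        if hyb == Chem.HybridizationType.SP2 or aromatic:
            # carbonyl-type: two in-plane lone pairs at 120 deg from the bond
            nbr = atom.GetNeighbors()[0]
            others = [n for n in nbr.GetNeighbors() if n.GetIdx() != atom_idx]
            if others:
                w = _unit(np.asarray(conf.GetAtomPosition(others[0].GetIdx()))
                          - np.asarray(conf.GetAtomPosition(nbr.GetIdx())))
                normal = np.cross(u, w)
                if np.linalg.norm(normal) < 1e-6:
                    normal = _any_perpendicular(u)
            else:
                normal = _any_perpendicular(u)
            return [_rotate(-u, normal, math.radians(120.0)),
                    _rotate(-u, normal, math.radians(-120.0))]
        # sp3 with one placed neighbor (implicit H): cone about the anti direction
        perp = _any_perpendicular(u)
        anti = -u
        return [_rotate(anti, perp, _TETRAHEDRAL_HALF),
                _rotate(anti, perp, -_TETRAHEDRAL_HALF)]
    if len(nbr_vecs) == 2:
        u1, u2 = nbr_vecs
        bisector_anti = -_unit(u1 + u2)
        if hyb == Chem.HybridizationType.SP2 or aromatic:
            return [bisector_anti]  # aromatic N / sp2 O: one in-plane lone pair
        normal = np.cross(u1, u2)
        if np.linalg.norm(normal) < 1e-6:
            normal = _any_perpendicular(u1)
        # tetrahedral: two lone pairs out of the bond plane
        return [
            _unit(bisector_anti * math.cos(_TETRAHEDRAL_HALF)
                  + _unit(normal) * math.sin(_TETRAHEDRAL_HALF)),
            _unit(bisector_anti * math.cos(_TETRAHEDRAL_HALF)
                  - _unit(normal) * math.sin(_TETRAHEDRAL_HALF)),
        ]
    # >= 3 neighbors: single remaining lone pair opposite the bond sum
    return [-_unit(np.sum(nbr_vecs, axis=0))]


def annotate_features(
    mol: Chem.Mol,
    conf_id: int = 0,
    proj_distance: float = ACC2_PROJECTION_DISTANCE,
) -> list[FeaturePoint]:
    """Annotate one conformer with Hyd/HydA/Acc/Acc2/Don feature points."""
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D coordinates")
    conf = mol.GetConformer(conf_id)
    points: list[FeaturePoint] = []

    hyd_pattern = Chem.MolFromSmarts(HYDROPHOBE_SMARTS)
    hyd_atoms = sorted(m[0] for m in mol.GetSubstructMatches(hyd_pattern))
    hyd_set = set(hyd_atoms)
    for idx in hyd_atoms:
        p = conf.GetAtomPosition(idx)
        points.append(FeaturePoint("HydA", (p.x, p.y, p.z), (idx,)))

    # connected groups of hydrophobic atoms -> centroid Hyd
    seen: set[int] = set()
    for start in hyd_atoms:
        if start in seen:
            continue
        group, stack = [], [start]
        while stack:
            a = stack.pop()
            if a in seen:
                continue
            seen.add(a)
            group.append(a)
            for n in mol.GetAtomWithIdx(a).GetNeighbors():
                if n.GetIdx() in hyd_set and n.GetIdx() not in seen:
                    stack.append(n.GetIdx())
        if len(group) >= 2:
            group = tuple(sorted(group))
            centroid = np.mean(
                [np.asarray(conf.GetAtomPosition(a)) for a in group], axis=0
            )
            points.append(FeaturePoint("Hyd", tuple(centroid), group))

    acc_idx: set[int] = set()
    for smarts in ACCEPTOR_SMARTS:
        for match in mol.GetSubstructMatches(Chem.MolFromSmarts(smarts)):
            acc_idx.add(match[0])
    for idx in sorted(acc_idx):
        p = np.asarray(conf.GetAtomPosition(idx))
        points.append(FeaturePoint("Acc", tuple(p), (idx,)))
        for lp in lone_pair_directions(mol, idx, conf_id):
            proj = p + proj_distance * lp
            points.append(FeaturePoint("Acc2", tuple(proj), (idx,), projected=True))

    don_pattern = Chem.MolFromSmarts(DONOR_SMARTS)
    for match in sorted(mol.GetSubstructMatches(don_pattern)):
        idx = match[0]
        p = conf.GetAtomPosition(idx)
        points.append(FeaturePoint("Don", (p.x, p.y, p.z), (idx,)))

    return points
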