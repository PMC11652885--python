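"""2D descriptors feeding the SVM filter: KierA2 and SlogP_VSA1.

Both are computed on the heavy-atom graph (hydrogens implicit).

``kier_alpha2`` implements the alpha-modified second shape index
(A + a - 1)(A + a - 2)^2 / (P2 + a)^2 with the covalent-radius correction
``a`` taken from the published Kier/Hall ratios relative to sp3 carbon.
``slogp_vsa1`` sums the per-atom approximate van der Waals surface area over
atoms whose Wildman-Crippen atomic logP contribution lies in (-0.4, -0.2].

Note: the vendor software used to produce the canonical fixture descriptor
table uses its own (unpublished) alpha and VSA parameterizations, so
recomputed values can deviate from the fixture for heteroatom-rich
molecules; the fixture values remain canonical for classifier work.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .registry import Compound

# Covalent-radius ratio corrections relative to Csp3 (r_x / r_Csp3 - 1),
# keyed by (atomic number, hybridization class).  Aromatic atoms count as sp2.
_ALPHA: dict[tuple[int, str], float] = {
    (6, "sp3"): 0.0, (6, "sp2"): -0.13, (6, "sp"): -0.22,
    (7, "sp3"): -0.04, (7, "sp2"): -0.20, (7, "sp"): -0.29,
    (8, "sp3"): -0.04, (8, "sp2"): -0.20,
    (9, "sp3"): -0.07,
    (15, "sp3"): 0.43,
    (16, "sp3"): 0.35, (16, "sp2"): 0.22,
    (17, "sp3"): 0.29,
    (35, "sp3"): 0.48,
    (53, "sp3"): 0.73,
}

_HYB = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


def _as_mol(molecule: Compound | Chem.Mol | str) -> Chem.Mol:
    if isinstance(molecule, Chem.Mol):
        return molecule
    if isinstance(molecule, Compound):
        return molecule.to_mol()
    mol = Chem.MolFromSmiles(molecule)
    if mol is None:
        raise ValueError(f"invalid SMILES {molecule!r}")
    return mol


def hall_kier_alpha(mol: Chem.Mol) -> float:
    """Sum of per-heavy-atom covalent-radius corrections (0 for sp3 carbon)."""
    total = 0.0
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if atom.GetIsAromatic():
            hyb = "sp2"
        else:
            hyb = _HYB.get(atom.GetHybridization(), "sp3")
        key = (z, hyb)
        if key not in _ALPHA:
            # halogens/others default to their sp3 entry if present
            key = (z, "sp3")
        if key not in _ALPHA:
            raise ValueError(
                f"no alpha correction for atom {atom.GetSymbol()} "
                f"(idx {atom.GetIdx()}, hybridization {hyb})"
            )
        total += _ALPHA[key]
    return total


def path2_count(mol: Chem.Mol) -> int:
    """Number of length-2 paths in the heavy-atom graph."""
    return sum(
        d * (d - 1) // 2 for d in (a.GetDegree() for a in mol.GetAtoms())
    )


def kier_alpha2(molecule: Compound | Chem.Mol | str) -> float:
    """Second alpha-modified shape index of the heavy-atom graph.

    Raises for molecules with fewer than 3 heavy atoms, where no length-2
    path exists and the index is undefined.
    """
    mol = _as_mol(molecule)
    a = mol.GetNumHeavyAtoms()
    p2 = path2_count(mol)
    if a < 3 or p2 < 1:
        raise ValueError(f"KierA2 undefined for molecules with < 3 heavy atoms (A={a})")
    alpha = hall_kier_alpha(mol)
    return (a + alpha - 1) * (a + alpha - 2) ** 2 / (p2 + alpha) ** 2


def atomic_logp_contributions(mol: Chem.Mol) -> list[float]:
    """Wildman-Crippen atomic logP contributions, one per heavy atom."""
    return [c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol)]


def atomic_vsa_contributions(mol: Chem.Mol) -> list[float]:
    """Approximate per-heavy-atom van der Waals surface areas (A^2)."""
    contribs = rdMolDescriptors._CalcLabuteASAContribs(mol)
    return list(contribs[0])


def slogp_vsa1(
    molecule: Compound | Chem.Mol | str,
    bin_lo: float = -0.4,
    bin_hi: float = -0.2,
) -> float:
    """VSA summed over atoms with atomic logP in the half-open bin (lo, hi]."""
    mol = _as_mol(molecule)
    logps = atomic_logp_contributions(mol)
    vsas = atomic_vsa_contributions(mol)
    return sum(v for lp, v in zip(logps, vsas) if bin_lo < lp <= bin_hi)


#: Descriptor registry for pair search; extend with any 2D descriptor.
DESCRIPTOR_FUNCS: dict[str, Callable[[Chem.Mol], float]] = {
    "KierA2": kier_alpha2,
    "SlogP_VSA1": slogp_vsa1,
    "MolWt": Descriptors.MolWt,
    "TPSA": Descriptors.TPSA,
    "MolLogP": Descriptors.MolLogP,
    "NumRotatableBonds": lambda m: float(Descriptors.NumRotatableBonds(m)),
    "FractionCSP3": Descriptors.FractionCSP3,
}


def descriptor_matrix(
    compounds: Sequence[Compound],
    descriptor_names: Iterable[str] = ("KierA2", "SlogP_VSA1"),
) -> pd.DataFrame:
    """Dense descriptor table, one row per compound.

    Any failure (missing structure, unparameterized atom) is aggregated into
    a single error listing every offending compound; no partial output.
    """
    names = list(descriptor_names)
    if not compounds:
        raise ValueError("empty compound list")
    unknown = [n for n in names if n not in DESCRIPTOR_FUNCS]
    if unknown:
        raise ValueError(f"unknown descriptor(s): {unknown}")

    rows, errors = [], []
    for comp in compounds:
        try:
            mol = comp.to_mol()
            rows.append([float(DESCRIPTOR_FUNCS[n](mol)) for n in names])
        except Exception as exc:  # aggregate, report all failures at once
            errors.append(f"{comp.id}: {exc}")
    if errors:
        raise ValueError(
            "descriptor computation failed for "
            f"{len(errors)} compound(s):\n" + "\n".join(errors)
        )
    index = pd.Index([c.id for c in compounds], name="compound_id")
    return pd.DataFrame(rows, index=index, columns=names)
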