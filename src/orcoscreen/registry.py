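"""Compound registry: packaged fixture tables and structure file I/O.

The six fixture tables shipped under :mod:`orcoscreen.data` are plain-text
transcriptions of the screening campaign this package models: prior
antagonists (T1), the training-screen hits (T2), the 49-VOC screen (T3),
the allosteric antagonists found in it (T4), the 32 pharmacophore hits with
their 2D descriptors (T5) and the 15 validation compounds (T6).  Rows whose
identity is not public (un-named appendix compounds needed to complete the
49-compound collection) are shipped as explicit placeholders without a
structure.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, asdict, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem

logger = logging.getLogger(__name__)

FIXTURE_TABLES = ("T1", "T2", "T3", "T4", "T5", "T6")

#: Compounds meeting the activity criterion (>=40% inhibition, i.e. <=60%
#: residual response at 100 uM agonist) are "active" in the screen's sense.
RESPONSE_CUTOFF_PCT = 60.0


@dataclass(frozen=True)
class Compound:
    """A registered compound: identity, optional structure, provenance."""

    id: str
    name: str
    smiles: str | None = None
    chemical_class: str = ""
    source_table: str = "appendix"
    isomer_mixture: bool = False

    def to_mol(self) -> Chem.Mol:
        if not self.smiles:
            raise ValueError(f"compound {self.id!r} has no structure")
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise ValueError(f"compound {self.id!r}: invalid SMILES {self.smiles!r}")
        return mol


@dataclass(frozen=True)
class ActivityRecord:
    """Ex vivo activity snapshot for one compound."""

    compound_id: str
    primary_response_pct: float | None = None
    secondary_response_pct: float | None = None
    ic50_uM: float | None = None
    mechanism: str = "untested"  # orthosteric | allosteric | inactive | untested

    def __post_init__(self) -> None:
        for v in (self.primary_response_pct, self.secondary_response_pct, self.ic50_uM):
            if v is not None and v < 0:
                raise ValueError("percentages and concentrations must be >= 0")
        if self.mechanism not in ("orthosteric", "allosteric", "inactive", "untested"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "inactive" and self.ic50_uM is not None:
            raise ValueError("inactive compounds cannot carry an IC50")


@dataclass(frozen=True)
class ScreenLabelRecord:
    """Screen-stage flags for one compound."""

    compound_id: str
    pharmacophore_hit: bool
    svm_retained: bool | None = None
    active_orthosteric: bool = False


@dataclass(frozen=True)
class FixtureRecord:
    compound: Compound
    activity: ActivityRecord
    label: ScreenLabelRecord
    extras: dict = field(default_factory=dict)


def _read_table(name: str) -> list[dict]:
    text = resources.files("orcoscreen.data").joinpath(name).read_text()
    return list(csv.DictReader(io.StringIO(text)))


def _opt_float(s: str) -> float | None:
    return float(s) if s not in ("", None) else None


def _compound(row: dict, table: str) -> Compound:
    return Compound(
        id=row["id"],
        name=row["name"],
        smiles=row["smiles"] or None,
        chemical_class=row["chemical_class"],
        source_table=table,
        isomer_mixture=row.get("isomer_mixture", "0") == "1",
    )


def load_fixture(table_id: str) -> list[FixtureRecord]:
    """Load one of the packaged fixture tables T1..T6 as immutable records."""
    if table_id not in FIXTURE_TABLES:
        raise ValueError(
            f"unknown fixture table {table_id!r}; valid ids: {', '.join(FIXTURE_TABLES)}"
        )
    loader = {
        "T1": _load_t1, "T2": _load_t2, "T3": _load_t3,
        "T4": _load_t4, "T5": _load_t5, "T6": _load_t6,
    }[table_id]
    records = loader()
    ids = [r.compound.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate compound ids in fixture {table_id}")
    return records


def _load_t1() -> list[FixtureRecord]:
    out = []
    for row in _read_table("table1.csv"):
        mech = row["antagonist_type"]
        out.append(FixtureRecord(
            compound=_compound(row, "T1"),
            activity=ActivityRecord(compound_id=row["id"], mechanism=mech),
            label=ScreenLabelRecord(
                compound_id=row["id"],
                pharmacophore_hit=(mech == "orthosteric"),
                active_orthosteric=(mech == "orthosteric"),
            ),
        ))
    return out


def _load_t2() -> list[FixtureRecord]:
    out = []
    for row in _read_table("table2.csv"):
        active = row["active_orthosteric"] == "1"
        out.append(FixtureRecord(
            compound=_compound(row, "T2"),
            activity=ActivityRecord(
                compound_id=row["id"],
                mechanism="orthosteric" if active else "inactive",
            ),
            label=ScreenLabelRecord(
                compound_id=row["id"],
                pharmacophore_hit=True,
                active_orthosteric=active,
            ),
        ))
    return out


def _load_t3() -> list[FixtureRecord]:
    out = []
    for row in _read_table("table3.csv"):
        mech = row["mechanism"]
        out.append(FixtureRecord(
            compound=_compound(row, "T3"),
            activity=ActivityRecord(
                compound_id=row["id"],
                ic50_uM=_opt_float(row["ic50_uM"]),
                mechanism=mech,
            ),
            label=ScreenLabelRecord(
                compound_id=row["id"],
                pharmacophore_hit=row["pharmacophore_hit"] == "1",
                active_orthosteric=(mech == "orthosteric"),
            ),
        ))
    return out


def _load_t4() -> list[FixtureRecord]:
    out = []
    for row in _read_table("table4.csv"):
        out.append(FixtureRecord(
            compound=_compound(row, "T4"),
            activity=ActivityRecord(
                compound_id=row["id"],
                ic50_uM=_opt_float(row["ic50_uM"]),
                mechanism="allosteric",
            ),
            label=ScreenLabelRecord(
                compound_id=row["id"],
                pharmacophore_hit=row["pharmacophore_hit"] == "1",
                active_orthosteric=False,
            ),
        ))
    return out


def _load_t5() -> list[FixtureRecord]:
    # Names/structures for T5 ids live in T2/T3; join them in.
    by_id = {}
    for tbl in ("T2", "T3"):
        for rec in load_fixture(tbl):
            by_id.setdefault(rec.compound.id, rec.compound)
    out = []
    for row in _read_table("table5.csv"):
        cid = row["id"]
        ic50 = _opt_float(row["ic50_uM"])
        src = by_id.get(cid)
        compound = Compound(
            id=cid,
            name=src.name if src else cid,
            smiles=src.smiles if src else None,
            chemical_class=src.chemical_class if src else "",
            source_table="T5",
            isomer_mixture=src.isomer_mixture if src else False,
        )
        out.append(FixtureRecord(
            compound=compound,
            activity=ActivityRecord(
                compound_id=cid,
                ic50_uM=ic50,
                mechanism="orthosteric" if ic50 is not None else "inactive",
            ),
            label=ScreenLabelRecord(
                compound_id=cid,
                pharmacophore_hit=True,
                svm_retained=row["within_svm"] == "1",
                active_orthosteric=ic50 is not None,
            ),
            extras={
                "kier_a2": float(row["kier_a2"]),
                "slogp_vsa1": float(row["slogp_vsa1"]),
                "low_confidence": row["low_confidence"] == "1",
            },
        ))
    return out


def _load_t6() -> list[FixtureRecord]:
    out = []
    for row in _read_table("table6.csv"):
        resp = float(row["response_pct"])
        retained = row["retained"] == "1"
        active = resp <= RESPONSE_CUTOFF_PCT
        out.append(FixtureRecord(
            compound=_compound(row, "T6"),
            activity=ActivityRecord(
                compound_id=row["id"],
                secondary_response_pct=resp,
                mechanism="untested",
            ),
            label=ScreenLabelRecord(
                compound_id=row["id"],
                # the pipeline's pharmacophore stage feeds the SVM, so a
                # retained compound was necessarily a pharmacophore hit
                pharmacophore_hit=retained,
                svm_retained=retained,
                active_orthosteric=active,
            ),
        ))
    return out


def read_structures(path: str | Path, format: str = "smiles_list") -> list[Compound]:
    """Read compounds from a SMILES list (``smiles [id]`` per line) or an SDF.

    Invalid records are skipped with a logged count; zero valid records is an
    error.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format not in ("smiles_list", "sdf"):
        raise ValueError(f"unknown format {format!r}; use 'smiles_list' or 'sdf'")

    compounds: list[Compound] = []
    skipped = 0
    if format == "smiles_list":
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None or mol.GetNumHeavyAtoms() < 1:
                skipped += 1
                continue
            compounds.append(Compound(id=cid, name=cid, smiles=Chem.MolToSmiles(mol)))
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier, start=1):
            if mol is None or mol.GetNumHeavyAtoms() < 1:
                skipped += 1
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
            smi = Chem.MolToSmiles(Chem.RemoveHs(mol))
            compounds.append(Compound(id=cid, name=cid, smiles=smi))
    if skipped:
        logger.warning("skipped %d unparsable record(s) in %s", skipped, path)
    if not compounds:
        raise ValueError(f"no valid structure records in {path}")
    return compounds


def write_screen_report(
    records: Sequence[ScreenLabelRecord],
    path: str | Path,
    names: dict[str, str] | None = None,
    descriptors: dict[str, tuple[float, float]] | None = None,
) -> Path:
    """Write a TSV screen report (header + one row per record, input order)."""
    if not records:
        raise ValueError("cannot write an empty screen report")
    path = Path(path)
    names = names or {}
    descriptors = descriptors or {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["compound_id", "name", "pharmacophore_hit", "svm_retained",
                    "kier_a2", "slogp_vsa1"])
        for rec in records:
            desc = descriptors.get(rec.compound_id, ("", ""))
            w.writerow([
                rec.compound_id,
                names.get(rec.compound_id, ""),
                int(rec.pharmacophore_hit),
                "" if rec.svm_retained is None else int(rec.svm_retained),
                desc[0], desc[1],
            ])
    return path


def read_screen_report(path: str | Path) -> list[ScreenLabelRecord]:
    """Inverse of :func:`write_screen_report` (flags only)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sv = row["svm_retained"]
            out.append(ScreenLabelRecord(
                compound_id=row["compound_id"],
                pharmacophore_hit=row["pharmacophore_hit"] == "1",
                svm_retained=None if sv == "" else sv == "1",
            ))
    return out


def registry_to_json(records: Iterable[FixtureRecord]) -> str:
    return json.dumps(
        [{"compound": asdict(r.compound), "activity": asdict(r.activity),
          "label": asdict(r.label), "extras": r.extras} for r in records],
        indent=2,
    )
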