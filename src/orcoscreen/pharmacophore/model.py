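"""Pharmacophore model and feature-point types.

A model is an ordered list of (kind, radius) features plus a symmetric
inter-feature distance matrix.  The shipped orthosteric-antagonist model has
four features (two centroid hydrophobes Hyd, one atom-centred hydrophobe
HydA, one projected H-bond-donor location Acc2), radii 1.0 A except 0.7 A
for HydA, and Hyd1-Hyd2 = 7.2 A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

FEATURE_KINDS = ("Hyd", "HydA", "Acc", "Acc2", "Don")

#: model-feature kind -> annotation-point kinds it accepts (kind hierarchy:
#: an atom-centred hydrophobe is a degenerate centroid)
KIND_COMPATIBILITY = {
    "Hyd": ("Hyd", "HydA"),
    "HydA": ("HydA",),
    "Acc": ("Acc",),
    "Acc2": ("Acc2",),
    "Don": ("Don",),
}

DEFAULT_RADII = {"Hyd": 1.0, "HydA": 0.7, "Acc": 1.0, "Acc2": 1.0, "Don": 1.0}


@dataclass(frozen=True)
class FeaturePoint:
    kind: str
    position: tuple[float, float, float]
    parent_atoms: tuple[int, ...]
    projected: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "Acc2" and not self.projected:
            raise ValueError("Acc2 points must be projected")
        if self.kind == "HydA" and len(self.parent_atoms) != 1:
            raise ValueError("HydA points are atom-centred (exactly one parent)")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("non-finite feature position")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class PharmacophoreModel:
    """Feature kinds + radii + inter-feature distance matrix (A)."""

    features: list[tuple[str, float]]
    distances: np.ndarray
    tolerance_scale: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        n = len(self.features)
        if self.distances.shape != (n, n):
            raise ValueError("distance matrix shape must match feature count")
        if not np.allclose(self.distances, self.distances.T):
            raise ValueError("distance matrix must be symmetric")
        off = self.distances[~np.eye(n, dtype=bool)]
        if n > 1 and np.any(off <= 0):
            raise ValueError("inter-feature distances must be positive")
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if self.distances[i, j] > self.distances[i, k] + self.distances[k, j] + 1e-9:
                        raise ValueError("distance matrix violates the triangle inequality")
        for kind, radius in self.features:
            if kind not in FEATURE_KINDS:
                raise ValueError(f"unknown feature kind {kind!r}")
            if radius <= 0:
                raise ValueError("feature radii must be positive")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def pair_tolerance(self, i: int, j: int) -> float:
        return self.tolerance_scale * (self.features[i][1] + self.features[j][1])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "features": [{"kind": k, "radius": r} for k, r in self.features],
            "distances": self.distances.tolist(),
            "tolerance_scale": self.tolerance_scale,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PharmacophoreModel":
        s = str(source)
        text = Path(s).read_text() if "\n" not in s and Path(s).suffix == ".json" else s
        d = json.loads(text)
        return cls(
            features=[(f["kind"], float(f["radius"])) for f in d["features"]],
            distances=np.asarray(d["distances"], dtype=float),
            tolerance_scale=float(d.get("tolerance_scale", 1.0)),
            provenance=d.get("provenance", ""),
        )


def load_shipped_model() -> PharmacophoreModel:
    """The calibrated orthosteric-antagonist model shipped as package data."""
    text = resources.files("orcoscreen.data").joinpath("orco_pharmacophore.json").read_text()
    return PharmacophoreModel.from_json(text)
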