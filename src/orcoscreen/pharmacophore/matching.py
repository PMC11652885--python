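"""Distance-geometry matching of annotated feature points against a model.

A conformer matches when an injective, kind-compatible assignment of its
annotation points to the model features exists such that every inter-point
distance deviates from the model distance by at most
``tolerance_scale * (radius_i + radius_j)``.  The search is a backtracking
branch-and-bound returning the assignment minimizing the maximum deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..registry import Compound
from .conformers import ConformerEnsemble, generate_conformers
from .features import annotate_features
from .model import KIND_COMPATIBILITY, FeaturePoint, PharmacophoreModel


@dataclass(frozen=True)
class MatchResult:
    compound_id: str
    matched: bool
    conformer_index: int | None = None
    assignment: dict[int, FeaturePoint] | None = None  # feature index -> point
    max_distance_error: float = float("inf")

    def __post_init__(self) -> None:
        if self.matched and self.assignment is None:
            raise ValueError("matched results must carry an assignment")


def match_conformer(
    points: list[FeaturePoint],
    model: PharmacophoreModel,
    compound_id: str = "",
) -> MatchResult:
    """Best kind-compatible assignment of points to all model features."""
    n = model.n_features
    candidates: list[list[int]] = []
    for kind, _radius in model.features:
        ok_kinds = KIND_COMPATIBILITY[kind]
        candidates.append([i for i, p in enumerate(points) if p.kind in ok_kinds])
    if any(not c for c in candidates):
        return MatchResult(compound_id, False)

    # precompute point-point distances
    coords = np.array([p.xyz for p in points])
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)

    order = sorted(range(n), key=lambda f: len(candidates[f]))
    best: dict = {"maxdev": np.inf, "assign": None}
    assign: dict[int, int] = {}

    def backtrack(depth: int, cur_max: float) -> None:
        if cur_max >= best["maxdev"]:
            return
        if depth == n:
            best["maxdev"] = cur_max
            best["assign"] = dict(assign)
            return
        f = order[depth]
        for pi in candidates[f]:
            if pi in assign.values():
                continue
            new_max = cur_max
            feasible = True
            for g, pj in assign.items():
                dev = abs(dmat[pi, pj] - model.distances[f, g])
                if dev > model.pair_tolerance(f, g):
                    feasible = False
                    break
                new_max = max(new_max, dev)
            if not feasible or new_max >= best["maxdev"]:
                continue
            assign[f] = pi
            backtrack(depth + 1, new_max)
            del assign[f]

    backtrack(0, 0.0)
    if best["assign"] is None:
        return MatchResult(compound_id, False)
    return MatchResult(
        compound_id=compound_id,
        matched=True,
        assignment={f: points[pi] for f, pi in best["assign"].items()},
        max_distance_error=float(best["maxdev"]),
    )


def match_ensemble(
    ensemble: ConformerEnsemble,
    model: PharmacophoreModel,
    proj_distance: float | None = None,
) -> MatchResult:
    """Match every conformer; matched iff any matches, keeping the best one."""
    kwargs = {} if proj_distance is None else {"proj_distance": proj_distance}
    best = MatchResult(ensemble.compound_id, False)
    for idx, conf_id in enumerate(ensemble.conformer_ids()):
        points = annotate_features(ensemble.mol, conf_id=conf_id, **kwargs)
        res = match_conformer(points, model, compound_id=ensemble.compound_id)
        if res.matched and res.max_distance_error < best.max_distance_error:
            best = MatchResult(
                compound_id=ensemble.compound_id,
                matched=True,
                conformer_index=idx,
                assignment=res.assignment,
                max_distance_error=res.max_distance_error,
            )
    return best


def screen_compound(
    molecule: Compound,
    model: PharmacophoreModel,
    n_conformers: int = 100,
    seed: int = 2024,
    dedup_rmsd: float = 0.5,
) -> MatchResult:
    """Generate an ensemble for the compound and match it against the model."""
    ensemble = generate_conformers(molecule, n=n_conformers, seed=seed,
                                   dedup_rmsd=dedup_rmsd)
    return match_ensemble(ensemble, model)
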