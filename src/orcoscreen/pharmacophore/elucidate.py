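"""Pharmacophore elucidation: enumerate candidate feature queries shared by
all actives and rank them by false-positive count on the inactives.

Candidates are drawn from the feature-point configurations of a reference
active (the one with the fewest annotation points).  Candidate inter-feature
distances keep the observed conformer geometry; the query-spacing grid
(default 0.9 A) deduplicates near-identical configurations.  A candidate
survives only if it matches 100% of the actives (active coverage 1); the
survivors are ranked ascending by inactive match count, then by feature
count descending.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from ..registry import Compound
from .conformers import ConformerEnsemble, generate_conformers
from .features import annotate_features
from .matching import match_ensemble
from .model import DEFAULT_RADII, KIND_COMPATIBILITY, PharmacophoreModel

logger = logging.getLogger(__name__)

DEFAULT_TEMPLATE = ("Hyd", "Hyd", "HydA", "Acc2")


@dataclass
class ElucidateConfig:
    templates: tuple[tuple[str, ...], ...] = (DEFAULT_TEMPLATE,)
    grid_spacing: float = 0.9
    n_conformers: int = 50
    seed: int = 2024
    tolerance_scale: float = 1.0
    radii: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    #: optional {(feature_i, feature_j): distance} clamps; candidates whose
    #: distance differs from the clamp by more than half the grid are dropped
    clamped_distances: dict = field(default_factory=dict)
    max_candidates: int | None = None


@dataclass(frozen=True)
class RankedModel:
    model: PharmacophoreModel
    active_matches: int
    inactive_matches: int


def _ensembles(compounds, cfg: ElucidateConfig) -> list[ConformerEnsemble]:
    return [
        generate_conformers(c, n=cfg.n_conformers, seed=cfg.seed)
        for c in compounds
    ]


def _candidate_models(ref: ConformerEnsemble, cfg: ElucidateConfig) -> list[PharmacophoreModel]:
    """Enumerate deduplicated candidate queries from the reference ensemble."""
    seen: set[tuple] = set()
    out: list[PharmacophoreModel] = []
    for conf_id in ref.conformer_ids():
        points = annotate_features(ref.mol, conf_id=conf_id)
        by_kind: dict[str, list[int]] = {}
        for i, p in enumerate(points):
            by_kind.setdefault(p.kind, []).append(i)
        coords = np.array([p.xyz for p in points])
        for template in cfg.templates:
            pools = [
                [i for i, p in enumerate(points) if p.kind in KIND_COMPATIBILITY[k]]
                for k in template
            ]
            for combo in itertools.product(*pools):
                if len(set(combo)) != len(combo):
                    continue
                # identical kinds are unordered: canonicalize to avoid mirrors
                skip = False
                for (ka, ia), (kb, ib) in itertools.combinations(zip(template, combo), 2):
                    if ka == kb and ia > ib:
                        skip = True
                        break
                if skip:
                    continue
                pts = coords[list(combo)]
                dmat = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
                m = len(template)
                if any(dmat[i, j] < 1e-6 for i in range(m) for j in range(i + 1, m)):
                    continue
                ok = True
                for (i, j), want in cfg.clamped_distances.items():
                    if abs(dmat[i, j] - want) > cfg.grid_spacing / 2.0:
                        ok = False
                        break
                if not ok:
                    continue
                key = (template, tuple(
                    round(dmat[i, j] / cfg.grid_spacing)
                    for i in range(m) for j in range(i + 1, m)
                ))
                if key in seen:
                    continue
                seen.add(key)
                out.append(PharmacophoreModel(
                    features=[(k, cfg.radii[k]) for k in template],
                    distances=dmat,
                    tolerance_scale=cfg.tolerance_scale,
                    provenance=f"elucidated from {ref.compound_id} conformer {conf_id}",
                ))
    return out


def elucidate(
    actives: list[Compound],
    inactives: list[Compound],
    config: ElucidateConfig | None = None,
) -> list[RankedModel]:
    """Rank candidate models covering all actives (see module docstring)."""
    cfg = config or ElucidateConfig()
    if len(actives) < 1:
        raise ValueError("at least one active is required")
    active_ens = _ensembles(actives, cfg)
    inactive_ens = _ensembles(inactives, cfg)

    # reference = active with fewest annotation points on its first conformer
    def point_count(ens: ConformerEnsemble) -> int:
        return len(annotate_features(ens.mol, conf_id=ens.conformer_ids()[0]))

    ref = min(active_ens, key=point_count)
    candidates = _candidate_models(ref, cfg)
    logger.info("enumerated %d candidate queries from %s", len(candidates), ref.compound_id)

    survivors: list[RankedModel] = []
    for cand in candidates:
        n_active = 0
        for ens in active_ens:
            if ens.compound_id == ref.compound_id or match_ensemble(ens, cand).matched:
                n_active += 1
            else:
                break  # active coverage 1: any miss disqualifies
        if n_active < len(active_ens):
            continue
        n_inactive = sum(match_ensemble(ens, cand).matched for ens in inactive_ens)
        survivors.append(RankedModel(cand, n_active, n_inactive))
        if cfg.max_candidates and len(survivors) >= cfg.max_candidates:
            break

    if not survivors:
        logger.warning(
            "no candidate query covers all %d actives at tolerance scale %.2f",
            len(actives), cfg.tolerance_scale,
        )
        return []
    survivors.sort(key=lambda r: (
        r.inactive_matches,
        -r.model.n_features,
        tuple(np.round(r.model.distances[np.triu_indices(r.model.n_features, 1)], 3)),
    ))
    return survivors
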