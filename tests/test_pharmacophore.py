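import itertools
import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from orcoscreen.pharmacophore import (
    FeaturePoint,
    PharmacophoreModel,
    annotate_features,
    generate_conformers,
    load_shipped_model,
    match_conformer,
)
from orcoscreen.pharmacophore.conformers import (
    extended_all_anti,
    max_hydrophobe_separation,
)
from orcoscreen.pharmacophore.elucidate import ElucidateConfig, elucidate
from orcoscreen.pharmacophore.matching import match_ensemble
from orcoscreen.pharmacophore.model import KIND_COMPATIBILITY
from orcoscreen.registry import Compound, load_fixture

from conftest import embed_3d


def exhaustive_match(points, model):
    """Independent oracle: enumerate every injective assignment."""
    n = model.n_features
    best = None
    for perm in itertools.permutations(range(len(points)), n):
        ok = True
        maxdev = 0.0
        for i in range(n):
            if points[perm[i]].kind not in KIND_COMPATIBILITY[model.features[i][0]]:
                ok = False
                break
        if not ok:
            continue
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(points[perm[i]].xyz - points[perm[j]].xyz)
                dev = abs(d - model.distances[i, j])
                if dev > model.pair_tolerance(i, j):
                    ok = False
                    break
                maxdev = max(maxdev, dev)
            if not ok:
                break
        if ok and (best is None or maxdev < best):
            best = maxdev
    return best


def random_points(rng, n, kinds=("Hyd", "HydA", "Acc2")):
    pts = []
    for i in range(n):
        kind = kinds[rng.integers(len(kinds))]
        pts.append(FeaturePoint(
            kind, tuple(rng.uniform(-5, 5, 3)), (i,), projected=(kind == "Acc2")
        ))
    return pts


def random_model(rng, n_feat=3):
    # build from realizable geometry so the distance matrix is embeddable
    coords = rng.uniform(-4, 4, (n_feat, 3))
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    if np.any(d[~np.eye(n_feat, dtype=bool)] < 0.5):
        return None
    kinds = [("Hyd", 1.0), ("HydA", 0.7), ("Acc2", 1.0)][:n_feat]
    return PharmacophoreModel(features=kinds, distances=d)


class TestAnnotation:
    def test_hexane_hydrophobic_no_acceptors(self):
        pts = annotate_features(embed_3d("CCCCCC"))
        kinds = [p.kind for p in pts]
        assert kinds.count("Hyd") >= 1
        assert kinds.count("Acc") == 0 and kinds.count("Acc2") == 0

    def test_ethyl_cinnamate_features(self):
        pts = annotate_features(embed_3d("CCOC(=O)/C=C/c1ccccc1"))
        kinds = [p.kind for p in pts]
        assert kinds.count("Hyd") + kinds.count("HydA") >= 2
        assert kinds.count("Acc2") >= 2  # both ester oxygens project

    def test_water_toy_projection_geometry(self):
        # hand-built water: O at origin, two H at the tetrahedral-ish angle
        mol = Chem.AddHs(Chem.MolFromSmiles("O"))
        conf = Chem.Conformer(mol.GetNumAtoms())
        conf.SetAtomPosition(0, (0.0, 0.0, 0.0))
        conf.SetAtomPosition(1, (0.9572, 0.0, 0.0))
        h2 = (0.9572 * math.cos(math.radians(104.5)),
              0.9572 * math.sin(math.radians(104.5)), 0.0)
        conf.SetAtomPosition(2, h2)
        mol.AddConformer(conf)
        acc2 = [p for p in annotate_features(mol) if p.kind == "Acc2"]
        assert len(acc2) == 2  # one point per sp3 lone pair
        for p in acc2:
            assert np.linalg.norm(p.xyz) == pytest.approx(2.8, abs=1e-6)
            assert p.projected and p.parent_atoms == (0,)
        # lone pairs are mirror images through the molecular plane
        a, b = acc2[0].xyz, acc2[1].xyz
        assert a[2] == pytest.approx(-b[2], abs=1e-6)
        assert a[:2] == pytest.approx(b[:2], abs=1e-6)
        angle = math.degrees(math.acos(np.dot(a, b) / (2.8 * 2.8)))
        assert angle == pytest.approx(109.47, abs=0.5)

    def test_nitrile_single_axial_projection(self):
        pts = annotate_features(embed_3d("CCCC#N"))
        acc2 = [p for p in pts if p.kind == "Acc2"]
        assert len(acc2) == 1

    def test_missing_coordinates_rejected(self):
        with pytest.raises(ValueError, match="no 3D"):
            annotate_features(Chem.MolFromSmiles("CCO"))

    def test_carbonyl_two_inplane_projections(self):
        pts = annotate_features(embed_3d("CCCC(C)=O"))
        acc2 = [p for p in pts if p.kind == "Acc2"]
        assert len(acc2) == 2


class TestConformers:
    def test_benzene_single_conformer(self):
        ens = generate_conformers("c1ccccc1", n=50, seed=2024)
        assert ens.n_conformers == 1

    def test_fixed_seed_reproducible(self):
        a = generate_conformers("CCCCCC(O)=O", n=50, seed=11)
        b = generate_conformers("CCCCCC(O)=O", n=50, seed=11)
        assert a.n_conformers == b.n_conformers
        assert np.allclose(a.heavy_coords(0), b.heavy_coords(0))

    def test_macrocycle_embeds(self, t3_records):
        c84 = next(r.compound for r in t3_records if r.compound.id == "84")
        ens = generate_conformers(c84, n=20, seed=2024)
        assert ens.n_conformers >= 1

    def test_invalid_smiles_rejected(self):
        with pytest.raises(ValueError):
            generate_conformers("NOT_A_SMILES", n=5)

    def test_extended_hexanoic_separation_6_4(self):
        mol = extended_all_anti("CCCCCC(O)=O")
        assert max_hydrophobe_separation(mol) == pytest.approx(6.4, abs=0.2)


class TestMatching:
    def _identity_case(self):
        model = load_shipped_model()
        pts = []
        coords = _embed_distance_matrix(model.distances)
        for (kind, _r), xyz in zip(model.features, coords):
            pts.append(FeaturePoint(kind, tuple(xyz), (len(pts),),
                                    projected=(kind == "Acc2")))
        return model, pts

    def test_identity_placement_matches_with_zero_error(self):
        model, pts = self._identity_case()
        res = match_conformer(pts, model, "toy")
        assert res.matched
        assert res.max_distance_error == pytest.approx(0.0, abs=1e-6)

    def test_no_acceptor_cannot_match(self):
        model = load_shipped_model()
        pts = annotate_features(embed_3d("CCCCCCCC"))
        assert not match_conformer(pts, model).matched

    @pytest.mark.parametrize("seed", range(8))
    def test_matcher_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, n_feat=3)
        if model is None:
            return
        pts = random_points(rng, 6)
        oracle = exhaustive_match(pts, model)
        res = match_conformer(pts, model)
        assert res.matched == (oracle is not None)
        if res.matched:
            assert res.max_distance_error == pytest.approx(oracle, abs=1e-9)

    def test_shipped_model_vs_oracle_on_real_points(self):
        model = load_shipped_model()
        pts = annotate_features(embed_3d("CCOC(=O)/C=C/c1ccccc1"))[:6]
        oracle = exhaustive_match(pts, model)
        res = match_conformer(pts, model)
        assert res.matched == (oracle is not None)

    def test_tolerance_monotone(self):
        rng = np.random.default_rng(42)
        model = random_model(rng, n_feat=3)
        pts = random_points(rng, 8)
        loose = PharmacophoreModel(
            features=[(k, r * 2) for k, r in model.features],
            distances=model.distances,
        )
        if match_conformer(pts, model).matched:
            assert match_conformer(pts, loose).matched

    def test_conformer_monotone(self):
        model = load_shipped_model()
        ens = generate_conformers("CC(=O)OC(C)(C=C)CCC=C(C)C", n=40, seed=2024)
        full = match_ensemble(ens, model)
        # drop all but the first conformer: matching can only degrade
        sub = Chem.Mol(ens.mol)
        for cid in [c.GetId() for c in sub.GetConformers()][1:]:
            sub.RemoveConformer(cid)
        from orcoscreen.pharmacophore.conformers import ConformerEnsemble
        sub_ens = ConformerEnsemble(ens.compound_id, sub, ens.seed)
        if match_ensemble(sub_ens, model).matched:
            assert full.matched

    def test_matched_result_requires_assignment(self):
        from orcoscreen.pharmacophore.matching import MatchResult
        with pytest.raises(ValueError):
            MatchResult("x", True)


class TestModelValidation:
    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            PharmacophoreModel(features=[("Hyd", 1.0), ("Hyd", 1.0)], distances=d)

    def test_triangle_inequality_enforced(self):
        d = np.array([[0, 1, 10.0], [1, 0, 1.0], [10.0, 1.0, 0]])
        with pytest.raises(ValueError, match="triangle"):
            PharmacophoreModel(
                features=[("Hyd", 1.0), ("Hyd", 1.0), ("HydA", 0.7)], distances=d)

    def test_shipped_model_radii_convention(self):
        model = load_shipped_model()
        radii = dict(model.features)
        assert radii["HydA"] == 0.7
        assert all(r == 1.0 for k, r in model.features if k != "HydA")

    def test_shipped_model_hyd_hyd_near_7_2(self):
        model = load_shipped_model()
        kinds = [k for k, _ in model.features]
        i, j = [idx for idx, k in enumerate(kinds) if k == "Hyd"][:2]
        assert model.distances[i, j] == pytest.approx(7.2, abs=0.45)

    def test_json_round_trip(self, tmp_path):
        model = load_shipped_model()
        p = tmp_path / "m.json"
        model.to_json(p)
        back = PharmacophoreModel.from_json(p)
        assert back.features == model.features
        assert np.allclose(back.distances, model.distances)
        assert back.tolerance_scale == model.tolerance_scale


class TestElucidate:
    def test_t1_recovery_small_scale(self, t1_records):
        actives = [r.compound for r in t1_records if r.activity.mechanism == "orthosteric"]
        inactives = [r.compound for r in t1_records if r.activity.mechanism == "allosteric"]
        cfg = ElucidateConfig(n_conformers=20, tolerance_scale=0.5,
                              clamped_distances={(0, 1): 7.2})
        ranked = elucidate(actives, inactives, cfg)
        assert ranked
        top = ranked[0]
        assert top.active_matches == 4
        assert top.inactive_matches == 0

    def test_single_active_no_inactives(self):
        c = Compound(id="ec", name="ethyl cinnamate", smiles="CCOC(=O)/C=C/c1ccccc1")
        ranked = elucidate([c], [], ElucidateConfig(n_conformers=5))
        assert ranked
        assert all(r.inactive_matches == 0 for r in ranked)
        assert all(r.active_matches == 1 for r in ranked)

    def test_planted_configuration_recovered(self):
        # two rigid molecules sharing the cinnamate scaffold: the elucidated
        # geometry must re-match both within the query tolerance
        a = Compound(id="a", name="ethyl cinnamate", smiles="CCOC(=O)/C=C/c1ccccc1")
        b = Compound(id="b", name="isopropyl cinnamate", smiles="CC(C)OC(=O)/C=C/c1ccccc1")
        cfg = ElucidateConfig(n_conformers=10, tolerance_scale=0.5)
        ranked = elucidate([a, b], [], cfg)
        assert ranked
        ens = generate_conformers(a, n=10, seed=2024)
        assert match_ensemble(ens, ranked[0].model).matched

    def test_no_actives_rejected(self):
        with pytest.raises(ValueError):
            elucidate([], [], ElucidateConfig())


def _embed_distance_matrix(d: np.ndarray) -> np.ndarray:
    """Classical MDS embedding of a small distance matrix into 3D."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:3]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0, None))
    return coords
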