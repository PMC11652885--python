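"""One-time calibration of the shipped pharmacophore model.

Only one inter-feature distance of the published model is printed
(Hyd1-Hyd2 = 7.2 A), so the remaining geometry is recovered by elucidation
on the known orthosteric actives (T1) with that distance clamped, and the
winning candidate is chosen by:

1. hard constraints: matches 4/4 T1 orthosteric antagonists, 0/3 T1
   allosteric antagonists and rejects hexanoic acid (a documented
   pharmacophore-stage negative), all at default ensemble settings;
2. soft score: agreement with the recorded training-screen (T2) and
   49-VOC screen (T3, incl. the T4 allosterics) hit flags.

Writes src/orcoscreen/data/orco_pharmacophore.json.

Usage: python scripts/calibrate_model.py [--quick]
"""

from __future__ import annotations

import argparse
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from orcoscreen.registry import Compound, load_fixture  # noqa: E402
from orcoscreen.pharmacophore.conformers import generate_conformers  # noqa: E402
from orcoscreen.pharmacophore.elucidate import ElucidateConfig, elucidate  # noqa: E402
from orcoscreen.pharmacophore.matching import match_ensemble  # noqa: E402

HEXANOIC = Compound(id="8892", name="Hexanoic acid", smiles="CCCCCC(O)=O")
OUT = Path(__file__).resolve().parents[1] / "src" / "orcoscreen" / "data" / "orco_pharmacophore.json"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--quick", action="store_true", help="fewer conformers (smoke run)")
    args = ap.parse_args()
    n_screen = 40 if args.quick else 100
    n_eluc = 30 if args.quick else 50

    t1 = load_fixture("T1")
    actives = [r.compound for r in t1 if r.activity.mechanism == "orthosteric"]
    allosteric = [r.compound for r in t1 if r.activity.mechanism == "allosteric"]

    # soft-scoring set: every structured compound with a printed hit flag
    flagged: list[tuple[Compound, bool]] = []
    for tbl in ("T2", "T3"):
        for rec in load_fixture(tbl):
            if rec.compound.smiles and rec.compound.id not in {c.id for c in actives}:
                flagged.append((rec.compound, rec.label.pharmacophore_hit))

    print(f"precomputing ensembles (screen n={n_screen}) ...", flush=True)
    t0 = time.time()
    ens_active = [generate_conformers(c, n=n_screen) for c in actives]
    ens_allo = [generate_conformers(c, n=n_screen) for c in allosteric]
    ens_hex = generate_conformers(HEXANOIC, n=n_screen)
    ens_flagged = [(generate_conformers(c, n=n_screen), hit) for c, hit in flagged]
    print(f"  done in {time.time() - t0:.0f}s", flush=True)

    best = None
    for scale in (0.5, 0.35, 0.25):
        cfg = ElucidateConfig(
            grid_spacing=0.9, n_conformers=n_eluc, tolerance_scale=scale,
            clamped_distances={(0, 1): 7.2},
        )
        ranked = elucidate(actives, allosteric, cfg)
        survivors = [r for r in ranked if r.inactive_matches == 0]
        print(f"scale {scale}: {len(survivors)} zero-FP candidates", flush=True)
        for r in survivors:
            model = r.model
            if not all(match_ensemble(e, model).matched for e in ens_active):
                continue
            if any(match_ensemble(e, model).matched for e in ens_allo):
                continue
            if match_ensemble(ens_hex, model).matched:
                continue
            score = sum(
                match_ensemble(e, model).matched == hit for e, hit in ens_flagged
            )
            print(f"  candidate scale={scale} score={score}/{len(ens_flagged)} "
                  f"d={[round(v, 2) for v in model.distances[[0, 0, 0, 1, 1, 2], [1, 2, 3, 2, 3, 3]]]}",
                  flush=True)
            if best is None or score > best[0]:
                best = (score, scale, model)

    if best is None:
        raise SystemExit("calibration failed: no candidate satisfies the hard constraints")
    score, scale, model = best
    model.provenance = (
        f"calibrated by elucidation on the T1 orthosteric/allosteric sets with "
        f"Hyd1-Hyd2 clamped to 7.2 A; tolerance scale {scale}; "
        f"screen-flag agreement {score}/{len(ens_flagged)}"
    )
    model.to_json(OUT)
    print(f"wrote {OUT}\n  scale={scale} agreement={score}/{len(ens_flagged)}")
    print(f"  distances:\n{model.distances.round(3)}")


if __name__ == "__main__":
    main()
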