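# orcoscreen

A two-step virtual-screening platform for discovering orthosteric
antagonists of the insect odorant receptor coreceptor (ORco), plus the
downstream assay analytics used to validate hits:

1. **Pharmacophore stage** — a 4-feature ligand-based pharmacophore
   (two centroid hydrophobes `Hyd`, one atom-centred hydrophobe `HydA`, one
   projected H-bond-donor location `Acc2`; radii 1.0 Å / 0.7 Å;
   Hyd1–Hyd2 ≈ 7.2 Å) matched against seeded conformer ensembles by
   distance geometry. Includes a model elucidator that recovers candidate
   queries from actives/inactives.
2. **SVM stage** — an RBF-kernel SVM over two 2D descriptors (KierA2,
   SlogP_VSA1) that refines pharmacophore hits into predicted orthosteric
   antagonists, with seeded 10-fold CV hyperparameter tuning and
   descriptor-pair search.

Supporting modules:

- `orcoscreen.registry` — compound registry, packaged fixture tables
  (T1–T6), SMILES/SDF input, TSV screen reports.
- `orcoscreen.descriptors` — KierA2 and SlogP_VSA1 from molecular graphs.
- `orcoscreen.metrics` — confusion counts, sensitivity, specificity and the
  power metric PM = TPR/(TPR+FPR).
- `orcoscreen.assay` — response normalization, antagonist hit calling
  (≤60% response cutoff), 4-parameter-logistic IC50 fitting,
  orthosteric/allosteric mechanism classification from agonist-dependent
  IC50 shifts, repellency index, and a seeded dose-response simulator.
- `orcoscreen.pharmacophore` — features, conformers, matching, elucidation;
  the calibrated screening model ships as package data.
- `orcoscreen.cli` — command-line orchestration.

## CLI

```sh
orcoscreen fixtures T3                 # dump a packaged fixture table as JSON
orcoscreen screen library.smi --out report.tsv
orcoscreen screen library.smi --svm-model svm.json   # two-step screen
orcoscreen train-svm --seed 0 --out svm.json
orcoscreen elucidate actives.smi inactives.smi --tolerance-scale 0.5
orcoscreen evaluate report.tsv truth.tsv
orcoscreen simulate --mechanism competitive --out plate.csv
orcoscreen fit-ic50 plate.csv
```

Screen reports are deterministic for a fixed seed (`--seed`, default 2024).
Exit codes: 0 success, 2 partial (some compounds failed), 1 fatal.

## Notes on descriptors

KierA2 uses the published covalent-radius (alpha) corrections and
SlogP_VSA1 the published Wildman–Crippen / Labute parameterizations; the
vendor software used to generate the canonical fixture descriptor table
(`table5.csv`) uses its own parameters, so recomputed values can differ for
heteroatom-rich molecules. Classifier work therefore consumes the fixture
values; `orcoscreen screen` recomputes descriptors for novel libraries.

The shipped pharmacophore model was calibrated by running the elucidator on
the known orthosteric/allosteric antagonist sets with Hyd1–Hyd2 clamped to
7.2 Å (see `scripts/calibrate_model.py`); the winning query matches 4/4
known orthosteric antagonists, 0/3 allosteric ones, rejects hexanoic acid,
and maximizes agreement with the recorded screen hit flags.
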