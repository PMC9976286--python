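# phore — 3D pharmacophore modeling and virtual screening

`phore` is a desk-scale reimplementation of the pharmacophore-based
virtual-screening workflow used to discover inhibitors of glutamate
carboxypeptidase II (GCPII), a zinc metallopeptidase whose binding cavity
comprises the S1 and S1′ pockets and an arene-binding exosite. The package is
for computational chemists who want a fully scriptable, reproducible version
of each stage of such a campaign: feature perception, model building,
multiconformer screening, enrichment validation and hit triage — with
synthetic ground-truth data so every stage is testable without licensed
libraries or proprietary modeling software.

## What it implements

**Feature perception.** A pharmacophore feature is a typed tolerance sphere:
negatively/positively ionizable groups (NI/PI), hydrogen-bond donors and
acceptors (HBD/HBA), hydrophobic contacts (HC), aromatic rings (AI) and
metal-binding groups (MB). Perception is rule-based (SMARTS plus cluster/ring
detection) under a fixed physiological-pH ionization table.

**Model building.** Structure-based models keep the ligand features of a
protein–ligand complex that have a complementary pocket partner under
crystallographic contact criteria (H-bond 2.5–3.8 Å, salt bridge ≤ 5.5 Å,
ring–ring ≤ 5.0 Å, ligand–metal ≤ 2.8 Å, hydrophobic 1.0–5.0 Å), then add
exclusion volumes (Xvols) — forbidden spheres on pocket atoms within 5 Å of
the ligand. Ligand-based models use the shared-feature mode: align training
actives onto a reference and keep only features present in every compound.
Refinement is by explicit single edits (remove/resize features,
add/remove/resize Xvols) with a before/after enrichment report.

**Screening.** A conformer matches a model when a kind-compatible assignment
of its perceived features onto the model features exists (found by clique
detection over pairs whose inter-feature distances agree within summed
tolerances) such that, after least-squares rigid superposition, every model
feature holds its partner inside its tolerance sphere and no ligand heavy
atom sits inside an Xvol. The fit score is

    fit = Σ_i (1 − d_i / tol_i)        (0 ≤ fit ≤ n_features)

**Validation.** From confusion counts (TP/FP/TN/FN) over a labelled
actives/decoys database of size N = A + D:

    sensitivity = TP/(TP+FN)       specificity = TN/(TN+FP)
    YoA = TP/(TP+FP)               accuracy = (TP+TN)/N
    EF  = YoA · N/A                EF_max = N/A

plus the ROC AUC (rank-sum with midrank ties, non-hits scored 0), and
property-matched decoy selection (property envelope + fingerprint diversity
clustering).

**Triage.** Substrate-like hits (glutamate moiety) are removed, all hits of
models with fewer than 10 hits are kept, near-duplicates are grouped by
ECFP4 Tanimoto single linkage, and consensus hits (retrieved by ≥ 2 models)
are tabulated. Scaffold novelty is the maximum Tanimoto against known
actives.

## Worked example

```python
from phore.synthdata import PlantSpec, example_model, generate_planted_library
from phore.screen import screen_library
from phore.valmetrics import confusion, metrics

model = example_model()                   # NI + HBA + AI + PI over ~12 Å
lib, labels = generate_planted_library(
    PlantSpec(model, n_actives=10, n_decoys=100, noise_sd=0.0, seed=20240901))
records = screen_library([model], lib)
rep = metrics(confusion(records, labels, model.name))
print(rep.display())
```

prints

```
{'TP': 10, 'FP': 0, 'TN': 100, 'FN': 0, 'n_actives': 10,
 'decoy_hitrate_pct': 0.0, 'accuracy': 1.0, 'yoa': 1.0,
 'ef': 11.0, 'ef_max': 11.0, 'ef_ratio': 1.0,
 'sensitivity': 1.0, 'specificity': 1.0}
```

All ten planted actives are retrieved and none of the hundred
geometry-violating decoys match, so the enrichment factor reaches its
theoretical maximum EF_max = (10+100)/10 = 11.

The same stages are available from the shell via the `phore` command
(`build-sb`, `build-lb`, `refine`, `screen`, `validate`, `make-decoys`,
`triage`, `synth`, `run`), and the `analysis/` directory contains numbered
drivers that regenerate every table under `results/`:

```bash
python analysis/01_simulate.py      # toy complex, planted libraries, decoys
python analysis/02_build_models.py  # structure- and ligand-based models
python analysis/03_screen.py        # planted screens, three decoy modes
python analysis/04_validate.py      # enrichment metrics and noise sweep
python analysis/05_triage.py        # consensus accounting and triage
```

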