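#!/usr/bin/env python
"""Build the two model flavours from the simulated inputs.

Structure-based: perceive ligand features in the toy complex, keep those with
a complementary pocket partner, and decorate with exclusion volumes on pocket
atoms.  Ligand-based: shared-feature model over eight training scaffolds that
share a large acceptor/anion arrangement (spread > 15 Å), wired differently
per molecule so only the common geometry survives.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from phore.featperc import FeatureKind, PharmacophoreFeature
from phore.model import PharmacophoreModel, write_model
from phore.modelgen import (add_exclusion_volumes, detect_interactions,
                            shared_feature_model)
from phore.molio import read_complex
from phore.synthdata import plant_template

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
MODELS = RESULTS / "models"


def main() -> None:
    MODELS.mkdir(parents=True, exist_ok=True)

    # --- structure-based -------------------------------------------------
    template_smiles = (RESULTS / "data" / "toy_complex_ligand.smi") \
        .read_text().split()[0]
    protein, ligand = read_complex(RESULTS / "data" / "toy_complex.pdb",
                                   "LIG", template_smiles)
    sb = detect_interactions(protein, ligand, name="sb_toy")
    sb = add_exclusion_volumes(sb, protein, ligand, shell=5.0)
    write_model(sb, MODELS / "sb_toy.phm")
    print(f"structure-based model: {sb.n_features} features "
          f"({', '.join(sorted(f.kind.value for f in sb.features))}), "
          f"{sb.n_xvols} Xvols -> {MODELS / 'sb_toy.phm'}")

    # --- ligand-based shared-feature -------------------------------------
    anchor = [
        PharmacophoreFeature(FeatureKind.NI, (0.0, 0.0, 0.0)),
        PharmacophoreFeature(FeatureKind.HBA, (5.0, 2.0, 0.0)),
        PharmacophoreFeature(FeatureKind.HBA, (9.0, -2.0, 1.0)),
        PharmacophoreFeature(FeatureKind.HBA, (12.0, 3.0, -1.0)),
        PharmacophoreFeature(FeatureKind.HBA, (16.0, 0.0, 0.0)),
    ]
    rng = np.random.default_rng(8)
    training = []
    for i in range(8):
        order = list(range(len(anchor)))
        if i:
            rng.shuffle(order)
        m = PharmacophoreModel(f"train{i}", [anchor[j] for j in order])
        training.append(plant_template(m, f"train{i}"))
    lb = shared_feature_model(training, "train0", name="lb_shared")
    write_model(lb, MODELS / "lb_shared.phm")
    centers = lb.feature_centers()
    spread = float(np.max(np.linalg.norm(
        centers[:, None] - centers[None, :], axis=-1)))
    counts = {k.value: v for k, v in lb.kind_counts().items()}
    print(f"shared-feature model: {lb.n_features} features {counts}, "
          f"max pairwise spread {spread:.1f} Å -> {MODELS / 'lb_shared.phm'}")

    pd.DataFrame([
        {"model": "sb_toy", "n_features": sb.n_features,
         "n_xvols": sb.n_xvols},
        {"model": "lb_shared", "n_features": lb.n_features,
         "n_xvols": lb.n_xvols},
    ]).to_csv(RESULTS / "model_compositions.csv", index=False)


if __name__ == "__main__":
    main()
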