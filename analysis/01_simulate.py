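#!/usr/bin/env python
"""Generate the study's synthetic inputs and summarise them.

Produces: a toy binding pocket with a ligand exhibiting known contacts
(written as a PDB fixture), planted active/decoy libraries for the reference
model under each decoy mode, and a property-matched decoy selection from a
synthetic compound pool.  Summary tables go to results/.
"""
from pathlib import Path

import pandas as pd
from rdkit import Chem

from phore.featperc import FeatureKind, perceive_features
from phore.molio import ConformerSet
from phore.synthdata import (PlantSpec, example_model,
                             generate_planted_library, generate_toy_complex,
                             plant_template)
from phore.valmetrics import select_decoys

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"
SEED = 20240901


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    # toy complex covering four interaction classes
    kinds = [FeatureKind.NI, FeatureKind.HBD, FeatureKind.HBA, FeatureKind.HC]
    tc = generate_toy_complex(kinds, seed=SEED)
    pdb_path = tc.write(DATA / "toy_complex.pdb")
    (DATA / "toy_complex_ligand.smi").write_text(tc.ligand_template + " LIG\n")
    print(f"toy complex with {len(kinds)} planted contacts -> {pdb_path}")

    # planted libraries for the reference model, one per decoy mode
    model = example_model()
    template = plant_template(model)
    rows = []
    for mode in PlantSpec.DECOY_MODES:
        if mode == "xvol_clash":
            continue  # needs a model with Xvols; exercised in 03_screen
        lib, labels = generate_planted_library(
            PlantSpec(model, 10, 100, 0.0, mode, seed=SEED))
        rows.append({"decoy_mode": mode, "n_actives": len(labels.actives()),
                     "n_decoys": len(labels.decoys()),
                     "atoms_per_molecule": lib[0].n_atoms})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "planted_libraries.csv", index=False)
    print(df.to_string(index=False))
    feats = perceive_features(template)
    print(f"template scaffold: {template.n_atoms} atoms, "
          f"{len(feats)} perceived features "
          f"({', '.join(sorted(f.kind.value for f in feats))})")

    # property-matched decoy selection from a synthetic pool
    actives = [ConformerSet("act0", Chem.MolFromSmiles("CCCCCO")),
               ConformerSet("act1", Chem.MolFromSmiles("CCCCCCCCCO"))]
    pool = []
    for k in range(3, 12):
        for pat in ("{}CO", "CC(C){}O", "{}OC", "{}OCC", "CC(C){}OC",
                    "{}C(C)CO"):
            smiles = pat.format("C" * k)
            mol = Chem.MolFromSmiles(smiles)
            if mol is not None:
                pool.append(ConformerSet(f"pool{len(pool):03d}", mol))
    decoys = select_decoys(pool, actives, n=25, seed=SEED)
    pd.DataFrame({"mol_id": [d.mol_id for d in decoys],
                  "smiles": [Chem.MolToSmiles(d.mol) for d in decoys]}) \
        .to_csv(RESULTS / "decoy_selection.csv", index=False)
    print(f"decoy selection: {len(pool)} pool compounds -> "
          f"{len(decoys)} property-matched decoys "
          f"-> {RESULTS / 'decoy_selection.csv'}")


if __name__ == "__main__":
    main()
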