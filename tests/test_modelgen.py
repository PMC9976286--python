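"""Model construction: interaction detection, Xvols, shared features, edits."""
import numpy as np
import pytest

from phore.featperc import FeatureKind, PharmacophoreFeature
from phore.model import ExclusionVolume, PharmacophoreModel
from phore.modelgen import (InteractionGeometryRules, add_exclusion_volumes,
                            detect_interactions, refine_model,
                            shared_feature_model)
from phore.molio import ProteinAtom, read_complex
from phore.screen import screen_library
from phore.synthdata import (PlantSpec, generate_planted_library,
                             generate_toy_complex, plant_template)

from conftest import mol3d


def load_toy(tmp_path, kinds, seed=0):
    tc = generate_toy_complex(kinds, seed=seed)
    p = tc.write(tmp_path / "toy.pdb")
    protein, ligand = read_complex(p, "LIG", tc.ligand_template)
    return protein, ligand


class TestDetectInteractions:
    @pytest.mark.parametrize("kinds", [
        [FeatureKind.NI],
        [FeatureKind.PI],
        [FeatureKind.HBD],
        [FeatureKind.HBA],
        [FeatureKind.HC],
        [FeatureKind.AI],
        [FeatureKind.MB],
        [FeatureKind.HBD, FeatureKind.HBA, FeatureKind.NI, FeatureKind.HC],
        [FeatureKind.NI, FeatureKind.PI, FeatureKind.AI, FeatureKind.MB],
    ])
    def test_planted_contacts_recovered_exactly(self, tmp_path, kinds):
        protein, ligand = load_toy(tmp_path, kinds)
        model = detect_interactions(protein, ligand)
        assert model is not None
        assert sorted(f.kind.value for f in model.features) == \
            sorted(k.value for k in kinds)

    def test_carboxylate_near_guanidinium_yields_ni(self):
        cs = mol3d("CC(=O)[O-]", "acetate")
        from phore.featperc import perceive_features
        center = [f for f in perceive_features(cs)
                  if f.kind == FeatureKind.NI][0].center_array
        # guanidinium group with centroid 4.0 Å from the carboxylate centre
        protein = [
            ProteinAtom("C", "CZ", "ARG", 1, "A", tuple(center + [0, 4, 0])),
            ProteinAtom("N", "NH1", "ARG", 1, "A",
                        tuple(center + [0, 4, 1.16])),
            ProteinAtom("N", "NH2", "ARG", 1, "A",
                        tuple(center + [0, 4, -1.16])),
        ]
        model = detect_interactions(protein, cs)
        assert any(f.kind == FeatureKind.NI for f in model.features)

    def test_donor_acceptor_beyond_range_gives_no_hbond(self):
        cs = mol3d("CCO", "ethanol")
        from phore.featperc import perceive_features
        donor = [f for f in perceive_features(cs)
                 if f.kind == FeatureKind.HBD][0].center_array
        protein = [ProteinAtom("O", "O", "GLY", 1, "A",
                               tuple(donor + [0.0, 5.0, 0.0]))]
        model = detect_interactions(protein, cs)
        assert model is None or not any(f.kind == FeatureKind.HBD
                                        for f in model.features)

    def test_no_interactions_returns_none_not_exception(self):
        cs = mol3d("CCO", "ethanol")
        assert detect_interactions([], cs) is None


class TestExclusionVolumes:
    def test_zero_shell_adds_nothing(self, tmp_path):
        protein, ligand = load_toy(tmp_path, [FeatureKind.NI])
        model = detect_interactions(protein, ligand)
        out = add_exclusion_volumes(model, protein, ligand, shell=0.0)
        assert out.n_xvols == 0

    def test_one_xvol_per_pocket_atom_in_shell(self):
        cs = mol3d("CC(=O)[O-]", "acetate")
        lig = cs.heavy_coords(0)
        rng = np.random.default_rng(4)
        # 19 pocket atoms planted inside the shell, a template-scale pocket
        protein = []
        for i in range(19):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = lig[i % len(lig)] + direction * rng.uniform(3.0, 4.9)
            protein.append(ProteinAtom("C", "CB", "ALA", i, "A", tuple(pos)))
        feats = [PharmacophoreFeature(FeatureKind.NI, (0.0, 0.0, 0.0))]
        model = PharmacophoreModel("m", feats)
        out = add_exclusion_volumes(model, protein, cs, shell=5.0,
                                    dedup_dist=0.0)
        assert out.n_xvols == 19

    def test_enlarging_shell_never_loses_xvols(self, tmp_path):
        protein, ligand = load_toy(tmp_path, [FeatureKind.NI, FeatureKind.HC])
        model = detect_interactions(protein, ligand)
        counts = [add_exclusion_volumes(model, protein, ligand, shell=s).n_xvols
                  for s in (2.0, 4.0, 6.0, 8.0)]
        assert counts == sorted(counts)


class TestSharedFeatureModel:
    def test_identical_training_molecules_keep_everything(self, planted_model,
                                                          planted_template):
        from phore.featperc import perceive_features
        a = planted_template.copy()
        a.mol_id = "A"
        b = planted_template.copy()
        b.mol_id = "B"
        model = shared_feature_model([a, b], "A")
        assert model.n_features == len(perceive_features(planted_template))

    def test_intersection_drops_unshared_kinds(self):
        ref_model = PharmacophoreModel("ref", [
            PharmacophoreFeature(FeatureKind.NI, (0.0, 0.0, 0.0)),
            PharmacophoreFeature(FeatureKind.AI, (7.0, 0.0, 0.0)),
            PharmacophoreFeature(FeatureKind.PI, (12.0, 4.0, 0.0)),
        ])
        partner_model = PharmacophoreModel("partner", [
            PharmacophoreFeature(FeatureKind.NI, (0.0, 0.0, 0.0)),
            PharmacophoreFeature(FeatureKind.AI, (7.0, 0.0, 0.0)),
        ])
        ref = plant_template(ref_model, "ref")
        partner = plant_template(partner_model, "partner")
        model = shared_feature_model([ref, partner], "ref")
        kinds = {f.kind for f in model.features}
        assert FeatureKind.NI in kinds and FeatureKind.AI in kinds
        assert FeatureKind.PI not in kinds

    def test_large_shared_arrangement_recovered_across_eight_actives(self):
        # four acceptors and one anionic anchor spread over more than 15 Å
        anchor = [
            PharmacophoreFeature(FeatureKind.NI, (0.0, 0.0, 0.0)),
            PharmacophoreFeature(FeatureKind.HBA, (5.0, 2.0, 0.0)),
            PharmacophoreFeature(FeatureKind.HBA, (9.0, -2.0, 1.0)),
            PharmacophoreFeature(FeatureKind.HBA, (12.0, 3.0, -1.0)),
            PharmacophoreFeature(FeatureKind.HBA, (16.0, 0.0, 0.0)),
        ]
        training = []
        rng = np.random.default_rng(8)
        for i in range(8):
            order = list(range(5))
            if i:  # vary the scaffold wiring, keep the feature geometry
                rng.shuffle(order)
            m = PharmacophoreModel(f"t{i}", [anchor[j] for j in order])
            cs = plant_template(m, f"train{i}")
            training.append(cs)
        model = shared_feature_model(training, "train0")
        kinds = [f.kind for f in model.features]
        assert kinds.count(FeatureKind.NI) >= 1
        assert kinds.count(FeatureKind.HBA) >= 4
        # every planted centre is recovered by a shared feature of its kind
        for f in anchor:
            assert any(g.kind == f.kind
                       and np.linalg.norm(g.center_array - f.center_array) < 0.5
                       for g in model.features)
        centers = model.feature_centers()
        pd = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        assert pd.max() > 15.0

    def test_fewer_than_two_actives_rejected(self, planted_template):
        with pytest.raises(ValueError):
            shared_feature_model([planted_template], "template")

    def test_output_is_subset_of_reference_features(self, planted_model,
                                                    planted_template):
        from phore.featperc import perceive_features
        ref_feats = {(f.kind, f.center)
                     for f in perceive_features(planted_template)}
        other_model = PharmacophoreModel("o", [
            PharmacophoreFeature(FeatureKind.NI, (0.0, 0.0, 0.0)),
            PharmacophoreFeature(FeatureKind.AI, (8.5, 0.0, 0.0)),
        ])
        other = plant_template(other_model, "other")
        a = planted_template.copy()
        a.mol_id = "ref"
        model = shared_feature_model([a, other], "ref")
        assert {(f.kind, f.center) for f in model.features} <= ref_feats


class TestRefinement:
    @pytest.fixture
    def screen_setup(self, planted_model):
        lib, _ = generate_planted_library(
            PlantSpec(planted_model, 6, 12, 0.35, seed=5))
        return planted_model, lib

    def hits(self, model, lib):
        return {r.mol_id for r in screen_library([model], lib)
                if r.models_hit}

    def test_removing_a_feature_can_only_gain_hits(self, screen_setup):
        model, lib = screen_setup
        before = self.hits(model, lib)
        edited = refine_model(model, "remove_feature", {"index": 0})
        assert edited.n_features == model.n_features - 1
        assert before <= self.hits(edited, lib)

    def test_adding_an_xvol_can_only_lose_hits(self, screen_setup):
        model, lib = screen_setup
        before = self.hits(model, lib)
        edited = refine_model(model, "add_xvol",
                              {"center": (2.0, 1.0, 0.5), "radius": 1.5})
        assert edited.n_xvols == model.n_xvols + 1
        assert self.hits(edited, lib) <= before

    def test_growing_a_tolerance_can_only_gain_hits(self, screen_setup):
        model, lib = screen_setup
        before = self.hits(model, lib)
        edited = refine_model(model, "resize_feature",
                              {"index": 1, "tolerance": 2.0})
        assert before <= self.hits(edited, lib)

    def test_reports_returned_with_screening_sets(self, planted_model):
        lib, labels = generate_planted_library(
            PlantSpec(planted_model, 4, 8, 0.0, seed=2))
        actives = [cs for cs in lib if labels.label(cs.mol_id) == "active"]
        decoys = [cs for cs in lib if labels.label(cs.mol_id) == "decoy"]
        out, before, after = refine_model(planted_model, "resize_feature",
                                          {"index": 0, "tolerance": 1.0},
                                          actives, decoys)
        assert before.counts.TP == 4 and before.counts.FP == 0
        assert after.counts.TP <= before.counts.TP

    def test_bad_edit_index_is_an_error(self, planted_model):
        with pytest.raises(IndexError):
            refine_model(planted_model, "remove_feature", {"index": 99})


def test_geometry_rules_validate_ranges():
    with pytest.raises(ValueError):
        InteractionGeometryRules(hbond_dist=(4.0, 3.0))
    with pytest.raises(ValueError):
        InteractionGeometryRules(hbond_angle_min=0.0)
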