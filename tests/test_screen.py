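"""Matching semantics: tolerances, Xvols, scores, once-per-molecule hits."""
import numpy as np
import pytest

from phore.featperc import FeatureKind, PharmacophoreFeature
from phore.geometry import random_rotation
from phore.model import ExclusionVolume, PharmacophoreModel
from phore.screen import (consensus_hits, match_features, screen_library,
                          HitRecord, MatchResult)
from phore.synthdata import PlantSpec, generate_planted_library

from oracles import brute_force_match

K = FeatureKind


def simple_model(xvols=(), xvol_check=True):
    m = PharmacophoreModel("m", [
        PharmacophoreFeature(K.NI, (0.0, 0.0, 0.0)),
        PharmacophoreFeature(K.AI, (5.0, 0.0, 0.0)),
        PharmacophoreFeature(K.HBA, (2.5, 3.0, 0.0)),
    ], [ExclusionVolume(c, 1.0) for c in xvols])
    m.policy.xvol_check = xvol_check
    return m


def transformed_copy(feats, R, t):
    return [PharmacophoreFeature(f.kind, tuple(np.asarray(f.center) @ R.T + t),
                                 f.tolerance) for f in feats]


class TestMatchSemantics:
    def test_exact_coincidence_under_rigid_motion_scores_full(self, rng):
        m = simple_model()
        R, t = random_rotation(rng), rng.uniform(-15, 15, 3)
        lig = transformed_copy(m.features, R, t)
        res = match_features(m, lig)
        assert res.matched
        assert res.fit_score == pytest.approx(m.n_features, abs=1e-9)

    def test_feature_just_outside_tolerance_fails(self):
        m = simple_model()
        lig = [PharmacophoreFeature(f.kind, f.center) for f in m.features]
        shifted = np.asarray(lig[0].center) + np.array([0.0, 0.0, 1.01 * 1.5])
        lig[0] = PharmacophoreFeature(lig[0].kind, tuple(shifted))
        # other two features pinned: the only rigid fit leaves one outside
        m2 = PharmacophoreModel("m2", [
            PharmacophoreFeature(K.NI, (0.0, 0.0, 0.0), 0.05),
            PharmacophoreFeature(K.AI, (5.0, 0.0, 0.0), 0.05),
        ])
        lig2 = [
            PharmacophoreFeature(K.NI, (0.0, 0.0, 0.0)),
            PharmacophoreFeature(K.AI, (5.0 + 0.11, 0.0, 0.0)),
        ]
        assert not match_features(m2, lig2).matched

    def test_heavy_atom_at_xvol_center_blocks_match_only_when_checked(self):
        xvol_at = (2.5, -2.0, 0.0)
        m_on = simple_model(xvols=[xvol_at], xvol_check=True)
        m_off = simple_model(xvols=[xvol_at], xvol_check=False)
        lig = [PharmacophoreFeature(f.kind, f.center) for f in m_on.features]
        heavy = np.vstack([[f.center for f in lig], [xvol_at]])
        assert not match_features(m_on, lig, heavy).matched
        assert match_features(m_off, lig, heavy).matched

    def test_score_bounded_and_maximal_only_at_zero_distance(self, rng):
        m = simple_model()
        for _ in range(20):
            lig = [PharmacophoreFeature(
                f.kind, tuple(np.asarray(f.center) + rng.normal(0, 0.5, 3)))
                for f in m.features]
            res = match_features(m, lig)
            if res.matched:
                assert 0.0 <= res.fit_score <= m.n_features + 1e-9

    def test_tolerance_scaling_never_converts_hit_to_miss(self, rng):
        for _ in range(25):
            feats = [PharmacophoreFeature(
                [K.NI, K.AI, K.HBA][i], tuple(rng.uniform(-5, 5, 3)))
                for i in range(3)]
            try:
                m = PharmacophoreModel("m", feats)
            except ValueError:
                continue
            lig = [PharmacophoreFeature(
                f.kind, tuple(np.asarray(f.center) + rng.normal(0, 0.8, 3)))
                for f in feats]
            base = match_features(m, lig).matched
            grown = PharmacophoreModel("g", [f.with_tolerance(f.tolerance * 1.5)
                                             for f in feats])
            if base:
                assert match_features(grown, lig).matched

    def test_agrees_with_exhaustive_enumeration(self, rng):
        kinds = [K.NI, K.AI, K.HBA]
        for _ in range(40):
            nm, nl = rng.integers(2, 6), rng.integers(2, 9)
            try:
                m = PharmacophoreModel("m", [
                    PharmacophoreFeature(kinds[rng.integers(3)],
                                         tuple(rng.uniform(-6, 6, 3)),
                                         float(rng.uniform(0.8, 2.0)))
                    for _ in range(nm)])
            except ValueError:
                continue
            lig = [PharmacophoreFeature(kinds[rng.integers(3)],
                                        tuple(rng.uniform(-6, 6, 3)))
                   for _ in range(nl)]
            fast = match_features(m, lig)
            slow = brute_force_match(m, lig)
            assert fast.matched == (slow is not None)
            if slow is not None:
                assert fast.fit_score == pytest.approx(slow, abs=1e-6)


class TestScreenLibrary:
    def test_planted_actives_hit_and_decoys_do_not(self, planted_model):
        lib, labels = generate_planted_library(
            PlantSpec(planted_model, 10, 100, 0.0, seed=7))
        records = screen_library([planted_model], lib)
        hit_ids = {r.mol_id for r in records if r.models_hit}
        assert hit_ids == set(labels.actives())

    def test_empty_model_list_gives_no_hits(self, planted_model):
        lib, _ = generate_planted_library(PlantSpec(planted_model, 2, 2, 0.0))
        records = screen_library([], lib)
        assert all(r.models_hit == [] for r in records)

    def test_duplicate_conformer_counts_once(self, planted_model,
                                             planted_template):
        cs = planted_template.copy()
        cs.add_conformer(cs.coords(0))
        records = screen_library([planted_model], [cs])
        assert len(records) == 1
        assert records[0].models_hit == [planted_model.name]

    def test_conformerless_molecule_is_a_non_hit(self, planted_model):
        from rdkit import Chem
        from phore.molio import ConformerSet
        cs = ConformerSet("flat", Chem.MolFromSmiles("CCO"))
        records = screen_library([planted_model], [cs])
        assert records[0].models_hit == []


class TestConsensus:
    @staticmethod
    def record(mol_id, hit, every):
        rec = HitRecord(mol_id)
        for name in every:
            rec.results[name] = (MatchResult(True, fit_score=1.0)
                                 if name in hit else MatchResult.no_match())
        return rec

    def test_only_multimodel_molecules_survive(self):
        every = ["m2", "m4", "m6"]
        records = [self.record("A", ["m2", "m4"], every),
                   self.record("B", ["m6"], every)]
        table = consensus_hits(records)
        assert list(table["mol_id"]) == ["A"]
        assert table.loc[0, "m2"] == "X" and table.loc[0, "m6"] == ""

    def test_all_single_model_hits_give_empty_table(self):
        every = ["m2", "m4"]
        records = [self.record(f"h{i}", [every[i % 2]], every)
                   for i in range(6)]
        assert len(consensus_hits(records)) == 0
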