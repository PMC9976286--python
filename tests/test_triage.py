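"""Hit triage: substrate filtering, small-model rule, similarity grouping."""
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from phore.molio import ConformerSet
from phore.screen import HitRecord, MatchResult
from phore.triage import (apply_small_model_rule, dedup_similar,
                          filter_substrate_like, fingerprint, max_similarity,
                          run_triage, tanimoto)


def flat(mol_id, smiles):
    return ConformerSet(mol_id, Chem.MolFromSmiles(smiles))


# a urea-linked glutarate scaffold, the hallmark of canonical substrate-like
# zinc-site binders
UREA_GLUTAMATE = "OC(=O)CCC(NC(=O)NC(CCC(=O)O)C(=O)O)C(=O)O"
XANTHENE_SULFONAMIDE = "O=S(=O)(N1CCCC1)c1ccc2Oc3ccccc3Cc2c1"


class TestSubstrateFilter:
    def test_urea_glutarate_scaffold_removed(self):
        kept, removed = filter_substrate_like(
            [flat("dcibzl_like", UREA_GLUTAMATE)])
        assert [c.mol_id for c in removed] == ["dcibzl_like"]
        assert kept == []

    def test_glutamate_free_scaffold_kept(self):
        kept, removed = filter_substrate_like(
            [flat("xanthene", XANTHENE_SULFONAMIDE)])
        assert [c.mol_id for c in kept] == ["xanthene"]
        assert removed == []

    def test_empty_hit_list(self):
        assert filter_substrate_like([]) == ([], [])

    def test_invalid_pattern_is_an_error(self):
        with pytest.raises(ValueError):
            filter_substrate_like([], pattern="[[[")


def records(counts):
    """counts: model name -> number of hits; distinct molecules per model."""
    recs = []
    names = list(counts)
    i = 0
    for name, n in counts.items():
        for _ in range(n):
            rec = HitRecord(f"h{i:03d}")
            for m in names:
                rec.results[m] = (MatchResult(True, fit_score=1.0)
                                  if m == name else MatchResult.no_match())
            recs.append(rec)
            i += 1
    return recs


class TestSmallModelRule:
    def test_two_hit_model_fully_selected(self):
        recs = records({"m7": 2, "m6": 51})
        selected = apply_small_model_rule(recs, threshold=10)
        m7_hits = {r.mol_id for r in recs if "m7" in r.models_hit}
        assert set(selected) == m7_hits

    def test_large_model_contributes_nothing(self):
        recs = records({"m6": 51})
        assert apply_small_model_rule(recs, threshold=10) == []

    def test_zero_threshold_selects_nothing(self):
        recs = records({"m7": 2})
        assert apply_small_model_rule(recs, threshold=0) == []


class TestFingerprints:
    def test_self_similarity_is_one(self):
        fp = fingerprint(flat("m", "CC(=O)Oc1ccccc1C(=O)O"))
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_environments_score_zero(self):
        a = fingerprint(flat("a", "CCCC"))
        b = fingerprint(flat("b", "FC(F)(F)F"))
        assert tanimoto(a, b) == 0.0

    def test_folded_value_matches_unfolded_environment_sets(self):
        # independent route: unfolded sparse environment identifiers
        def env_set(smiles, radius=1):
            m = Chem.MolFromSmiles(smiles)
            return set(AllChem.GetMorganFingerprint(m, radius)
                       .GetNonzeroElements())
        ethane, ethanol = env_set("CC"), env_set("CCO")
        expected = len(ethane & ethanol) / len(ethane | ethanol)
        got = tanimoto(fingerprint(flat("e", "CC"), radius=1),
                       fingerprint(flat("o", "CCO"), radius=1))
        assert got == pytest.approx(expected)

    def test_invariant_under_atom_reordering(self):
        a = fingerprint(flat("a", "c1ccccc1CCN"))
        b = fingerprint(flat("b", "NCCc1ccccc1"))
        assert tanimoto(a, b) == 1.0

    def test_symmetry_and_range(self):
        a = fingerprint(flat("a", "CCCCCCO"))
        b = fingerprint(flat("b", "c1ccncc1"))
        assert tanimoto(a, b) == tanimoto(b, a)
        assert 0.0 <= tanimoto(a, b) <= 1.0

    def test_max_similarity_against_reference_set(self):
        refs = [flat("r1", "CCCCCCO"), flat("r2", "c1ccccc1")]
        assert max_similarity(flat("q", "CCCCCCO"), refs) == 1.0
        assert max_similarity(flat("q", "CCCCCCO"), []) == 0.0


class TestDedup:
    def test_identical_structures_one_representative(self):
        hits = [flat("z_copy", "CCCCCCO"), flat("a_copy", "CCCCCCO")]
        groups, reps = dedup_similar(hits, cutoff=0.8)
        assert groups == [["a_copy", "z_copy"]]
        assert reps == ["a_copy"]

    def test_dissimilar_set_stays_apart(self):
        hits = [flat("a", "CCCCCCO"), flat("b", "c1ccncc1"),
                flat("c", "FC(F)(F)C(=O)O")]
        groups, reps = dedup_similar(hits, cutoff=0.8)
        assert sorted(len(g) for g in groups) == [1, 1, 1]
        assert sorted(reps) == ["a", "b", "c"]

    def test_single_linkage_chains_transitively(self):
        # A~B and B~C above cutoff, A~C far below: one group of three
        hits = [flat("A", "c1ccccc1CCCCCC"), flat("B", "c1ccccc1CCCCCCO"),
                flat("C", "OCCCCCCO")]
        a, b, c = (fingerprint(h) for h in hits)
        assert tanimoto(a, b) >= 0.35 and tanimoto(b, c) >= 0.35
        assert tanimoto(a, c) < 0.35
        groups, reps = dedup_similar(hits, cutoff=0.35)
        assert groups == [["A", "B", "C"]]
        assert reps == ["A"]


class TestPipeline:
    def library(self):
        return [flat("h000", UREA_GLUTAMATE),
                flat("h001", XANTHENE_SULFONAMIDE),
                flat("h002", "CCCCCCO"), flat("h003", "CCCCCCO"),
                flat("h004", "c1ccncc1CC(=O)O")]

    def records(self):
        hits = {"h000": ["big"], "h001": ["tiny"], "h002": ["big"],
                "h003": ["big"], "h004": ["big", "tiny"]}
        recs = []
        for mol_id, models in hits.items():
            rec = HitRecord(mol_id)
            for m in ("big", "tiny"):
                rec.results[m] = (MatchResult(True, fit_score=1.0)
                                  if m in models else MatchResult.no_match())
            recs.append(rec)
        # pad "big" above the small-model threshold
        for i in range(8):
            rec = HitRecord(f"pad{i}")
            rec.results["big"] = MatchResult(True, fit_score=1.0)
            rec.results["tiny"] = MatchResult.no_match()
            recs.append(rec)
        return recs

    def test_selected_and_removed_disjoint_and_idempotent(self):
        lib = self.library()
        recs = self.records()
        rep1 = run_triage(recs, lib, small_model_threshold=10)
        assert set(rep1.removed_substrate_like) == {"h000"}
        assert "tiny" in rep1.kept_all_models
        assert not set(rep1.selected) & set(rep1.removed_substrate_like)
        # duplicate alcohols collapse to one representative
        assert ("h002" in rep1.selected) != ("h003" in rep1.selected) or \
            ("h002" in rep1.selected and "h003" not in rep1.selected)
        rep2 = run_triage(recs, lib, small_model_threshold=10)
        assert rep1.selected == rep2.selected
        assert rep1.dedup_groups == rep2.dedup_groups
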