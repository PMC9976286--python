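"""Post-screening hit triage and scaffold-novelty analysis.

Hits resembling the natural substrate (a glutamate moiety, the hallmark of
canonical glutamate carboxypeptidase II inhibitors) are removed; hits of
highly restrictive models that retrieved fewer than ten molecules are all
kept; remaining hits are grouped by ECFP4-style Tanimoto similarity and one
representative per group is selected.  Novelty of a hit is the highest
Tanimoto similarity against a set of known actives — low values signal a new
scaffold.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .molio import ConformerSet

__all__ = ["Fingerprint", "TriageReport", "fingerprint", "tanimoto",
           "filter_substrate_like", "apply_small_model_rule", "dedup_similar",
           "max_similarity", "run_triage", "GLUTAMATE_SMARTS"]

# alpha-amino / N-acyl glutamate moiety (glutarate arm + alpha carboxylate),
# drawn neutral or ionized; editable via the `pattern` argument
GLUTAMATE_SMARTS = ("[NX3][CX4H1]([CH2][CH2][CX3](=[OX1])[OX2H1,OX1-])"
                    "[CX3](=[OX1])[OX2H1,OX1-]")


@dataclass(frozen=True)
class Fingerprint:
    """Folded circular substructure fingerprint (default ECFP4-equivalent)."""

    bits: DataStructs.ExplicitBitVect
    radius: int = 2
    n_bits: int = 2048


def fingerprint(mol, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    rdmol = getattr(mol, "mol", mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    return Fingerprint(gen.GetFingerprint(rdmol), radius, n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a & b| / |a | b|; defined 0 when both fingerprints are empty."""
    if a.bits.GetNumOnBits() == 0 and b.bits.GetNumOnBits() == 0:
        return 0.0
    return float(DataStructs.TanimotoSimilarity(a.bits, b.bits))


def max_similarity(mol, references: list) -> float:
    """Highest Tanimoto of ``mol`` against a reference set (novelty score)."""
    fp = fingerprint(mol)
    return max((tanimoto(fp, fingerprint(r)) for r in references), default=0.0)


@dataclass
class TriageReport:
    removed_substrate_like: list[str] = field(default_factory=list)
    kept_all_models: list[str] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    dedup_groups: list[list[str]] = field(default_factory=list)


def filter_substrate_like(hits: list[ConformerSet],
                          pattern: str = GLUTAMATE_SMARTS
                          ) -> tuple[list[ConformerSet], list[ConformerSet]]:
    """Partition hits into (kept, removed) by substrate-moiety substructure."""
    patt = Chem.MolFromSmarts(pattern)
    if patt is None:
        raise ValueError(f"invalid substructure pattern {pattern!r}")
    kept, removed = [], []
    for cs in hits:
        (removed if cs.mol.HasSubstructMatch(patt) else kept).append(cs)
    return kept, removed


def apply_small_model_rule(records, threshold: int = 10) -> list[str]:
    """All hits of any model that retrieved fewer than ``threshold`` molecules.

    Such restrictive models are represented in full in the experimental
    selection; their hits are selected unconditionally.
    """
    counts: dict[str, int] = {}
    for rec in records:
        for name in rec.models_hit:
            counts[name] = counts.get(name, 0) + 1
    small = {name for name, c in counts.items() if c < threshold}
    selected: list[str] = []
    for rec in records:
        if any(name in small for name in rec.models_hit) and \
                rec.mol_id not in selected:
            selected.append(rec.mol_id)
    return selected


def dedup_similar(hits: list[ConformerSet], cutoff: float = 0.8
                  ) -> tuple[list[list[str]], list[str]]:
    """Single-linkage similarity groups and one representative per group.

    Molecules joined by any chain of pairwise Tanimoto >= cutoff form one
    group; the lexicographically lowest mol_id represents it.
    """
    fps = [fingerprint(cs) for cs in hits]
    g = nx.Graph()
    g.add_nodes_from(range(len(hits)))
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            if tanimoto(fps[i], fps[j]) >= cutoff:
                g.add_edge(i, j)
    groups, reps = [], []
    comps = sorted(nx.connected_components(g),
                   key=lambda c: min(hits[i].mol_id for i in c))
    for comp in comps:
        ids = sorted(hits[i].mol_id for i in comp)
        groups.append(ids)
        reps.append(ids[0])
    return groups, reps


def run_triage(records, library: list[ConformerSet],
               pattern: str = GLUTAMATE_SMARTS,
               small_model_threshold: int = 10,
               dedup_cutoff: float = 0.8) -> TriageReport:
    """Documented triage pipeline: substrate filter -> small-model rule -> dedup.

    The small-model rule can resurrect a substrate-like hit only if its model
    is restrictive *and* the hit survived the substrate filter; removed hits
    never re-enter (selected and removed stay disjoint).
    """
    by_id = {cs.mol_id: cs for cs in library}
    hit_ids = [rec.mol_id for rec in records if rec.models_hit]
    hits = [by_id[i] for i in hit_ids if i in by_id]
    kept, removed = filter_substrate_like(hits, pattern)
    removed_ids = {cs.mol_id for cs in removed}
    auto = [m for m in apply_small_model_rule(records, small_model_threshold)
            if m not in removed_ids]
    rest = [cs for cs in kept if cs.mol_id not in auto]
    groups, reps = dedup_similar(rest, dedup_cutoff)
    selected = sorted(set(auto) | set(reps))
    counts: dict[str, int] = {}
    for rec in records:
        for name in rec.models_hit:
            counts[name] = counts.get(name, 0) + 1
    small_models = sorted(n for n, c in counts.items()
                          if c < small_model_threshold)
    return TriageReport(sorted(removed_ids), small_models, selected, groups)
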