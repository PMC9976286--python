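"""Retrospective validation of pharmacophore models.

Confusion counts from a screen against a labelled actives/decoys database and
the standard enrichment metric suite:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    yield of actives (YoA) = TP / (TP + FP)
    enrichment factor EF = YoA * N / A,  with N = A + D the database size
    accuracy = (TP + TN) / N

EF is bounded by EF_max = N / A, reached when every retrieved molecule is
active.  The ROC AUC is computed by the rank-sum (Mann–Whitney) formulation
with midrank tie handling; molecules a model does not retrieve enter with
score 0, below every hit.
"""
from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .geometry import round_half_up
from .molio import ActivityTable, ConformerSet

logger = logging.getLogger(__name__)

__all__ = ["ConfusionCounts", "EnrichmentReport", "confusion", "metrics",
           "roc_auc", "select_decoys", "evaluate_model"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_actives(self) -> int:
        return self.TP + self.FN

    @property
    def n_decoys(self) -> int:
        return self.FP + self.TN

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EnrichmentReport:
    counts: ConfusionCounts
    n_actives: int
    n_decoys: int
    sensitivity: float
    specificity: float
    accuracy: float
    yoa: float
    ef: float
    ef_max: float
    decoy_hitrate_pct: float
    auc: float | None = None

    def display(self) -> dict[str, float]:
        """Derived quantities rounded half-up to 2 decimals for tabulation."""
        out = {
            "TP": self.counts.TP, "FP": self.counts.FP,
            "TN": self.counts.TN, "FN": self.counts.FN,
            "n_actives": self.n_actives,
            "decoy_hitrate_pct": round_half_up(self.decoy_hitrate_pct),
            "accuracy": round_half_up(self.accuracy),
            "yoa": round_half_up(self.yoa),
            "ef": round_half_up(self.ef),
            "ef_max": round_half_up(self.ef_max),
            "ef_ratio": round_half_up(self.ef / self.ef_max),
            "sensitivity": round_half_up(self.sensitivity),
            "specificity": round_half_up(self.specificity),
        }
        if self.auc is not None:
            out["auc"] = round_half_up(self.auc)
        return out


def confusion(records, labels: ActivityTable, model_name: str,
              subset_filter: str | None = None) -> ConfusionCounts:
    """Confusion counts for one model over a screened, labelled library.

    ``subset_filter`` restricts which *actives* are counted (only actives of
    the model's own binding mode are considered); decoys always all count.
    Every screened molecule must be labelled.
    """
    TP = FP = TN = FN = 0
    for rec in records:
        label = labels.label(rec.mol_id)  # raises on unlabelled molecules
        hit = rec.results[model_name].matched if model_name in rec.results \
            else model_name in rec.models_hit
        if label == "active":
            if subset_filter is not None and \
                    labels.subset(rec.mol_id) != subset_filter:
                continue
            TP, FN = (TP + 1, FN) if hit else (TP, FN + 1)
        else:
            FP, TN = (FP + 1, TN) if hit else (FP, TN + 1)
    return ConfusionCounts(TP, FP, TN, FN)


def metrics(counts: ConfusionCounts, n_actives: int | None = None,
            n_decoys: int | None = None) -> EnrichmentReport:
    """Enrichment metric suite from confusion counts (full precision kept)."""
    n_actives = counts.n_actives if n_actives is None else n_actives
    n_decoys = counts.n_decoys if n_decoys is None else n_decoys
    if n_actives <= 0:
        raise ValueError("enrichment is undefined without actives")
    if counts.n_actives != n_actives or counts.n_decoys != n_decoys:
        raise ValueError("counts inconsistent with n_actives/n_decoys")
    N = n_actives + n_decoys
    sens = counts.TP / n_actives
    spec = counts.TN / n_decoys if n_decoys else 1.0
    retrieved = counts.TP + counts.FP
    yoa = counts.TP / retrieved if retrieved else 0.0
    ef_max = N / n_actives
    ef = yoa * ef_max
    acc = (counts.TP + counts.TN) / N
    hitrate = 100.0 * counts.FP / n_decoys if n_decoys else 0.0
    return EnrichmentReport(counts, n_actives, n_decoys, sens, spec, acc,
                            yoa, ef, ef_max, hitrate)


def roc_auc(scores: list[tuple[float, str]]) -> float:
    """AUC from (fit_score, label) pairs; rank-sum with midrank ties.

    Non-hits should be passed with score 0 so they rank below every hit.
    """
    y = np.array([1 if lab == "active" else 0 for _, lab in scores])
    s = np.array([float(v) for v, _ in scores])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one active and one decoy")
    ranks = rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def evaluate_model(model, actives: list[ConformerSet],
                   decoys: list[ConformerSet],
                   feature_rules=None) -> EnrichmentReport:
    """Screen actives+decoys with one model and report its enrichment."""
    from .screen import screen_library
    labels = ActivityTable()
    for cs in actives:
        labels.add(cs.mol_id, "active")
    for cs in decoys:
        labels.add(cs.mol_id, "decoy")
    records = screen_library([model], list(actives) + list(decoys),
                             feature_rules)
    counts = confusion(records, labels, model.name)
    rep = metrics(counts)
    scores = []
    for rec in records:
        r = rec.results[model.name]
        scores.append((r.fit_score if r.matched else 0.0,
                       labels.label(rec.mol_id)))
    rep.auc = roc_auc(scores)
    return rep


# ---------------------------------------------------------------------------
# property-matched decoy selection

def _property_vector(cs: ConformerSet) -> np.ndarray:
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    from .featperc import FeatureKind, default_rules
    mol = cs.mol
    rules = default_rules()
    ni = sum(len(mol.GetSubstructMatches(r.pattern()))
             for r in rules.for_kind(FeatureKind.NI))
    pi = sum(len(mol.GetSubstructMatches(r.pattern()))
             for r in rules.for_kind(FeatureKind.PI))
    logp_bin = float(np.floor(Crippen.MolLogP(mol)))
    return np.array([Descriptors.MolWt(mol), mol.GetNumHeavyAtoms(),
                     rdMolDescriptors.CalcNumRings(mol), ni, pi, logp_bin],
                    dtype=float)


def select_decoys(pool: list[ConformerSet], actives: list[ConformerSet],
                  n: int, seed: int = 0,
                  similarity_cutoff: float = 0.6,
                  envelope: float = 0.10) -> list[ConformerSet]:
    """Property-matched, structurally diverse decoys from a compound pool.

    Known actives are removed from the pool by structure (canonical SMILES).
    Pool members whose property vector (molecular weight, heavy atoms, ring
    count, ionizable group counts, logP bin) falls inside the actives'
    per-property [min - 10 %, max + 10 %] envelope survive; survivors are
    leader-clustered by Morgan fingerprint Tanimoto at the given cutoff and
    drawn one per cluster (then round-robin within clusters) in seeded order
    until ``n`` decoys are collected.  Returns min(n, available) decoys.
    """
    from rdkit import Chem

    from .triage import fingerprint, tanimoto

    active_smiles = {Chem.MolToSmiles(cs.mol) for cs in actives}
    pool = [cs for cs in pool
            if Chem.MolToSmiles(cs.mol) not in active_smiles]
    if not pool:
        return []
    props = np.array([_property_vector(cs) for cs in actives])
    lo, hi = props.min(axis=0), props.max(axis=0)
    lo = lo - envelope * np.abs(lo)
    hi = hi + envelope * np.abs(hi)
    survivors = [cs for cs in pool
                 if np.all((_property_vector(cs) >= lo - 1e-9)
                           & (_property_vector(cs) <= hi + 1e-9))]
    rng = random.Random(seed)
    order = list(range(len(survivors)))
    rng.shuffle(order)

    fps = {i: fingerprint(survivors[i]) for i in order}
    clusters: list[list[int]] = []  # leader clustering in seeded order
    for i in order:
        for cl in clusters:
            if tanimoto(fps[i], fps[cl[0]]) >= similarity_cutoff:
                cl.append(i)
                break
        else:
            clusters.append([i])

    chosen: list[int] = []
    depth = 0
    while len(chosen) < n:
        added = False
        for cl in clusters:
            if depth < len(cl):
                chosen.append(cl[depth])
                added = True
                if len(chosen) == n:
                    break
        if not added:
            break
        depth += 1
    if len(chosen) < n:
        logger.warning("only %d decoys available after property filtering "
                       "(requested %d)", len(chosen), n)
    return [survivors[i] for i in chosen]
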