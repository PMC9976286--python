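"""Pharmacophore matching of multiconformer libraries.

A conformer matches a model when there is a kind-compatible assignment of its
perceived features to the model features such that, after least-squares rigid
superposition of the paired centres, every mandatory model feature holds its
partner within its tolerance radius, and (when the Xvol check is on) no ligand
heavy atom falls strictly inside an exclusion volume.

Candidate assignments are found by clique detection: nodes are kind-compatible
(model feature, ligand feature) pairs, and two nodes are compatible when their
inter-feature distances agree within the summed tolerances — a necessary
condition for both features to land inside their spheres after any rigid
motion.  The fit score of an accepted match is sum(1 - d_i/tol_i) over matched
features, so it runs from 0 to the number of model features and hits the
maximum only on an exact geometric match.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .featperc import FeatureRuleSet, PharmacophoreFeature, perceive_features
from .geometry import apply_rigid, superpose
from .model import PharmacophoreModel
from .molio import ConformerSet

logger = logging.getLogger(__name__)

__all__ = ["MatchResult", "HitRecord", "match_conformer", "match_features",
           "screen_library", "consensus_hits"]


@dataclass
class MatchResult:
    matched: bool
    correspondence: dict[int, int] = field(default_factory=dict)
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    fit_score: float = 0.0
    conformer_index: int = -1

    @classmethod
    def no_match(cls) -> "MatchResult":
        return cls(matched=False)


@dataclass
class HitRecord:
    """Per-molecule screening outcome across all screened models."""

    mol_id: str
    results: dict[str, MatchResult] = field(default_factory=dict)

    @property
    def models_hit(self) -> list[str]:
        return [name for name, r in self.results.items() if r.matched]


def _pair_key(corr: dict[int, int]) -> tuple:
    return tuple(sorted(corr.items()))


def match_features(model: PharmacophoreModel,
                   ligand_features: list[PharmacophoreFeature],
                   heavy_coords: np.ndarray | None = None) -> MatchResult:
    """Match perceived ligand features (one conformer) against a model.

    ``heavy_coords`` — ligand heavy-atom coordinates in the same frame as the
    features — are required for the exclusion-volume check; when absent the
    Xvol check is skipped.
    """
    n_model = model.n_features
    n_req = model.n_required
    if len(ligand_features) < n_req:
        return MatchResult.no_match()

    mcenters = model.feature_centers()
    lcenters = np.array([f.center for f in ligand_features], dtype=float)
    mdist = np.linalg.norm(mcenters[:, None] - mcenters[None, :], axis=-1)
    ldist = np.linalg.norm(lcenters[:, None] - lcenters[None, :], axis=-1)

    nodes = [(i, j) for i in range(n_model) for j, lf in enumerate(ligand_features)
             if lf.kind == model.features[i].kind]
    if not nodes:
        return MatchResult.no_match()

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (i, j), (k, l) in itertools.combinations(nodes, 2):
        if i == k or j == l:
            continue
        tol_sum = model.features[i].tolerance + model.features[k].tolerance
        if abs(mdist[i, k] - ldist[j, l]) <= tol_sum + 1e-9:
            g.add_edge((i, j), (k, l))

    candidates: list[tuple[tuple, ...]] = []
    for clique in nx.find_cliques(g):
        if len(clique) >= n_req:
            if len(clique) == n_req:
                candidates.append(tuple(clique))
            else:
                candidates.extend(itertools.combinations(clique, n_req))
    if not candidates:
        return MatchResult.no_match()

    best: MatchResult | None = None
    seen: set[tuple] = set()
    for cand in candidates:
        corr = dict(sorted(cand))
        key = _pair_key(corr)
        if key in seen:
            continue
        seen.add(key)
        mi = list(corr.keys())
        lj = [corr[i] for i in mi]
        R, t = superpose(lcenters[lj], mcenters[mi])
        moved = apply_rigid(lcenters[lj], R, t)
        dists = np.linalg.norm(moved - mcenters[mi], axis=1)
        tols = np.array([model.features[i].tolerance for i in mi])
        if np.any(dists > tols + 1e-9):
            continue
        if model.policy.xvol_check and model.xvols and heavy_coords is not None:
            hv = apply_rigid(heavy_coords, R, t)
            clash = False
            for xv in model.xvols:
                if np.any(np.linalg.norm(hv - xv.center_array, axis=1)
                          < xv.radius - 1e-9):
                    clash = True
                    break
            if clash:
                continue
        score = float(np.sum(1.0 - dists / tols))
        res = MatchResult(True, corr, R, t, score)
        if best is None or score > best.fit_score + 1e-12 or (
                abs(score - best.fit_score) <= 1e-12
                and _pair_key(corr) < _pair_key(best.correspondence)):
            best = res
    return best if best is not None else MatchResult.no_match()


def match_conformer(model: PharmacophoreModel, cs: ConformerSet,
                    conf_index: int = 0,
                    rules: FeatureRuleSet | None = None) -> MatchResult:
    """Perceive features on one conformer and match them against the model."""
    feats = perceive_features(cs, conf_index, rules)
    res = match_features(model, feats, cs.heavy_coords(conf_index))
    if res.matched:
        res.conformer_index = conf_index
    return res


def screen_library(models: list[PharmacophoreModel],
                   library: list[ConformerSet],
                   rules: FeatureRuleSet | None = None) -> list[HitRecord]:
    """Screen every molecule of a multiconformer library against every model.

    A molecule hits a model at most once; the best-scoring conformer is
    recorded.  Molecules without conformers are counted as non-hits.
    """
    records: list[HitRecord] = []
    n_unscreenable = 0
    for cs in library:
        rec = HitRecord(cs.mol_id)
        if cs.n_conformers == 0:
            n_unscreenable += 1
            for m in models:
                rec.results[m.name] = MatchResult.no_match()
            records.append(rec)
            continue
        per_conf = [(ci, perceive_features(cs, ci, rules))
                    for ci in range(cs.n_conformers)]
        for m in models:
            best = MatchResult.no_match()
            for ci, feats in per_conf:
                r = match_features(m, feats, cs.heavy_coords(ci))
                if r.matched:
                    r.conformer_index = ci
                    if not best.matched or r.fit_score > best.fit_score:
                        best = r
            rec.results[m.name] = best
        records.append(rec)
    if n_unscreenable:
        logger.warning("%d molecules had no conformers and were counted as "
                       "non-hits", n_unscreenable)
    return records


def consensus_hits(records: list[HitRecord]) -> pd.DataFrame:
    """Molecules retrieved by more than one model (consensus hits).

    Rows sorted by number of models hit (descending) then mol_id, with one
    indicator column per model.
    """
    model_names: list[str] = []
    for rec in records:
        for name in rec.results:
            if name not in model_names:
                model_names.append(name)
    rows = []
    for rec in records:
        hit = rec.models_hit
        if len(hit) >= 2:
            row = {"mol_id": rec.mol_id, "n_models": len(hit)}
            for name in model_names:
                row[name] = "X" if name in hit else ""
            rows.append(row)
    df = pd.DataFrame(rows, columns=["mol_id", "n_models"] + model_names)
    if len(df):
        df = df.sort_values(["n_models", "mol_id"],
                            ascending=[False, True]).reset_index(drop=True)
    return df
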