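"""Pharmacophore model construction.

Structure-based: perceive ligand features in a protein–ligand complex and keep
those with a complementary protein partner under crystallographic interaction
geometry criteria; decorate with exclusion volumes on pocket atoms.
Ligand-based: shared-feature mode — align training actives onto a reference
and keep only the reference features matched in every training compound.
Refinement: explicit, single edits (remove/resize features, add/remove/resize
Xvols) with a before/after enrichment report, never an automatic optimizer.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .featperc import (FeatureKind, FeatureRuleSet, PharmacophoreFeature,
                       perceive_features, sort_features)
from .geometry import angle_deg, apply_rigid, superpose
from .model import ExclusionVolume, MatchPolicy, PharmacophoreModel
from .molio import ConformerSet, ProteinAtom

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionGeometryRules", "detect_interactions", "add_exclusion_volumes",
    "shared_feature_model", "refine_model",
]


@dataclass
class InteractionGeometryRules:
    """Distance/angle criteria for protein–ligand interaction detection (Å, deg).

    Defaults follow consensus crystallographic contact criteria: hydrogen
    bonds 2.5–3.8 Å heavy-atom distance with >=120 deg at the donor (angle
    applied only when an explicit hydrogen is present), salt bridges up to
    5.5 Å between charged-group centroids, hydrophobic contacts 1.0–5.0 Å
    from cluster centroid to apolar protein atom, aromatic ring centroids up
    to 5.0 Å, ligand-to-metal up to 2.8 Å.
    """

    hbond_dist: tuple[float, float] = (2.5, 3.8)
    hbond_angle_min: float = 120.0
    ionic_dist_max: float = 5.5
    hydrophobic_dist: tuple[float, float] = (1.0, 5.0)
    aromatic_dist_max: float = 5.0
    metal_dist_max: float = 2.8

    def __post_init__(self) -> None:
        if not (self.hbond_dist[0] < self.hbond_dist[1]
                and self.hydrophobic_dist[0] < self.hydrophobic_dist[1]):
            raise ValueError("distance ranges need min < max")
        if not (0.0 < self.hbond_angle_min <= 180.0):
            raise ValueError("hbond_angle_min must be in (0, 180]")


# --- protein-side interaction vocabulary (PDB atom naming) ------------------

BACKBONE_ACCEPTORS = {"O", "OXT"}
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1"},
}
BACKBONE_DONORS = {"N"}
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"NE2", "ND1"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "TRP": {"NE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
}
CATION_GROUPS = {  # residue -> atom names whose centroid carries the + charge
    "ARG": ("CZ", "NH1", "NH2"), "LYS": ("NZ",), "HIS": ("ND1", "NE2"),
}
ANION_GROUPS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP",
                   "CYS", "TYR"}


def _protein_acceptors(protein: list[ProteinAtom]) -> list[ProteinAtom]:
    return [a for a in protein
            if a.name in BACKBONE_ACCEPTORS
            or a.name in SIDECHAIN_ACCEPTORS.get(a.resname, ())]


def _protein_donors(protein: list[ProteinAtom]) -> list[ProteinAtom]:
    return [a for a in protein
            if a.name in BACKBONE_DONORS
            or a.name in SIDECHAIN_DONORS.get(a.resname, ())]


def _residue_groups(protein, table):
    """Centroids of charged/aromatic residue groups present in the structure."""
    by_res: dict[tuple, dict[str, ProteinAtom]] = {}
    for a in protein:
        by_res.setdefault((a.chain, a.resseq, a.resname), {})[a.name] = a
    out = []
    for (chain, resseq, resname), atoms in by_res.items():
        names = table.get(resname)
        if names and all(n in atoms for n in names):
            pts = np.array([atoms[n].coords for n in names])
            out.append(pts.mean(axis=0))
    return out


def _metals(protein: list[ProteinAtom]) -> list[ProteinAtom]:
    return [a for a in protein if a.is_metal]


def _apolar_atoms(protein: list[ProteinAtom]) -> list[ProteinAtom]:
    return [a for a in protein
            if a.element == "C" and a.resname in APOLAR_RESIDUES
            and a.name not in ("C", "CA")]


def _explicit_h_positions(ligand: ConformerSet, conf_index: int,
                          heavy_idx: int) -> list[np.ndarray]:
    coords = ligand.coords(conf_index)
    atom = ligand.mol.GetAtomWithIdx(heavy_idx)
    return [coords[n.GetIdx()] for n in atom.GetNeighbors()
            if n.GetAtomicNum() == 1]


def detect_interactions(protein: list[ProteinAtom], ligand: ConformerSet,
                        rules: InteractionGeometryRules | None = None,
                        feature_rules: FeatureRuleSet | None = None,
                        conf_index: int = 0,
                        name: str = "structure-based"
                        ) -> PharmacophoreModel | None:
    """Structure-based model from observed protein–ligand contacts.

    Every perceived ligand feature is promoted to a model feature iff a
    complementary protein partner satisfies the geometry rules.  Feature
    centres stay on the ligand side, in the complex frame.  Returns ``None``
    when no interaction is found (the model invariant forbids empty models).
    """
    rules = rules or InteractionGeometryRules()
    candidates = perceive_features(ligand, conf_index, feature_rules)
    acceptors = _protein_acceptors(protein)
    donors = _protein_donors(protein)
    cations = _residue_groups(protein, {k: v for k, v in CATION_GROUPS.items()})
    anions = _residue_groups(protein, ANION_GROUPS)
    rings = _residue_groups(protein, AROMATIC_RINGS)
    metals = _metals(protein)
    apolar = _apolar_atoms(protein)

    def hb_ok(center, partner_coords, donor_idx=None):
        d = float(np.linalg.norm(center - partner_coords))
        if not (rules.hbond_dist[0] <= d <= rules.hbond_dist[1]):
            return False
        if donor_idx is not None:
            hs = _explicit_h_positions(ligand, conf_index, donor_idx)
            if hs:  # D–H···A angle, decidable only with explicit hydrogens
                best = max(angle_deg(center, h, partner_coords) for h in hs)
                if best < rules.hbond_angle_min:
                    return False
        return True

    kept: list[PharmacophoreFeature] = []
    for f in candidates:
        c = f.center_array
        ok = False
        if f.kind == FeatureKind.HBD:
            didx = f.origin_atoms[0] if f.origin_atoms else None
            ok = any(hb_ok(c, a.coords_array, didx) for a in acceptors)
        elif f.kind == FeatureKind.HBA:
            ok = any(hb_ok(c, a.coords_array) for a in donors)
        elif f.kind == FeatureKind.NI:
            ok = any(np.linalg.norm(c - g) <= rules.ionic_dist_max
                     for g in cations)
            ok = ok or any(np.linalg.norm(c - m.coords_array)
                           <= rules.ionic_dist_max for m in metals)
        elif f.kind == FeatureKind.PI:
            ok = any(np.linalg.norm(c - g) <= rules.ionic_dist_max
                     for g in anions)
        elif f.kind == FeatureKind.HC:
            ok = any(rules.hydrophobic_dist[0]
                     <= np.linalg.norm(c - a.coords_array)
                     <= rules.hydrophobic_dist[1] for a in apolar)
        elif f.kind == FeatureKind.AI:
            ok = any(np.linalg.norm(c - g) <= rules.aromatic_dist_max
                     for g in rings)
        elif f.kind == FeatureKind.MB:
            ok = any(np.linalg.norm(c - m.coords_array) <= rules.metal_dist_max
                     for m in metals)
        if ok:
            kept.append(f)

    if not kept:
        logger.warning("no protein–ligand interactions detected; "
                       "no model can be built")
        return None
    return PharmacophoreModel(name, sort_features(kept))


def add_exclusion_volumes(model: PharmacophoreModel,
                          protein: list[ProteinAtom], ligand: ConformerSet,
                          shell: float = 5.0, radius: float = 1.0,
                          conf_index: int = 0,
                          dedup_dist: float = 0.5) -> PharmacophoreModel:
    """One Xvol per protein heavy atom within ``shell`` Å of the ligand.

    Xvols whose centres fall within ``dedup_dist`` of an already placed one
    are merged.  Returns a new model; the input is untouched.
    """
    lig = ligand.heavy_coords(conf_index)
    centers: list[np.ndarray] = [x.center_array for x in model.xvols]
    new_xvols = list(model.xvols)
    if shell > 0:
        for a in protein:
            if a.element == "H":
                continue
            pc = a.coords_array
            if np.min(np.linalg.norm(lig - pc, axis=1)) <= shell:
                if any(np.linalg.norm(pc - c) < dedup_dist for c in centers):
                    continue
                centers.append(pc)
                new_xvols.append(ExclusionVolume(tuple(pc), radius))
    out = model.copy()
    out.xvols = new_xvols
    logger.info("model %s: %d exclusion volumes", model.name, len(new_xvols))
    return out


# ---------------------------------------------------------------------------
# ligand-based shared-feature models

_KIND_PRIORITY = [FeatureKind.NI, FeatureKind.PI, FeatureKind.AI,
                  FeatureKind.HBA, FeatureKind.HBD, FeatureKind.HC,
                  FeatureKind.MB]


def _best_alignment(ref_feats, other_feats):
    """Largest-correspondence rigid alignment of one feature set onto another.

    Returns (matched reference indices, rmsd) for the best conformer-level
    alignment: maximise the number of same-kind pairs whose post-alignment
    distance is within the summed tolerances; ties broken by lowest RMSD over
    the paired centres.
    """
    import itertools

    import networkx as nx

    rcent = np.array([f.center for f in ref_feats])
    ocent = np.array([f.center for f in other_feats])
    rd = np.linalg.norm(rcent[:, None] - rcent[None, :], axis=-1)
    od = np.linalg.norm(ocent[:, None] - ocent[None, :], axis=-1)
    nodes = [(i, j) for i, rf in enumerate(ref_feats)
             for j, of in enumerate(other_feats) if rf.kind == of.kind]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (i, j), (k, l) in itertools.combinations(nodes, 2):
        if i == k or j == l:
            continue
        tol = ref_feats[i].tolerance + ref_feats[k].tolerance
        if abs(rd[i, k] - od[j, l]) <= tol + 1e-9:
            g.add_edge((i, j), (k, l))
    best: tuple[int, float, set[int]] | None = None  # (-count, rmsd, matched)
    for clique in nx.find_cliques(g):
        corr = dict(clique)
        mi = sorted(corr)
        oj = [corr[i] for i in mi]
        R, t = superpose(ocent[oj], rcent[mi])
        moved = apply_rigid(ocent[oj], R, t)
        dist = np.linalg.norm(moved - rcent[mi], axis=1)
        tols = np.array([ref_feats[i].tolerance + other_feats[corr[i]].tolerance
                         for i in mi])
        matched = {i for i, d, tl in zip(mi, dist, tols) if d <= tl + 1e-9}
        if not matched:
            continue
        sel = [k for k, i in enumerate(mi) if i in matched]
        rmsd = float(np.sqrt(np.mean(dist[sel] ** 2)))
        cand = (-len(matched), rmsd, matched)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return set(), float("inf")
    return best[2], best[1]


def shared_feature_model(actives: list[ConformerSet], reference: str,
                         feature_rules: FeatureRuleSet | None = None,
                         name: str = "shared-feature") -> PharmacophoreModel:
    """Ligand-based model containing only features shared by all training actives.

    The reference molecule's first conformer fixes the frame.  Every other
    training compound contributes its best conformer-level alignment onto the
    reference feature set; reference features matched in *every* compound
    survive into the model.
    """
    if len(actives) < 2:
        raise ValueError("shared-feature model needs at least 2 training actives")
    by_id = {cs.mol_id: cs for cs in actives}
    if reference not in by_id:
        raise ValueError(f"reference {reference!r} not among the actives")
    ref = by_id[reference]
    if ref.n_conformers == 0:
        raise ValueError("reference molecule has no conformer")
    ref_feats = perceive_features(ref, 0, feature_rules)
    if not ref_feats:
        raise ValueError("no features perceivable on the reference molecule")

    surviving = set(range(len(ref_feats)))
    for cs in actives:
        if cs.mol_id == reference:
            continue
        if cs.n_conformers == 0:
            raise ValueError(f"training active {cs.mol_id!r} has no conformer")
        best_matched: set[int] = set()
        best_rmsd = float("inf")
        for ci in range(cs.n_conformers):
            feats = perceive_features(cs, ci, feature_rules)
            matched, rmsd = _best_alignment(ref_feats, feats)
            if (len(matched), -rmsd) > (len(best_matched), -best_rmsd):
                best_matched, best_rmsd = matched, rmsd
        surviving &= best_matched
        if not surviving:
            counts: dict[str, int] = {}
            for f in ref_feats:
                counts[f.kind.value] = counts.get(f.kind.value, 0) + 1
            raise ValueError(
                "no feature shared by all training compounds; reference "
                f"per-kind counts: {counts}")

    feats = [ref_feats[i] for i in sorted(surviving)]
    return PharmacophoreModel(name, sort_features(feats))


# ---------------------------------------------------------------------------
# manual refinement

REFINE_EDITS = ("remove_feature", "resize_feature", "add_xvol", "remove_xvol",
                "resize_xvol")


def refine_model(model: PharmacophoreModel, edit: str, params: dict,
                 actives: list[ConformerSet] | None = None,
                 decoys: list[ConformerSet] | None = None):
    """Apply one explicit model edit; optionally report enrichment before/after.

    Edits: ``remove_feature {index}``, ``resize_feature {index, tolerance}``,
    ``add_xvol {center, radius}``, ``remove_xvol {index}``,
    ``resize_xvol {index, radius}``.  With actives and decoys supplied, the
    edited model is screened on both sets and (edited_model, report_before,
    report_after) is returned so the edit can be accepted or reverted; there
    is no automatic optimization loop.
    """
    if edit not in REFINE_EDITS:
        raise ValueError(f"unknown edit {edit!r}; choose from {REFINE_EDITS}")
    out = model.copy()
    if edit in ("remove_feature", "resize_feature"):
        idx = params["index"]
        if not (0 <= idx < out.n_features):
            raise IndexError(f"feature index {idx} out of range")
        if edit == "remove_feature":
            if out.n_features == 1:
                raise ValueError("cannot remove the last feature of a model")
            out.features = out.features[:idx] + out.features[idx + 1:]
        else:
            out.features = list(out.features)
            out.features[idx] = replace(out.features[idx],
                                        tolerance=float(params["tolerance"]))
    elif edit == "add_xvol":
        out.xvols = out.xvols + [ExclusionVolume(tuple(params["center"]),
                                                 float(params.get("radius", 1.0)))]
    else:
        idx = params["index"]
        if not (0 <= idx < out.n_xvols):
            raise IndexError(f"Xvol index {idx} out of range")
        if edit == "remove_xvol":
            out.xvols = out.xvols[:idx] + out.xvols[idx + 1:]
        else:
            out.xvols = list(out.xvols)
            out.xvols[idx] = ExclusionVolume(out.xvols[idx].center,
                                             float(params["radius"]))
    if actives is None or decoys is None:
        return out
    from .valmetrics import evaluate_model
    before = evaluate_model(model, actives, decoys)
    after = evaluate_model(out, actives, decoys)
    return out, before, after
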