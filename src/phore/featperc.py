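"""Ligand-side pharmacophore feature perception.

A pharmacophore feature is a typed tolerance sphere placed on a 3D conformer:
negatively/positively ionizable groups (NI/PI), hydrogen-bond donors and
acceptors (HBD/HBA), hydrophobic contacts (HC), aromatic interactions (AI) and
metal-binding groups (MB).  Perception is rule-based: SMARTS patterns with a
placement policy for the charged/polar kinds, algorithmic cluster and ring
detection for HC and AI.  Ionization follows a fixed physiological-pH rule
table (carboxylic acids treated as deprotonated, aliphatic amines as
protonated); no pKa calculation is attempted.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

__all__ = [
    "FeatureKind",
    "PharmacophoreFeature",
    "FeatureRule",
    "FeatureRuleSet",
    "default_rules",
    "perceive_features",
    "transform_features",
]

DEFAULT_TOLERANCE = 1.5  # Å, ligand-side default for every feature kind


class FeatureKind(str, enum.Enum):
    """Closed taxonomy of interaction feature types."""

    NI = "NI"   # negatively ionizable
    PI = "PI"   # positively ionizable
    HBD = "HBD"  # hydrogen-bond donor
    HBA = "HBA"  # hydrogen-bond acceptor
    HC = "HC"   # hydrophobic contact
    AI = "AI"   # aromatic interaction
    MB = "MB"   # metal binding

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_KIND_ORDER = {k: i for i, k in enumerate(FeatureKind)}


@dataclass(frozen=True)
class PharmacophoreFeature:
    """A typed tolerance sphere, optionally with a direction vector.

    ``center`` and ``direction`` are in Å in whatever frame the feature was
    perceived in (ligand conformer frame, or protein frame for model
    features).  ``origin_atoms`` records the 0-based ligand atom indices the
    feature was derived from.
    """

    kind: FeatureKind
    center: tuple[float, float, float]
    tolerance: float = DEFAULT_TOLERANCE
    direction: tuple[float, float, float] | None = None
    origin_atoms: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.tolerance <= 5.0):
            raise ValueError(f"tolerance must be in (0, 5], got {self.tolerance}")
        if self.direction is not None:
            n = float(np.linalg.norm(self.direction))
            if abs(n - 1.0) > 1e-6:
                raise ValueError("direction must be a unit vector")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    def with_tolerance(self, tol: float) -> "PharmacophoreFeature":
        return replace(self, tolerance=tol)


@dataclass(frozen=True)
class FeatureRule:
    """One SMARTS-driven perception rule.

    ``focus`` selects, by index into the SMARTS match, the atoms over which
    the placement is computed (e.g. the two acidic oxygens of a carboxylate);
    when empty the whole match is used.
    """

    kind: FeatureKind
    smarts: str
    placement: str = "centroid"  # centroid | atom | midpoint
    focus: tuple[int, ...] = ()

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS in rule: {self.smarts}")
        return patt


@dataclass
class FeatureRuleSet:
    rules: list[FeatureRule] = field(default_factory=list)
    tolerance: float = DEFAULT_TOLERANCE
    hc_min_cluster: int = 3
    hc_split_threshold: int = 6

    def for_kind(self, kind: FeatureKind) -> list[FeatureRule]:
        return [r for r in self.rules if r.kind == kind]


def default_rules() -> FeatureRuleSet:
    """The documented default perception table (fixed pH-7.4 ionization).

    NI: carboxylate, phosphonate/phosphate, sulfonate, tetrazole,
    acyl-sulfonamide.  PI: aliphatic amines, amidines, guanidines.
    HBA: N/O bearing a lone pair, excluding amide/anilinic nitrogens and
    protonated amines.  HBD: N–H, O–H, S–H.  MB: thiol sulfur, hydroxamate
    oxygens, carboxylate oxygens (co-existing with NI by design).
    HC and AI are algorithmic (apolar clusters / aromatic rings), not SMARTS.
    """
    R = FeatureRule
    K = FeatureKind
    rules = [
        # --- negatively ionizable ------------------------------------------
        R(K.NI, "[CX3](=[OX1])[OX2H1,OX1-]", focus=(1, 2)),          # carboxylic acid / carboxylate
        R(K.NI, "[PX4](=[OX1])([OX2H1,OX1-])[OX2H1,OX1-]", focus=(1, 2, 3)),  # phosphonate/phosphate
        R(K.NI, "[SX4](=[OX1])(=[OX1])[OX2H1,OX1-]", focus=(1, 2, 3)),        # sulfonate
        R(K.NI, "c1nnn[nH1,n-]1"),                                    # tetrazole (carboxylate bioisostere)
        R(K.NI, "[CX3](=[OX1])[NX3;H1,H0-][SX4](=[OX1])(=[OX1])", focus=(2,)),  # acyl sulfonamide
        # --- positively ionizable ------------------------------------------
        R(K.PI, "[NX3;H2,H1,H0;+0,+1;!$(N~[!#6;!#1]);!$(NC=[O,N,S]);!$(Nc)]",
          placement="atom", focus=(0,)),                              # aliphatic amine
        R(K.PI, "[NX3][CX3](=[NX2])[NX3]", placement="atom", focus=(1,)),  # guanidine
        R(K.PI, "[NX3][CX3;!$(C([NX3])[NX3])]=[NX2]", placement="atom", focus=(1,)),  # amidine
        # --- hydrogen-bond donors ------------------------------------------
        R(K.HBD, "[#7;H1,H2,H3;+0,+1]", placement="atom", focus=(0,)),
        R(K.HBD, "[OX2H1]", placement="atom", focus=(0,)),
        R(K.HBD, "[SX2H1]", placement="atom", focus=(0,)),
        # --- hydrogen-bond acceptors ---------------------------------------
        R(K.HBA, "[OX2;H0,H1;!$(O=*)]", placement="atom", focus=(0,)),
        R(K.HBA, "[OX1]", placement="atom", focus=(0,)),
        R(K.HBA, "[nX2]", placement="atom", focus=(0,)),
        R(K.HBA, "[NX2;!$(N=[O,S])]", placement="atom", focus=(0,)),
        R(K.HBA, "[NX1]", placement="atom", focus=(0,)),
        R(K.HBA, "[NX3;H0;+0;!$(N[C,S,P]=[O,S,N]);!$(Nc);!$(Na)]", placement="atom", focus=(0,)),
        # --- metal binding --------------------------------------------------
        R(K.MB, "[SX2H1]", placement="atom", focus=(0,)),
        R(K.MB, "[CX3](=[OX1])[NX3][OX2H1,OX1-]", focus=(1, 3)),      # hydroxamate O pair
        R(K.MB, "[CX3](=[OX1])[OX2H1,OX1-]", focus=(1, 2)),           # carboxylate oxygens
    ]
    return FeatureRuleSet(rules=rules)


def _as_rdkit(mol) -> Chem.Mol:
    """Accept a ConformerSet-like object (``.mol``) or a plain RDKit Mol."""
    return getattr(mol, "mol", mol)


def _conf_coords(rdmol: Chem.Mol, conf_index: int) -> np.ndarray:
    if rdmol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3D conformer; embed it first")
    return np.asarray(rdmol.GetConformer(conf_index).GetPositions(), dtype=float)


def _unit(v: np.ndarray) -> tuple[float, float, float] | None:
    n = float(np.linalg.norm(v))
    if n < 1e-8:
        return None
    u = v / n
    return (float(u[0]), float(u[1]), float(u[2]))


def _lone_pair_direction(rdmol, coords, idx) -> tuple[float, float, float] | None:
    """Approximate acceptor lone-pair direction: away from bonded neighbours."""
    nbrs = [n.GetIdx() for n in rdmol.GetAtomWithIdx(idx).GetNeighbors()
            if n.GetAtomicNum() > 1]
    if not nbrs:
        return None
    vecs = []
    for j in nbrs:
        v = coords[idx] - coords[j]
        n = np.linalg.norm(v)
        if n > 1e-8:
            vecs.append(v / n)
    if not vecs:
        return None
    return _unit(np.mean(vecs, axis=0))


def _donor_direction(rdmol, coords, idx) -> tuple[float, float, float] | None:
    """H direction if explicit hydrogens carry coordinates, else lone-pair style."""
    hs = [n.GetIdx() for n in rdmol.GetAtomWithIdx(idx).GetNeighbors()
          if n.GetAtomicNum() == 1]
    if hs:
        v = np.mean([coords[h] - coords[idx] for h in hs], axis=0)
        return _unit(v)
    return _lone_pair_direction(rdmol, coords, idx)


def _apolar_carbon(atom: Chem.Atom) -> bool:
    if atom.GetAtomicNum() != 6:
        return False
    return all(n.GetAtomicNum() in (1, 6) for n in atom.GetNeighbors())


def _hc_features(rdmol, coords, rules: FeatureRuleSet) -> list[PharmacophoreFeature]:
    """Hydrophobic features: centroids of connected apolar heavy-atom clusters.

    Clusters of >= ``hc_split_threshold`` atoms are split per aromatic ring /
    residual chain fragment so each lipophilic moiety gets its own feature.
    """
    import networkx as nx

    eligible = {a.GetIdx() for a in rdmol.GetAtoms() if _apolar_carbon(a)}
    g = nx.Graph()
    g.add_nodes_from(eligible)
    for b in rdmol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in eligible and j in eligible:
            g.add_edge(i, j)
    ring_info = rdmol.GetRingInfo()
    feats: list[PharmacophoreFeature] = []

    def emit(atom_ids):
        atom_ids = tuple(sorted(atom_ids))
        c = coords[list(atom_ids)].mean(axis=0)
        feats.append(PharmacophoreFeature(
            FeatureKind.HC, tuple(np.round(c, 10)), rules.tolerance,
            origin_atoms=atom_ids))

    for comp in nx.connected_components(g):
        if len(comp) < rules.hc_min_cluster:
            continue
        if len(comp) < rules.hc_split_threshold:
            emit(comp)
            continue
        covered: set[int] = set()
        for ring in ring_info.AtomRings():
            ring_set = set(ring)
            if ring_set <= comp and not ring_set <= covered:
                emit(ring_set)
                covered |= ring_set
        rest = g.subgraph(comp - covered)
        for sub in nx.connected_components(rest):
            if len(sub) >= rules.hc_min_cluster:
                emit(sub)
    return feats


def _ai_features(rdmol, coords, rules: FeatureRuleSet) -> list[PharmacophoreFeature]:
    feats = []
    for ring in rdmol.GetRingInfo().AtomRings():
        if not all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        pts = coords[list(ring)]
        centroid = pts.mean(axis=0)
        # ring normal from SVD of centred ring atoms
        _, _, vt = np.linalg.svd(pts - centroid)
        normal = _unit(vt[2])
        feats.append(PharmacophoreFeature(
            FeatureKind.AI, tuple(np.round(centroid, 10)), rules.tolerance,
            direction=normal, origin_atoms=tuple(sorted(ring))))
    return feats


def sort_features(feats: list[PharmacophoreFeature]) -> list[PharmacophoreFeature]:
    """Canonical order: kind, then lexicographic center."""
    return sorted(feats, key=lambda f: (_KIND_ORDER[f.kind], f.center))


def perceive_features(mol, conf_index: int = 0,
                      rules: FeatureRuleSet | None = None) -> list[PharmacophoreFeature]:
    """Perceive all pharmacophore feature candidates on one conformer.

    ``mol`` may be a :class:`phore.molio.ConformerSet` or a plain RDKit Mol
    with at least one conformer.  Output is deterministic and canonically
    sorted; same-kind features landing on the same centre are deduplicated.
    """
    rules = rules or default_rules()
    rdmol = _as_rdkit(mol)
    coords = _conf_coords(rdmol, conf_index)

    feats: list[PharmacophoreFeature] = []
    seen: set[tuple] = set()
    for rule in rules.rules:
        patt = rule.pattern()
        for match in rdmol.GetSubstructMatches(patt, uniquify=True):
            focus = rule.focus if rule.focus else tuple(range(len(match)))
            atom_ids = tuple(sorted(match[i] for i in focus))
            pts = coords[list(atom_ids)]
            center = tuple(np.round(pts.mean(axis=0), 10))
            key = (rule.kind, tuple(np.round(center, 3)))
            if key in seen:
                continue
            seen.add(key)
            direction = None
            if rule.kind == FeatureKind.HBA and len(atom_ids) == 1:
                direction = _lone_pair_direction(rdmol, coords, atom_ids[0])
            elif rule.kind == FeatureKind.HBD and len(atom_ids) == 1:
                direction = _donor_direction(rdmol, coords, atom_ids[0])
            feats.append(PharmacophoreFeature(
                rule.kind, center, rules.tolerance,
                direction=direction, origin_atoms=atom_ids))

    feats.extend(_hc_features(rdmol, coords, rules))
    feats.extend(_ai_features(rdmol, coords, rules))
    return sort_features(feats)


def transform_features(feats: list[PharmacophoreFeature], R: np.ndarray,
                       t: np.ndarray) -> list[PharmacophoreFeature]:
    """Apply a rigid transform (centres by R,t; directions by R only)."""
    out = []
    for f in feats:
        c = np.asarray(f.center) @ np.asarray(R).T + np.asarray(t)
        d = None
        if f.direction is not None:
            dv = np.asarray(f.direction) @ np.asarray(R).T
            d = _unit(dv)
        out.append(replace(f, center=tuple(c), direction=d))
    return out
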