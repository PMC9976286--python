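"""Synthetic fixtures with provable ground truth.

Everything the pipeline needs for testing is generated here, without any
download: libraries of "actives" whose conformers carry a planted feature
geometry that exactly realises a reference pharmacophore model, decoys built
from the same scaffolds but altered so that matching is impossible, toy
protein–ligand complexes whose contacts satisfy the interaction-geometry
rules with a safety margin, random confusion tables, and synthetic screening
records mirroring a given consensus/unique hit accounting.

Planted molecules are assembled from a small fragment vocabulary (carboxylate,
amine, hydroxyl, ether, thiol, phenyl/pyrimidinyl rings, alkyl clusters) wired
together by ether-type linkers with deterministic coordinates; no
conformational sampling is involved, which keeps the ground truth provable.
Linkers alternate C and O on purpose: the oxygens break up apolar clusters so
no stray hydrophobic feature appears, at the cost of harmless extra
hydrogen-bond-acceptor candidates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .featperc import FeatureKind, PharmacophoreFeature, perceive_features
from .geometry import random_rotation
from .model import ExclusionVolume, PharmacophoreModel
from .molio import ActivityTable, ConformerSet
from .screen import HitRecord, MatchResult

__all__ = [
    "PlantSpec", "generate_planted_library", "plant_template", "example_model",
    "ToyComplex", "generate_toy_complex", "random_confusion",
    "consensus_records",
]


# ---------------------------------------------------------------------------
# low-level molecule assembly

_BOND = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE}


class _MolBuilder:
    def __init__(self) -> None:
        self.atoms: list[tuple[str, int, np.ndarray]] = []
        self.bonds: list[tuple[int, int, int]] = []

    def add_atom(self, symbol: str, pos, charge: int = 0) -> int:
        self.atoms.append((symbol, charge, np.asarray(pos, dtype=float)))
        return len(self.atoms) - 1

    def add_bond(self, i: int, j: int, order: int = 1) -> None:
        self.bonds.append((i, j, order))

    def coords(self) -> np.ndarray:
        return np.array([p for _, _, p in self.atoms])

    def build(self, mol_id: str, source_tag: str = "synthetic") -> ConformerSet:
        rw = Chem.RWMol()
        for sym, charge, _ in self.atoms:
            a = Chem.Atom(sym)
            a.SetFormalCharge(charge)
            rw.AddAtom(a)
        for i, j, order in self.bonds:
            rw.AddBond(i, j, _BOND[order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (_, _, p) in enumerate(self.atoms):
            conf.SetAtomPosition(i, tuple(float(v) for v in p))
        mol.AddConformer(conf, assignId=True)
        cs = ConformerSet(mol_id, mol, source_tag=source_tag)
        return cs


def _perp(u: np.ndarray) -> np.ndarray:
    trial = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, trial)
    return v / np.linalg.norm(v)


@dataclass
class _Fragment:
    atom_ids: list[int]
    anchor: int            # sp3 carbon accepting linker bonds
    feature_atoms: list[int]
    kind: FeatureKind


def _add_fragment(b: _MolBuilder, kind: FeatureKind, center: np.ndarray,
                  u: np.ndarray, aromatic_variant: str = "benzene") -> _Fragment:
    """Place one interaction fragment whose perceived feature centre is `center`.

    ``u`` is the unit vector pointing from the feature towards the molecule
    interior (the anchor side).
    """
    c = np.asarray(center, dtype=float)
    v = _perp(u)
    w = np.cross(u, v)
    if kind == FeatureKind.NI:
        # carboxylate: perceived NI (and MB) at the O–O midpoint
        C = b.add_atom("C", c + 0.572 * u)
        O1 = b.add_atom("O", c + 1.122 * v)
        O2 = b.add_atom("O", c - 1.122 * v, charge=-1)
        A = b.add_atom("C", c + 2.07 * u)
        b.add_bond(C, O1, 2)
        b.add_bond(C, O2, 1)
        b.add_bond(C, A, 1)
        return _Fragment([C, O1, O2, A], A, [C, O1, O2], kind)
    if kind == FeatureKind.PI:
        N = b.add_atom("N", c)
        A = b.add_atom("C", c + 1.5 * u)
        b.add_bond(N, A, 1)
        return _Fragment([N, A], A, [N], kind)
    if kind == FeatureKind.HBD:
        O = b.add_atom("O", c)  # hydroxyl (implicit H): donor and acceptor
        A = b.add_atom("C", c + 1.4 * u)
        b.add_bond(O, A, 1)
        return _Fragment([O, A], A, [O], kind)
    if kind == FeatureKind.HBA:
        O = b.add_atom("O", c)  # dialkyl ether: pure acceptor
        Me = b.add_atom("C", c - 1.4 * u)
        A = b.add_atom("C", c + 1.4 * u)
        b.add_bond(O, Me, 1)
        b.add_bond(O, A, 1)
        return _Fragment([O, Me, A], A, [O], kind)
    if kind == FeatureKind.MB:
        S = b.add_atom("S", c)  # thiol (implicit H)
        A = b.add_atom("C", c + 1.8 * u)
        b.add_bond(S, A, 1)
        return _Fragment([S, A], A, [S], kind)
    if kind == FeatureKind.AI:
        if aromatic_variant == "pyrimidine":
            # ring N's silence the apolar cluster so no stray HC appears
            symbols = ["N", "C", "N", "C", "C", "C"]
            kek = [2, 1, 2, 1, 2, 1]  # bond orders around the ring
            attach_pos = 4            # C5, flanked by carbons
        else:
            symbols = ["C"] * 6
            kek = [2, 1, 2, 1, 2, 1]
            attach_pos = 0
        ids = []
        for k in range(6):
            theta = math.radians(60.0 * (k - attach_pos))
            pos = c + 1.39 * (math.cos(theta) * u + math.sin(theta) * v)
            ids.append(b.add_atom(symbols[k], pos))
        for k in range(6):
            b.add_bond(ids[k], ids[(k + 1) % 6], kek[k])
        A = b.add_atom("C", c + 2.89 * u)
        b.add_bond(ids[attach_pos], A, 1)
        return _Fragment(ids + [A], A, ids, kind)
    if kind == FeatureKind.HC:
        ids = []
        prev = None
        for k in range(1, 5):  # four-carbon chain, centroid at `center`
            pos = c + (k - 2.5) * 1.5 * v
            idx = b.add_atom("C", pos)
            if prev is not None:
                b.add_bond(prev, idx, 1)
            ids.append(idx)
            prev = idx
        A = b.add_atom("C", c - 2.25 * v + 1.5 * u)
        b.add_bond(A, ids[0], 1)
        return _Fragment(ids + [A], A, ids, kind)
    raise ValueError(f"unknown feature kind {kind!r}")


def _link(b: _MolBuilder, a1: int, a2: int, bow: float = 2.0) -> list[int]:
    """Ether-type linker between two anchor carbons (first atom is oxygen).

    The path bows sideways (towards -y when possible) so it neither threads
    through fragment atoms nor approaches the protein side of a toy pocket.
    """
    p, q = b.atoms[a1][2], b.atoms[a2][2]
    d = q - p
    dist = float(np.linalg.norm(d))
    w = np.cross(d, np.array([0.0, 0.0, 1.0]))
    nw = np.linalg.norm(w)
    w = w / nw if nw > 1e-6 else np.array([1.0, 0.0, 0.0])
    if w[1] > 0:
        w = -w
    n_pts = max(1, int(round(dist / 1.45)) - 1)
    prev = a1
    ids = []
    for k in range(1, n_pts + 1):
        frac = k / (n_pts + 1)
        pos = p + d * frac + bow * math.sin(math.pi * frac) * w
        sym = "O" if k % 2 == 1 else "C"
        idx = b.add_atom(sym, pos)
        b.add_bond(prev, idx, 1)
        ids.append(idx)
        prev = idx
    b.add_bond(prev, a2, 1)
    return ids


# ---------------------------------------------------------------------------
# planted libraries

@dataclass
class PlantSpec:
    """Study conditions for one planted library."""

    model: PharmacophoreModel
    n_actives: int = 10
    n_decoys: int = 100
    noise_sd: float = 0.0          # Å Gaussian jitter on every heavy atom
    decoy_mode: str = "displace_one_feature"
    seed: int = 0

    DECOY_MODES = ("displace_one_feature", "wrong_kind", "xvol_clash")

    def __post_init__(self) -> None:
        if self.n_actives < 0 or self.n_decoys < 0:
            raise ValueError("n_actives and n_decoys must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.decoy_mode not in self.DECOY_MODES:
            raise ValueError(f"decoy_mode must be one of {self.DECOY_MODES}")


def example_model(name: str = "planted") -> PharmacophoreModel:
    """A canonical four-feature reference model used across tests and demos.

    One negatively ionizable group, one acceptor, one aromatic ring and one
    basic amine spread over ~12 Å, all with the default 1.5 Å tolerance —
    scaled after the mixed-feature anchor arrangements of real binding-site
    models.
    """
    f = [
        PharmacophoreFeature(FeatureKind.NI, (0.0, 0.0, 0.0)),
        PharmacophoreFeature(FeatureKind.HBA, (4.2, 3.0, 0.0)),
        PharmacophoreFeature(FeatureKind.AI, (8.5, 0.0, 0.0)),
        PharmacophoreFeature(FeatureKind.PI, (12.0, 3.0, 0.0)),
    ]
    return PharmacophoreModel(name, f)


def _build_template(model: PharmacophoreModel,
                    aromatic_variant: str = "benzene"
                    ) -> tuple[_MolBuilder, list[_Fragment]]:
    centers = model.feature_centers()
    if len(centers) >= 2:
        pd = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        iu = np.triu_indices(len(centers), 1)
        if np.min(pd[iu]) < 1.5:
            raise ValueError("model geometry chemically unrealizable: "
                             "features closer than 1.5 Å")
    hub = centers.mean(axis=0)
    b = _MolBuilder()
    frags: list[_Fragment] = []
    for f in model.features:
        c = f.center_array
        u = hub - c
        nu = np.linalg.norm(u)
        u = u / nu if nu > 1e-6 else np.array([1.0, 0.0, 0.0])
        frags.append(_add_fragment(b, f.kind, c, u, aromatic_variant))
    for f1, f2 in zip(frags, frags[1:]):
        _link(b, f1.anchor, f2.anchor)
    return b, frags


def plant_template(model: PharmacophoreModel,
                   mol_id: str = "template") -> ConformerSet:
    """The rigid scaffold realising a model's feature geometry exactly.

    Raises if the construction fails to reproduce every model feature, or if
    a scaffold atom would sit inside one of the model's exclusion volumes.
    """
    b, _ = _build_template(model)
    cs = b.build(mol_id)
    _verify_template(cs, model)
    return cs


def _verify_template(cs: ConformerSet, model: PharmacophoreModel,
                     tol: float = 0.2) -> None:
    feats = perceive_features(cs)
    for mf in model.features:
        ok = any(f.kind == mf.kind
                 and np.linalg.norm(f.center_array - mf.center_array) <= tol
                 for f in feats)
        if not ok:
            raise RuntimeError(
                f"template construction failed to realise {mf.kind} at "
                f"{mf.center}")
    if model.xvols:
        hv = cs.heavy_coords(0)
        for xv in model.xvols:
            if np.min(np.linalg.norm(hv - xv.center_array, axis=1)) < xv.radius:
                raise ValueError("model exclusion volumes overlap the "
                                 "constructed scaffold; move or shrink them")


_DISPLACE_PRIORITY = [FeatureKind.NI, FeatureKind.PI, FeatureKind.AI,
                      FeatureKind.HC, FeatureKind.MB]


def _unique_kind_index(model: PharmacophoreModel, template_feats) -> int:
    """Model feature whose kind occurs exactly once on the template scaffold.

    Linkers contribute no NI/PI/AI/HC/MB candidates, so displacing (or
    mutating) such a feature's fragment leaves the model unmatchable.
    """
    t_counts: dict[FeatureKind, int] = {}
    for f in template_feats:
        t_counts[f.kind] = t_counts.get(f.kind, 0) + 1
    for kind in _DISPLACE_PRIORITY:
        for i, mf in enumerate(model.features):
            if mf.kind == kind and t_counts.get(kind, 0) == 1:
                return i
    raise ValueError(
        "no uniquely-realised NI/PI/AI/HC/MB feature available; this decoy "
        "mode needs one feature kind without substitutable candidates")


def _displaced_decoy(model: PharmacophoreModel) -> _MolBuilder:
    """Move one fragment far enough that no rigid frame can restore it.

    The displaced feature's distance to every remaining feature ends up
    larger than any model inter-feature distance plus the summed tolerances,
    so the pairwise-distance compatibility that any successful superposition
    implies is violated for every candidate correspondence.
    """
    b, frags = _build_template(model)
    cs = b.build("probe")
    feats = perceive_features(cs)
    idx = _unique_kind_index(model, feats)
    centers = model.feature_centers()
    tols = [f.tolerance for f in model.features]
    if len(centers) < 2:
        raise ValueError("displace_one_feature needs a model with >= 2 features")
    pd = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    diameter = float(np.max(np.linalg.norm(
        b.coords()[:, None] - b.coords()[None, :], axis=-1)))
    L = float(np.max(pd)) + 2 * (2 * max(tols)) + diameter + 2.0
    hub = centers.mean(axis=0)
    u = centers[idx] - hub
    nu = np.linalg.norm(u)
    u = u / nu if nu > 1e-6 else np.array([1.0, 0.0, 0.0])
    moved = frags[idx].feature_atoms  # anchor stays: one bond stretches
    for ai in moved:
        sym, ch, pos = b.atoms[ai]
        b.atoms[ai] = (sym, ch, pos + L * u)
    # the guarantee, checked: displaced centre far from every other feature
    new_center = np.mean([b.atoms[ai][2] for ai in moved], axis=0)
    others = np.delete(centers, idx, axis=0)
    needed = float(np.max(pd)) + 2 * max(tols)
    if np.min(np.linalg.norm(others - new_center, axis=1)) <= needed:
        raise RuntimeError("displacement failed to break pair compatibility")
    return b


def _wrong_kind_decoy(model: PharmacophoreModel) -> _MolBuilder:
    """Mutate one fragment so its feature kind disappears from the molecule."""
    b, frags = _build_template(model)
    cs = b.build("probe")
    feats = perceive_features(cs)
    idx = _unique_kind_index(model, feats)
    frag = frags[idx]
    kind = model.features[idx].kind
    if kind == FeatureKind.NI:
        C, O1, O2 = frag.feature_atoms  # carboxylate -> ketone
        sym, _, pos = b.atoms[O2]
        b.atoms[O2] = ("C", 0, pos)
    elif kind == FeatureKind.PI:
        N = frag.feature_atoms[0]       # amine -> hydroxyl
        _, _, pos = b.atoms[N]
        b.atoms[N] = ("O", 0, pos)
    elif kind == FeatureKind.AI:
        ring = set(frag.feature_atoms)  # aromatic ring -> saturated ring
        b.bonds = [(i, j, 1) if i in ring and j in ring else (i, j, o)
                   for i, j, o in b.bonds]
    elif kind == FeatureKind.HC:
        chain = frag.feature_atoms      # alkyl chain -> oxygenated chain
        sym, _, pos = b.atoms[chain[1]]
        b.atoms[chain[1]] = ("O", 0, pos)
        sym, _, pos = b.atoms[chain[3]]
        b.atoms[chain[3]] = ("O", 0, pos)
    elif kind == FeatureKind.MB:
        S = frag.feature_atoms[0]       # thiol -> methyl
        _, _, pos = b.atoms[S]
        b.atoms[S] = ("C", 0, pos)
    return b


def _xvol_clash_decoy(model: PharmacophoreModel,
                      rng: np.random.Generator) -> _MolBuilder:
    """Active-like scaffold plus a carbon placed at an exclusion volume centre."""
    if not model.xvols:
        raise ValueError("xvol_clash decoys need a model with exclusion volumes")
    b, frags = _build_template(model)
    xv = model.xvols[int(rng.integers(len(model.xvols)))]
    target = xv.center_array
    # bond the clash atom to the nearest carbon that already has an oxygen
    # neighbour (anchor/linker carbons), so no hydrophobic cluster is altered
    oxy_neighbours: dict[int, bool] = {}
    nbrs: dict[int, list[int]] = {}
    for i, j, _ in b.bonds:
        nbrs.setdefault(i, []).append(j)
        nbrs.setdefault(j, []).append(i)
    candidates = [i for i, (sym, _, _) in enumerate(b.atoms)
                  if sym == "C" and any(b.atoms[k][0] == "O"
                                        for k in nbrs.get(i, []))]
    if not candidates:
        candidates = [i for i, (sym, _, _) in enumerate(b.atoms) if sym == "C"]
    dists = [np.linalg.norm(b.atoms[i][2] - target) for i in candidates]
    host = candidates[int(np.argmin(dists))]
    clash = b.add_atom("C", target)
    b.add_bond(host, clash, 1)
    return b


def generate_planted_library(spec: PlantSpec
                             ) -> tuple[list[ConformerSet], ActivityTable]:
    """Planted actives and unmatchable decoys for a reference model.

    Actives are rigid copies of the template scaffold under a random rigid
    motion plus per-atom Gaussian jitter of ``noise_sd`` Å; at zero noise
    every active matches the model exactly.  Decoys are the same scaffold
    altered per ``decoy_mode`` so that matching is impossible (for
    ``xvol_clash``: impossible only while the Xvol check is on).  Fully
    deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    template = plant_template(spec.model)

    if spec.n_decoys > 0:
        if spec.decoy_mode == "displace_one_feature":
            decoy_builder = _displaced_decoy(spec.model)
        elif spec.decoy_mode == "wrong_kind":
            decoy_builder = _wrong_kind_decoy(spec.model)
        else:
            decoy_builder = _xvol_clash_decoy(spec.model, rng)
        decoy_base = decoy_builder.build("decoy_base")

    library: list[ConformerSet] = []
    labels = ActivityTable()

    def jittered_copy(base: ConformerSet, mol_id: str) -> ConformerSet:
        out = base.copy()
        out.mol_id = mol_id
        coords = out.coords(0)
        coords = coords + rng.normal(0.0, spec.noise_sd, coords.shape) \
            if spec.noise_sd > 0 else coords.copy()
        R = random_rotation(rng)
        t = rng.uniform(-20.0, 20.0, 3)
        coords = coords @ R.T + t
        conf = out.mol.GetConformer(0)
        for i, p in enumerate(coords):
            conf.SetAtomPosition(i, tuple(float(v) for v in p))
        return out

    for i in range(spec.n_actives):
        cs = jittered_copy(template, f"act{i:03d}")
        library.append(cs)
        labels.add(cs.mol_id, "active")
    for i in range(spec.n_decoys):
        cs = jittered_copy(decoy_base, f"dec{i:03d}")
        library.append(cs)
        labels.add(cs.mol_id, "decoy")
    return library, labels


# ---------------------------------------------------------------------------
# toy protein–ligand complexes

_RESIDUE_PARTNERS = {
    FeatureKind.NI: "ARG", FeatureKind.PI: "ASP", FeatureKind.HBD: "GLY",
    FeatureKind.HBA: "SER", FeatureKind.HC: "LEU", FeatureKind.AI: "PHE",
    FeatureKind.MB: "ZN",
}


@dataclass
class ToyComplex:
    pdb_text: str
    ligand_resname: str
    ligand_template: str           # SMILES restoring bond orders
    expected_kinds: list[FeatureKind]
    ground_truth: list[PharmacophoreFeature] = field(default_factory=list)

    def write(self, path) -> Path:
        p = Path(path)
        p.write_text(self.pdb_text)
        return p


def _pdb_atom_line(record: str, serial: int, name: str, resname: str,
                   chain: str, resseq: int, pos, element: str) -> str:
    x, y, z = (float(v) for v in pos)
    return (f"{record:<6}{serial:>5} {name:<4}{'':1}{resname:<3} {chain}"
            f"{resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


def generate_toy_complex(kinds: list[FeatureKind], seed: int = 0) -> ToyComplex:
    """Minimal binding pocket whose contacts realise the requested kinds.

    The ligand carries one fragment per requested kind, spaced 8 Å apart;
    each fragment faces a minimal protein partner (arginine guanidinium for
    NI, aspartate carboxylate for PI, a backbone carbonyl for HBD, a serine
    hydroxyl for HBA, leucine side-chain carbons for HC, a phenylalanine ring
    for AI, a zinc ion for MB) placed comfortably inside the default
    interaction-geometry criteria.  Structure-based perception on the result
    recovers exactly the requested kinds.
    """
    if not kinds:
        raise ValueError("kinds must be non-empty")
    kinds = [FeatureKind(k) for k in kinds]
    for k in kinds:
        if k not in _RESIDUE_PARTNERS:
            raise ValueError(f"unknown feature kind {k!r}")

    b = _MolBuilder()
    frags = []
    centers = [np.array([8.0 * i, 0.0, 0.0]) for i in range(len(kinds))]
    hub = np.mean(centers, axis=0)
    for k, c in zip(kinds, centers):
        u = hub - c
        nu = np.linalg.norm(u)
        u = u / nu if nu > 1e-6 else np.array([1.0, 0.0, 0.0])
        frags.append(_add_fragment(b, k, c, u, aromatic_variant="pyrimidine"))
    for f1, f2 in zip(frags, frags[1:]):
        _link(b, f1.anchor, f2.anchor)
    ligand = b.build("LIG")
    smiles = Chem.MolToSmiles(ligand.mol)

    lines: list[str] = []
    serial = 1
    resseq = 1
    truth: list[PharmacophoreFeature] = []

    def emit(name, resname, pos, element, record="ATOM"):
        nonlocal serial
        lines.append(_pdb_atom_line(record, serial, name, resname, "A",
                                    resseq, pos, element))
        serial += 1

    for k, c, frag in zip(kinds, centers, frags):
        feat_center = np.mean([b.atoms[i][2] for i in frag.feature_atoms],
                              axis=0)
        truth.append(PharmacophoreFeature(k, tuple(feat_center)))
        if k == FeatureKind.NI:    # guanidinium centroid 5.0 Å, N–O > 3.8 Å
            emit("CD", "ARG", c + [0.0, 6.4, 0.0], "C")
            emit("NE", "ARG", c + [0.0, 6.3, 1.2], "N")
            emit("CZ", "ARG", c + [0.0, 5.0, 0.0], "C")
            emit("NH1", "ARG", c + [0.0, 5.0, 1.16], "N")
            emit("NH2", "ARG", c + [0.0, 5.0, -1.16], "N")
        elif k == FeatureKind.PI:  # carboxylate centroid 4.5 Å from the amine
            emit("CG", "ASP", c + [0.0, 5.6, 0.0], "C")
            emit("OD1", "ASP", c + [0.0, 4.5, 1.1], "O")
            emit("OD2", "ASP", c + [0.0, 4.5, -1.1], "O")
        elif k == FeatureKind.HBD:  # backbone carbonyl O at 3.1 Å
            emit("C", "GLY", c + [0.0, 4.3, 0.6], "C")
            emit("O", "GLY", c + [0.0, 3.1, 0.0], "O")
        elif k == FeatureKind.HBA:  # serine hydroxyl donor at 3.1 Å
            emit("CB", "SER", c + [0.0, 4.4, 0.7], "C")
            emit("OG", "SER", c + [0.0, 3.1, 0.0], "O")
        elif k == FeatureKind.HC:   # leucine side-chain carbons 3.6–4.6 Å
            emit("CG", "LEU", c + [0.0, 3.6, 0.0], "C")
            emit("CD1", "LEU", c + [0.0, 4.3, 1.2], "C")
            emit("CD2", "LEU", c + [0.0, 4.3, -1.2], "C")
        elif k == FeatureKind.AI:   # phenyl ring centroid 3.8 Å, parallel
            ring_c = c + np.array([0.0, 3.8, 0.0])
            names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
            for m, nm in enumerate(names):
                th = math.radians(60.0 * m)
                emit(nm, "PHE",
                     ring_c + 1.39 * np.array([math.cos(th), 0.0, math.sin(th)]),
                     "C")
        elif k == FeatureKind.MB:   # catalytic zinc at 2.3 Å
            emit("ZN", "ZN", c + [0.0, 2.3, 0.0], "Zn", record="HETATM")
        resseq += 1

    lig_serials = {}
    lig_res = 900
    for i, (sym, _, pos) in enumerate(b.atoms):
        name = f"{sym.upper()}{i + 1}"
        lines.append(_pdb_atom_line("HETATM", serial, name, "LIG", "A",
                                    lig_res, pos, sym.upper()))
        lig_serials[i] = serial
        serial += 1
    for i, j, _ in b.bonds:
        lines.append(f"CONECT{lig_serials[i]:>5}{lig_serials[j]:>5}")
    lines.append("END")
    return ToyComplex("\n".join(lines) + "\n", "LIG", smiles, kinds, truth)


# ---------------------------------------------------------------------------
# fuzzing and accounting fixtures

def random_confusion(n_actives: int, n_decoys: int, seed: int = 0,
                     trials: int = 100):
    """Uniform random valid confusion splits (TP+FN and FP+TN fixed)."""
    from .valmetrics import ConfusionCounts
    if n_actives < 1 or n_decoys < 1:
        raise ValueError("need at least one active and one decoy")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(trials):
        tp = int(rng.integers(0, n_actives + 1))
        fp = int(rng.integers(0, n_decoys + 1))
        out.append(ConfusionCounts(tp, fp, n_decoys - fp, n_actives - tp))
    return out


def consensus_records(per_model: dict[str, tuple[int, int]],
                      n_consensus: int) -> list[HitRecord]:
    """Synthetic screening records mirroring a consensus/unique hit table.

    ``per_model`` maps model name -> (consensus hit count, unique hit count);
    ``n_consensus`` is the number of distinct molecules retrieved by more
    than one model.  Consensus molecules are assigned greedily to the models
    with the largest remaining membership counts, so every consensus molecule
    maps at least two models and each model's accounting is honoured exactly.
    """
    names = list(per_model)
    memberships = sum(c for c, _ in per_model.values())
    if memberships < 2 * n_consensus:
        raise ValueError("membership counts cannot cover the consensus "
                         "molecules twice each")
    sizes = [2] * n_consensus
    extra = memberships - 2 * n_consensus
    i = 0
    while extra > 0:  # spread extra memberships round-robin, one at a time
        if sizes[i % n_consensus] < len(names):
            sizes[i % n_consensus] += 1
            extra -= 1
        i += 1
        if i > memberships * len(names):
            raise ValueError("membership counts exceed available model slots")

    remaining = {n: c for n, (c, _) in per_model.items()}
    records: list[HitRecord] = []

    def make_record(mol_id: str, hit_models: list[str]) -> HitRecord:
        rec = HitRecord(mol_id)
        for n in names:
            rec.results[n] = (MatchResult(True, fit_score=1.0)
                              if n in hit_models else MatchResult.no_match())
        return rec

    for i, size in enumerate(sorted(sizes, reverse=True)):
        avail = sorted((n for n in names if remaining[n] > 0),
                       key=lambda n: (-remaining[n], n))
        if len(avail) < size:
            raise ValueError("per-model consensus counts are infeasible for "
                             f"{n_consensus} consensus molecules")
        chosen = avail[:size]
        for n in chosen:
            remaining[n] -= 1
        records.append(make_record(f"chit{i:03d}", chosen))
    if any(v != 0 for v in remaining.values()):
        raise ValueError("greedy assignment left unplaced consensus "
                         "memberships; counts are inconsistent")

    for n in names:
        for i in range(per_model[n][1]):
            records.append(make_record(f"uhit_{n}_{i:03d}", [n]))
    return records
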