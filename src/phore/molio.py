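"""Molecule, conformer-database, complex and label IO.

Conventions used across the package: coordinates in Å, 0-based atom indices,
RDKit molecules as the in-memory chemistry container.  Multi-record SDF
entries that share a title and connectivity are merged into one multiconformer
molecule, mirroring how vendor multiconformational screening databases are
laid out.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem import rdMolAlign

from .model import PharmacophoreModel, read_model, write_model  # re-exported  # noqa: F401

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AtomRecord", "ConformerSet", "ActivityTable", "ProteinAtom",
    "read_library", "write_library", "embed_conformers", "prune_conformers",
    "read_complex", "read_model", "write_model",
    "read_activity_table", "write_activity_table",
]

# metals kept on the protein side of a complex (catalytic/structural cofactors)
METAL_WHITELIST = {"ZN", "MG", "MN", "FE", "CA", "NI", "CO", "CU", "NA", "K"}
WATER_RESNAMES = {"HOH", "WAT", "DOD"}

FAST_MAX_CONFS = 25    # "fast" conformer-generation preset
BEST_MAX_CONFS = 500   # "best" conformer-generation preset
DUPLICATE_RMSD = 0.5   # Å heavy-atom RMSD under which two conformers are one


@dataclass(frozen=True)
class AtomRecord:
    element: str
    coords: tuple[float, float, float] | None
    formal_charge: int
    is_heavy: bool
    atom_index: int


@dataclass
class ConformerSet:
    """A molecule plus zero or more 3D coordinate sets — the screening unit."""

    mol_id: str
    mol: Chem.Mol
    source_tag: str = ""
    unscreenable: bool = False

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def n_conformers(self) -> int:
        return self.mol.GetNumConformers()

    @property
    def conformers(self) -> list[np.ndarray]:
        return [np.asarray(c.GetPositions(), dtype=float)
                for c in self.mol.GetConformers()]

    def coords(self, conf_index: int = 0) -> np.ndarray:
        return np.asarray(self.mol.GetConformer(conf_index).GetPositions(),
                          dtype=float)

    def heavy_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    def heavy_coords(self, conf_index: int = 0) -> np.ndarray:
        return self.coords(conf_index)[self.heavy_indices()]

    @property
    def atoms(self) -> list[AtomRecord]:
        has3d = self.n_conformers > 0
        pos = self.coords(0) if has3d else None
        return [AtomRecord(a.GetSymbol(),
                           tuple(pos[a.GetIdx()]) if has3d else None,
                           a.GetFormalCharge(), a.GetAtomicNum() > 1, a.GetIdx())
                for a in self.mol.GetAtoms()]

    @property
    def connectivity(self) -> list[tuple[int, int, float]]:
        return [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
                for b in self.mol.GetBonds()]

    def connectivity_hash(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(self.mol)))

    def add_conformer(self, coords: np.ndarray) -> None:
        conf = Chem.Conformer(self.n_atoms)
        for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        self.mol.AddConformer(conf, assignId=True)

    def copy(self) -> "ConformerSet":
        return ConformerSet(self.mol_id, Chem.Mol(self.mol), self.source_tag,
                            self.unscreenable)


@dataclass
class ActivityTable:
    """mol_id -> activity label (active/decoy) and binding-mode subset."""

    entries: dict[str, dict] = field(default_factory=dict)

    VALID_SUBSETS = {"S1", "S1'", "S1&S1'-small", "S1&S1'-large", "S1&S1'&ABS",
                     "none"}

    def add(self, mol_id: str, label: str, subset: str = "none") -> None:
        if label not in ("active", "decoy"):
            raise ValueError(f"label must be active|decoy, got {label!r}")
        if label == "decoy" and subset != "none":
            raise ValueError("subsets are assigned only to actives")
        self.entries[mol_id] = {"label": label, "subset": subset}

    def label(self, mol_id: str) -> str:
        if mol_id not in self.entries:
            raise KeyError(f"molecule {mol_id!r} has no activity label")
        return self.entries[mol_id]["label"]

    def subset(self, mol_id: str) -> str:
        return self.entries[mol_id]["subset"]

    def actives(self, subset: str | None = None) -> list[str]:
        return [m for m, e in self.entries.items() if e["label"] == "active"
                and (subset is None or e["subset"] == subset)]

    def decoys(self) -> list[str]:
        return [m for m, e in self.entries.items() if e["label"] == "decoy"]


def read_activity_table(path) -> ActivityTable:
    """TSV with columns mol_id, label, subset (header optional)."""
    table = ActivityTable()
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if parts[0] == "mol_id":
                continue
            mol_id, label = parts[0], parts[1]
            subset = parts[2] if len(parts) > 2 else "none"
            table.add(mol_id, label, subset)
    return table


def write_activity_table(table: ActivityTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("mol_id\tlabel\tsubset\n")
        for mol_id, e in table.entries.items():
            fh.write(f"{mol_id}\t{e['label']}\t{e['subset']}\n")


# ---------------------------------------------------------------------------
# libraries

def read_library(path, format: str | None = None) -> list[ConformerSet]:
    """Read an SDF or SMILES library into ConformerSets.

    SDF records sharing a title *and* connectivity are merged as conformers of
    one molecule.  Unparsable records are skipped with a logged warning; an
    empty file yields an empty list.
    """
    path = Path(path)
    if format is None:
        format = "smiles" if path.suffix.lower() in (".smi", ".smiles") else "sdf"
    if format not in ("sdf", "smiles"):
        raise ValueError(f"unknown library format {format!r}")

    out: list[ConformerSet] = []
    index: dict[tuple[str, str], ConformerSet] = {}
    n_read = n_skipped = 0

    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_skipped += 1
                continue
            n_read += 1
            title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            mol_id = title or f"{path.stem}_{i}"
            cs = ConformerSet(mol_id, mol, source_tag=str(path))
            key = (mol_id, cs.connectivity_hash())
            if key in index and mol.GetNumConformers() > 0:
                index[key].add_conformer(
                    np.asarray(mol.GetConformer().GetPositions()))
            else:
                index[key] = cs
                out.append(cs)
    else:
        with open(path) as fh:
            for i, ln in enumerate(fh):
                ln = ln.strip()
                if not ln or ln.startswith("#"):
                    continue
                parts = ln.split()
                mol = Chem.MolFromSmiles(parts[0])
                if mol is None:
                    n_skipped += 1
                    continue
                n_read += 1
                mol_id = parts[1] if len(parts) > 1 else f"{path.stem}_{i}"
                out.append(ConformerSet(mol_id, mol, source_tag=str(path)))

    logger.info("%s: %d records read, %d skipped", path, n_read, n_skipped)
    return out


def write_library(library: list[ConformerSet], path) -> None:
    """Write each conformer of each molecule as one SDF record (shared title)."""
    writer = Chem.SDWriter(str(path))
    try:
        for cs in library:
            mol = Chem.Mol(cs.mol)
            mol.SetProp("_Name", cs.mol_id)
            if mol.GetNumConformers() == 0:
                writer.write(mol)
            else:
                for conf in mol.GetConformers():
                    writer.write(mol, confId=conf.GetId())
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# conformer generation

def _heavy_rmsd_matrix_prune(mol: Chem.Mol, threshold: float) -> Chem.Mol:
    """Drop conformers within `threshold` heavy-atom RMSD of a kept one."""
    heavy = Chem.RemoveHs(Chem.Mol(mol))
    conf_ids = [c.GetId() for c in mol.GetConformers()]
    kept: list[int] = []
    for cid in conf_ids:
        dup = False
        for kid in kept:
            rms = rdMolAlign.GetBestRMS(heavy, heavy, prbId=cid, refId=kid)
            if rms < threshold:
                dup = True
                break
        if not dup:
            kept.append(cid)
    for cid in conf_ids:
        if cid not in kept:
            mol.RemoveConformer(cid)
    return mol


def prune_conformers(cs: ConformerSet,
                     threshold: float = DUPLICATE_RMSD) -> ConformerSet:
    """Remove duplicate conformers (pairwise heavy-atom RMSD < threshold)."""
    out = cs.copy()
    if out.n_conformers > 1:
        _heavy_rmsd_matrix_prune(out.mol, threshold)
    return out


def embed_conformers(cs: ConformerSet, max_confs: int | None = None,
                     mode: str = "fast", seed: int = 0) -> ConformerSet:
    """Generate up to ``max_confs`` 3D conformers (ETKDG), deterministically.

    ``mode`` presets the conformer cap: "fast" -> 25, "best" -> 500.  Duplicate
    conformers (heavy-atom RMSD < 0.5 Å) are pruned.  Embedding failure flags
    the molecule unscreenable with zero conformers.
    """
    if mode not in ("fast", "best"):
        raise ValueError(f"mode must be fast|best, got {mode!r}")
    if max_confs is None:
        max_confs = FAST_MAX_CONFS if mode == "fast" else BEST_MAX_CONFS
    if max_confs < 1:
        raise ValueError("max_confs must be >= 1")

    molH = Chem.AddHs(Chem.Mol(cs.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    params.numThreads = 1
    conf_ids = AllChem.EmbedMultipleConfs(molH, numConfs=max_confs, params=params)
    if len(conf_ids) == 0:
        out = ConformerSet(cs.mol_id, Chem.Mol(cs.mol), cs.source_tag,
                           unscreenable=True)
        out.mol.RemoveAllConformers()
        logger.warning("embedding failed for %s; flagged unscreenable", cs.mol_id)
        return out
    mol = Chem.RemoveHs(molH)
    _heavy_rmsd_matrix_prune(mol, DUPLICATE_RMSD)
    return ConformerSet(cs.mol_id, mol, cs.source_tag)


# ---------------------------------------------------------------------------
# protein–ligand complexes

@dataclass(frozen=True)
class ProteinAtom:
    element: str
    name: str
    resname: str
    resseq: int
    chain: str
    coords: tuple[float, float, float]
    serial: int = 0

    @property
    def is_metal(self) -> bool:
        return self.resname.strip() in METAL_WHITELIST and \
            self.name.strip() in METAL_WHITELIST

    @property
    def coords_array(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


def _parse_pdb_atoms(text: str):
    """Fixed-column ATOM/HETATM records -> (records, conect_lines)."""
    atoms, conect = [], []
    for ln in text.splitlines():
        rec = ln[:6].strip()
        if rec in ("ATOM", "HETATM"):
            serial = int(ln[6:11])
            name = ln[12:16].strip()
            resname = ln[17:20].strip()
            chain = ln[21:22].strip() or "A"
            resseq = int(ln[22:26])
            x, y, z = float(ln[30:38]), float(ln[38:46]), float(ln[46:54])
            element = ln[76:78].strip() if len(ln) >= 78 else ""
            if not element:
                element = name[:1]
            atoms.append(dict(record=rec, serial=serial, name=name,
                              resname=resname, chain=chain, resseq=resseq,
                              coords=(x, y, z), element=element, line=ln))
        elif rec == "CONECT":
            conect.append(ln)
    return atoms, conect


def read_complex(path, ligand_resname: str,
                 ligand_template: str | None = None
                 ) -> tuple[list[ProteinAtom], ConformerSet]:
    """Split a PDB complex into protein-side atoms and the bound ligand.

    Water is dropped; whitelisted metals (e.g. the catalytic zinc) stay on the
    protein side for metal-feature perception.  The ligand residue is rebuilt
    as an RDKit molecule (CONECT/proximity bonding); ``ligand_template`` — a
    SMILES for the ligand — restores bond orders and formal charges that the
    PDB format cannot carry.
    """
    text = Path(path).read_text()
    atoms, conect = _parse_pdb_atoms(text)
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records")

    ligand_lines, ligand_serials = [], set()
    protein: list[ProteinAtom] = []
    het_resnames = set()
    for a in atoms:
        rn = a["resname"]
        if rn in WATER_RESNAMES:
            continue
        if rn == ligand_resname:
            ligand_lines.append(a["line"])
            ligand_serials.add(a["serial"])
        else:
            if a["record"] == "HETATM" and rn not in METAL_WHITELIST:
                het_resnames.add(rn)
                continue  # foreign hetero residue: neither protein nor ligand
            protein.append(ProteinAtom(a["element"].capitalize(), a["name"],
                                       rn, a["resseq"], a["chain"],
                                       a["coords"], a["serial"]))

    if not ligand_lines:
        available = sorted(het_resnames) or ["<none>"]
        raise ValueError(
            f"{path}: no HETATM residue named {ligand_resname!r}; "
            f"candidate ligand residues: {', '.join(available)}")

    conect_lines = [ln for ln in conect
                    if any(str(s) in ln.split() for s in ligand_serials)]
    block = "\n".join(ligand_lines + conect_lines) + "\nEND\n"
    # with CONECT records present, trust them; else fall back to proximity
    ligmol = Chem.MolFromPDBBlock(block, removeHs=False,
                                  proximityBonding=not conect_lines)
    if ligmol is None:
        raise ValueError(f"{path}: could not build ligand {ligand_resname!r}")
    if ligand_template is not None:
        template = Chem.MolFromSmiles(ligand_template)
        if template is None:
            raise ValueError(f"invalid ligand template SMILES {ligand_template!r}")
        ligmol = AllChem.AssignBondOrdersFromTemplate(template, ligmol)
    ligand = ConformerSet(ligand_resname, ligmol, source_tag=str(path))
    return protein, ligand
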