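"""Readers/writers for structure and dataset formats plus the core domain types.

Reads PDBbind-style index files, pocket PDB files and ligand mol2/SDF files
into :class:`ComplexRecord` / :class:`LigandMolecule`, and writes prediction
CSVs.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ComplexRecord",
    "LigandMolecule",
    "PocketResidue",
    "FormatError",
    "IndexParseError",
    "read_pdbbind_index",
    "read_pocket_pdb",
    "read_ligand_file",
    "ligand_from_rdkit",
    "write_predictions",
    "read_predictions",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: hybridization classes used by the 18-dim atom feature scheme
HYBRIDIZATION_CLASSES = ("S", "SP", "SP2", "SP3", "OTHER")

#: bond order classes (index into the 4-wide one-hot of the edge features)
BOND_ORDER_CLASSES = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")


class FormatError(ValueError):
    """Raised for unparseable or structurally invalid input files."""


class IndexParseError(FormatError):
    """Raised when a PDBbind index line cannot be parsed."""


@dataclass(frozen=True)
class LigandAtom:
    element: str
    formal_charge: int
    aromatic: bool
    in_ring: bool
    hybridization: str  # one of HYBRIDIZATION_CLASSES
    coord: tuple[float, float, float]


@dataclass(frozen=True)
class LigandBond:
    i: int
    j: int
    order: str  # one of BOND_ORDER_CLASSES
    in_ring: bool


@dataclass
class LigandMolecule:
    """A hydrogen-stripped small molecule with 3-D coordinates."""

    atoms: list[LigandAtom]
    bonds: list[LigandBond]
    smiles: str
    rdmol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) out of atom range {n}")
        coords = self.coords()
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("non-finite ligand coordinates")
        if n > 1:
            # connectivity after hydrogen removal
            adj = {k: set() for k in range(n)}
            for b in self.bonds:
                adj[b.i].add(b.j)
                adj[b.j].add(b.i)
            seen, stack = {0}, [0]
            while stack:
                for nb in adj[stack.pop()]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if len(seen) != n:
                raise ValueError("ligand heavy-atom graph is disconnected")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class PocketResidue:
    aa: str  # one-letter code
    coord: tuple[float, float, float]  # Calpha position, Angstrom
    sse: str  # 8-state code or '-' when unknown


@dataclass
class ComplexRecord:
    """One protein-ligand complex: sequences, pocket geometry, ligand, label."""

    complex_id: str
    protein_seq: str
    pocket_seq: str
    pocket_residues: list[PocketResidue]
    ligand: LigandMolecule
    affinity_label: Optional[float] = None

    def __post_init__(self):
        if len(self.pocket_seq) != len(self.pocket_residues):
            raise ValueError("pocket_seq length must match pocket_residues")
        coords = self.pocket_coords()
        if coords.size and not np.isfinite(coords).all():
            raise ValueError("non-finite pocket coordinates")

    def pocket_coords(self) -> np.ndarray:
        return np.array([r.coord for r in self.pocket_residues], dtype=float).reshape(-1, 3)


# --------------------------------------------------------------------------
# PDBbind index
# --------------------------------------------------------------------------

def read_pdbbind_index(path) -> list[tuple[str, float]]:
    """Parse a PDBbind INDEX file into (complex_id, affinity) pairs.

    Expected data-line layout: ``<id> <resolution> <year> <-logKd/Ki> ...``;
    lines starting with ``#`` are comments.
    """
    out: list[tuple[str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise IndexParseError(
                    f"{path}: line {lineno}: expected >=4 fields, got {len(fields)}")
            try:
                affinity = float(fields[3])
            except ValueError as exc:
                raise IndexParseError(
                    f"{path}: line {lineno}: cannot parse affinity {fields[3]!r}") from exc
            out.append((fields[0], affinity))
    return out


# --------------------------------------------------------------------------
# Pocket PDB
# --------------------------------------------------------------------------

def read_pocket_pdb(path, sse_source: str = "unknown",
                    sse_map: Optional[dict] = None) -> tuple[str, list[PocketResidue]]:
    """Read pocket residues (one entry per residue with a Calpha atom).

    ``sse_source`` selects where 8-state secondary-structure labels come from:

    - ``"column"``: the PDB segment-identifier column (73-76) of the CA atom
      carries a single-letter SSE code (the convention used by our writer);
    - ``"external_map"``: ``sse_map[(chain_id, resseq, icode)]`` -> code;
    - ``"unknown"``: every residue is labelled ``'-'``.

    Residues without a Calpha are dropped with a warning.
    """
    if sse_source not in ("column", "external_map", "unknown"):
        raise ValueError(f"invalid sse_source {sse_source!r}")
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = PDBParser(QUIET=True).get_structure("pocket", str(path))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    residues: list[PocketResidue] = []
    seq_chars: list[str] = []
    n_atoms = 0
    for model in structure:
        for chain in model:
            for res in chain:
                n_atoms += len(res)
                if res.id[0] != " ":  # skip hetero/water records
                    continue
                if "CA" not in res:
                    logger.warning("%s: residue %s %s lacks CA; dropped",
                                   path.name, res.get_resname(), res.id[1])
                    continue
                ca = res["CA"]
                aa = THREE_TO_ONE.get(res.get_resname(), "X")
                if sse_source == "column":
                    seg = (ca.get_parent().segid or "").strip() or \
                          (ca.segid.strip() if hasattr(ca, "segid") else "")
                    sse = seg[:1] if seg else "-"
                elif sse_source == "external_map":
                    key = (chain.id, res.id[1], res.id[2])
                    sse = (sse_map or {}).get(key, "-")
                else:
                    sse = "-"
                coord = tuple(float(x) for x in ca.coord)
                residues.append(PocketResidue(aa=aa, coord=coord, sse=sse))
                seq_chars.append(aa)
        break  # first model only
    if n_atoms == 0:
        raise FormatError(f"{path}: no ATOM records found")
    return "".join(seq_chars), residues


# --------------------------------------------------------------------------
# Ligand files
# --------------------------------------------------------------------------

def _hybridization_class(atom: Chem.Atom) -> str:
    name = str(atom.GetHybridization())
    return name if name in ("S", "SP", "SP2", "SP3") else "OTHER"


def _bond_order_class(bond: Chem.Bond) -> str:
    bt = bond.GetBondType()
    if bt == Chem.BondType.SINGLE:
        return "SINGLE"
    if bt == Chem.BondType.DOUBLE:
        return "DOUBLE"
    if bt == Chem.BondType.TRIPLE:
        return "TRIPLE"
    if bt == Chem.BondType.AROMATIC:
        return "AROMATIC"
    return "SINGLE"


def ligand_from_rdkit(mol: Chem.Mol) -> LigandMolecule:
    """Convert an RDKit molecule (with a conformer) into a LigandMolecule."""
    mol = Chem.RemoveHs(mol)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:  # drop counter-ions / solvent, keep the largest piece
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    if mol.GetNumHeavyAtoms() == 0:
        raise FormatError("ligand has zero heavy atoms")
    if mol.GetNumConformers() == 0:
        raise FormatError("ligand has no 3-D coordinates")
    Chem.RemoveStereochemistry(mol)  # SMILES identity is topological
    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        atoms.append(LigandAtom(
            element=atom.GetSymbol(),
            formal_charge=atom.GetFormalCharge(),
            aromatic=atom.GetIsAromatic(),
            in_ring=atom.IsInRing(),
            hybridization=_hybridization_class(atom),
            coord=(pos.x, pos.y, pos.z),
        ))
    bonds = [LigandBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                        _bond_order_class(b), b.IsInRing())
             for b in mol.GetBonds()]
    return LigandMolecule(atoms=atoms, bonds=bonds,
                          smiles=Chem.MolToSmiles(mol), rdmol=mol)


def read_ligand_file(path) -> LigandMolecule:
    """Read a mol2 or SDF ligand file; hydrogens are stripped."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=True, removeHs=True)
    elif suffix in (".sdf", ".mol"):
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        mol = next(iter(supplier), None)
    else:
        raise FormatError(f"{path}: unsupported ligand format {suffix!r}")
    if mol is None:
        raise FormatError(f"{path}: could not parse ligand")
    return ligand_from_rdkit(mol)


# --------------------------------------------------------------------------
# Predictions CSV
# --------------------------------------------------------------------------

def write_predictions(records: Sequence[tuple[str, float]], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["complex_id", "prediction"])
        for cid, pred in records:
            writer.writerow([cid, f"{float(pred):.6f}"])


def read_predictions(path) -> list[tuple[str, float]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["complex_id", "prediction"]:
            raise FormatError(f"{path}: unexpected header {header}")
        return [(row[0], float(row[1])) for row in reader if row]
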