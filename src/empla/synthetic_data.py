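"""Fully synthetic protein-ligand complexes with a planted affinity law.

Pockets are random amino-acid sequences placed on a jittered 3-D lattice;
ligands are random chemically valid trees over C/N/O/S heavy atoms (valence
capped by construction) with optional ring closures, embedded next to the
pocket. The planted affinity is a documented linear law over signals every
model branch can observe:

    affinity = BASE
             + ALPHA * (number of pocket-ligand atom pairs within 5 A)
             + BETA  * ligand_HBD * pocket_polar_fraction
             - GAMMA * rotatable_bond_count
             + Normal(0, noise_sd)

Records are deterministic per (seed, index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Lipinski
from rdkit.Geometry import Point3D

from .io_formats import (ComplexRecord, LigandMolecule, PocketResidue,
                         THREE_TO_ONE, ligand_from_rdkit)
from .sequence_features import SSE_ORDER, _POLAR

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "generate_complex", "generate_dataset",
           "planted_affinity", "planted_signals", "write_dataset",
           "load_dataset", "ALPHA", "BETA", "GAMMA", "BASE"]

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# planted-law constants (documented; recovered by tests)
BASE = 4.0
ALPHA = 0.08
BETA = 2.0
GAMMA = 0.15
CONTACT_RADIUS = 5.0  # Angstrom

_VALENCE_CAP = {"C": 4, "N": 3, "O": 2, "S": 2}
_ELEMENT_WEIGHTS = {"C": 0.6, "N": 0.15, "O": 0.2, "S": 0.05}


@dataclass(frozen=True)
class SynthConfig:
    n_complexes: int = 100
    pocket_residues: tuple[int, int] = (8, 24)
    ligand_atoms: tuple[int, int] = (8, 24)
    contact_scale: float = 6.0  # Angstrom; controls pocket-ligand separation
    ring_closure_prob: float = 0.25
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")
        lo, hi = self.pocket_residues
        if not (1 <= lo <= hi <= 64):
            raise ValueError("pocket_residues range must lie within [1, 64]")
        lo, hi = self.ligand_atoms
        if not (1 <= lo <= hi <= 150):
            raise ValueError("ligand_atoms range must lie within [1, 150]")
        if self.contact_scale <= 0:
            raise ValueError("contact_scale must be positive")


def _random_ligand(rng: np.random.Generator, n_atoms: int,
                   ring_prob: float, center: np.ndarray) -> LigandMolecule:
    """Grow a valence-capped random tree of heavy atoms, then close rings."""
    elements = list(_ELEMENT_WEIGHTS)
    probs = np.array(list(_ELEMENT_WEIGHTS.values()))
    mol = Chem.RWMol()
    coords: list[np.ndarray] = []
    free: list[int] = []  # remaining valence per atom
    symbols: list[str] = []

    def add_atom(parent: int | None):
        sym = elements[rng.choice(len(elements), p=probs)]
        idx = mol.AddAtom(Chem.Atom(sym))
        symbols.append(sym)
        free.append(_VALENCE_CAP[sym])
        if parent is None:
            coords.append(center + rng.normal(scale=0.3, size=3))
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords.append(coords[parent] + 1.5 * direction)
            mol.AddBond(parent, idx, Chem.BondType.SINGLE)
            free[parent] -= 1
            free[idx] -= 1
        return idx

    add_atom(None)
    while mol.GetNumAtoms() < n_atoms:
        candidates = [i for i in range(mol.GetNumAtoms()) if free[i] > 0]
        if not candidates:
            break
        parent = int(candidates[rng.integers(len(candidates))])
        add_atom(parent)

    # optional ring closures between non-adjacent atoms with spare valence
    n = mol.GetNumAtoms()
    if n >= 4 and rng.random() < ring_prob:
        spare = [i for i in range(n) if free[i] > 0]
        rng.shuffle(spare)
        for a in spare:
            partners = [b for b in spare
                        if b != a and free[b] > 0 and free[a] > 0
                        and mol.GetBondBetweenAtoms(a, b) is None]
            if partners:
                b = int(partners[rng.integers(len(partners))])
                mol.AddBond(a, b, Chem.BondType.SINGLE)
                free[a] -= 1
                free[b] -= 1
                break

    conf = Chem.Conformer(n)
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol.AddConformer(conf)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return ligand_from_rdkit(out)


def _random_pocket(rng: np.random.Generator, n_res: int) -> list[PocketResidue]:
    """Residues on a jittered cubic lattice (4 A pitch) around the origin."""
    side = int(np.ceil(n_res ** (1.0 / 3.0)))
    sites = [(i, j, k) for i in range(side) for j in range(side) for k in range(side)]
    order = rng.permutation(len(sites))[:n_res]
    aas = "ACDEFGHIKLMNPQRSTVWY"
    residues = []
    for s in order:
        i, j, k = sites[s]
        base = 4.0 * (np.array([i, j, k]) - (side - 1) / 2.0)
        coord = base + rng.normal(scale=0.4, size=3)
        residues.append(PocketResidue(
            aa=aas[rng.integers(len(aas))],
            coord=tuple(float(x) for x in coord),
            sse=SSE_ORDER[rng.integers(len(SSE_ORDER))],
        ))
    return residues


def generate_complex(cfg: SynthConfig, index: int) -> ComplexRecord:
    """Deterministic synthetic complex for (cfg.seed, index); unlabeled."""
    rng = np.random.default_rng([cfg.seed, index])
    n_res = int(rng.integers(cfg.pocket_residues[0], cfg.pocket_residues[1] + 1))
    n_atoms = int(rng.integers(cfg.ligand_atoms[0], cfg.ligand_atoms[1] + 1))
    residues = _random_pocket(rng, n_res)
    pocket_seq = "".join(r.aa for r in residues)

    # ligand sits at a random offset from the pocket surface
    pocket_coords = np.array([r.coord for r in residues])
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = float(np.abs(pocket_coords).max()) if n_res > 1 else 2.0
    offset = rng.uniform(0.5, cfg.contact_scale)
    center = direction * (radius + offset) * 0.5
    ligand = _random_ligand(rng, n_atoms, cfg.ring_closure_prob, center)

    aas = "ACDEFGHIKLMNPQRSTVWY"
    protein_len = int(rng.integers(60, 160))
    protein_seq = "".join(aas[i] for i in rng.integers(len(aas), size=protein_len))
    # embed the pocket so the protein branch sees related composition
    pos = int(rng.integers(0, max(1, protein_len - n_res)))
    protein_seq = protein_seq[:pos] + pocket_seq + protein_seq[pos + n_res:]

    return ComplexRecord(
        complex_id=f"syn{cfg.seed:03d}_{index:05d}",
        protein_seq=protein_seq,
        pocket_seq=pocket_seq,
        pocket_residues=residues,
        ligand=ligand,
        affinity_label=None,
    )


def planted_signals(record: ComplexRecord) -> tuple[float, float, float]:
    """(contacts, hbd * polar_fraction, rotatable_bonds) for the planted law."""
    p = record.pocket_coords()
    l = record.ligand.coords()
    dist = np.sqrt(((p[:, None, :] - l[None, :, :]) ** 2).sum(axis=-1))
    contacts = float((dist <= CONTACT_RADIUS).sum())
    rdmol = record.ligand.rdmol or Chem.MolFromSmiles(record.ligand.smiles)
    hbd = float(Lipinski.NumHDonors(rdmol))
    polar_frac = float(np.mean([aa in _POLAR for aa in record.pocket_seq]))
    rot = float(Lipinski.NumRotatableBonds(rdmol))
    return contacts, hbd * polar_frac, rot


def planted_affinity(record: ComplexRecord, noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None) -> float:
    contacts, hbd_polar, rot = planted_signals(record)
    value = BASE + ALPHA * contacts + BETA * hbd_polar - GAMMA * rot
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        value += float(rng.normal(scale=noise_sd))
    return float(value)


def generate_dataset(cfg: SynthConfig) -> list[ComplexRecord]:
    """n_complexes labeled records, deterministic in cfg.seed."""
    records = []
    for index in range(cfg.n_complexes):
        record = generate_complex(cfg, index)
        noise_rng = np.random.default_rng([cfg.seed, index, 7919])
        record.affinity_label = planted_affinity(record, cfg.noise_sd, noise_rng)
        records.append(record)
    return records


# --------------------------------------------------------------------------
# On-disk layout exercising the real readers
# --------------------------------------------------------------------------

def _write_pocket_pdb(record: ComplexRecord, path: Path) -> None:
    lines = []
    for i, res in enumerate(record.pocket_residues, start=1):
        name = ONE_TO_THREE.get(res.aa, "UNK")
        x, y, z = res.coord
        lines.append(
            f"ATOM  {i:5d}  CA  {name:<3s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00      {res.sse:<4s} C")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_dataset(records: list[ComplexRecord], out_dir) -> Path:
    """Write pocket PDBs, ligand SDFs and a PDBbind-style index file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index_lines = ["# synthetic dataset index",
                   "# id  resolution  year  -logKd/Ki"]
    for record in records:
        cdir = out_dir / record.complex_id
        cdir.mkdir(exist_ok=True)
        _write_pocket_pdb(record, cdir / f"{record.complex_id}_pocket.pdb")
        writer = Chem.SDWriter(str(cdir / f"{record.complex_id}_ligand.sdf"))
        writer.write(record.ligand.rdmol)
        writer.close()
        (cdir / f"{record.complex_id}_protein.seq").write_text(record.protein_seq + "\n")
        label = record.affinity_label if record.affinity_label is not None else 0.0
        index_lines.append(f"{record.complex_id}  2.00  2024  {label:.4f}")
    (out_dir / "index.txt").write_text("\n".join(index_lines) + "\n")
    return out_dir


def load_dataset(data_dir) -> list[ComplexRecord]:
    """Read a write_dataset() layout back through the standard readers."""
    from .io_formats import read_ligand_file, read_pdbbind_index, read_pocket_pdb

    data_dir = Path(data_dir)
    entries = read_pdbbind_index(data_dir / "index.txt")
    records = []
    for cid, label in entries:
        cdir = data_dir / cid
        pocket_seq, residues = read_pocket_pdb(
            cdir / f"{cid}_pocket.pdb", sse_source="column")
        ligand = read_ligand_file(cdir / f"{cid}_ligand.sdf")
        seq_file = cdir / f"{cid}_protein.seq"
        protein_seq = seq_file.read_text().strip() if seq_file.exists() else pocket_seq
        records.append(ComplexRecord(
            complex_id=cid, protein_seq=protein_seq, pocket_seq=pocket_seq,
            pocket_residues=residues, ligand=ligand, affinity_label=label))
    return records
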