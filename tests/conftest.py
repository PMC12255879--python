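"""Shared fixtures: small molecules built from SMILES with embedded 3-D
coordinates and tiny synthetic complexes. Everything is generated at test
time; no binary fixtures live in the repository."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from empla.io_formats import (ComplexRecord, LigandAtom, LigandBond,
                              LigandMolecule, PocketResidue, ligand_from_rdkit)
from empla.model import ModelConfig
from empla.synthetic_data import SynthConfig, generate_complex, generate_dataset


def mol_from_smiles(smiles: str, seed: int = 7) -> LigandMolecule:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    return ligand_from_rdkit(mol)


@pytest.fixture(scope="session")
def benzene() -> LigandMolecule:
    return mol_from_smiles("c1ccccc1")


@pytest.fixture(scope="session")
def ethanol() -> LigandMolecule:
    return mol_from_smiles("CCO")


@pytest.fixture(scope="session")
def butane() -> LigandMolecule:
    return mol_from_smiles("CCCC")


@pytest.fixture(scope="session")
def small_record() -> ComplexRecord:
    return generate_complex(SynthConfig(seed=42), 0)


@pytest.fixture(scope="session")
def small_dataset() -> list[ComplexRecord]:
    return generate_dataset(SynthConfig(n_complexes=6, seed=13))


@pytest.fixture(scope="session")
def tiny_model_cfg() -> ModelConfig:
    return ModelConfig(hidden_dim=16, fusion_hidden=(16, 8))


def two_residue_record(separation: float,
                       ligand: LigandMolecule | None = None) -> ComplexRecord:
    """Minimal record with two residues on the x axis `separation` apart."""
    if ligand is None:
        atoms = [LigandAtom("C", 0, False, False, "SP3", (0.0, 3.0, 0.0)),
                 LigandAtom("O", 0, False, False, "SP3", (1.4, 3.0, 0.0))]
        bonds = [LigandBond(0, 1, "SINGLE", False)]
        ligand = LigandMolecule(atoms=atoms, bonds=bonds, smiles="CO")
    residues = [PocketResidue("G", (0.0, 0.0, 0.0), "H"),
                PocketResidue("A", (separation, 0.0, 0.0), "E")]
    return ComplexRecord(complex_id="pair", protein_seq="GA", pocket_seq="GA",
                         pocket_residues=residues, ligand=ligand,
                         affinity_label=5.0)


def rigid_transform_record(record: ComplexRecord, rotation: np.ndarray,
                           translation: np.ndarray) -> ComplexRecord:
    """Apply the same rotation+translation to all coordinates of a record."""
    residues = [PocketResidue(r.aa, tuple(rotation @ np.asarray(r.coord) + translation), r.sse)
                for r in record.pocket_residues]
    atoms = [LigandAtom(a.element, a.formal_charge, a.aromatic, a.in_ring,
                        a.hybridization,
                        tuple(rotation @ np.asarray(a.coord) + translation))
             for a in record.ligand.atoms]
    ligand = LigandMolecule(atoms=atoms, bonds=list(record.ligand.bonds),
                            smiles=record.ligand.smiles, rdmol=record.ligand.rdmol)
    return ComplexRecord(complex_id=record.complex_id,
                         protein_seq=record.protein_seq,
                         pocket_seq=record.pocket_seq,
                         pocket_residues=residues, ligand=ligand,
                         affinity_label=record.affinity_label)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
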