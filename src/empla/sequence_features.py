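"""Fixed-shape padded sequence featurization.

Proteins and pockets are encoded residue-wise into 40 channels
(21 amino-acid one-hot + 8-state secondary-structure one-hot + 11
physicochemical properties min-max scaled over the 20 standard residues).
Ligands are encoded atom-wise into 18 channels (9 atom-type one-hot +
4 atomic properties + 5 SMARTS-pattern flags).

Capacities are fixed: protein 1024 x 40, pocket 64 x 40, ligand 150 x 18;
shorter inputs are zero-padded, longer inputs truncated from the tail with
a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Lipinski

from .io_formats import LigandMolecule, PocketResidue

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceFeatureMatrix",
    "AA_ORDER", "SSE_ORDER",
    "PROTEIN_MAX_LEN", "POCKET_MAX_LEN", "LIGAND_MAX_LEN",
    "RESIDUE_FEATURE_DIM", "ATOM_FEATURE_DIM",
    "encode_residue", "encode_protein_sequence", "encode_pocket_sequence",
    "encode_ligand_smiles", "atom_features", "ligand_atom_features",
    "pocket_pseudo_atom_features", "aa_one_hot",
]

PROTEIN_MAX_LEN = 1024
POCKET_MAX_LEN = 64
LIGAND_MAX_LEN = 150
RESIDUE_FEATURE_DIM = 40  # 21 + 8 + 11
ATOM_FEATURE_DIM = 18  # 9 + 4 + 5

AA_ORDER = "ACDEFGHIKLMNPQRSTVWYX"  # X = unknown/nonstandard (21 classes)
SSE_ORDER = "HBEGITS-"  # DSSP 8-state; '-' doubles as coil and unknown

# Per-residue property tables over the 20 standard amino acids.
# Columns of the 11-dim physicochemical block, in order:
#   hydropathy (Kyte-Doolittle), net charge at pH 7, isoelectric point,
#   molecular weight, polar flag, aromatic flag, aliphatic flag,
#   side-chain H-bond donors, side-chain H-bond acceptors,
#   side-chain volume, flexibility index (Bhaskaran-Ponnuswamy).
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_NET_CHARGE_PH7 = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}
_PI = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
}
_MW = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "Q": 146.15, "E": 147.13, "G": 75.07, "H": 155.16, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}
_POLAR = set("RNDCEQHKSTY")
_AROMATIC = set("FWYH")
_ALIPHATIC = set("AGILPV")
_HBD = {"R": 2, "N": 1, "Q": 1, "H": 1, "K": 1, "S": 1, "T": 1, "W": 1,
        "Y": 1, "C": 1}
_HBA = {"D": 2, "E": 2, "N": 1, "Q": 1, "H": 1, "S": 1, "T": 1, "Y": 1}
_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}
_FLEXIBILITY = {
    "A": 0.357, "R": 0.529, "N": 0.463, "D": 0.511, "C": 0.346, "Q": 0.493,
    "E": 0.497, "G": 0.544, "H": 0.323, "I": 0.462, "L": 0.365, "K": 0.466,
    "M": 0.295, "F": 0.314, "P": 0.509, "S": 0.507, "T": 0.444, "W": 0.305,
    "Y": 0.420, "V": 0.386,
}


def _minmax(table: dict[str, float]) -> dict[str, float]:
    vals = [table.get(aa, 0.0) for aa in AA_ORDER[:20]]
    lo, hi = min(vals), max(vals)
    span = (hi - lo) or 1.0
    return {aa: (table.get(aa, 0.0) - lo) / span for aa in AA_ORDER[:20]}


def _build_physchem_table() -> dict[str, np.ndarray]:
    scaled = [
        _minmax(_KYTE_DOOLITTLE),
        _minmax({aa: _NET_CHARGE_PH7.get(aa, 0.0) for aa in AA_ORDER[:20]}),
        _minmax(_PI),
        _minmax(_MW),
        {aa: float(aa in _POLAR) for aa in AA_ORDER[:20]},
        {aa: float(aa in _AROMATIC) for aa in AA_ORDER[:20]},
        {aa: float(aa in _ALIPHATIC) for aa in AA_ORDER[:20]},
        _minmax({aa: float(_HBD.get(aa, 0)) for aa in AA_ORDER[:20]}),
        _minmax({aa: float(_HBA.get(aa, 0)) for aa in AA_ORDER[:20]}),
        _minmax(_VOLUME),
        _minmax(_FLEXIBILITY),
    ]
    table = {aa: np.array([col[aa] for col in scaled]) for aa in AA_ORDER[:20]}
    table["X"] = np.zeros(11)
    return table


PHYSCHEM_TABLE = _build_physchem_table()


@dataclass
class SequenceFeatureMatrix:
    values: np.ndarray  # (L_max, D) float
    mask: np.ndarray  # (L_max,) bool
    kind: str  # 'protein' | 'pocket' | 'ligand'

    EXPECTED_SHAPES = {
        "protein": (PROTEIN_MAX_LEN, RESIDUE_FEATURE_DIM),
        "pocket": (POCKET_MAX_LEN, RESIDUE_FEATURE_DIM),
        "ligand": (LIGAND_MAX_LEN, ATOM_FEATURE_DIM),
    }

    def __post_init__(self):
        expected = self.EXPECTED_SHAPES[self.kind]
        if self.values.shape != expected:
            raise ValueError(f"{self.kind} matrix must be {expected}, "
                             f"got {self.values.shape}")
        if self.mask.shape != (expected[0],):
            raise ValueError("mask length mismatch")
        if np.any(self.values[~self.mask] != 0):
            raise ValueError("masked rows must be exactly zero")

    @property
    def length(self) -> int:
        return int(self.mask.sum())


# --------------------------------------------------------------------------
# Residue-level encoding
# --------------------------------------------------------------------------

def encode_residue(aa: str, sse: str) -> np.ndarray:
    """40-dim residue vector: [AA one-hot(21) | SSE one-hot(8) | physchem(11)].

    Total over its inputs: unknown letters fall into the unknown AA class /
    the '-' SSE class.
    """
    aa = aa.upper() if aa else "X"
    if aa not in AA_ORDER:
        aa = "X"
    sse = sse.upper() if sse else "-"
    if sse not in SSE_ORDER:
        sse = "-"
    vec = np.zeros(RESIDUE_FEATURE_DIM)
    vec[AA_ORDER.index(aa)] = 1.0
    vec[21 + SSE_ORDER.index(sse)] = 1.0
    vec[29:40] = PHYSCHEM_TABLE[aa]
    return vec


def aa_one_hot(seq: str) -> np.ndarray:
    """(L, 21) amino-acid one-hot matrix (pocket-graph node features)."""
    out = np.zeros((len(seq), 21))
    for i, aa in enumerate(seq.upper()):
        out[i, AA_ORDER.index(aa if aa in AA_ORDER else "X")] = 1.0
    return out


def _encode_sequence(seq: str, sse: str | None, max_len: int,
                     kind: str) -> SequenceFeatureMatrix:
    if not seq:
        raise ValueError("empty sequence")
    if sse is None:
        sse = "-" * len(seq)
    if len(sse) != len(seq):
        raise ValueError("sse length must match sequence length")
    if len(seq) > max_len:
        logger.warning("sequence of length %d truncated to %d", len(seq), max_len)
        seq, sse = seq[:max_len], sse[:max_len]
    values = np.zeros((max_len, RESIDUE_FEATURE_DIM))
    mask = np.zeros(max_len, dtype=bool)
    for i, (aa, s) in enumerate(zip(seq, sse)):
        values[i] = encode_residue(aa, s)
        mask[i] = True
    return SequenceFeatureMatrix(values=values, mask=mask, kind=kind)


def encode_protein_sequence(seq: str, sse: str | None = None) -> SequenceFeatureMatrix:
    return _encode_sequence(seq, sse, PROTEIN_MAX_LEN, "protein")


def encode_pocket_sequence(seq: str, sse: str | None = None) -> SequenceFeatureMatrix:
    return _encode_sequence(seq, sse, POCKET_MAX_LEN, "pocket")


# --------------------------------------------------------------------------
# Atom-level encoding (18 dims)
# --------------------------------------------------------------------------

_ATOM_TYPE_ORDER = ("B", "C", "N", "O", "P", "S", "Se", "halogen", "other")
_HALOGENS = {"F", "Cl", "Br", "I"}
_HYBRID_SCALE = {"S": 0.0, "SP": 0.25, "SP2": 0.5, "SP3": 0.75, "OTHER": 1.0}

# SMARTS flags: carbon/sulfur/halogen hydrophobes, aromatic member,
# Lipinski acceptor/donor, any-ring member.
_HYDROPHOBIC = Chem.MolFromSmarts("[#6+0!$(*~[#7,#8,F]),Cl,Br,I,S&H0&v2]")
_AROMATIC_SM = Chem.MolFromSmarts("[a]")
_RING_SM = Chem.MolFromSmarts("[R]")
_ACCEPTOR_SM = Lipinski.HAcceptorSmarts
_DONOR_SM = Lipinski.HDonorSmarts


def _match_set(mol: Chem.Mol, pattern: Chem.Mol) -> set[int]:
    return {idx for match in mol.GetSubstructMatches(pattern) for idx in match}


def atom_features(mol: Chem.Mol) -> np.ndarray:
    """(n_heavy, 18) per-atom features for an RDKit molecule."""
    hydrophobic = _match_set(mol, _HYDROPHOBIC)
    aromatic = _match_set(mol, _AROMATIC_SM)
    ring = _match_set(mol, _RING_SM)
    acceptor = _match_set(mol, _ACCEPTOR_SM)
    donor = _match_set(mol, _DONOR_SM)
    rows = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        vec = np.zeros(ATOM_FEATURE_DIM)
        symbol = atom.GetSymbol()
        if symbol in _ATOM_TYPE_ORDER[:7]:
            vec[_ATOM_TYPE_ORDER.index(symbol)] = 1.0
        elif symbol in _HALOGENS:
            vec[7] = 1.0
        else:
            vec[8] = 1.0
        hyb = str(atom.GetHybridization())
        vec[9] = _HYBRID_SCALE.get(hyb, 1.0)
        vec[10] = min(atom.GetDegree(), 4) / 4.0
        vec[11] = float(atom.GetFormalCharge())
        vec[12] = float(atom.GetIsAromatic())
        idx = atom.GetIdx()
        vec[13] = float(idx in hydrophobic)
        vec[14] = float(idx in aromatic)
        vec[15] = float(idx in acceptor)
        vec[16] = float(idx in donor)
        vec[17] = float(idx in ring)
        rows.append(vec)
    return np.array(rows).reshape(-1, ATOM_FEATURE_DIM)


def _resolve_rdmol(mol: LigandMolecule) -> Chem.Mol:
    if mol.rdmol is not None:
        return mol.rdmol
    rdmol = Chem.MolFromSmiles(mol.smiles)
    if rdmol is None:
        raise ValueError(f"cannot rebuild molecule from SMILES {mol.smiles!r}")
    return rdmol


def ligand_atom_features(mol: LigandMolecule) -> np.ndarray:
    """(n_atoms, 18) features in the LigandMolecule atom order."""
    feats = atom_features(_resolve_rdmol(mol))
    if feats.shape[0] != mol.n_atoms:
        raise ValueError("atom count mismatch between molecule and features")
    return feats


def encode_ligand_smiles(mol: LigandMolecule) -> SequenceFeatureMatrix:
    """Atom-wise ligand matrix padded to 150 x 18."""
    feats = ligand_atom_features(mol)
    n = feats.shape[0]
    if n == 0:
        raise ValueError("ligand has no heavy atoms")
    if n > LIGAND_MAX_LEN:
        logger.warning("ligand with %d atoms truncated to %d", n, LIGAND_MAX_LEN)
        feats = feats[:LIGAND_MAX_LEN]
        n = LIGAND_MAX_LEN
    values = np.zeros((LIGAND_MAX_LEN, ATOM_FEATURE_DIM))
    values[:n] = feats
    mask = np.zeros(LIGAND_MAX_LEN, dtype=bool)
    mask[:n] = True
    return SequenceFeatureMatrix(values=values, mask=mask, kind="ligand")


def pocket_pseudo_atom_features(residues: list[PocketResidue],
                                degrees: np.ndarray | None = None) -> np.ndarray:
    """18-dim features for pocket residue representatives (Calpha carbons).

    The complex graph types protein nodes with the same 18-dim scheme as
    ligand atoms; residue chemistry is projected onto it: the representative
    is a carbon, sp3, with donor/acceptor/aromatic/hydrophobic flags taken
    from the residue's side-chain character.
    """
    n = len(residues)
    out = np.zeros((n, ATOM_FEATURE_DIM))
    for i, res in enumerate(residues):
        aa = res.aa if res.aa in AA_ORDER else "X"
        out[i, 1] = 1.0  # carbon
        out[i, 9] = _HYBRID_SCALE["SP3"]
        if degrees is not None:
            out[i, 10] = min(float(degrees[i]), 4.0) / 4.0
        out[i, 11] = _NET_CHARGE_PH7.get(aa, 0.0)
        out[i, 13] = float(aa not in _POLAR and aa != "X")
        out[i, 14] = float(aa in _AROMATIC)
        out[i, 15] = float(_HBA.get(aa, 0) > 0)
        out[i, 16] = float(_HBD.get(aa, 0) > 0)
        out[i, 17] = float(aa in _AROMATIC)
    return out
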