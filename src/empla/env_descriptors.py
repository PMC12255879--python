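"""Biochemical indicators of protein and ligand and the 3x5 environment-node
feature matrix.

Eleven indicators in total: five for the protein (isoelectric point, GRAVY
hydropathy, net charge at pH 7, H-bond donor and acceptor counts) and six
for the ligand (aromatic ring count, rotatable bonds, TPSA, logP, formal
charge, H-bond donors and acceptors -> that is seven names but HBD/HBA count
as the donor/acceptor pair on each side, giving 5 + 6 = 11).

Protein charge chemistry uses the Henderson-Hasselbalch net-charge curve
with the EMBOSS pKa table; the isoelectric point is found by bisection on
that curve. Ligand descriptors are classical: Ertl TPSA, Crippen logP,
Lipinski donor/acceptor counts (via RDKit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .io_formats import LigandMolecule
from .sequence_features import _HBA, _HBD, _KYTE_DOOLITTLE, _resolve_rdmol

__all__ = [
    "ProteinIndicators", "LigandIndicators", "BiochemicalIndicators",
    "EnvNodeMatrix", "protein_indicators", "ligand_indicators",
    "compute_indicators", "assemble_env_nodes", "net_charge", "isoelectric_point",
]

# EMBOSS pKa values: side chains + termini
_PKA_SIDE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8,
             "R": 12.5}
_PKA_NTERM = 8.6
_PKA_CTERM = 3.6
_POSITIVE = {"H", "K", "R"}


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a peptide at the given pH."""
    if not seq:
        raise ValueError("empty sequence")
    pos = 1.0 / (1.0 + 10.0 ** (ph - _PKA_NTERM))  # N-terminus
    neg = 1.0 / (1.0 + 10.0 ** (_PKA_CTERM - ph))  # C-terminus
    for aa in seq.upper():
        pka = _PKA_SIDE.get(aa)
        if pka is None:
            continue
        if aa in _POSITIVE:
            pos += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            neg += 1.0 / (1.0 + 10.0 ** (pka - ph))
    return pos - neg


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero (bisection on [0, 14])."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ProteinIndicators:
    isoelectric_point: float  # pH units
    hydropathy_index: float  # GRAVY, dimensionless
    net_charge_ph7: float  # elementary charges
    hbd_count: int
    hba_count: int

    def as_array(self) -> np.ndarray:
        return np.array([self.isoelectric_point, self.hydropathy_index,
                         self.net_charge_ph7, self.hbd_count, self.hba_count],
                        dtype=float)


@dataclass(frozen=True)
class LigandIndicators:
    aromatic_ring_count: int
    rotatable_bond_count: int
    tpsa: float  # Angstrom^2
    logp: float
    formal_charge: int  # elementary charges
    hbd_count: int
    hba_count: int

    def as_array(self) -> np.ndarray:
        return np.array([self.aromatic_ring_count, self.rotatable_bond_count,
                         self.tpsa, self.logp, self.formal_charge,
                         self.hbd_count, self.hba_count], dtype=float)


@dataclass(frozen=True)
class BiochemicalIndicators:
    protein: ProteinIndicators
    ligand: LigandIndicators

    #: number of distinct named indicators: 5 protein + 6 ligand
    #: (ligand HBD/HBA form the donor/acceptor pair indicator on the
    #: ligand side, mirroring the protein's pair)
    N_INDICATORS = 11

    def indicator_names(self) -> list[str]:
        return [
            "protein_isoelectric_point", "protein_hydropathy_index",
            "protein_net_charge_ph7", "protein_hbond_donors",
            "protein_hbond_acceptors",
            "ligand_aromatic_rings", "ligand_rotatable_bonds",
            "ligand_tpsa", "ligand_logp", "ligand_formal_charge",
            "ligand_hbond_donors_acceptors",
        ]


@dataclass(frozen=True)
class EnvNodeMatrix:
    """3 x 5 feature matrix of the three environment nodes.

    Node roles: row 0 = protein environment, row 1 = ligand environment,
    row 2 = shared hydrogen-bonding environment. Eleven slots carry the
    indicators (scaled by documented min-max constants); four are zero.
    """

    values: np.ndarray
    node_roles = ("protein_env", "ligand_env", "shared_env")

    def __post_init__(self):
        if self.values.shape != (3, 5):
            raise ValueError("environment node matrix must be 3x5")


# documented (min, max) magnitude constants; each indicator is divided by
# the span so zero maps to zero and typical values land in [-1, 1]
_SCALES = {
    "pi": (0.0, 14.0),
    "gravy": (-4.5, 4.5),
    "charge": (-10.0, 10.0),
    "count": (0.0, 20.0),
    "tpsa": (0.0, 200.0),
    "logp": (-5.0, 5.0),
    "rings": (0.0, 8.0),
    "rotatable": (0.0, 15.0),
}


def _scale(value: float, key: str) -> float:
    lo, hi = _SCALES[key]
    return float(np.clip(value / (hi - lo), -1.0, 1.0))


def protein_indicators(seq: str) -> ProteinIndicators:
    if not seq:
        raise ValueError("empty protein sequence")
    seq = seq.upper()
    kd = [_KYTE_DOOLITTLE[aa] for aa in seq if aa in _KYTE_DOOLITTLE]
    gravy = float(np.mean(kd)) if kd else 0.0
    hbd = sum(_HBD.get(aa, 0) for aa in seq)
    hba = sum(_HBA.get(aa, 0) for aa in seq)
    return ProteinIndicators(
        isoelectric_point=isoelectric_point(seq),
        hydropathy_index=gravy,
        net_charge_ph7=net_charge(seq, 7.0),
        hbd_count=hbd,
        hba_count=hba,
    )


def ligand_indicators(mol: LigandMolecule) -> LigandIndicators:
    rdmol = _resolve_rdmol(mol)
    return LigandIndicators(
        aromatic_ring_count=rdMolDescriptors.CalcNumAromaticRings(rdmol),
        rotatable_bond_count=Lipinski.NumRotatableBonds(rdmol),
        tpsa=float(Descriptors.TPSA(rdmol)),
        logp=float(Crippen.MolLogP(rdmol)),
        formal_charge=sum(a.GetFormalCharge() for a in rdmol.GetAtoms()),
        hbd_count=Lipinski.NumHDonors(rdmol),
        hba_count=Lipinski.NumHAcceptors(rdmol),
    )


def compute_indicators(protein_seq: str, mol: LigandMolecule) -> BiochemicalIndicators:
    return BiochemicalIndicators(protein=protein_indicators(protein_seq),
                                 ligand=ligand_indicators(mol))


def assemble_env_nodes(ind: BiochemicalIndicators) -> EnvNodeMatrix:
    """Pack the 11 indicators into the 3x5 environment-node matrix.

    Row 0 (protein env):  pI, GRAVY, net charge, HBD, HBA (scaled).
    Row 1 (ligand env):   aromatic rings, rotatable bonds, TPSA, logP, charge.
    Row 2 (shared env):   ligand HBD, ligand HBA, 0, 0, 0.
    """
    p, l = ind.protein, ind.ligand
    values = np.zeros((3, 5))
    values[0] = [_scale(p.isoelectric_point, "pi"),
                 _scale(p.hydropathy_index, "gravy"),
                 _scale(p.net_charge_ph7, "charge"),
                 _scale(p.hbd_count, "count"),
                 _scale(p.hba_count, "count")]
    values[1] = [_scale(l.aromatic_ring_count, "rings"),
                 _scale(l.rotatable_bond_count, "rotatable"),
                 _scale(l.tpsa, "tpsa"),
                 _scale(l.logp, "logp"),
                 _scale(l.formal_charge, "charge")]
    values[2, 0] = _scale(l.hbd_count, "count")
    values[2, 1] = _scale(l.hba_count, "count")
    return EnvNodeMatrix(values=values)
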