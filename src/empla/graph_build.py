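"""Construction of the pocket graph, ligand graph and environment-aware
heterogeneous complex graph.

Pocket graph: residues as nodes (21-dim one-hot), edges between residues
whose Calpha atoms lie within 5 A (inclusive). Ligand graph: heavy atoms as
nodes (18-dim), covalent bonds as edges with 12-dim features. Complex graph:
protein and ligand nodes (both 18-dim) plus 3 environment nodes (3 x 5
features); bidirectional protein-ligand contact edges carry the
Euclidean distance, environment edges carry distance zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .env_descriptors import EnvNodeMatrix
from .io_formats import BOND_ORDER_CLASSES, ComplexRecord, LigandMolecule
from .sequence_features import (aa_one_hot, ligand_atom_features,
                                pocket_pseudo_atom_features)

__all__ = [
    "PocketGraph", "LigandGraph", "ComplexGraph",
    "build_pocket_graph", "build_ligand_graph", "build_complex_graph",
    "save_complex_graph", "load_complex_graph",
    "POCKET_EDGE_CUTOFF", "CONTACT_CUTOFF", "EDGE_FEATURE_DIM",
]

POCKET_EDGE_CUTOFF = 5.0  # Angstrom, inclusive
CONTACT_CUTOFF = 5.0  # Angstrom, protein-ligand contacts
EDGE_FEATURE_DIM = 12
N_ENV_NODES = 3


@dataclass
class PocketGraph:
    node_features: np.ndarray  # (n, 21) AA one-hot
    edges: np.ndarray  # (e, 2) undirected pairs, i < j
    coords: np.ndarray  # (n, 3) Angstrom

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def directed_edges(self) -> np.ndarray:
        """Both directions of every undirected edge, (2e, 2)."""
        if self.edges.size == 0:
            return np.zeros((0, 2), dtype=int)
        return np.vstack([self.edges, self.edges[:, ::-1]])


@dataclass
class LigandGraph:
    node_features: np.ndarray  # (m, 18)
    edges: np.ndarray  # (2e, 2) directed bond pairs
    edge_features: np.ndarray  # (2e, 12)
    coords: np.ndarray  # (m, 3)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]


@dataclass
class ComplexGraph:
    protein_nodes: np.ndarray  # (p, 18)
    ligand_nodes: np.ndarray  # (q, 18)
    env_nodes: EnvNodeMatrix  # 3 x 5
    pl_edges: np.ndarray  # (c, 2) directed (protein idx, ligand idx) contacts
    pl_distances: np.ndarray  # (c,) Angstrom, one per directed p->l edge
    protein_coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    ligand_coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    # Environment edges connect every env node to every protein and ligand
    # node bidirectionally with distance 0; they are implied by the node
    # counts and materialized on demand.
    @property
    def n_protein(self) -> int:
        return self.protein_nodes.shape[0]

    @property
    def n_ligand(self) -> int:
        return self.ligand_nodes.shape[0]

    def env_protein_edges(self) -> np.ndarray:
        """(3*p, 2) pairs (env idx, protein idx); distances are all zero."""
        e, p = np.meshgrid(np.arange(N_ENV_NODES), np.arange(self.n_protein),
                           indexing="ij")
        return np.stack([e.ravel(), p.ravel()], axis=1)

    def env_ligand_edges(self) -> np.ndarray:
        e, q = np.meshgrid(np.arange(N_ENV_NODES), np.arange(self.n_ligand),
                           indexing="ij")
        return np.stack([e.ravel(), q.ravel()], axis=1)

    def env_edge_distances(self) -> np.ndarray:
        return np.zeros(N_ENV_NODES * (self.n_protein + self.n_ligand))


# --------------------------------------------------------------------------

def build_pocket_graph(record: ComplexRecord,
                       cutoff: float = POCKET_EDGE_CUTOFF) -> PocketGraph:
    coords = record.pocket_coords()
    if coords.shape[0] == 0:
        raise ValueError("pocket has no residues")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = dist[iu, ju] <= cutoff
    edges = np.stack([iu[keep], ju[keep]], axis=1)
    return PocketGraph(node_features=aa_one_hot(record.pocket_seq),
                       edges=edges, coords=coords)


def _incident_mean_angles(coords: np.ndarray, neighbors: list[list[int]]) -> np.ndarray:
    """Mean bond angle (radians) at each atom; 0 for atoms with < 2 bonds."""
    n = coords.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = neighbors[i]
        if len(nbrs) < 2:
            continue
        angles = []
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                u = coords[nbrs[a]] - coords[i]
                v = coords[nbrs[b]] - coords[i]
                denom = np.linalg.norm(u) * np.linalg.norm(v)
                if denom == 0:
                    continue
                cosang = np.clip(np.dot(u, v) / denom, -1.0, 1.0)
                angles.append(np.arccos(cosang))
        if angles:
            out[i] = float(np.mean(angles))
    return out


def build_ligand_graph(mol: LigandMolecule) -> LigandGraph:
    """Covalent ligand graph with 12-dim directed edge features.

    Edge-feature layout (fixed):
      [0:4]  bond-order one-hot (single, double, triple, aromatic)
      [4]    in-ring flag
      [5]    conjugated flag (aromatic or double/triple order)
      [6]    bond length, Angstrom
      [7:9]  mean incident bond angle at source and target atom, radians
      [9]    bond-length z-score within the molecule
      [10:12] reserved, zero
    """
    if mol.n_atoms == 0:
        raise ValueError("ligand has no atoms")
    coords = mol.coords()
    feats = ligand_atom_features(mol)
    neighbors: list[list[int]] = [[] for _ in range(mol.n_atoms)]
    for b in mol.bonds:
        neighbors[b.i].append(b.j)
        neighbors[b.j].append(b.i)
    angles = _incident_mean_angles(coords, neighbors)
    lengths = np.array([np.linalg.norm(coords[b.i] - coords[b.j])
                        for b in mol.bonds])
    if lengths.size:
        mean_len = lengths.mean()
        std_len = lengths.std()
        if std_len < 1e-6:  # near-uniform lengths: z-scores are noise
            std_len = 1.0
    edges, edge_feats = [], []
    for k, b in enumerate(mol.bonds):
        base = np.zeros(EDGE_FEATURE_DIM)
        base[BOND_ORDER_CLASSES.index(b.order)] = 1.0
        base[4] = float(b.in_ring)
        base[5] = float(b.order in ("AROMATIC", "DOUBLE", "TRIPLE"))
        base[6] = lengths[k]
        base[9] = (lengths[k] - mean_len) / std_len
        for src, dst in ((b.i, b.j), (b.j, b.i)):
            vec = base.copy()
            vec[7] = angles[src]
            vec[8] = angles[dst]
            edges.append((src, dst))
            edge_feats.append(vec)
    edges_arr = np.array(edges, dtype=int).reshape(-1, 2)
    feats_arr = np.array(edge_feats).reshape(-1, EDGE_FEATURE_DIM)
    return LigandGraph(node_features=feats, edges=edges_arr,
                       edge_features=feats_arr, coords=coords)


def build_complex_graph(record: ComplexRecord, env: EnvNodeMatrix,
                        contact_cutoff: float = CONTACT_CUTOFF) -> ComplexGraph:
    """Heterogeneous complex graph over protein, ligand and environment nodes.

    Protein nodes are the pocket residue representatives (Calpha) typed with
    the 18-dim atom scheme; ligand nodes are heavy atoms. Directed
    protein->ligand contact edges are stored once; the reverse direction is
    implied (edges are bidirectional with the same distance).
    """
    p_coords = record.pocket_coords()
    l_coords = record.ligand.coords()
    if p_coords.shape[0] == 0 or l_coords.shape[0] == 0:
        raise ValueError("complex graph needs at least one protein and one ligand atom")
    diff = p_coords[:, None, :] - l_coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    pi, li = np.nonzero(dist <= contact_cutoff)
    # pocket degrees (within 5 A) inform the neighbor-count channel
    pdiff = p_coords[:, None, :] - p_coords[None, :, :]
    pdist = np.sqrt((pdiff ** 2).sum(axis=-1))
    degrees = ((pdist <= POCKET_EDGE_CUTOFF).sum(axis=1) - 1).astype(float)
    return ComplexGraph(
        protein_nodes=pocket_pseudo_atom_features(record.pocket_residues, degrees),
        ligand_nodes=ligand_atom_features(record.ligand),
        env_nodes=env,
        pl_edges=np.stack([pi, li], axis=1),
        pl_distances=dist[pi, li],
        protein_coords=p_coords,
        ligand_coords=l_coords,
    )


# --------------------------------------------------------------------------
# Serialization (NPZ key-value tensor store)
# --------------------------------------------------------------------------

def save_complex_graph(graph: ComplexGraph, path) -> None:
    np.savez(path,
             protein_nodes=graph.protein_nodes,
             ligand_nodes=graph.ligand_nodes,
             env_nodes=graph.env_nodes.values,
             pl_edges=graph.pl_edges,
             pl_distances=graph.pl_distances,
             protein_coords=graph.protein_coords,
             ligand_coords=graph.ligand_coords)


def load_complex_graph(path) -> ComplexGraph:
    data = np.load(path)
    return ComplexGraph(
        protein_nodes=data["protein_nodes"],
        ligand_nodes=data["ligand_nodes"],
        env_nodes=EnvNodeMatrix(values=data["env_nodes"]),
        pl_edges=data["pl_edges"],
        pl_distances=data["pl_distances"],
        protein_coords=data["protein_coords"],
        ligand_coords=data["ligand_coords"],
    )
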