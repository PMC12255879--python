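"""Graph construction: cutoff boundary behaviour, brute-force all-pairs
oracles, isometry invariance, and the heterogeneous-graph contracts."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Geometry import Point3D

from empla.env_descriptors import EnvNodeMatrix, assemble_env_nodes, compute_indicators
from empla.graph_build import (EDGE_FEATURE_DIM, build_complex_graph,
                               build_ligand_graph, build_pocket_graph,
                               load_complex_graph, save_complex_graph)
from empla.io_formats import (ComplexRecord, LigandAtom, LigandBond,
                              LigandMolecule, PocketResidue, ligand_from_rdkit)
from .conftest import random_rotation, rigid_transform_record, two_residue_record


def _env3x5() -> EnvNodeMatrix:
    return EnvNodeMatrix(values=np.arange(15, dtype=float).reshape(3, 5) / 15.0)


def _record_from_coords(coords: np.ndarray) -> ComplexRecord:
    residues = [PocketResidue("A", tuple(map(float, c)), "-") for c in coords]
    seq = "A" * len(residues)
    lig = two_residue_record(1.0).ligand
    return ComplexRecord(complex_id="x", protein_seq=seq, pocket_seq=seq,
                         pocket_residues=residues, ligand=lig)


class TestPocketGraph:
    @pytest.mark.parametrize("sep,n_edges", [(4.9, 1), (5.0, 1), (5.1, 0)])
    def test_cutoff_boundary(self, sep, n_edges):
        g = build_pocket_graph(two_residue_record(sep))
        assert g.edges.shape[0] == n_edges

    def test_collinear_three_residues(self):
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        g = build_pocket_graph(_record_from_coords(coords))
        assert sorted(map(tuple, g.edges)) == [(0, 1), (1, 2)]

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n = int(rng.integers(3, 50))
            coords = rng.uniform(-8, 8, size=(n, 3))
            g = build_pocket_graph(_record_from_coords(coords))
            expected = {(i, j) for i in range(n) for j in range(i + 1, n)
                        if np.linalg.norm(coords[i] - coords[j]) <= 5.0}
            assert set(map(tuple, g.edges)) == expected

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(-6, 6, size=(10, 3))
        rec = _record_from_coords(coords)
        g1 = build_pocket_graph(rec)
        R, t = random_rotation(rng), rng.normal(size=3) * 5
        g2 = build_pocket_graph(_record_from_coords(coords @ R.T + t))
        assert np.array_equal(g1.edges, g2.edges)

    def test_node_features_are_21_dim(self, small_record):
        g = build_pocket_graph(small_record)
        assert g.node_features.shape == (len(small_record.pocket_seq), 21)

    def test_empty_pocket_raises(self):
        lig = two_residue_record(1.0).ligand
        with pytest.raises(ValueError):
            rec = ComplexRecord(complex_id="e", protein_seq="A", pocket_seq="",
                                pocket_residues=[], ligand=lig)
            build_pocket_graph(rec)


class TestLigandGraph:
    def test_ethane_single_bond(self):
        atoms = [LigandAtom("C", 0, False, False, "SP3", (0.0, 0.0, 0.0)),
                 LigandAtom("C", 0, False, False, "SP3", (1.54, 0.0, 0.0))]
        mol = LigandMolecule(atoms=atoms,
                             bonds=[LigandBond(0, 1, "SINGLE", False)],
                             smiles="CC")
        g = build_ligand_graph(mol)
        assert g.edges.shape[0] == 2  # directed
        assert np.all(g.edge_features[:, 0] == 1.0)  # single-bond bit
        assert np.all(g.edge_features[:, 4] == 0.0)  # not in ring
        assert g.edge_features[0, 6] == pytest.approx(1.54)

    def test_ideal_benzene_geometry(self):
        # regular hexagon with 1.39 A sides: all angles exactly 2*pi/3
        mol = Chem.MolFromSmiles("c1ccccc1")
        mol = Chem.AddHs(mol)
        conf = Chem.Conformer(mol.GetNumAtoms())
        r = 1.39
        for i in range(6):
            theta = np.pi * i / 3.0
            conf.SetAtomPosition(i, Point3D(r * np.cos(theta),
                                            r * np.sin(theta), 0.0))
        for i in range(6, mol.GetNumAtoms()):
            conf.SetAtomPosition(i, Point3D(2.5 * np.cos(np.pi * (i - 6) / 3.0),
                                            2.5 * np.sin(np.pi * (i - 6) / 3.0), 0.0))
        mol.AddConformer(conf)
        lig = ligand_from_rdkit(mol)
        g = build_ligand_graph(lig)
        assert g.edges.shape[0] == 12  # 6 undirected bonds
        assert np.all(g.edge_features[:, 3] == 1.0)  # aromatic bit
        assert np.all(g.edge_features[:, 4] == 1.0)  # ring flag
        assert g.edge_features[:, 7] == pytest.approx(2 * np.pi / 3, abs=1e-6)

    def test_edge_feature_width_always_12(self, ethanol, benzene):
        for mol in (ethanol, benzene):
            g = build_ligand_graph(mol)
            assert g.edge_features.shape[1] == EDGE_FEATURE_DIM == 12

    def test_edge_rows_match_directed_edges(self, benzene):
        g = build_ligand_graph(benzene)
        assert g.edge_features.shape[0] == g.edges.shape[0]


class TestComplexGraph:
    def _one_one_record(self, distance: float) -> ComplexRecord:
        atoms = [LigandAtom("C", 0, False, False, "SP3", (distance, 0.0, 0.0))]
        lig = LigandMolecule(atoms=atoms, bonds=[], smiles="C")
        residues = [PocketResidue("G", (0.0, 0.0, 0.0), "-")]
        return ComplexRecord(complex_id="one", protein_seq="G", pocket_seq="G",
                             pocket_residues=residues, ligand=lig)

    def test_close_pair_contact_and_env_edges(self):
        g = build_complex_graph(self._one_one_record(3.0), _env3x5())
        assert g.pl_edges.shape[0] == 1
        assert g.pl_distances[0] == pytest.approx(3.0)
        assert g.env_protein_edges().shape[0] == 3  # 3 env x 1 protein
        assert g.env_ligand_edges().shape[0] == 3

    def test_distant_pair_still_connected_via_env(self):
        g = build_complex_graph(self._one_one_record(12.0), _env3x5())
        assert g.pl_edges.shape[0] == 0
        assert g.env_protein_edges().shape[0] + g.env_ligand_edges().shape[0] == 6

    def test_env_edge_distances_all_zero(self, small_record):
        env = assemble_env_nodes(
            compute_indicators(small_record.protein_seq, small_record.ligand))
        g = build_complex_graph(small_record, env)
        assert np.all(g.env_edge_distances() == 0.0)

    def test_contact_edges_match_oracle(self, small_record):
        env = _env3x5()
        g = build_complex_graph(small_record, env)
        p = small_record.pocket_coords()
        l = small_record.ligand.coords()
        expected = {(i, j) for i in range(len(p)) for j in range(len(l))
                    if np.linalg.norm(p[i] - l[j]) <= 5.0}
        assert set(map(tuple, g.pl_edges)) == expected
        for (i, j), d in zip(g.pl_edges, g.pl_distances):
            assert d == pytest.approx(np.linalg.norm(p[i] - l[j]))

    def test_node_features_18_dim(self, small_record):
        g = build_complex_graph(small_record, _env3x5())
        assert g.protein_nodes.shape[1] == 18
        assert g.ligand_nodes.shape[1] == 18

    def test_isometry_preserves_distances(self, small_record):
        rng = np.random.default_rng(3)
        g1 = build_complex_graph(small_record, _env3x5())
        moved = rigid_transform_record(small_record, random_rotation(rng),
                                       rng.normal(size=3) * 10)
        g2 = build_complex_graph(moved, _env3x5())
        assert np.array_equal(g1.pl_edges, g2.pl_edges)
        assert g1.pl_distances == pytest.approx(g2.pl_distances, abs=1e-6)

    def test_npz_roundtrip(self, tmp_path, small_record):
        g = build_complex_graph(small_record, _env3x5())
        path = tmp_path / "graph.npz"
        save_complex_graph(g, path)
        back = load_complex_graph(path)
        assert np.array_equal(back.protein_nodes, g.protein_nodes)
        assert np.array_equal(back.pl_edges, g.pl_edges)
        assert np.array_equal(back.env_nodes.values, g.env_nodes.values)
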