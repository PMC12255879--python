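"""Model branches: attention closed forms, invariances, ablation mechanics,
gradient flow, checkpointing."""

import numpy as np
import pytest

from empla.graph_build import build_ligand_graph, build_pocket_graph
from empla.model import (AffinityModel, CrossAttention, ModelConfig,
                         load_checkpoint, predict_affinity, save_checkpoint)
from empla.nn import Tensor
from .conftest import random_rotation, rigid_transform_record


@pytest.fixture(scope="module")
def model(tiny_model_cfg):
    return AffinityModel(tiny_model_cfg, seed=0)


class TestModelConfig:
    def test_defaults_match_architecture(self):
        cfg = ModelConfig()
        assert cfg.protein_dilations == (1, 2, 4, 8, 16)
        assert cfg.ligand_dilations == (1, 2, 4, 8)
        assert cfg.attention_heads == 2
        assert cfg.key_dim * cfg.attention_heads == cfg.hidden_dim
        assert cfg.egnn_layers == cfg.hgt_layers == 3

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_dim=15, attention_heads=2)

    def test_all_branches_off_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(use_protein=False, use_sequence_complex=False,
                        use_covalent=False, use_noncovalent=False)

    def test_round_trip_dict(self):
        cfg = ModelConfig(hidden_dim=32, use_covalent=False)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestDilatedConvEncoder:
    def test_five_layers_for_protein(self, model):
        assert len(model.protein_encoder.convs) == 5

    def test_four_layers_for_ligand_path(self, model):
        assert len(model.seq_complex_encoder.lig_dilated.convs) == 4

    def test_padding_inert(self, model):
        # trailing zero-padding never reaches the encoder: featurize crops
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 40))
        out1 = model.protein_encoder(Tensor(x)).data
        out2 = model.protein_encoder(Tensor(x.copy())).data
        assert np.array_equal(out1, out2)

    def test_empty_input_raises(self, model):
        with pytest.raises(ValueError):
            model.protein_encoder(Tensor(np.zeros((0, 40))))


class TestCrossAttention:
    def test_singleton_key_gets_weight_one(self, tiny_model_cfg):
        attn = CrossAttention(tiny_model_cfg, np.random.default_rng(0))
        q = Tensor(np.random.default_rng(1).normal(size=(3, 16)))
        kv = Tensor(np.random.default_rng(2).normal(size=(1, 16)))
        attn(q, kv)
        for w in attn.last_weights:
            assert w == pytest.approx(np.ones((3, 1)))

    def test_rows_sum_to_one(self, tiny_model_cfg):
        attn = CrossAttention(tiny_model_cfg, np.random.default_rng(0))
        q = Tensor(np.random.default_rng(1).normal(size=(4, 16)))
        kv = Tensor(np.random.default_rng(2).normal(size=(7, 16)))
        attn(q, kv)
        for w in attn.last_weights:
            assert w.sum(axis=1) == pytest.approx(np.ones(4))

    def test_identical_keys_give_value_mean(self, tiny_model_cfg):
        # equal logits -> uniform weights -> attended output = mean of values
        attn = CrossAttention(tiny_model_cfg, np.random.default_rng(0))
        q = Tensor(np.random.default_rng(1).normal(size=(2, 16)))
        kv = Tensor(np.tile(np.random.default_rng(2).normal(size=(1, 16)), (5, 1)))
        out = attn(q, kv)
        for w in attn.last_weights:
            assert w == pytest.approx(np.full((2, 5), 0.2))
        single = attn(q, Tensor(kv.data[:1]))
        assert out.data == pytest.approx(single.data)


class TestEGNN:
    def test_rigid_motion_invariance(self, model, small_record):
        g1 = build_pocket_graph(small_record)
        rng = np.random.default_rng(5)
        moved = rigid_transform_record(small_record, random_rotation(rng),
                                       rng.normal(size=3) * 8)
        g2 = build_pocket_graph(moved)
        p1 = model.egnn_encoder(g1).data
        p2 = model.egnn_encoder(g2).data
        assert p1 == pytest.approx(p2, abs=1e-5)

    def test_node_permutation_invariance(self, model, small_record):
        g = build_pocket_graph(small_record)
        rng = np.random.default_rng(6)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g2 = type(g)(node_features=g.node_features[perm],
                     edges=inv[g.edges], coords=g.coords[perm])
        assert model.egnn_encoder(g).data == pytest.approx(
            model.egnn_encoder(g2).data, abs=1e-9)

    def test_single_node_graph_runs(self, model):
        from empla.graph_build import PocketGraph
        g = PocketGraph(node_features=np.eye(21)[:1],
                        edges=np.zeros((0, 2), dtype=int),
                        coords=np.zeros((1, 3)))
        out = model.egnn_encoder(g)
        assert np.all(np.isfinite(out.data))


class TestAttentiveFP:
    def test_permutation_invariance(self, model, small_record):
        g = build_ligand_graph(small_record.ligand)
        rng = np.random.default_rng(7)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g2 = type(g)(node_features=g.node_features[perm],
                     edges=inv[g.edges], edge_features=g.edge_features,
                     coords=g.coords[perm])
        assert model.afp_encoder(g).data == pytest.approx(
            model.afp_encoder(g2).data, abs=1e-9)

    def test_single_atom_molecule(self, model):
        from empla.graph_build import LigandGraph
        g = LigandGraph(node_features=np.zeros((1, 18)),
                        edges=np.zeros((0, 2), dtype=int),
                        edge_features=np.zeros((0, 12)),
                        coords=np.zeros((1, 3)))
        out = model.afp_encoder(g)
        assert np.all(np.isfinite(out.data))


class TestEnvHGT:
    def test_env_disabled_ignores_env_features(self, small_record, tiny_model_cfg):
        import dataclasses
        cfg = dataclasses.replace(tiny_model_cfg, use_environment_nodes=False)
        m = AffinityModel(cfg, seed=0)
        feat = m.featurize(small_record)
        out1 = m.hgt_encoder(feat.complex_graph).data
        g2 = dataclasses.replace(feat.complex_graph)
        g2.env_nodes = type(feat.complex_graph.env_nodes)(
            values=np.ones((3, 5)) * 9.0)
        out2 = m.hgt_encoder(g2).data
        assert np.array_equal(out1, out2)  # steps 1 and 3 skipped entirely

    def test_ligand_permutation_invariance(self, model, small_record):
        feat = model.featurize(small_record)
        g = feat.complex_graph
        rng = np.random.default_rng(8)
        perm = rng.permutation(g.n_ligand)
        inv = np.argsort(perm)
        import dataclasses
        g2 = dataclasses.replace(
            g, ligand_nodes=g.ligand_nodes[perm],
            pl_edges=np.stack([g.pl_edges[:, 0], inv[g.pl_edges[:, 1]]], axis=1),
            ligand_coords=g.ligand_coords[perm])
        assert model.hgt_encoder(g).data == pytest.approx(
            model.hgt_encoder(g2).data, abs=1e-9)

    def test_no_contact_fallback(self, model):
        from .conftest import two_residue_record
        rec = two_residue_record(3.0)
        # move the ligand far away: no protein-ligand contacts remain
        rng = np.random.default_rng(9)
        far = rigid_transform_record(rec, np.eye(3), np.zeros(3))
        from empla.io_formats import LigandAtom, LigandMolecule
        atoms = [LigandAtom(a.element, a.formal_charge, a.aromatic, a.in_ring,
                            a.hybridization,
                            (a.coord[0] + 50.0, a.coord[1], a.coord[2]))
                 for a in far.ligand.atoms]
        far.ligand = LigandMolecule(atoms=atoms, bonds=far.ligand.bonds,
                                    smiles=far.ligand.smiles)
        feat = model.featurize(far)
        assert feat.complex_graph.pl_edges.shape[0] == 0
        out = model.hgt_encoder(feat.complex_graph)
        assert np.all(np.isfinite(out.data))


class TestPredictAffinity:
    def test_deterministic(self, small_record, tiny_model_cfg):
        a = predict_affinity(small_record, tiny_model_cfg, seed=3)
        b = predict_affinity(small_record, tiny_model_cfg, seed=3)
        assert a == b

    def test_finite_on_synthetic_complexes(self, small_dataset, model):
        for rec in small_dataset:
            assert np.isfinite(model.predict(rec))

    def test_branch_isolation_under_ablation(self, small_record, tiny_model_cfg):
        import dataclasses
        full = AffinityModel(tiny_model_cfg, seed=0)
        ablated = AffinityModel(
            dataclasses.replace(tiny_model_cfg, use_sequence_complex=False),
            seed=0)
        feat_f = full.featurize(small_record)
        feat_a = ablated.featurize(small_record)
        emb_f = full.branch_embeddings(feat_f)
        emb_a = ablated.branch_embeddings(feat_a)
        assert "S_complex" in emb_f and "S_complex" not in emb_a
        for key in emb_a:
            assert np.array_equal(emb_f[key].data, emb_a[key].data)

    def test_gradient_reaches_every_branch(self, small_dataset, model):
        feats = [model.featurize(r) for r in small_dataset[:2]]
        loss = None
        for f in feats:
            term = (model.forward(f) - f.label) ** 2
            loss = term if loss is None else loss + term
        loss.backward()
        branch_modules = {
            "protein": model.protein_encoder,
            "seq_complex": model.seq_complex_encoder,
            "egnn": model.egnn_encoder,
            "afp": model.afp_encoder,
            "hgt": model.hgt_encoder,
            "fusion": model.fusion,
        }
        for name, module in branch_modules.items():
            total = sum(float(np.abs(p.grad).sum())
                        for p in module.parameters() if p.grad is not None)
            assert total > 0, f"branch {name} received no gradient"

    def test_checkpoint_roundtrip(self, tmp_path, small_record, tiny_model_cfg):
        model = AffinityModel(tiny_model_cfg, seed=1)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert restored.predict(small_record) == pytest.approx(
            model.predict(small_record), abs=1e-12)

    def test_all_ablation_configs_runnable(self, small_record, tiny_model_cfg):
        import dataclasses
        settings = [
            {"use_environment_nodes": False},
            {"use_covalent": False},
            {"use_noncovalent": False},
            {"use_sequence_complex": False},
            {"use_protein": False},
        ]
        for flags in settings:
            cfg = dataclasses.replace(tiny_model_cfg, **flags)
            value = predict_affinity(small_record, cfg, seed=0)
            assert np.isfinite(value)
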