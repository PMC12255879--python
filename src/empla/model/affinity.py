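"""Branch fusion and the end-to-end affinity predictor."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..env_descriptors import assemble_env_nodes, compute_indicators
from ..graph_build import (ComplexGraph, LigandGraph, PocketGraph,
                           build_complex_graph, build_ligand_graph,
                           build_pocket_graph)
from ..io_formats import ComplexRecord
from ..nn import MLP, Module, Tensor, concat
from ..sequence_features import (encode_ligand_smiles, encode_pocket_sequence,
                                 encode_protein_sequence)
from .branches import (AttentiveFPEncoder, DilatedConvEncoder, EGNNEncoder,
                       EnvHGTEncoder, SequenceComplexEncoder)
from .config import ModelConfig

__all__ = ["AffinityModel", "FeaturizedComplex", "predict_affinity",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class FeaturizedComplex:
    """Pre-computed per-complex model inputs (cropped to valid lengths)."""

    complex_id: str
    protein: np.ndarray  # (Lp, 40)
    pocket: np.ndarray  # (Lpoc, 40)
    ligand_seq: np.ndarray  # (Llig, 18)
    pocket_graph: PocketGraph
    ligand_graph: LigandGraph
    complex_graph: ComplexGraph
    label: Optional[float] = None


class AffinityModel(Module):
    """Four encoder branches fused by an MLP into a scalar -log10 affinity."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        # each branch draws from its own seeded stream so that removing one
        # branch (ablation) leaves the others' parameters bit-identical
        def rng(branch: int):
            return np.random.default_rng([seed, branch])

        self.cfg = cfg
        h = cfg.hidden_dim
        n_branch_vectors = 0
        if cfg.use_protein:
            self.protein_encoder = DilatedConvEncoder(
                40, h, cfg.protein_dilations, rng(0))
            n_branch_vectors += 1
        if cfg.use_sequence_complex:
            self.seq_complex_encoder = SequenceComplexEncoder(cfg, rng(1))
            n_branch_vectors += 1
        if cfg.use_covalent:
            self.egnn_encoder = EGNNEncoder(cfg, rng(2))
            self.afp_encoder = AttentiveFPEncoder(cfg, rng(3))
            n_branch_vectors += 2
        if cfg.use_noncovalent:
            self.hgt_encoder = EnvHGTEncoder(cfg, rng(4))
            n_branch_vectors += 1
        dims = [n_branch_vectors * h, *cfg.fusion_hidden, 1]
        self.fusion = MLP(dims, rng(5))

    # ------------------------------------------------------------- pipeline
    def featurize(self, record: ComplexRecord) -> FeaturizedComplex:
        pro = encode_protein_sequence(record.protein_seq)
        sse = "".join(r.sse for r in record.pocket_residues)
        poc = encode_pocket_sequence(record.pocket_seq, sse)
        lig = encode_ligand_smiles(record.ligand)
        env = assemble_env_nodes(
            compute_indicators(record.protein_seq, record.ligand))
        return FeaturizedComplex(
            complex_id=record.complex_id,
            protein=pro.values[pro.mask],
            pocket=poc.values[poc.mask],
            ligand_seq=lig.values[lig.mask],
            pocket_graph=build_pocket_graph(record),
            ligand_graph=build_ligand_graph(record.ligand),
            complex_graph=build_complex_graph(record, env),
            label=record.affinity_label,
        )

    def branch_embeddings(self, feat: FeaturizedComplex) -> dict[str, Tensor]:
        cfg = self.cfg
        out: dict[str, Tensor] = {}
        if cfg.use_protein:
            out["P_seq"] = self.protein_encoder(Tensor(feat.protein))
        if cfg.use_sequence_complex:
            out["S_complex"] = self.seq_complex_encoder(
                Tensor(feat.pocket), Tensor(feat.ligand_seq))
        if cfg.use_covalent:
            out["P3d"] = self.egnn_encoder(feat.pocket_graph)
            out["L3d"] = self.afp_encoder(feat.ligand_graph)
        if cfg.use_noncovalent:
            out["C3d"] = self.hgt_encoder(feat.complex_graph)
        return out

    def forward(self, feat: FeaturizedComplex) -> Tensor:
        embeddings = self.branch_embeddings(feat)
        fused = concat(list(embeddings.values()), axis=0)
        return self.fusion(fused).reshape(-1)

    def predict(self, record: ComplexRecord) -> float:
        return float(self.forward(self.featurize(record)).data[0])


def predict_affinity(record: ComplexRecord, cfg: ModelConfig,
                     model: AffinityModel | None = None,
                     seed: int = 0) -> float:
    """Scalar affinity prediction; builds a fresh seeded model when no
    trained one is supplied."""
    if model is None:
        model = AffinityModel(cfg, seed=seed)
    return model.predict(record)


# --------------------------------------------------------------------------
# Checkpoints: single NPZ with the parameter tensors + embedded config JSON
# --------------------------------------------------------------------------

def save_checkpoint(model: AffinityModel, path) -> None:
    state = model.state_dict()
    state = {f"param:{k}": v for k, v in state.items()}
    state["config_json"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> AffinityModel:
    data = np.load(path)
    cfg = ModelConfig.from_dict(json.loads(bytes(data["config_json"]).decode()))
    model = AffinityModel(cfg)
    model.load_state_dict({k[len("param:"):]: data[k] for k in data.files
                           if k.startswith("param:")})
    return model
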