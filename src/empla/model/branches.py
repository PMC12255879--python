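"""The encoder branches: dilated-convolution sequence encoders, the
bidirectional cross-attention module, the EGNN pocket encoder, the
AttentiveFP ligand encoder and the three-step environment-HGT.

All encoders operate on variable-length (cropped) inputs so that padding is
inert by construction; every 3-D computation enters only through pairwise
distances and angles, which makes the outputs invariant to rigid motions.
"""

from __future__ import annotations

import numpy as np

from ..graph_build import ComplexGraph, LigandGraph, PocketGraph
from ..nn import (GRUCell, Linear, MLP, Module, Tensor, concat, segment_mean,
                  segment_sum)
from ..nn.layers import Conv1d
from .config import ModelConfig

__all__ = ["DilatedConvEncoder", "CrossAttention", "SequenceComplexEncoder",
           "EGNNEncoder", "AttentiveFPEncoder", "EnvHGTEncoder"]


def _segment_softmax(logits: Tensor, segment_ids: np.ndarray,
                     num_segments: int) -> Tensor:
    """Softmax of (E, 1) logits within segments given by segment_ids."""
    shifted = logits - float(logits.data.max()) if logits.data.size else logits
    e = shifted.exp()
    denom = segment_sum(e, segment_ids, num_segments)
    return e * denom.gather_rows(segment_ids) ** (-1.0)


class DilatedConvEncoder(Module):
    """Stacked 1-D dilated convolutions; per-layer outputs are concatenated
    across scales and mean-pooled over positions into a fixed-width vector.
    """

    def __init__(self, in_dim: int, hidden_dim: int, dilations, rng):
        self.convs = [Conv1d(in_dim if i == 0 else hidden_dim, hidden_dim,
                             kernel_size=3, dilation=d, rng=rng)
                      for i, d in enumerate(dilations)]
        self.out = Linear(hidden_dim * len(dilations), hidden_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[0] == 0:
            raise ValueError("encoder input has no valid positions")
        outputs = []
        for conv in self.convs:
            x = conv(x).relu()
            outputs.append(x)
        multi_scale = concat(outputs, axis=1)  # (L, n_layers * hidden)
        return self.out(multi_scale.mean(axis=0))


class CrossAttention(Module):
    """Multi-head scaled dot-product attention of queries over keys/values:
    softmax(Q_i K_i^T / sqrt(d_k)) V_i per head, heads concatenated, then W^O.
    """

    def __init__(self, cfg: ModelConfig, rng):
        h, dk = cfg.hidden_dim, cfg.key_dim
        self.heads = cfg.attention_heads
        self.scale = 1.0 / np.sqrt(dk)
        self.w_q = [Linear(h, dk, rng, bias=False) for _ in range(self.heads)]
        self.w_k = [Linear(h, dk, rng, bias=False) for _ in range(self.heads)]
        self.w_v = [Linear(h, dk, rng, bias=False) for _ in range(self.heads)]
        self.w_o = Linear(h, h, rng, bias=False)
        self.last_weights: list[np.ndarray] = []  # per head, for inspection

    def __call__(self, query: Tensor, key_value: Tensor) -> Tensor:
        heads = []
        self.last_weights = []
        for i in range(self.heads):
            q = self.w_q[i](query)
            k = self.w_k[i](key_value)
            v = self.w_v[i](key_value)
            logits = (q @ k.T) * self.scale
            weights = logits.softmax(axis=-1)
            self.last_weights.append(weights.data)
            heads.append(weights @ v)
        return self.w_o(concat(heads, axis=1))


class SequenceComplexEncoder(Module):
    """Pocket/ligand sequence interaction branch.

    Pocket attends over the ligand and vice versa (two cross-attention
    directions); the enriched pocket passes through a plain 1-D convolution
    and the enriched ligand through a four-scale dilated stack, both
    mean-pooled and fused into one vector.
    """

    def __init__(self, cfg: ModelConfig, rng):
        h = cfg.hidden_dim
        self.poc_in = Linear(40, h, rng)
        self.lig_in = Linear(18, h, rng)
        self.attn_poc = CrossAttention(cfg, rng)  # pocket = Q, ligand = K,V
        self.attn_lig = CrossAttention(cfg, rng)  # ligand = Q, pocket = K,V
        self.poc_conv = Conv1d(h, h, kernel_size=3, dilation=1, rng=rng)
        self.lig_dilated = DilatedConvEncoder(h, h, cfg.ligand_dilations, rng)
        self.fuse = Linear(2 * h, h, rng)

    def __call__(self, poc: Tensor, lig: Tensor) -> Tensor:
        poc_h = self.poc_in(poc).relu()
        lig_h = self.lig_in(lig).relu()
        poc_enr = self.attn_poc(poc_h, lig_h)
        lig_enr = self.attn_lig(lig_h, poc_h)
        poc_vec = self.poc_conv(poc_enr).relu().mean(axis=0)
        lig_vec = self.lig_dilated(lig_enr)
        return self.fuse(concat([poc_vec, lig_vec], axis=0)).relu()


class EGNNLayer(Module):
    """One E(n)-equivariant layer: messages on (h_i, h_j, ||x_i - x_j||^2),
    relative-position coordinate update, then the feature update.
    """

    def __init__(self, hidden_dim: int, rng):
        self.phi_e = MLP([2 * hidden_dim + 1, hidden_dim, hidden_dim], rng)
        self.phi_x = Linear(hidden_dim, 1, rng, bias=False)
        self.phi_h = MLP([2 * hidden_dim, hidden_dim, hidden_dim], rng)

    def __call__(self, h: Tensor, x: Tensor, edges: np.ndarray):
        n = h.shape[0]
        if edges.shape[0] == 0:
            agg = Tensor(np.zeros((n, h.shape[1])))
            h_new = self.phi_h(concat([h, agg], axis=1))
            return h_new, x  # no neighbors: coordinates unchanged
        src, dst = edges[:, 0], edges[:, 1]
        h_src, h_dst = h.gather_rows(src), h.gather_rows(dst)
        x_src, x_dst = x.gather_rows(src), x.gather_rows(dst)
        rel = x_dst - x_src  # points toward the receiving node
        sqdist = (rel * rel).sum(axis=1, keepdims=True)
        m = self.phi_e(concat([h_dst, h_src, sqdist], axis=1))
        coef = self.phi_x(m).tanh()  # bounded coordinate step
        x_new = x + segment_mean(rel * coef, dst, n)
        agg = segment_mean(m, dst, n)
        h_new = self.phi_h(concat([h, agg], axis=1))
        return h_new, x_new


class EGNNEncoder(Module):
    """Three EGNN layers over the pocket graph; layer outputs concatenated
    and mean-pooled into the invariant pocket embedding.
    """

    def __init__(self, cfg: ModelConfig, rng):
        h = cfg.hidden_dim
        self.embed = Linear(21, h, rng)
        self.layers = [EGNNLayer(h, rng) for _ in range(cfg.egnn_layers)]
        self.out = Linear(cfg.egnn_layers * h, h, rng)

    def __call__(self, graph: PocketGraph) -> Tensor:
        if graph.n_nodes == 0:
            raise ValueError("empty pocket graph")
        h = self.embed(Tensor(graph.node_features)).relu()
        x = Tensor(graph.coords.copy())
        edges = graph.directed_edges()
        per_layer = []
        for layer in self.layers:
            h, x = layer(h, x, edges)
            per_layer.append(h)
        stacked = concat(per_layer, axis=1)  # (n, layers * hidden)
        return self.out(stacked.mean(axis=0))


class AttentiveFPEncoder(Module):
    """Graph-attention atom updates with a GRU state and an attentive
    molecule-level readout over several timesteps.
    """

    def __init__(self, cfg: ModelConfig, rng):
        h = cfg.hidden_dim
        self.n_layers = cfg.attentivefp_layers
        self.timesteps = cfg.attentivefp_timesteps
        self.atom_in = Linear(18, h, rng)
        self.nbr_in = Linear(18 + 12, h, rng)  # neighbor atom + bond features
        self.align = [Linear(2 * h, 1, rng) for _ in range(self.n_layers)]
        self.attend = [Linear(h, h, rng) for _ in range(self.n_layers)]
        self.gru = [GRUCell(h, h, rng) for _ in range(self.n_layers)]
        self.mol_align = Linear(2 * h, 1, rng)
        self.mol_attend = Linear(h, h, rng)
        self.mol_gru = GRUCell(h, h, rng)

    def __call__(self, graph: LigandGraph) -> Tensor:
        if graph.n_nodes == 0:
            raise ValueError("empty ligand graph")
        n = graph.n_nodes
        h = self.atom_in(Tensor(graph.node_features)).relu()
        edges = graph.edges
        has_edges = edges.shape[0] > 0
        if has_edges:
            src, dst = edges[:, 0], edges[:, 1]
            nbr_feats = Tensor(np.concatenate(
                [graph.node_features[src], graph.edge_features], axis=1))
            nbr = self.nbr_in(nbr_feats).relu()  # (E, h) neighbor descriptors
        for layer in range(self.n_layers):
            if has_edges:
                logits = self.align[layer](
                    concat([h.gather_rows(dst), nbr], axis=1)).leaky_relu(0.01)
                alpha = _segment_softmax(logits, dst, n)
                contrib = alpha * self.attend[layer](nbr).elu()
                context = segment_sum(contrib, dst, n)
            else:
                context = Tensor(np.zeros(h.shape))
            h = self.gru[layer](context, h)
        # molecule-level attentive readout
        s = h.mean(axis=0).reshape(1, -1)
        ones = np.zeros(n, dtype=np.intp)
        for _ in range(self.timesteps):
            s_b = s.gather_rows(ones)  # broadcast super-node state
            logits = self.mol_align(concat([s_b, h], axis=1)).leaky_relu(0.01)
            alpha = _segment_softmax(logits, ones, 1)
            context = segment_sum(alpha * self.mol_attend(h).elu(), ones, 1)
            s = self.mol_gru(context, s)
        return s.reshape(-1)


class SAGEConv(Module):
    """GraphSAGE with mean aggregation: W_self h_dst + W_nbr mean(h_src)."""

    def __init__(self, dst_dim: int, src_dim: int, out_dim: int, rng):
        self.w_self = Linear(dst_dim, out_dim, rng)
        self.w_nbr = Linear(src_dim, out_dim, rng, bias=False)

    def __call__(self, dst_feats: Tensor, src_feats: Tensor,
                 edges: np.ndarray) -> Tensor:
        n_dst = dst_feats.shape[0]
        if edges.shape[0] == 0:
            nbr = Tensor(np.zeros((n_dst, src_feats.shape[1])))
        else:
            messages = src_feats.gather_rows(edges[:, 0])
            nbr = segment_mean(messages, edges[:, 1], n_dst)
        return self.w_self(dst_feats) + self.w_nbr(nbr)


class EnvHGTEncoder(Module):
    """Three-step environment-aware heterogeneous graph convolution.

    Per layer, strictly in order: (1) protein/ligand nodes absorb the
    environment, (2) protein/ligand nodes exchange over the bidirectional
    contact relation, (3) environment nodes absorb the complex. Distance-
    gated edge pooling plus an MLP produce the non-covalent embedding.
    """

    def __init__(self, cfg: ModelConfig, rng):
        h = cfg.hidden_dim
        self.use_env = cfg.use_environment_nodes
        self.n_layers = cfg.hgt_layers
        self.c_in = Linear(18, h, rng)
        self.e_in = Linear(5, h, rng)
        self.env_to_c = [SAGEConv(h, h, h, rng) for _ in range(self.n_layers)]
        self.c_to_c = [SAGEConv(h, h, h, rng) for _ in range(self.n_layers)]
        self.c_to_env = [SAGEConv(h, h, h, rng) for _ in range(self.n_layers)]
        self.gate = Linear(1, 1, rng)  # learned scalar on edge distance
        self.out = MLP([2 * h + 1, h, h], rng)

    def __call__(self, graph: ComplexGraph) -> Tensor:
        p, q = graph.n_protein, graph.n_ligand
        if p == 0 or q == 0:
            raise ValueError("complex graph needs protein and ligand nodes")
        c_feats = np.concatenate([graph.protein_nodes, graph.ligand_nodes])
        c = self.c_in(Tensor(c_feats)).relu()
        e = self.e_in(Tensor(graph.env_nodes.values)).relu()
        n_c, n_e = p + q, 3
        # relation edge lists in (src, dst) layout with type-local indexing
        pl = graph.pl_edges
        c2c = np.vstack([
            np.stack([pl[:, 0], pl[:, 1] + p], axis=1),  # protein -> ligand
            np.stack([pl[:, 1] + p, pl[:, 0]], axis=1),  # ligand -> protein
        ]) if pl.shape[0] else np.zeros((0, 2), dtype=int)
        env_src = np.repeat(np.arange(n_e), n_c)
        all_c = np.tile(np.arange(n_c), n_e)
        e2c = np.stack([env_src, all_c], axis=1)
        c2e = np.stack([all_c, env_src], axis=1)
        for layer in range(self.n_layers):
            if self.use_env:
                c = self.env_to_c[layer](c, e, e2c).relu()
            c = self.c_to_c[layer](c, c, c2c).relu()
            if self.use_env:
                e = self.c_to_env[layer](e, c, c2e).relu()
        return self._edge_pool(graph, c, p)

    def _edge_pool(self, graph: ComplexGraph, c: Tensor, p: int) -> Tensor:
        pl = graph.pl_edges
        if pl.shape[0] == 0:
            # no contacts: fall back to node-mean pooling
            pooled = concat([c.slice_rows(0, p).mean(axis=0),
                             c.slice_rows(p, c.shape[0]).mean(axis=0)], axis=0)
            total = Tensor(np.zeros(1))
        else:
            dists = Tensor(graph.pl_distances.reshape(-1, 1))
            w = self.gate(dists).sigmoid()  # (E, 1)
            ends = concat([c.gather_rows(pl[:, 0]),
                           c.gather_rows(pl[:, 1] + p)], axis=1)  # (E, 2h)
            wsum = w.sum(axis=0)  # (1,)
            pooled = (ends * w).sum(axis=0) * (wsum + 1e-8) ** (-1.0)
            total = wsum
        # log-compressed gated contact count channel keeps the total number
        # of contacts visible to the head without saturating
        return self.out(concat([pooled, (total * 0.1 + 1.0).log()], axis=0))
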