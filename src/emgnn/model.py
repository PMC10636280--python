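"""EMGNN forward computation.

Three stages: a per-layer GNN with parameters shared across every input
network, a meta-GNN run on each gene's star graph (the gene's layer
instances joined to one meta-node), and an MLP classifier on the meta-node
state.  Built on the autodiff core so the same code path serves training,
prediction, and gradient-based attribution (including gradients with
respect to meta-edge weights).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, concat, softmax, spmm
from .graphs import MetaGraph, MultilayerDataset, build_meta_graph

__all__ = [
    "ModelConfig", "EmgnnModel", "NodeState", "forward",
    "gcn_aggregate", "gat_aggregate", "count_parameters",
    "normalized_adjacency", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    conv_type: str = "gcn"  # gcn | gat
    f1_layers: int = 3
    f1_hidden: int = 64
    f2_layers: int = 1
    f2_hidden: int = 64
    gat_heads: int = 1
    dropout: float = 0.5
    meta_init: str = "raw_features_projected"
    seed: int = 0

    def __post_init__(self):
        if self.conv_type not in ("gcn", "gat"):
            raise ValueError(f"conv_type must be gcn or gat, got {self.conv_type!r}")
        if self.f1_layers < 1 or self.f2_layers < 1:
            raise ValueError("f1_layers and f2_layers must be >= 1")
        if self.f1_hidden < 1 or self.f2_hidden < 1:
            raise ValueError("hidden dimensions must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.conv_type == "gat":
            if self.f1_hidden % self.gat_heads or self.f2_hidden % self.gat_heads:
                raise ValueError("hidden dims must be divisible by gat_heads")
        if self.meta_init != "raw_features_projected":
            raise ValueError(f"unknown meta_init {self.meta_init!r}")


def _glorot(rng, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape if shape is not None else (fan_in, fan_out))


class _Conv:
    """One graph-convolution layer's parameters (GCN or GAT with heads)."""

    def __init__(self, rng, conv_type: str, d_in: int, d_out: int, heads: int):
        self.conv_type = conv_type
        self.d_in, self.d_out, self.heads = d_in, d_out, heads
        if conv_type == "gcn":
            self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
            self.params = [self.W]
        else:
            hd = d_out // heads
            self.W = [Tensor(_glorot(rng, d_in, hd), requires_grad=True) for _ in range(heads)]
            self.a_dst = [Tensor(_glorot(rng, hd, 1, shape=(hd,)), requires_grad=True)
                          for _ in range(heads)]
            self.a_src = [Tensor(_glorot(rng, hd, 1, shape=(hd,)), requires_grad=True)
                          for _ in range(heads)]
            self.params = [*self.W, *self.a_dst, *self.a_src]
        self.b = Tensor(np.zeros(d_out), requires_grad=True)
        self.params.append(self.b)


class _Linear:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)
        self.params = [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class EmgnnModel:
    """Parameter container for the f1 / f2 / f3 pipeline.

    f1 is shared across all input networks and f2 across all genes, so the
    trainable parameter count does not depend on the number of layers K.
    """

    def __init__(self, config: ModelConfig, n_features: int):
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(config.seed)
        c = config
        self.f1: List[_Conv] = []
        d = n_features
        for _ in range(c.f1_layers):
            self.f1.append(_Conv(rng, c.conv_type, d, c.f1_hidden, c.gat_heads))
            d = c.f1_hidden
        self.meta_projection = _Linear(rng, n_features, c.f1_hidden)
        self.f2: List[_Conv] = []
        d = c.f1_hidden
        for _ in range(c.f2_layers):
            self.f2.append(_Conv(rng, c.conv_type, d, c.f2_hidden, c.gat_heads))
            d = c.f2_hidden
        self.f3_hidden = _Linear(rng, c.f2_hidden, c.f2_hidden)
        self.f3_out = _Linear(rng, c.f2_hidden, 2)

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        for conv in self.f1 + self.f2:
            out.extend(conv.params)
        out.extend(self.meta_projection.params)
        out.extend(self.f3_hidden.params)
        out.extend(self.f3_out.params)
        return out

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = a.copy()


def count_parameters(model: EmgnnModel) -> int:
    """Total scalar trainable parameters; independent of the number of layers K."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# Aggregation primitives
# ---------------------------------------------------------------------------

def normalized_adjacency(n_nodes: int, edges: Sequence[Tuple[int, int]]) -> sp.csr_matrix:
    """Symmetric GCN propagation matrix D^-1/2 (A + I) D^-1/2, d_hat = 1 + deg."""
    rows, cols = [], []
    for i, j in edges:
        if i == j:
            raise ValueError("self-loops must not appear in the edge set")
        rows += [i, j]
        cols += [j, i]
    a = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_nodes, n_nodes))
    a = a + sp.eye(n_nodes)
    dhat = np.asarray(a.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(dhat)
    return (sp.diags(dinv) @ a @ sp.diags(dinv)).tocsr()


def gcn_aggregate(node_states, edges, weight):
    """GCN step: h'_u = W^T sum_{v in N(u) u {u}} h_v / sqrt(d_hat_v d_hat_u).

    `node_states` is an (n, d_in) array or Tensor, `edges` an iterable of
    integer index pairs, `weight` a (d_in, d_out) matrix (applied as H @ W).
    """
    h = Tensor._ensure(node_states)
    w = Tensor._ensure(weight)
    if h.shape[-1] != w.shape[0]:
        raise ValueError(f"state dim {h.shape[-1]} != weight rows {w.shape[0]}")
    s = normalized_adjacency(h.shape[-2], list(edges))
    out = spmm(s, h) @ w
    if isinstance(node_states, Tensor) or isinstance(weight, Tensor):
        return out
    return out.data


def _gat_pairs(n_nodes: int, edges: Sequence[Tuple[int, int]]):
    """Directed (dst, src) pairs over closed neighborhoods: self pairs first."""
    dst = list(range(n_nodes))
    src = list(range(n_nodes))
    for i, j in edges:
        dst += [i, j]
        src += [j, i]
    return np.asarray(dst, dtype=np.intp), np.asarray(src, dtype=np.intp)


def _gat_head(h: Tensor, dst, src, W: Tensor, a_dst: Tensor, a_src: Tensor,
              n_nodes: int, slope: float, edge_weight: Optional[Tensor] = None):
    """Single-head GAT aggregation; returns (node outputs, per-pair alphas).

    `edge_weight`, when given, multiplies the messages of the non-self pairs
    (ordered as in `_gat_pairs`); attention itself is computed unweighted.
    """
    z = h @ W
    zd = z.take_rows(dst)
    zs = z.take_rows(src)
    logits = (zd * a_dst).sum(axis=-1) + (zs * a_src).sum(axis=-1)
    logits = logits.leaky_relu(slope)
    # per-destination max as a detached constant: value-preserving shift
    seg_max = np.full(logits.data.shape[:-1] + (n_nodes,), -np.inf)
    np.maximum.at(seg_max, (..., dst), logits.data)
    ex = (logits - seg_max[..., dst]).exp()
    denom = ex.reshape(*ex.shape, 1).scatter_rows(dst, n_nodes)
    alpha = ex.reshape(*ex.shape, 1) / denom.take_rows(dst)
    msg = zs * alpha
    if edge_weight is not None:
        n_self = n_nodes
        idx_self = np.arange(n_self)
        idx_edge = np.arange(n_self, len(dst))
        w = edge_weight.reshape(*edge_weight.shape, 1)
        msg = concat([msg.take_rows(idx_self), msg.take_rows(idx_edge) * w], axis=-2)
    out = msg.scatter_rows(dst, n_nodes)
    return out, alpha


def gat_aggregate(node_states, edges, weight, attention_vector, leaky_slope: float = 0.2,
                  return_attention: bool = False):
    """GAT step with softmax attention over the closed neighborhood.

    `attention_vector` has length 2*d_out: the first half scores the central
    node's transformed state, the second half the neighbor's.
    """
    h = Tensor._ensure(node_states)
    w = Tensor._ensure(weight)
    if h.shape[-1] != w.shape[0]:
        raise ValueError(f"state dim {h.shape[-1]} != weight rows {w.shape[0]}")
    a = np.asarray(attention_vector, dtype=np.float64)
    d_out = w.shape[1]
    if a.size != 2 * d_out:
        raise ValueError("attention vector must have length 2*d_out")
    n = h.shape[-2]
    dst, src = _gat_pairs(n, list(edges))
    out, alpha = _gat_head(h, dst, src, w, Tensor._ensure(a[:d_out]),
                           Tensor._ensure(a[d_out:]), n, leaky_slope)
    result = out if isinstance(node_states, Tensor) else out.data
    if return_attention:
        coeffs = {(int(u), int(v)): float(al) for u, v, al
                  in zip(dst, src, np.asarray(alpha.data).reshape(-1))}
        return result, coeffs
    return result


# ---------------------------------------------------------------------------
# Compiled multilayer structure
# ---------------------------------------------------------------------------

@dataclass
class _CompiledLayer:
    layer_id: str
    genes: List[str]              # local order
    universe_idx: np.ndarray      # local -> universe row
    s_hat: sp.csr_matrix          # GCN propagation matrix
    gat_dst: np.ndarray
    gat_src: np.ndarray


@dataclass
class _Compiled:
    universe: Tuple[str, ...]
    uni_index: Dict[str, int]
    layers: List[_CompiledLayer]
    n_inst: int
    inst_slices: Dict[str, slice]           # layer_id -> rows in the stacked instance matrix
    inst_rows: Dict[Tuple[str, str], int]   # (layer_id, gene) -> stacked row
    meta_edges: List[Tuple[Tuple[str, str], str]]
    edge_inst_row: np.ndarray               # per meta-edge
    edge_meta_row: np.ndarray               # per meta-edge (offset into n_all)
    edge_gene_idx: np.ndarray
    edge_layer: List[str]
    edge_coef: np.ndarray                   # 1/sqrt(2 * (1 + m_gene))
    self_coef: np.ndarray                   # (n_all,)
    s_meta: sp.csr_matrix                   # structural star propagation (unit weights)
    gat_meta_dst: np.ndarray
    gat_meta_src: np.ndarray
    gat_meta_wid: np.ndarray                # meta-edge id per non-self pair

    @property
    def n_all(self) -> int:
        return self.n_inst + len(self.universe)


def compile_dataset(dataset: MultilayerDataset, meta_graph: Optional[MetaGraph] = None) -> _Compiled:
    cached = getattr(dataset, "_compiled", None)
    cacheable = meta_graph is None
    if cached is not None and cacheable:
        return cached
    if meta_graph is None:
        meta_graph = build_meta_graph(dataset.layers, dataset.universe)
    if tuple(meta_graph.meta_nodes) != tuple(dataset.universe):
        raise ValueError("meta-graph gene universe does not match the dataset universe")

    uni_index = {g: i for i, g in enumerate(dataset.universe)}
    layers: List[_CompiledLayer] = []
    inst_slices: Dict[str, slice] = {}
    inst_rows: Dict[Tuple[str, str], int] = {}
    offset = 0
    for lg in dataset.layers:
        genes = [g for g in lg.nodes if g in uni_index]
        local = {g: k for k, g in enumerate(genes)}
        edges = [(local[a], local[b]) for a, b in
                 (tuple(sorted(e)) for e in lg.edges)
                 if a in local and b in local]
        s_hat = normalized_adjacency(len(genes), edges)
        dst, src = _gat_pairs(len(genes), edges)
        layers.append(_CompiledLayer(lg.layer_id, genes,
                                     np.asarray([uni_index[g] for g in genes], dtype=np.intp),
                                     s_hat, dst, src))
        inst_slices[lg.layer_id] = slice(offset, offset + len(genes))
        for g in genes:
            inst_rows[(lg.layer_id, g)] = offset + local[g]
        offset += len(genes)
    n_inst = offset

    # meta star graphs: instance d_hat = 2 (self + meta edge); meta d_hat = 1 + multiplicity
    edges_list = [e for e in meta_graph.meta_edges if e[0] in inst_rows]
    multiplicity = np.zeros(len(dataset.universe))
    for _, gene in edges_list:
        multiplicity[uni_index[gene]] += 1
    edge_inst_row = np.asarray([inst_rows[inst] for inst, _ in edges_list], dtype=np.intp)
    edge_gene_idx = np.asarray([uni_index[g] for _, g in edges_list], dtype=np.intp)
    edge_meta_row = n_inst + edge_gene_idx
    edge_layer = [inst[0] for inst, _ in edges_list]
    edge_coef = 1.0 / np.sqrt(2.0 * (1.0 + multiplicity[edge_gene_idx]))
    self_coef = np.concatenate([np.full(n_inst, 0.5), 1.0 / (1.0 + multiplicity)])

    n_all = n_inst + len(dataset.universe)
    rows = np.concatenate([np.arange(n_all), edge_meta_row, edge_inst_row])
    cols = np.concatenate([np.arange(n_all), edge_inst_row, edge_meta_row])
    vals = np.concatenate([self_coef, edge_coef, edge_coef])
    s_meta = sp.coo_matrix((vals, (rows, cols)), shape=(n_all, n_all)).tocsr()
    gat_meta_dst = np.concatenate([np.arange(n_all),
                                   edge_meta_row, edge_inst_row]).astype(np.intp)
    gat_meta_src = np.concatenate([np.arange(n_all),
                                   edge_inst_row, edge_meta_row]).astype(np.intp)
    gat_meta_wid = np.concatenate([np.arange(len(edges_list)),
                                   np.arange(len(edges_list))]).astype(np.intp)

    compiled = _Compiled(tuple(dataset.universe), uni_index, layers, n_inst,
                         inst_slices, inst_rows, edges_list, edge_inst_row,
                         edge_meta_row, edge_gene_idx, edge_layer, edge_coef,
                         self_coef, s_meta, gat_meta_dst, gat_meta_src, gat_meta_wid)
    if cacheable:
        dataset._compiled = compiled
    return compiled


def stacked_inputs(dataset: MultilayerDataset, compiled: Optional[_Compiled] = None) -> np.ndarray:
    """Node-input feature matrix: one row per layer instance, then one per
    meta-node, each holding the gene's feature vector.  This is the leaf the
    node-feature attribution differentiates against."""
    c = compiled or compile_dataset(dataset)
    blocks = [dataset.features.rows(cl.genes) for cl in c.layers]
    blocks.append(dataset.features.rows(list(c.universe)))
    return np.concatenate(blocks, axis=0)


@dataclass
class NodeState:
    """Forward-pass outputs for every gene in the universe."""

    layer_outputs: Dict[str, np.ndarray]
    meta_outputs: np.ndarray
    logits: np.ndarray
    yhat: np.ndarray
    logits_tensor: Tensor = field(repr=False, default=None)
    yhat_tensor: Tensor = field(repr=False, default=None)


def _dropout(h: Tensor, p: float, rng) -> Tensor:
    if p <= 0:
        return h
    mask = (rng.random(h.shape) >= p) / (1.0 - p)
    return h * mask


def _run_conv(conv: _Conv, h: Tensor, *, s_hat=None, dst=None, src=None,
              n_nodes=None, slope: float = 0.2,
              edge_weight: Optional[Tensor] = None,
              gcn_edges=None) -> Tensor:
    if conv.conv_type == "gcn":
        if gcn_edges is not None:
            out = gcn_edges(h) @ conv.W
        else:
            out = spmm(s_hat, h) @ conv.W
        return out + conv.b
    heads = []
    for W, ad, asrc in zip(conv.W, conv.a_dst, conv.a_src):
        out, _ = _gat_head(h, dst, src, W, ad, asrc, n_nodes, slope, edge_weight)
        heads.append(out)
    out = heads[0] if len(heads) == 1 else concat(heads, axis=-1)
    return out + conv.b


def forward(model: EmgnnModel, dataset: MultilayerDataset,
            meta_graph: Optional[MetaGraph] = None, *,
            training: bool = False, dropout_rng=None,
            node_inputs: Optional[Tensor] = None,
            meta_edge_weights: Optional[Tensor] = None) -> NodeState:
    """Run the three-stage pipeline and return per-gene outputs.

    `node_inputs` overrides the stacked feature matrix (see
    :func:`stacked_inputs`); `meta_edge_weights` is a tensor of one weight
    per meta-edge (default all ones) scaling instance<->meta messages.
    Evaluation mode (training=False) is fully deterministic.
    """
    c = compile_dataset(dataset, meta_graph)
    if model.n_features != len(dataset.features.feature_names):
        raise ValueError("model feature dimension does not match the dataset")
    z = node_inputs if node_inputs is not None else Tensor(stacked_inputs(dataset, c))
    return forward_compiled(model, c, z, training=training, dropout_rng=dropout_rng,
                            meta_edge_weights=meta_edge_weights)


def forward_compiled(model: EmgnnModel, c: _Compiled, z: Tensor, *,
                     training: bool = False, dropout_rng=None,
                     meta_edge_weights: Optional[Tensor] = None) -> NodeState:
    """Pipeline over a pre-compiled multilayer structure (see compile_dataset)."""
    cfg = model.config
    if training and dropout_rng is None:
        dropout_rng = np.random.default_rng(cfg.seed + 1)

    # stage 1: shared f1 on each layer graph
    layer_states: Dict[str, Tensor] = {}
    for cl in c.layers:
        h = z.take_rows(np.arange(c.inst_slices[cl.layer_id].start,
                                  c.inst_slices[cl.layer_id].stop))
        for conv in model.f1:
            h = _run_conv(conv, h, s_hat=cl.s_hat, dst=cl.gat_dst, src=cl.gat_src,
                          n_nodes=len(cl.genes)).relu()
            if training:
                h = _dropout(h, cfg.dropout, dropout_rng)
        layer_states[cl.layer_id] = h

    # stage 2: meta-GNN on the disjoint star graphs
    h_inst = concat([layer_states[cl.layer_id] for cl in c.layers], axis=-2)
    meta_rows = np.arange(c.n_inst, c.n_all)
    h_meta0 = model.meta_projection(z.take_rows(meta_rows))
    h_all = concat([h_inst, h_meta0], axis=-2)

    w = meta_edge_weights

    def gcn_meta(h: Tensor) -> Tensor:
        msgs_fwd = h.take_rows(c.edge_inst_row) * c.edge_coef[:, None]
        msgs_bwd = h.take_rows(c.edge_meta_row) * c.edge_coef[:, None]
        if w is not None:
            wexp = w.reshape(*w.shape, 1)
            msgs_fwd = msgs_fwd * wexp
            msgs_bwd = msgs_bwd * wexp
        agg = msgs_fwd.scatter_rows(c.edge_meta_row, c.n_all) \
            + msgs_bwd.scatter_rows(c.edge_inst_row, c.n_all) \
            + h * c.self_coef[:, None]
        return agg

    for k, conv in enumerate(model.f2):
        if conv.conv_type == "gcn":
            if w is None:
                h_all = _run_conv(conv, h_all, s_hat=c.s_meta)
            else:
                h_all = _run_conv(conv, h_all, gcn_edges=gcn_meta, edge_weight=w)
        else:
            ew = None
            if w is not None:
                ew = w.take_last(c.gat_meta_wid)
            h_all = _run_conv(conv, h_all, dst=c.gat_meta_dst, src=c.gat_meta_src,
                              n_nodes=c.n_all, edge_weight=ew)
        if k < len(model.f2) - 1:
            h_all = h_all.relu()
            if training:
                h_all = _dropout(h_all, cfg.dropout, dropout_rng)

    h_meta = h_all.take_rows(meta_rows)

    # stage 3: MLP classifier on the meta-node state
    hidden = model.f3_hidden(h_meta).relu()
    if training:
        hidden = _dropout(hidden, cfg.dropout, dropout_rng)
    logits = model.f3_out(hidden)
    probs = softmax(logits, axis=-1)
    yhat = probs.take_last(np.asarray([1]))
    yhat = yhat.reshape(*yhat.shape[:-1])

    return NodeState(
        layer_outputs={cl.layer_id: layer_states[cl.layer_id].data for cl in c.layers},
        meta_outputs=h_meta.data,
        logits=logits.data,
        yhat=yhat.data,
        logits_tensor=logits,
        yhat_tensor=yhat,
    )


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(model: EmgnnModel, path, *, universe: Sequence[str] = (),
                    layer_ids: Sequence[str] = (), feature_names: Sequence[str] = (),
                    extra: Optional[dict] = None) -> None:
    header = {
        "format": "emgnn-checkpoint",
        "version": _CKPT_VERSION,
        "config": model.config.__dict__,
        "n_features": model.n_features,
        "universe": list(universe),
        "layer_ids": list(layer_ids),
        "feature_names": list(feature_names),
        "extra": extra or {},
    }
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, header=json.dumps(header), **arrays)


def load_checkpoint(path) -> Tuple[EmgnnModel, dict]:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        if header.get("format") != "emgnn-checkpoint":
            raise ValueError(f"{path}: not an EMGNN checkpoint")
        cfg = ModelConfig(**header["config"])
        model = EmgnnModel(cfg, header["n_features"])
        n = len(model.parameters())
        model.load_state_arrays([data[f"param_{i}"] for i in range(n)])
    return model, header
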