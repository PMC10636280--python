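"""Integrated-gradients explanations of trained models.

Two separate attribution problems: node-feature attributions with the graph
structure held fixed, and meta-edge attributions with the node features held
fixed.  Both integrate the gradient of the target gene's positive-class
probability along a straight path (midpoint Riemann sum) from a baseline to
the actual input; meta-edge attributions are afterwards normalized per
meta-node to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor
from .graphs import MultilayerDataset
from .model import (EmgnnModel, _Compiled, _CompiledLayer, compile_dataset,
                    forward, forward_compiled, stacked_inputs)

__all__ = ["AttributionResult", "integrated_gradients", "ig_node_features",
           "ig_meta_edges", "ig_meta_edges_all", "aggregate_neighbor_importance"]

DEFAULT_STEPS = 128


@dataclass
class AttributionResult:
    """Attributions for one target gene.

    `feature_matrix` has one row per instance node in the target's receptive
    field (k hops in each layer, k = number of f1 message-passing steps);
    `row_index` gives the (layer_id, gene) of each row.  `meta_node_row` is
    the target's own meta-node feature attribution.  `meta_edge_attr` maps
    layer_id -> normalized meta-edge attribution in [0, 1] (absent layers
    are structurally 0 and omitted).
    """

    target_gene: str
    feature_matrix: Optional[np.ndarray] = None
    row_index: List[Tuple[str, str]] = field(default_factory=list)
    meta_node_row: Optional[np.ndarray] = None
    meta_edge_attr: Dict[str, float] = field(default_factory=dict)
    meta_edge_raw: Dict[str, float] = field(default_factory=dict)
    baseline: float = 0.0
    steps: int = DEFAULT_STEPS


def _alpha_grid(steps: int) -> np.ndarray:
    if steps < 1:
        raise ValueError("steps must be >= 1")
    return (np.arange(steps) + 0.5) / steps  # midpoint rule


def integrated_gradients(f, x: np.ndarray, baseline: Optional[np.ndarray] = None,
                         steps: int = DEFAULT_STEPS, chunk: int = 16) -> np.ndarray:
    """Path-integrated gradients of a scalar-per-sample function.

    `f` receives a Tensor of shape (B, *x.shape) -- a batch of interpolated
    inputs -- and must return a Tensor whose entries depend on one batch
    element each (its sum is differentiated).  Returns
    (x - baseline) * mean of df/dx over the midpoint interpolation grid.
    """
    x = np.asarray(x, dtype=np.float64)
    base = np.zeros_like(x) if baseline is None else np.asarray(baseline, dtype=np.float64)
    delta = x - base
    alphas = _alpha_grid(steps)
    grad_sum = np.zeros_like(x)
    expand = (slice(None),) + (None,) * x.ndim
    for start in range(0, steps, chunk):
        batch = alphas[start:start + chunk]
        z = Tensor(base[None] + batch[expand] * delta[None], requires_grad=True)
        f(z).sum().backward()
        grad_sum += z.grad.sum(axis=0)
    return delta * grad_sum / steps


def _local_receptive(cl: _CompiledLayer, target_gene: str, k: int) -> np.ndarray:
    """Local indices of the k-hop closed neighborhood of the target in a layer."""
    local = {g: i for i, g in enumerate(cl.genes)}
    n = len(cl.genes)
    adj = (cl.s_hat != 0)
    reach = np.zeros(n, dtype=bool)
    frontier = np.zeros(n, dtype=bool)
    frontier[local[target_gene]] = True
    reach |= frontier
    for _ in range(k):
        frontier = np.asarray((adj @ frontier.astype(float)) > 0).ravel()
        reach |= frontier
    return np.flatnonzero(reach)


def _subcompile(c: _Compiled, target_gene: str, k: int
                ) -> Tuple[_Compiled, np.ndarray]:
    """Restrict the compiled structure to the target's receptive field.

    The target's prediction depends only on nodes within k hops in each
    layer (k = f1 depth) and on its own star graph, so the forward pass over
    this substructure reproduces the target's output exactly -- propagation
    coefficients are sliced from the full-graph matrices, keeping true
    degrees.  Returns the substructure and the map from its stacked rows to
    the full stacked rows.
    """
    layers: List[_CompiledLayer] = []
    inst_slices: Dict[str, slice] = {}
    inst_rows: Dict[Tuple[str, str], int] = {}
    sub_to_full: List[int] = []
    offset = 0
    for cl in c.layers:
        if target_gene not in set(cl.genes):
            continue
        keep = _local_receptive(cl, target_gene, k)
        genes_sub = [cl.genes[i] for i in keep]
        s_sub = cl.s_hat[np.ix_(keep, keep)].tocsr()
        in_keep = np.zeros(len(cl.genes), dtype=bool)
        in_keep[keep] = True
        remap = np.full(len(cl.genes), -1, dtype=np.intp)
        remap[keep] = np.arange(len(keep))
        sel = in_keep[cl.gat_dst] & in_keep[cl.gat_src]
        layers.append(_CompiledLayer(cl.layer_id, genes_sub,
                                     cl.universe_idx[keep],
                                     s_sub, remap[cl.gat_dst[sel]],
                                     remap[cl.gat_src[sel]]))
        inst_slices[cl.layer_id] = slice(offset, offset + len(keep))
        for j, g in enumerate(genes_sub):
            inst_rows[(cl.layer_id, g)] = offset + j
        base = c.inst_slices[cl.layer_id].start
        sub_to_full.extend(int(base + i) for i in keep)
        offset += len(keep)

    # the target's star: its instances plus a single meta-node
    edge_ids = [e for e, (_, g) in enumerate(c.meta_edges) if g == target_gene]
    edges_list = [c.meta_edges[e] for e in edge_ids]
    n_all = offset + 1
    edge_inst_row = np.asarray([inst_rows[inst] for inst, _ in edges_list], dtype=np.intp)
    edge_meta_row = np.full(len(edges_list), offset, dtype=np.intp)
    edge_coef = c.edge_coef[edge_ids]
    self_coef = np.concatenate([np.full(offset, 0.5),
                                [c.self_coef[c.n_inst + c.uni_index[target_gene]]]])
    rows = np.concatenate([np.arange(n_all), edge_meta_row, edge_inst_row])
    cols = np.concatenate([np.arange(n_all), edge_inst_row, edge_meta_row])
    vals = np.concatenate([self_coef, edge_coef, edge_coef])
    s_meta = sp.coo_matrix((vals, (rows, cols)), shape=(n_all, n_all)).tocsr()
    gat_dst = np.concatenate([np.arange(n_all), edge_meta_row, edge_inst_row]).astype(np.intp)
    gat_src = np.concatenate([np.arange(n_all), edge_inst_row, edge_meta_row]).astype(np.intp)
    gat_wid = np.concatenate([np.arange(len(edges_list))] * 2).astype(np.intp)

    sub = _Compiled((target_gene,), {target_gene: 0}, layers, offset,
                    inst_slices, inst_rows, edges_list, edge_inst_row,
                    edge_meta_row, np.zeros(len(edges_list), dtype=np.intp),
                    [inst[0] for inst, _ in edges_list], edge_coef, self_coef,
                    s_meta, gat_dst, gat_src, gat_wid)
    sub_to_full.append(c.n_inst + c.uni_index[target_gene])
    return sub, np.asarray(sub_to_full, dtype=np.intp)


def ig_node_features(model: EmgnnModel, dataset: MultilayerDataset,
                     target_gene: str, steps: int = DEFAULT_STEPS,
                     chunk: int = 16) -> AttributionResult:
    """Node-feature attributions for `target_gene` with edges held fixed.

    The differentiated input is the stacked node-feature matrix (one row per
    layer instance plus one per meta-node); the baseline is all-zero, so
    attribution_i = x_i * mean_s dF/dx_i along the interpolation path.
    Attributions outside the target's receptive field are structurally zero,
    so the computation runs on the receptive subgraph only.
    """
    c = compile_dataset(dataset)
    if target_gene not in c.uni_index:
        raise ValueError(f"gene {target_gene!r} not in the universe")
    k = model.config.f1_layers
    sub, sub_to_full = _subcompile(c, target_gene, k)
    x_sub = stacked_inputs(dataset, c)[sub_to_full]
    attr = integrated_gradients(
        lambda z: forward_compiled(model, sub, z).yhat_tensor,
        x_sub, steps=steps, chunk=chunk)

    row_index = [key for key, row in sorted(sub.inst_rows.items(), key=lambda kv: kv[1])]
    return AttributionResult(
        target_gene=target_gene,
        feature_matrix=attr[: sub.n_inst],
        row_index=row_index,
        meta_node_row=attr[sub.n_inst].copy(),
        baseline=0.0,
        steps=steps,
    )


def ig_meta_edges_all(model: EmgnnModel, dataset: MultilayerDataset,
                      steps: int = DEFAULT_STEPS, chunk: int = 16,
                      ) -> Dict[str, Dict[str, Dict[str, float]]]:
    """Meta-edge attributions for every gene in one batched computation.

    The star graphs of different genes are disjoint, so the gradient of the
    summed positive-class outputs with respect to a meta-edge weight equals
    the gradient of that edge's own gene -- one pass explains all genes.
    All meta-edge weights are interpolated jointly from 0 to 1 with node
    features fixed.  Returns {gene: {"normalized": {layer: a}, "raw": ...}}.
    """
    c = compile_dataset(dataset)
    n_edges = len(c.meta_edges)
    raw = integrated_gradients(
        lambda w: forward(model, dataset, meta_edge_weights=w).yhat_tensor,
        np.ones(n_edges), steps=steps, chunk=chunk)

    per_gene: Dict[str, Dict[str, float]] = {}
    for e, (inst, gene) in enumerate(c.meta_edges):
        per_gene.setdefault(gene, {})[inst[0]] = float(raw[e])
    out: Dict[str, Dict[str, Dict[str, float]]] = {}
    for gene, layer_raw in per_gene.items():
        # divide by the (signed) maximum, clip the rest into [0, 1]; a gene
        # with no positive attribution reports all zeros
        m = max(layer_raw.values())
        if m <= 0.0:
            norm = {lid: 0.0 for lid in layer_raw}
        else:
            norm = {lid: min(1.0, max(0.0, v / m)) for lid, v in layer_raw.items()}
        out[gene] = {"normalized": norm, "raw": layer_raw}
    return out


def ig_meta_edges(model: EmgnnModel, dataset: MultilayerDataset,
                  target_gene: str, steps: int = DEFAULT_STEPS,
                  chunk: int = 16) -> AttributionResult:
    """Meta-edge attributions for a single target gene (see ig_meta_edges_all)."""
    c = compile_dataset(dataset)
    if target_gene not in c.uni_index:
        raise ValueError(f"gene {target_gene!r} not in the universe")
    all_attr = ig_meta_edges_all(model, dataset, steps=steps, chunk=chunk)
    entry = all_attr.get(target_gene, {"normalized": {}, "raw": {}})
    return AttributionResult(
        target_gene=target_gene,
        meta_edge_attr=entry["normalized"],
        meta_edge_raw=entry["raw"],
        baseline=0.0,
        steps=steps,
    )


def aggregate_neighbor_importance(result: AttributionResult,
                                  mode: str = "signed",
                                  ) -> List[Tuple[str, float]]:
    """Rank the target's receptive-field genes by their top feature attribution.

    Per gene the importance is the maximum over all of its instance rows and
    features -- of the signed attributions by default, of the absolute values
    with mode="absolute".  Genes with zero importance are dropped; ties break
    lexicographically.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    if result.feature_matrix is None or len(result.row_index) == 0:
        raise ValueError("empty receptive field: compute ig_node_features first")
    per_gene: Dict[str, float] = {}
    for (layer_id, gene), row in zip(result.row_index, result.feature_matrix):
        if gene == result.target_gene:
            continue
        vals = np.abs(row) if mode == "absolute" else row
        best = float(vals.max())
        if gene not in per_gene or best > per_gene[gene]:
            per_gene[gene] = best
    ranked = [(g, v) for g, v in per_gene.items() if v != 0.0]
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    return ranked
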