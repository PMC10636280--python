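"""Multilayer gene-network data model: layer graphs, features, labels,
meta-graph construction and input perturbations."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Edge = FrozenSet[str]


def _edge(a: str, b: str) -> Edge:
    return frozenset((a, b))


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list lines; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass
class LayerGraph:
    """A single undirected gene–gene interaction network.

    Self-loops are never stored; the GCN aggregation adds the self
    contribution internally.  Edges are unordered gene pairs.
    """

    layer_id: str
    nodes: Tuple[str, ...]
    edges: Set[Edge]
    confidence: Optional[Dict[Edge, float]] = None

    def __post_init__(self):
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError(f"layer {self.layer_id}: duplicate nodes")
        for e in self.edges:
            if len(e) != 2:
                raise ValueError(f"layer {self.layer_id}: self-loop or malformed edge {set(e)}")
            if not e <= node_set:
                raise ValueError(f"layer {self.layer_id}: edge endpoint outside node set: {set(e)}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_node(self, gene: str) -> bool:
        return gene in set(self.nodes)

    def neighbors(self, gene: str) -> Set[str]:
        out: Set[str] = set()
        for e in self.edges:
            if gene in e:
                (other,) = e - {gene} or {gene}
                out.add(other)
        return out

    def degree(self, gene: str) -> int:
        return len(self.neighbors(gene))

    def subgraph_without(self, dropped: Set[str]) -> "LayerGraph":
        """Copy with `dropped` genes and their incident edges removed."""
        keep = tuple(n for n in self.nodes if n not in dropped)
        edges = {e for e in self.edges if not (e & dropped)}
        conf = None
        if self.confidence is not None:
            conf = {e: c for e, c in self.confidence.items() if e in edges}
        return LayerGraph(self.layer_id, keep, edges, conf)


@dataclass
class GeneFeatureTable:
    genes: Tuple[str, ...]
    feature_names: Tuple[str, ...]
    values: np.ndarray  # (N, d_I), no NaNs after loading

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.genes), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("feature table contains NaNs after imputation")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def rows(self, genes: Sequence[str]) -> np.ndarray:
        return self.values[[self._index[g] for g in genes]]


@dataclass
class LabelSet:
    positives: Set[str]
    negatives: Set[str]

    def __post_init__(self):
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"genes labeled both positive and negative: {sorted(overlap)[:5]}")

    @property
    def labeled(self) -> Set[str]:
        return self.positives | self.negatives

    def label_of(self, gene: str) -> Optional[int]:
        if gene in self.positives:
            return 1
        if gene in self.negatives:
            return 0
        return None


@dataclass
class MetaGraph:
    """Per-gene star graphs joining each gene's layer instances to one meta-node.

    ``instance_nodes`` are (layer_id, gene) pairs; ``meta_edges`` link an
    instance node to the meta-node of the same gene.
    """

    instance_nodes: List[Tuple[str, str]]
    meta_nodes: Tuple[str, ...]
    meta_edges: List[Tuple[Tuple[str, str], str]]
    layer_of: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        for inst, gene in self.meta_edges:
            if inst[1] != gene:
                raise ValueError(f"meta-edge joins different genes: {inst} -> {gene}")
        if not self.layer_of:
            self.layer_of = {inst: inst[0] for inst in self.instance_nodes}

    def meta_degree(self, gene: str) -> int:
        return sum(1 for _, g in self.meta_edges if g == gene)


@dataclass(frozen=True)
class PerturbationSpec:
    mode: str = "none"  # none | random_features | constant_features | drop_edges
    fraction: float = 0.0
    seed: int = 0

    _MODES = ("none", "random_features", "constant_features", "drop_edges")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass
class MultilayerDataset:
    """K layer graphs over a gene universe, plus features and labels."""

    layers: List[LayerGraph]
    features: GeneFeatureTable
    labels: LabelSet
    universe: Tuple[str, ...]

    @classmethod
    def build(cls, layers: Sequence[LayerGraph], features: GeneFeatureTable,
              labels: LabelSet) -> "MultilayerDataset":
        universe = build_gene_universe(layers, features)
        trimmed = []
        for layer in layers:
            missing = set(layer.nodes) - set(features._index)
            if missing:
                logger.warning(
                    "layer %s: dropping %d genes without feature rows",
                    layer.layer_id, len(missing),
                )
                layer = layer.subgraph_without(missing)
            trimmed.append(layer)
        return cls(list(trimmed), features, labels, universe)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer(self, layer_id: str) -> LayerGraph:
        for lg in self.layers:
            if lg.layer_id == layer_id:
                return lg
        raise KeyError(f"no layer {layer_id!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_layer_graph(path, layer_id: str, min_confidence: Optional[float] = None) -> LayerGraph:
    """Read an undirected edge list (TSV: gene_a, gene_b[, confidence]).

    Duplicate edges are collapsed, self-loops dropped, and edges with a
    confidence below ``min_confidence`` removed.  Nodes left with degree 0
    after confidence filtering are dropped.
    """
    path = Path(path)
    edges: Dict[Edge, Optional[float]] = {}
    endpoints: Set[str] = set()
    has_conf = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise EdgeListParseError(path, lineno, f"expected >=2 columns, got {len(parts)}")
            a, b = parts[0], parts[1]
            conf = None
            if len(parts) >= 3:
                try:
                    conf = float(parts[2])
                except ValueError as exc:
                    raise EdgeListParseError(path, lineno, f"bad confidence {parts[2]!r}") from exc
                has_conf = True
            endpoints.update((a, b))
            if a == b:
                continue  # self-loop
            e = _edge(a, b)
            if e in edges:
                prev = edges[e]
                edges[e] = conf if prev is None else (prev if conf is None else max(prev, conf))
            else:
                edges[e] = conf

    if min_confidence is not None:
        if not has_conf:
            raise ValueError(
                f"{path}: min_confidence={min_confidence} given but file has no confidence column"
            )
        edges = {e: c for e, c in edges.items() if c is not None and c >= min_confidence}

    # keep endpoints seen in the file, then drop genes isolated after filtering
    connected: Set[str] = set()
    for e in edges:
        connected |= e
    dropped = endpoints - connected
    if dropped:
        logger.debug("layer %s: dropping %d isolated nodes after filtering", layer_id, len(dropped))
    nodes = tuple(sorted(connected))
    conf_map = {e: c for e, c in edges.items() if c is not None} if has_conf else None
    return LayerGraph(layer_id, nodes, set(edges), conf_map)


def write_layer_graph(layer: LayerGraph, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# gene_a\tgene_b" + ("\tconfidence" if layer.confidence else "") + "\n")
        for e in sorted(layer.edges, key=lambda e: tuple(sorted(e))):
            a, b = sorted(e)
            if layer.confidence and e in layer.confidence:
                fh.write(f"{a}\t{b}\t{layer.confidence[e]:g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def load_feature_table(path) -> GeneFeatureTable:
    """First column = gene id, header row = feature names; NaNs imputed as 0
    (0 is the attribution baseline, so imputed cells get zero attribution)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    values = df.to_numpy(dtype=np.float64)
    values = np.nan_to_num(values, nan=0.0)
    return GeneFeatureTable(tuple(df.index.astype(str)), tuple(df.columns.astype(str)), values)


def write_feature_table(features: GeneFeatureTable, path) -> None:
    df = pd.DataFrame(features.values, index=list(features.genes),
                      columns=list(features.feature_names))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def load_labels(path) -> LabelSet:
    """TSV with columns gene, label in {0, 1}; absent genes are unlabeled."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label file needs columns gene, label")
    genes = df.iloc[:, 0].astype(str)
    labels = df.iloc[:, 1].astype(int)
    bad = set(labels.unique()) - {0, 1}
    if bad:
        raise ValueError(f"{path}: labels must be 0/1, found {sorted(bad)}")
    pos = set(genes[labels == 1])
    neg = set(genes[labels == 0])
    return LabelSet(pos, neg)


def write_labels(labels: LabelSet, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tlabel\n")
        for g in sorted(labels.positives):
            fh.write(f"{g}\t1\n")
        for g in sorted(labels.negatives):
            fh.write(f"{g}\t0\n")


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_gene_universe(layers: Sequence[LayerGraph], features: GeneFeatureTable) -> Tuple[str, ...]:
    """Union of layer node sets, restricted to genes with feature rows,
    in deterministic lexicographic order."""
    if not layers:
        raise ValueError("at least one layer required")
    union: Set[str] = set()
    for lg in layers:
        union |= set(lg.nodes)
    universe = sorted(union & set(features._index))
    if not universe:
        raise ValueError("no gene appears in both the layers and the feature table")
    return tuple(universe)


def build_meta_graph(layers: Sequence[LayerGraph], universe: Sequence[str]) -> MetaGraph:
    uni = set(universe)
    instance_nodes: List[Tuple[str, str]] = []
    meta_edges: List[Tuple[Tuple[str, str], str]] = []
    for lg in layers:
        outside = set(lg.nodes) - uni
        if outside:
            logger.warning("layer %s: %d genes outside the universe skipped",
                           lg.layer_id, len(outside))
        for gene in lg.nodes:
            if gene not in uni:
                continue
            inst = (lg.layer_id, gene)
            instance_nodes.append(inst)
            meta_edges.append((inst, gene))
    return MetaGraph(instance_nodes, tuple(universe), meta_edges)


# ---------------------------------------------------------------------------
# Perturbations (ablation inputs)
# ---------------------------------------------------------------------------

def apply_perturbation(dataset: MultilayerDataset, spec: PerturbationSpec) -> MultilayerDataset:
    """Return a perturbed copy of the dataset; the original is untouched."""
    if spec.mode == "none":
        return dataset
    if spec.mode in ("random_features", "constant_features"):
        if spec.mode == "random_features":
            rng = np.random.default_rng(spec.seed)
            values = rng.standard_normal(dataset.features.values.shape)
        else:
            values = np.ones_like(dataset.features.values)
        feats = GeneFeatureTable(dataset.features.genes, dataset.features.feature_names, values)
        return MultilayerDataset(list(dataset.layers), feats, dataset.labels, dataset.universe)
    # drop_edges: per-layer derived seeds so layer order does not matter
    layers = []
    for i, lg in enumerate(dataset.layers):
        rng = np.random.default_rng(spec.seed + i)
        ordered = sorted(lg.edges, key=lambda e: tuple(sorted(e)))
        n_drop = int(np.floor(spec.fraction * len(ordered)))
        drop = set(rng.choice(len(ordered), size=n_drop, replace=False)) if n_drop else set()
        kept = {e for k, e in enumerate(ordered) if k not in drop}
        conf = None
        if lg.confidence is not None:
            conf = {e: c for e, c in lg.confidence.items() if e in kept}
        layers.append(LayerGraph(lg.layer_id, lg.nodes, kept, conf))
    return MultilayerDataset(layers, dataset.features, dataset.labels, dataset.universe)
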