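"""Seeded generator of multilayer benchmark datasets with planted,
layer-resolved label signal.

Positives get a mean shift on the informative feature columns and, in the
informative layers, an elevated within-class wiring probability (homophily).
Non-informative layers are plain Erdos-Renyi noise, so attribution methods
can be checked against a known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .graphs import (GeneFeatureTable, LabelSet, LayerGraph, MultilayerDataset,
                     write_feature_table, write_labels, write_layer_graph)

__all__ = ["BenchmarkSpec", "BenchmarkBundle", "generate", "write_benchmark",
           "load_benchmark"]

HOMOPHILY_BOOST = 15.0  # within-positive wiring prob = density * (1 + boost*homophily)


@dataclass(frozen=True)
class BenchmarkSpec:
    n_genes: int = 600
    n_layers: int = 3
    d_features: int = 16
    informative_features: int = 2
    informative_layers: Tuple[int, ...] = (1,)  # 1-based layer indices
    homophily: float = 0.8
    edge_density: float = 0.01
    missing_gene_rate: float = 0.1
    label_prevalence: float = 0.15
    unlabeled_rate: float = 0.2
    noise_sd: float = 1.0
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.informative_features > self.d_features:
            raise ValueError("informative_features must be <= d_features")
        if not set(self.informative_layers) <= set(range(1, self.n_layers + 1)):
            raise ValueError("informative_layers must be within 1..n_layers")
        if not 0.0 <= self.homophily <= 1.0:
            raise ValueError("homophily must be in [0, 1]")
        if not 0.0 <= self.missing_gene_rate < 1.0:
            raise ValueError("missing_gene_rate must be in [0, 1)")
        if not 0.0 < self.label_prevalence < 1.0:
            raise ValueError("label_prevalence must be in (0, 1)")
        if not 0.0 <= self.unlabeled_rate < 1.0:
            raise ValueError("unlabeled_rate must be in [0, 1)")


@dataclass
class BenchmarkBundle:
    dataset: MultilayerDataset
    ground_truth: dict


def _gene_names(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate(spec: BenchmarkSpec) -> BenchmarkBundle:
    """Draw a fully reproducible multilayer dataset from the spec."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)

    # ground-truth class of every gene at exact prevalence (permutation draw);
    # a slice of genes is withheld from the label file as "unlabeled"
    n_pos = int(round(spec.label_prevalence * spec.n_genes))
    if n_pos == 0 or n_pos == spec.n_genes:
        raise ValueError("label_prevalence yields an empty class")
    perm = rng.permutation(spec.n_genes)
    positive = np.zeros(spec.n_genes, dtype=bool)
    positive[perm[:n_pos]] = True
    n_unlab = int(round(spec.unlabeled_rate * spec.n_genes))
    unlabeled = np.zeros(spec.n_genes, dtype=bool)
    unlabeled[rng.permutation(spec.n_genes)[:n_unlab]] = True
    if (positive & ~unlabeled).sum() == 0 or (~positive & ~unlabeled).sum() == 0:
        raise ValueError("unlabeled_rate leaves an empty labeled class")
    labels = LabelSet({g for g, p, u in zip(genes, positive, unlabeled) if p and not u},
                      {g for g, p, u in zip(genes, positive, unlabeled) if not p and not u})

    # features: pure noise, plus an effect-size shift on informative columns
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.d_features))
    values[positive, : spec.informative_features] += spec.effect_size
    feature_names = tuple(
        (f"inf_{j}" if j < spec.informative_features else f"noise_{j}")
        for j in range(spec.d_features)
    )
    features = GeneFeatureTable(tuple(genes), feature_names, values)

    # per-gene layer membership; every gene must appear somewhere
    present = rng.random((spec.n_genes, spec.n_layers)) >= spec.missing_gene_rate
    for i in range(spec.n_genes):
        while not present[i].any():
            present[i] = rng.random(spec.n_layers) >= spec.missing_gene_rate

    p_base = spec.edge_density
    p_homo = min(1.0, p_base * (1.0 + HOMOPHILY_BOOST * spec.homophily))
    layers: List[LayerGraph] = []
    census: List[dict] = []
    for k in range(spec.n_layers):
        layer_id = f"L{k + 1}"
        informative = (k + 1) in spec.informative_layers
        members = np.flatnonzero(present[:, k])
        edges = set()
        pp = pn = nn = 0
        iu, ju = np.triu_indices(len(members), k=1)
        gi, gj = members[iu], members[ju]
        both_pos = positive[gi] & positive[gj]
        probs = np.where(both_pos & informative, p_homo, p_base)
        draw = rng.random(len(probs)) < probs
        for a, b, bp in zip(gi[draw], gj[draw], both_pos[draw]):
            edges.add(frozenset((genes[a], genes[b])))
            if bp:
                pp += 1
            elif positive[a] or positive[b]:
                pn += 1
            else:
                nn += 1
        # edge lists cannot represent isolated nodes: give each one a partner
        touched = {g for e in edges for g in e}
        for m in members:
            if genes[m] not in touched and len(members) > 1:
                other = m
                while other == m:
                    other = int(members[rng.integers(len(members))])
                edges.add(frozenset((genes[m], genes[other])))
                touched.update((genes[m], genes[other]))
                if positive[m] and positive[other]:
                    pp += 1
                elif positive[m] or positive[other]:
                    pn += 1
                else:
                    nn += 1
        layers.append(LayerGraph(layer_id, tuple(genes[m] for m in members), edges))
        census.append({"layer_id": layer_id, "informative": informative,
                       "n_nodes": len(members), "n_edges": len(edges),
                       "pos_pos_edges": pp, "pos_neg_edges": pn, "neg_neg_edges": nn})

    dataset = MultilayerDataset.build(layers, features, labels)
    truth = {
        "spec": {**asdict(spec), "informative_layers": list(spec.informative_layers)},
        "n_positives": int(n_pos),
        "n_unlabeled": int(n_unlab),
        "true_positive_genes": [g for g, p in zip(genes, positive) if p],
        "informative_layer_ids": [f"L{i}" for i in spec.informative_layers],
        "layer_census": census,
    }
    return BenchmarkBundle(dataset, truth)


def write_benchmark(bundle: BenchmarkBundle, directory) -> Dict[str, str]:
    """Emit edge-list TSVs, feature TSV, label TSV and ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, str] = {}
    for lg in bundle.dataset.layers:
        p = directory / f"network_{lg.layer_id}.tsv"
        write_layer_graph(lg, p)
        paths[f"network_{lg.layer_id}"] = str(p)
    write_feature_table(bundle.dataset.features, directory / "features.tsv")
    paths["features"] = str(directory / "features.tsv")
    write_labels(bundle.dataset.labels, directory / "labels.tsv")
    paths["labels"] = str(directory / "labels.tsv")
    with (directory / "ground_truth.json").open("w") as fh:
        json.dump(bundle.ground_truth, fh, indent=2, sort_keys=True)
    paths["ground_truth"] = str(directory / "ground_truth.json")
    return paths


def load_benchmark(directory) -> BenchmarkBundle:
    """Re-load a written benchmark through the standard loaders."""
    from .graphs import load_feature_table, load_labels, load_layer_graph

    directory = Path(directory)
    with (directory / "ground_truth.json").open() as fh:
        truth = json.load(fh)
    layers = []
    for entry in truth["layer_census"]:
        lid = entry["layer_id"]
        layers.append(load_layer_graph(directory / f"network_{lid}.tsv", lid))
    features = load_feature_table(directory / "features.tsv")
    labels = load_labels(directory / "labels.tsv")
    dataset = MultilayerDataset.build(layers, features, labels)
    return BenchmarkBundle(dataset, truth)
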