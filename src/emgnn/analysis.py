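"""Downstream attribution analyses: cancer-neighbor fractions, meta-edge
variance/correlation statistics, one-way ANOVA across networks, and
self-contained preranked gene-set enrichment."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .graphs import LabelSet, LayerGraph

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection", "EnrichmentResult", "read_gmt",
    "cancer_neighbor_fraction", "meta_edge_correlation_analysis",
    "anova_across_layers", "preranked_gsea",
]


@dataclass
class GeneSetCollection:
    sets: Dict[str, Set[str]]
    source: str = ""

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    p_value: float
    fdr: float = float("nan")
    leading_edge: List[str] = field(default_factory=list)
    n_overlap: int = 0


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: one set per tab-separated line (name, description, genes...)."""
    sets: Dict[str, Set[str]] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = {g for g in parts[2:] if g}
            sets[name] = genes
    return GeneSetCollection(sets, source=str(path))


# ---------------------------------------------------------------------------
# Neighborhood statistics
# ---------------------------------------------------------------------------

def cancer_neighbor_fraction(gene: str, layer: LayerGraph, labels: LabelSet) -> float:
    """Fraction of a gene's neighbors that are labeled positive, i.e. the
    positive-neighbor count normalized by the gene's degree in that network."""
    neigh = layer.neighbors(gene)
    if not neigh:
        raise ValueError(f"gene {gene!r} has degree 0 in layer {layer.layer_id!r}")
    return sum(1 for v in neigh if v in labels.positives) / len(neigh)


def meta_edge_correlation_analysis(
    attributions: Mapping[str, Mapping[str, float]],
    fractions: Mapping[str, Mapping[str, float]],
) -> Tuple[Dict[str, Tuple[float, float]], dict]:
    """Per-gene spread of meta-edge importance and its correlation with the
    cancer-neighbor fraction across networks.

    For each gene with >=3 layers present in both inputs, computes the sample
    standard deviation of its meta-edge importances and the Pearson r between
    importances and cancer-neighbor fractions.  Genes are stratified into
    high/low-spread groups at the median std; the summary reports the mean r
    of each group.
    """
    per_gene: Dict[str, Tuple[float, float]] = {}
    skipped: List[str] = []
    for gene, layer_attr in attributions.items():
        if gene not in fractions:
            continue
        common = sorted(set(layer_attr) & set(fractions[gene]))
        if len(common) < 3:
            continue
        a = np.asarray([layer_attr[l] for l in common], dtype=float)
        f = np.asarray([fractions[gene][l] for l in common], dtype=float)
        std = float(np.std(a, ddof=1))
        if np.allclose(a, a[0]) or np.allclose(f, f[0]):
            skipped.append(gene)
            logger.warning("gene %s: constant vector, correlation undefined; skipped", gene)
            continue
        r = float(stats.pearsonr(a, f).statistic)
        per_gene[gene] = (std, r)

    summary: dict = {"n_genes": len(per_gene), "n_skipped": len(skipped)}
    if per_gene:
        stds = np.asarray([v[0] for v in per_gene.values()])
        rs = np.asarray([v[1] for v in per_gene.values()])
        cut = float(np.median(stds))
        high = rs[stds > cut]
        low = rs[stds <= cut]
        summary.update(
            median_std=cut,
            mean_r_high_std=float(high.mean()) if len(high) else float("nan"),
            mean_r_low_std=float(low.mean()) if len(low) else float("nan"),
            mean_r_overall=float(rs.mean()),
        )
    return per_gene, summary


def anova_across_layers(attributions: Mapping[str, Mapping[str, float]],
                        ) -> Tuple[float, float]:
    """One-way fixed-effects ANOVA with networks as groups and per-gene
    meta-edge attributions as observations."""
    groups: Dict[str, List[float]] = {}
    for layer_attr in attributions.values():
        for layer_id, val in layer_attr.items():
            groups.setdefault(layer_id, []).append(float(val))
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two networks")
    arrays = [np.asarray(v) for _, v in sorted(groups.items())]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every network needs at least two observations")
    grand = np.concatenate(arrays)
    ss_between = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays)
    if ss_between == 0.0:
        return 0.0, 1.0  # identical group means (possibly zero variance)
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def _running_es(in_set: np.ndarray, weights: np.ndarray, power: float) -> Tuple[float, int]:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    Hits advance proportionally to |importance|^power, misses retreat by
    1/(N - N_h).  Returns the signed extreme deviation and its position.
    """
    n = len(in_set)
    n_hit = int(in_set.sum())
    w = np.abs(weights) ** power
    hit_total = w[in_set].sum()
    if hit_total == 0:
        hit_steps = np.where(in_set, 1.0 / max(n_hit, 1), 0.0)
    else:
        hit_steps = np.where(in_set, w / hit_total, 0.0)
    miss_steps = np.where(~in_set, 1.0 / (n - n_hit), 0.0)
    running = np.cumsum(hit_steps - miss_steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def preranked_gsea(ranked: Sequence[Tuple[str, float]], sets: GeneSetCollection,
                   n_perm: int = 1000, seed: int = 0, power: float = 1.0,
                   min_size: int = 5, max_size: int = 500,
                   ) -> List[EnrichmentResult]:
    """Classic preranked GSEA on a (gene, importance) list sorted by importance.

    Significance comes from permuting which ranked genes carry the set label
    (seeded); FDR is Benjamini-Hochberg across the evaluated sets.
    """
    genes = [g for g, _ in ranked]
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate genes")
    weights = np.asarray([v for _, v in ranked], dtype=float)
    order = np.argsort(-weights, kind="stable")
    genes = [genes[i] for i in order]
    weights = weights[order]
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    results: List[EnrichmentResult] = []
    for name in sorted(sets.sets):
        members = sets.sets[name]
        overlap = [g for g in genes if g in members]
        if len(overlap) < min_size or len(overlap) > max_size or len(overlap) == n:
            logger.warning("set %s skipped (overlap %d outside [%d, %d] or degenerate)",
                           name, len(overlap), min_size, max_size)
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[[gene_pos[g] for g in overlap]] = True
        es, peak = _running_es(in_set, weights, power)
        n_hit = len(overlap)
        extreme = 0
        for _ in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=n_hit, replace=False)] = True
            es_p, _ = _running_es(perm, weights, power)
            if es >= 0 and es_p >= es:
                extreme += 1
            elif es < 0 and es_p <= es:
                extreme += 1
        p = (1 + extreme) / (1 + n_perm)
        if es >= 0:
            leading = [g for i, g in enumerate(genes[: peak + 1]) if in_set[i]]
        else:
            leading = [g for i, g in enumerate(genes) if i >= peak and in_set[i]]
        results.append(EnrichmentResult(name, es, p, leading_edge=leading,
                                        n_overlap=n_hit))

    if results:
        fdrs = stats.false_discovery_control([r.p_value for r in results], method="bh")
        for r, q in zip(results, fdrs):
            r.fdr = float(q)
    return results
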