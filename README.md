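# emgnn

Explainable multilayer graph neural network for gene classification.

The model learns gene-level labels (e.g. cancer vs non-cancer) jointly from
several gene–gene interaction networks: a shared GNN (`f1`, GCN or GAT) runs
on every input network, each gene's per-network states are joined to a
per-gene *meta-node* through *meta-edges*, a second GNN (`f2`) updates the
meta-node on that star graph, and an MLP (`f3`) classifies the meta-node
state. Because `f1` is shared across networks and `f2` across genes, the
trainable parameter count is independent of the number of input networks.

Explanations come from integrated gradients, split into two parts:

- **node-feature attributions** (graph fixed): which multi-omics features of
  which neighboring genes drive a prediction;
- **meta-edge attributions** (features fixed): which input network drives a
  prediction, normalized per gene to [0, 1].

Downstream analyses include cancer-neighbor fractions, meta-edge
variance/correlation statistics, a one-way ANOVA of attribution differences
across networks, and self-contained preranked GSEA over neighbor-importance
rankings. A seeded synthetic benchmark with planted, layer-resolved label
signal makes the whole pipeline testable offline.

Everything is implemented in numpy/scipy on top of a small reverse-mode
autodiff core (`emgnn.autodiff`) — no deep-learning framework required.

## CLI walkthrough

```bash
# 1. generate a synthetic multilayer benchmark
emgnn simulate --out bench/ --seed 7

# 2. sanity-check the inputs
emgnn data validate \
  --networks bench/network_L1.tsv --networks bench/network_L2.tsv \
  --networks bench/network_L3.tsv \
  --features bench/features.tsv --labels bench/labels.tsv

# 3. train (config carries data paths + model/training fields)
cat > cfg.yaml <<EOF
networks: [bench/network_L1.tsv, bench/network_L2.tsv, bench/network_L3.tsv]
features: bench/features.tsv
labels: bench/labels.tsv
conv_type: gcn
epochs: 300
seed: 7
EOF
emgnn train --config cfg.yaml --test-layer L2 --out run/

# 4. predict, rank unlabeled genes, explain, analyze
emgnn predict --model run/checkpoint.npz --out preds.tsv
emgnn rank --model run/checkpoint.npz --precision 0.95 --out novel.tsv
emgnn explain --model run/checkpoint.npz --gene G0001 --out explain/
emgnn analyze --rundir run/ --gmt sets.gmt --out analysis/
```

Input formats: edge lists are TSV (`gene_a  gene_b  [confidence]`, `#`
comments allowed); the feature table is TSV/CSV with a gene column and a
header of feature names; labels are TSV `gene  label` with label in {0, 1}
(absent genes are unlabeled); gene sets use standard GMT.

## Library entry points

```python
from emgnn import (
    BenchmarkSpec, generate,            # synthetic benchmark
    MultilayerDataset, load_layer_graph,  # data model / IO
    ModelConfig, EmgnnModel, forward,   # model
    make_splits, train, auprc,          # training & evaluation
    ig_node_features, ig_meta_edges,    # integrated-gradients explanations
    preranked_gsea, anova_across_layers,  # downstream analyses
)
```
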