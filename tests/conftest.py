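import numpy as np
import pytest

from emgnn import (
    BenchmarkSpec, EmgnnModel, GeneFeatureTable, LabelSet, LayerGraph,
    ModelConfig, MultilayerDataset, generate, make_splits, train,
)


def make_layer(layer_id, edges, extra_nodes=()):
    """LayerGraph from an iterable of (a, b) gene pairs."""
    nodes = set(extra_nodes)
    es = set()
    for a, b in edges:
        nodes.update((a, b))
        es.add(frozenset((a, b)))
    return LayerGraph(layer_id, tuple(sorted(nodes)), es)


def make_features(genes, d=4, seed=0):
    rng = np.random.default_rng(seed)
    return GeneFeatureTable(tuple(genes), tuple(f"f{i}" for i in range(d)),
                            rng.standard_normal((len(genes), d)))


@pytest.fixture
def tiny_dataset():
    """Three genes in two small layers with features and labels."""
    l1 = make_layer("L1", [("A", "B"), ("B", "C")])
    l2 = make_layer("L2", [("A", "C")])
    feats = make_features(["A", "B", "C", "D"])
    labels = LabelSet({"A"}, {"C"})
    return MultilayerDataset.build([l1, l2], feats, labels)


SMALL_SPEC = BenchmarkSpec(n_genes=120, n_layers=3, d_features=8,
                           informative_features=3, label_prevalence=0.2,
                           edge_density=0.04, seed=11)


@pytest.fixture(scope="session")
def small_bundle():
    return generate(SMALL_SPEC)


ACCEPT_EPOCHS = 250  # default-benchmark training length for acceptance checks
ACCEPT_SEEDS = range(5)


@pytest.fixture(scope="session")
def default_trained():
    """Models trained on the default planted benchmark, one per seed.

    Shared by the acceptance criteria and the ablation-direction property
    tests so the (comparatively slow) default-scale trainings run once.
    """
    out = []
    for seed in ACCEPT_SEEDS:
        ds = generate(BenchmarkSpec(seed=seed)).dataset
        split = make_splits(ds.labels, ds.layers, "L2", seed=seed)
        model = EmgnnModel(ModelConfig(seed=seed),
                           len(ds.features.feature_names))
        model, report = train(model, ds, split, epochs=ACCEPT_EPOCHS, eval_every=10)
        out.append((ds, split, model, report))
    return out


@pytest.fixture(scope="session")
def trained_small():
    """A small trained model: enough epochs to carry real signal."""
    bundle = generate(SMALL_SPEC)
    ds = bundle.dataset
    cfg = ModelConfig(f1_hidden=16, f2_hidden=16, seed=5, dropout=0.1)
    model = EmgnnModel(cfg, len(ds.features.feature_names))
    split = make_splits(ds.labels, ds.layers, "L1", seed=5)
    model, report = train(model, ds, split, epochs=120, eval_every=20)
    return model, ds, split, report
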