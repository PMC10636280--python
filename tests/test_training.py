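"""Split protocol, metrics, baselines and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score

from emgnn import (
    EmgnnModel, LabelSet, ModelConfig, auprc, majority_vote, make_splits,
    precision_threshold_cutoff, train,
)

from conftest import make_layer


def layer_with_labels(layer_id, n_pos, n_neg, prefix=""):
    genes = [f"{prefix}p{i}" for i in range(n_pos)] + \
            [f"{prefix}n{i}" for i in range(n_neg)]
    edges = [(genes[i], genes[i + 1]) for i in range(len(genes) - 1)]
    return make_layer(layer_id, edges), set(genes[:n_pos]), set(genes[n_pos:])


class TestMakeSplits:
    def test_stratified_counts_75_25(self):
        lg, pos, neg = layer_with_labels("T", 80, 320)
        labels = LabelSet(pos, neg)
        split = make_splits(labels, [lg], "T", seed=0)
        assert len(split.test_genes & pos) == 20
        assert len(split.test_genes & neg) == 80

    def test_second_layer_with_only_test_genes_adds_nothing(self):
        lg, pos, neg = layer_with_labels("T", 20, 20)
        labels = LabelSet(pos, neg)
        base = make_splits(labels, [lg], "T", seed=1)
        test_genes = sorted(base.test_genes)
        extra = make_layer("E", [(test_genes[i], test_genes[i + 1])
                                 for i in range(len(test_genes) - 1)])
        both = make_splits(labels, [lg, extra], "T", seed=1)
        assert both.test_genes == base.test_genes
        assert both.train_genes == base.train_genes
        assert both.val_genes == base.val_genes

    def test_disjoint_and_counts_oracle(self):
        rng = np.random.default_rng(7)
        layers, pos, neg = [], set(), set()
        lg, p, n = layer_with_labels("T", 100, 150)
        layers.append(lg); pos |= p; neg |= n
        for k in range(2):
            lg2, p2, n2 = layer_with_labels(f"X{k}", 50, 75, prefix=f"x{k}")
            layers.append(lg2); pos |= p2; neg |= n2
        labels = LabelSet(pos, neg)
        split = make_splits(labels, layers, "T", seed=7)
        # set-algebra oracle
        assert not (split.test_genes & (split.train_genes | split.val_genes))
        assert not (split.train_genes & split.val_genes)
        all_labeled = pos | neg
        assert split.test_genes | split.train_genes | split.val_genes == all_labeled
        # test stratification: 25% of each class of the test layer
        assert len(split.test_genes & pos) == round(0.25 * 100)
        assert len(split.test_genes & neg) == round(0.25 * 150)
        # val is 10% of the remaining labeled genes, per class
        rem_pos = len((all_labeled - split.test_genes) & pos)
        rem_neg = len((all_labeled - split.test_genes) & neg)
        assert len(split.val_genes & pos) == round(0.1 * rem_pos)
        assert len(split.val_genes & neg) == round(0.1 * rem_neg)

    def test_test_set_stable_as_layers_added(self):
        lg, pos, neg = layer_with_labels("T", 40, 60)
        labels_all = pos | neg
        extra_layers = []
        reference = None
        for k in range(3):
            lg2, p2, n2 = layer_with_labels(f"X{k}", 10, 15, prefix=f"x{k}")
            extra_layers.append(lg2)
            pos |= p2
            neg |= n2
            labels = LabelSet(pos, neg)
            split = make_splits(labels, [lg] + extra_layers, "T", seed=3)
            if reference is None:
                reference = split.test_genes
            assert split.test_genes == reference

    def test_small_class_errors(self):
        lg, pos, neg = layer_with_labels("T", 3, 50)
        with pytest.raises(ValueError, match="stratified"):
            make_splits(LabelSet(pos, neg), [lg], "T", seed=0)

    def test_unknown_test_layer(self):
        lg, pos, neg = layer_with_labels("T", 10, 10)
        with pytest.raises(ValueError):
            make_splits(LabelSet(pos, neg), [lg], "Z", seed=0)


def brute_force_average_precision(scores, labels):
    """Oracle: walk tie-groups of the sorted list, accumulate precision mass."""
    import collections
    groups = collections.defaultdict(lambda: [0, 0])
    for s, y in zip(scores, labels):
        groups[s][y] += 1
    tp = fp = 0
    total = 0.0
    for s in sorted(groups, reverse=True):
        neg, p = groups[s]
        tp += p
        fp += neg
        total += p * tp / (tp + fp)
    return total / sum(labels)


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_uniform_scores_give_prevalence(self):
        labels = [1, 0, 0, 0, 1]
        assert auprc([0.5] * 5, labels) == pytest.approx(2 / 5)

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(11)
        scores = np.round(rng.random(100), 2)  # rounding forces ties
        labels = (rng.random(100) < 0.3).astype(int)
        got = auprc(scores, labels)
        assert got == pytest.approx(brute_force_average_precision(scores, labels))
        assert got == pytest.approx(average_precision_score(labels, scores))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auprc([0.1, 0.2], [1, 1])

    @given(st.lists(st.tuples(st.integers(0, 100),
                              st.integers(0, 1)), min_size=4, max_size=60))
    @settings(max_examples=40, deadline=None)
    def test_monotone_transform_invariance(self, pairs):
        scores = np.array([p[0] for p in pairs]) / 100.0
        labels = np.array([p[1] for p in pairs])
        if labels.sum() in (0, len(labels)):
            return
        before = auprc(scores, labels)
        after = auprc(np.exp(3 * scores), labels)  # strictly monotone
        assert after == pytest.approx(before, abs=1e-12)


class TestMajorityVote:
    def test_basic(self):
        assert majority_vote([[1], [1], [0]])[0] == 1

    def test_tie_resolves_positive(self):
        assert majority_vote([[1], [0]])[0] == 1

    def test_idempotent_on_identical_predictors(self):
        v = np.array([1, 0, 1, 1, 0])
        np.testing.assert_array_equal(majority_vote([v, v, v]), v)

    def test_counting_oracle(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 2, size=(6, 50))
        got = majority_vote(mat)
        for j in range(50):
            ones = int(mat[:, j].sum())
            expected = 1 if ones >= 3 else 0  # 6 voters, ties positive
            assert got[j] == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            majority_vote([[1, 0], [1]])


class TestPrecisionThreshold:
    def test_perfectly_separated(self):
        t, sel = precision_threshold_cutoff([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0],
                                            0.95, {"u1": 0.85, "u2": 0.15})
        assert t == 0.8
        assert sel == [("u1", 0.85)]

    def test_degenerate_uniform_scores(self):
        labels = [1, 0, 0, 1]
        t, _ = precision_threshold_cutoff([0.4] * 4, labels, 0.5)
        assert t == 0.4

    def test_matches_exhaustive_sweep_oracle(self):
        rng = np.random.default_rng(13)
        scores = np.round(rng.random(200), 2)
        labels = (scores + rng.normal(0, 0.3, 200) > 0.6).astype(int)
        if labels.sum() in (0, 200):
            pytest.skip("degenerate draw")
        target = 0.8
        # oracle: sweep every candidate threshold
        feasible = [t for t in np.unique(scores)
                    if labels[scores >= t].sum() / (scores >= t).sum() >= target]
        if not feasible:
            with pytest.raises(ValueError):
                precision_threshold_cutoff(scores, labels, target)
        else:
            t, _ = precision_threshold_cutoff(scores, labels, target)
            assert t == min(feasible)

    def test_unattainable_names_max(self):
        with pytest.raises(ValueError, match="0.5"):
            precision_threshold_cutoff([0.5, 0.5], [1, 0], 0.99)

    def test_bad_target(self):
        with pytest.raises(ValueError):
            precision_threshold_cutoff([0.5], [1], 0.0)


class TestTrain:
    def test_lr_zero_keeps_loss_constant(self, small_bundle):
        ds = small_bundle.dataset
        from emgnn import make_splits
        split = make_splits(ds.labels, ds.layers, "L1", seed=0)
        model = EmgnnModel(ModelConfig(f1_hidden=8, f2_hidden=8, seed=0, dropout=0.0),
                           len(ds.features.feature_names))
        _, report = train(model, ds, split, epochs=5, lr=0.0, weight_decay=0.0)
        assert np.ptp(report.train_loss) < 1e-12

    def test_loss_decreases_on_separable_data(self, trained_small):
        _, _, _, report = trained_small
        assert report.train_loss[-1] < report.train_loss[0]

    def test_best_epoch_within_range(self, trained_small):
        _, _, _, report = trained_small
        assert 0 < report.best_epoch <= report.epochs

    def test_test_auprc_beats_prevalence(self, trained_small):
        _, ds, split, report = trained_small
        labeled_test = split.test_genes & ds.labels.labeled
        prevalence = len(split.test_genes & ds.labels.positives) / len(labeled_test)
        assert report.test_auprc > prevalence

    def test_deterministic_given_seed(self, small_bundle):
        ds = small_bundle.dataset
        from emgnn import make_splits
        split = make_splits(ds.labels, ds.layers, "L1", seed=4)
        outs = []
        for _ in range(2):
            model = EmgnnModel(ModelConfig(f1_hidden=8, f2_hidden=8, seed=9),
                               len(ds.features.feature_names))
            model, report = train(model, ds, split, epochs=30, eval_every=10)
            outs.append(report.train_loss)
        np.testing.assert_array_equal(outs[0], outs[1])
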