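"""Split protocol, training loop, AUPRC evaluation, majority-vote baseline
and precision-thresholded ranking of unlabeled genes.

Split protocol: the labeled genes of one designated test network are split
75/25 with stratified sampling; the 25% become the held-out test set and
stay bit-identical no matter which or how many other networks are supplied.
All remaining labeled genes (from any network, minus the test genes) are
split 90/10 into train/validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Adam, log_softmax
from .graphs import LabelSet, LayerGraph, MultilayerDataset
from .model import EmgnnModel, compile_dataset, forward

__all__ = ["SplitSpec", "TrainReport", "make_splits", "train", "auprc",
           "majority_vote", "precision_threshold_cutoff"]


@dataclass(frozen=True)
class SplitSpec:
    test_layer: str
    train_genes: frozenset
    val_genes: frozenset
    test_genes: frozenset
    seed: int

    def __post_init__(self):
        if self.test_genes & (self.train_genes | self.val_genes):
            raise ValueError("test genes leak into train/val")
        if self.train_genes & self.val_genes:
            raise ValueError("train and val genes overlap")


@dataclass
class TrainReport:
    train_loss: List[float] = field(default_factory=list)
    val_epochs: List[int] = field(default_factory=list)
    val_auprc: List[float] = field(default_factory=list)
    best_epoch: int = 0
    test_auprc: Optional[float] = None
    epochs: int = 0
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "val_epochs": self.val_epochs,
            "val_auprc": self.val_auprc,
            "best_epoch": self.best_epoch,
            "test_auprc": self.test_auprc,
            "epochs": self.epochs,
            "config": self.config,
            "seed": self.seed,
        }


def _stratified_take(genes_by_class: Dict[int, List[str]], fraction: float,
                     rng) -> Tuple[set, set]:
    """Per-class seeded shuffle; `fraction` of each class goes to the first set."""
    first, rest = set(), set()
    for cls in sorted(genes_by_class):
        genes = sorted(genes_by_class[cls])
        perm = rng.permutation(len(genes))
        k = int(round(fraction * len(genes)))
        chosen = {genes[i] for i in perm[:k]}
        first |= chosen
        rest |= set(genes) - chosen
    return first, rest


def make_splits(labels: LabelSet, layers: Sequence[LayerGraph], test_layer: str,
                seed: int, test_fraction: float = 0.25,
                val_fraction: float = 0.10) -> SplitSpec:
    """Build the train/val/test split around a designated test network."""
    layer_ids = [lg.layer_id for lg in layers]
    if test_layer not in layer_ids:
        raise ValueError(f"test layer {test_layer!r} not among {layer_ids}")
    test_lg = next(lg for lg in layers if lg.layer_id == test_layer)

    test_nodes = set(test_lg.nodes)
    by_class = {
        1: sorted(labels.positives & test_nodes),
        0: sorted(labels.negatives & test_nodes),
    }
    if not (by_class[0] or by_class[1]):
        raise ValueError(f"no labeled genes in test layer {test_layer!r}")
    for cls, genes in by_class.items():
        if len(genes) < 4:
            raise ValueError(
                f"class {cls} has only {len(genes)} labeled genes in layer "
                f"{test_layer!r}; stratified 75/25 split impossible"
            )
    # the test split depends only on (test_layer, seed), never on other layers
    rng_test = np.random.default_rng(seed)
    test_genes, _ = _stratified_take({c: list(g) for c, g in by_class.items()},
                                     test_fraction, rng_test)

    all_labeled: set = set()
    for lg in layers:
        all_labeled |= labels.labeled & set(lg.nodes)
    remaining = all_labeled - test_genes
    rem_by_class = {
        1: sorted(remaining & labels.positives),
        0: sorted(remaining & labels.negatives),
    }
    rng_tv = np.random.default_rng((seed, 0x7A1))
    val_genes, train_genes = _stratified_take(rem_by_class, val_fraction, rng_tv)

    return SplitSpec(test_layer, frozenset(train_genes), frozenset(val_genes),
                     frozenset(test_genes), seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve as average precision.

    Step-wise (no interpolation); tied scores are treated as one group, so
    uniform scores give exactly the label prevalence.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUPRC needs at least one positive and one negative label")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    ap = 0.0
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp_block = int(y[i:j].sum())
        fp_block = (j - i) - tp_block
        tp += tp_block
        fp += fp_block
        if tp_block:
            ap += tp_block * tp / (tp + fp)
        i = j
    return ap / n_pos


def majority_vote(per_layer_predictions: Sequence[Sequence[int]]) -> np.ndarray:
    """Per-gene majority over binary predictors; even splits resolve to 1."""
    if len(per_layer_predictions) == 0:
        raise ValueError("need at least one predictor")
    mat = np.asarray(per_layer_predictions, dtype=int)
    if mat.ndim != 2:
        raise ValueError("predictions must be equal-length vectors")
    k = mat.shape[0]
    return (2 * mat.sum(axis=0) >= k).astype(int)


def precision_threshold_cutoff(scores: Sequence[float], labels: Sequence[int],
                               target_precision: float,
                               unlabeled_scores: Optional[Mapping[str, float]] = None,
                               ) -> Tuple[float, List[Tuple[str, float]]]:
    """Smallest score threshold whose labeled-set precision reaches the target.

    Returns the threshold and the unlabeled genes scoring at or above it,
    ranked by score descending (ties by gene id).
    """
    if not 0.0 < target_precision <= 1.0:
        raise ValueError("target_precision must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    best_threshold = None
    best_precision = 0.0
    tp = tot = 0
    i, n = 0, len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        tot += j - i
        prec = tp / tot
        best_precision = max(best_precision, prec)
        if prec >= target_precision:
            best_threshold = s[i]  # smallest threshold so far achieving the target
        i = j
    if best_threshold is None:
        raise ValueError(
            f"target precision {target_precision} unattainable; "
            f"maximum achievable is {best_precision:.4f}"
        )
    selected: List[Tuple[str, float]] = []
    if unlabeled_scores:
        selected = sorted(
            ((g, v) for g, v in unlabeled_scores.items() if v >= best_threshold),
            key=lambda kv: (-kv[1], kv[0]),
        )
    return float(best_threshold), selected


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _gene_rows(dataset: MultilayerDataset, genes) -> np.ndarray:
    index = {g: i for i, g in enumerate(dataset.universe)}
    return np.asarray(sorted(index[g] for g in genes if g in index), dtype=np.intp)


def train(model: EmgnnModel, dataset: MultilayerDataset, split: SplitSpec,
          epochs: int = 2000, lr: float = 1e-3, weight_decay: float = 5e-4,
          eval_every: int = 10, verbose: bool = False,
          ) -> Tuple[EmgnnModel, TrainReport]:
    """Full-batch Adam on the cross-entropy of train meta-node outputs.

    Validation AUPRC is computed every `eval_every` epochs; the returned
    model carries the best-validation checkpoint.  Fully deterministic given
    the model config seed.
    """
    compile_dataset(dataset)
    labels = dataset.labels
    y_all = np.zeros(len(dataset.universe), dtype=int)
    uni_index = {g: i for i, g in enumerate(dataset.universe)}
    for g in labels.positives:
        if g in uni_index:
            y_all[uni_index[g]] = 1

    train_rows = _gene_rows(dataset, split.train_genes & labels.labeled)
    val_rows = _gene_rows(dataset, split.val_genes & labels.labeled)
    test_rows = _gene_rows(dataset, split.test_genes & labels.labeled)
    if len(train_rows) == 0:
        raise ValueError("empty training set")

    y_train = y_all[train_rows]
    opt = Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
    dropout_rng = np.random.default_rng(model.config.seed + 1)
    report = TrainReport(epochs=epochs, config=model.config.__dict__.copy(),
                         seed=model.config.seed)
    best_val = -np.inf
    best_state = model.state_arrays()
    best_epoch = 0

    col = np.arange(len(train_rows))
    for epoch in range(1, epochs + 1):
        state = forward(model, dataset, training=True, dropout_rng=dropout_rng)
        logp = log_softmax(state.logits_tensor, axis=-1)
        picked = logp.take_rows(train_rows)
        # select the true-class log-probability per training gene
        sel = picked.take_last(np.asarray([0]))
        sel = sel.reshape(*sel.shape[:-1])
        sel_pos = picked.take_last(np.asarray([1]))
        sel_pos = sel_pos.reshape(*sel_pos.shape[:-1])
        chosen = sel * (1.0 - y_train) + sel_pos * y_train
        loss = -chosen.mean()
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"non-finite training loss at epoch {epoch} "
                f"(loss={loss_val}); consider lowering the learning rate"
            )
        report.train_loss.append(loss_val)
        opt.zero_grad()
        loss.backward()
        opt.step()

        if epoch % eval_every == 0 or epoch == epochs:
            eval_state = forward(model, dataset)
            report.val_epochs.append(epoch)
            if len(val_rows) and len(set(y_all[val_rows])) == 2:
                v = auprc(eval_state.yhat[val_rows], y_all[val_rows])
            else:
                v = float("nan")
            report.val_auprc.append(v)
            if np.isnan(v) or v >= best_val:
                best_val = -np.inf if np.isnan(v) else v
                best_state = model.state_arrays()
                best_epoch = epoch
            if verbose:  # pragma: no cover
                print(f"epoch {epoch}: loss={loss_val:.4f} val_auprc={v:.4f}")

    report.best_epoch = best_epoch
    model.load_state_arrays(best_state)
    if len(test_rows) and len(set(y_all[test_rows])) == 2:
        final = forward(model, dataset)
        report.test_auprc = auprc(final.yhat[test_rows], y_all[test_rows])
    return model, report


def predict(model: EmgnnModel, dataset: MultilayerDataset) -> Dict[str, float]:
    """Predicted positive-class probability for every universe gene."""
    state = forward(model, dataset)
    return {g: float(p) for g, p in zip(dataset.universe, state.yhat)}
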