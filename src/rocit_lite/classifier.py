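"""Training, chromosome-held-out splitting and evaluation of the read classifier.

One model is trained per biopsy on its labeled reads.  Chromosomes 4 and 21
are held out for validation (early stopping), 5 and 22 for the final test
evaluation; everything else trains.  Training uses weighted binary
cross-entropy with the non-tumor/tumor count ratio as positive weight,
AdamW with a linear warmup, Gaussian input noise, per-epoch re-subsampling
of over-long reads, and early stopping on validation AUC with best-epoch
weight restoration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .features import FeatureSet, cap_cpgs, cap_cpgs_stable
from .nn import AdamW, Batch, ModelConfig, TransformerClassifier, pad_batch, sigmoid, weighted_bce_with_logits

logger = logging.getLogger(__name__)

VALIDATION_CHROMOSOMES = frozenset({"chr4", "chr21", "4", "21"})
TEST_CHROMOSOMES = frozenset({"chr5", "chr22", "5", "22"})


@dataclass
class Split:
    validation: frozenset = VALIDATION_CHROMOSOMES
    test: frozenset = TEST_CHROMOSOMES

    def part(self, chromosome: str) -> str:
        if chromosome in self.validation:
            return "validation"
        if chromosome in self.test:
            return "test"
        return "train"

    def divide(self, feature_sets: Sequence[FeatureSet]):
        parts = {"train": [], "validation": [], "test": []}
        for fs in feature_sets:
            parts[self.part(fs.chromosome)].append(fs)
        return parts


@dataclass
class TrainConfig:
    lr: float = 1e-4
    warmup_steps: int = 100
    noise_sd: float = 0.01
    early_stop_patience: int = 5
    max_epochs: int = 100
    batch_size: int = 256
    weight_decay: float = 0.01
    seed: int = 0

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Optimization sized for desk-scale labeled sets (hundreds of reads,
        a handful of batches per epoch): larger steps, shorter warmup."""
        kw = dict(lr=3e-3, warmup_steps=20, batch_size=32, max_epochs=10)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TrainHistory:
    val_auc: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = float("nan")


def positive_weight(n_nontumor: int, n_tumor: int) -> float:
    """Class weight for the tumor (positive) class: #non-tumor / #tumor."""
    if n_tumor <= 0:
        raise ValueError("no tumor-labeled reads; cannot weight the positive class")
    return n_nontumor / n_tumor


def evaluate_auc(labels, probabilities) -> float:
    """Rank-based ROC AUC with midrank tie handling."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(probabilities)))


def _length_bucketed_batches(feature_sets, batch_size, rng=None):
    order = np.argsort([fs.n_cpg for fs in feature_sets], kind="stable")
    chunks = [order[i: i + batch_size] for i in range(0, len(order), batch_size)]
    if rng is not None:
        rng.shuffle(chunks)
    return chunks


def _noisy(batch: Batch, rng, sd: float) -> Batch:
    if sd <= 0:
        return batch
    return Batch(
        meth=batch.meth + rng.normal(0, sd, batch.meth.shape).astype(batch.meth.dtype),
        pos_norm=batch.pos_norm,
        percentiles=batch.percentiles + rng.normal(0, sd, batch.percentiles.shape).astype(batch.percentiles.dtype),
        atlas=batch.atlas + rng.normal(0, sd, batch.atlas.shape).astype(batch.atlas.dtype),
        atlas_missing=batch.atlas_missing,
        valid=batch.valid,
        labels=batch.labels,
        read_ids=batch.read_ids,
    )


def predict(model: TransformerClassifier, feature_sets: Sequence[FeatureSet],
            batch_size: int = 256, seed: int = 0) -> np.ndarray:
    """Per-read tumor probability; reads above max_cpgs get one per-read
    seeded subsample, so outputs are invariant to batch order."""
    if not feature_sets:
        return np.empty(0)
    capped = [cap_cpgs_stable(fs, seed, model.config.max_cpgs) for fs in feature_sets]
    out = np.empty(len(capped))
    for idx in _length_bucketed_batches(capped, batch_size):
        batch = pad_batch([capped[i] for i in idx])
        logits, _ = model.forward(batch, train=False)
        out[idx] = sigmoid(logits)
    return out


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard call: tumor iff p >= 0.5 (boundary inclusive)."""
    return np.asarray(probabilities) >= threshold


def train(
    model: TransformerClassifier,
    train_sets: Sequence[FeatureSet],
    val_sets: Sequence[FeatureSet],
    cfg: TrainConfig,
) -> TrainHistory:
    """Train in place; returns the history with best-epoch restoration applied."""
    if not train_sets or not val_sets:
        raise ValueError("train and validation sets must be non-empty")
    y_train = np.array([fs.label for fs in train_sets], dtype=float)
    y_val = np.array([fs.label for fs in val_sets], dtype=float)
    if len(np.unique(y_train)) < 2 or len(np.unique(y_val)) < 2:
        raise ValueError("both classes required in train and validation sets")
    pw = positive_weight(int((y_train == 0).sum()), int((y_train == 1).sum()))
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_state = model.state_dict()
    step = 0
    for epoch in range(cfg.max_epochs):
        capped = [cap_cpgs(fs, rng, model.config.max_cpgs) for fs in train_sets]
        losses = []
        for idx in _length_bucketed_batches(capped, cfg.batch_size, rng):
            batch = _noisy(pad_batch([capped[i] for i in idx]), rng, cfg.noise_sd)
            logits, cache = model.forward(batch, train=True, rng=rng)
            loss, dlogits = weighted_bce_with_logits(logits, y_train[idx], pos_weight=pw)
            grads, _ = model.backward(cache, dlogits)
            step += 1
            lr_scale = min(1.0, step / max(1, cfg.warmup_steps))
            opt.step(grads, lr_scale=lr_scale)
            losses.append(loss)
        val_prob = predict(model, val_sets, batch_size=cfg.batch_size, seed=cfg.seed)
        auc = evaluate_auc(y_val, val_prob)
        history.train_loss.append(float(np.mean(losses)))
        history.val_auc.append(auc)
        if history.best_epoch < 0 or auc > history.best_val_auc:
            history.best_epoch = epoch
            history.best_val_auc = auc
            best_state = model.state_dict()
        elif epoch - history.best_epoch >= cfg.early_stop_patience:
            break
    model.load_state_dict(best_state)
    logger.info(
        "training stopped after %d epochs; best val AUC %.4f at epoch %d",
        len(history.val_auc), history.best_val_auc, history.best_epoch,
    )
    return history


def train_on_split(
    feature_sets: Sequence[FeatureSet],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    split: Optional[Split] = None,
):
    """Split by chromosome, train, and evaluate on the held-out test part.

    Returns (model, history, parts) where parts maps split name to its
    feature sets.
    """
    split = split or Split()
    parts = split.divide([fs for fs in feature_sets if fs.label is not None])
    model = TransformerClassifier(model_cfg, seed=train_cfg.seed)
    history = train(model, parts["train"], parts["validation"], train_cfg)
    return model, history, parts


def train_with_normal(
    tumor_sets: Sequence[FeatureSet],
    normal_sets: Sequence[FeatureSet],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    frac: float = 0.05,
    seed: int = 0,
    split: Optional[Split] = None,
):
    """Merge a random 5% of adjacent-normal reads as non-tumor labels, then train.

    Sampled normal reads join the chromosome-based split like any labeled
    read; the positive weight is recomputed from the merged training set.
    """
    from dataclasses import replace as dc_replace

    rng = np.random.default_rng(seed)
    n_take = int(round(frac * len(normal_sets)))
    take = rng.choice(len(normal_sets), size=n_take, replace=False) if n_take else []
    merged = list(tumor_sets) + [dc_replace(normal_sets[i], label=0) for i in take]
    return train_on_split(merged, model_cfg, train_cfg, split)


FEATURE_SUBSETS = {
    "meth_only": dict(use_atlas=False, use_percentiles=False),
    "meth+atlas": dict(use_atlas=True, use_percentiles=False),
    "meth+percentiles": dict(use_atlas=False, use_percentiles=True),
    "all": dict(use_atlas=True, use_percentiles=True),
}


def ablation_train(
    feature_sets: Sequence[FeatureSet],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    subsets: Sequence[str] = ("meth_only", "all"),
    split: Optional[Split] = None,
    eval_labels: Optional[dict[str, int]] = None,
) -> dict[str, float]:
    """Train one model per feature subset; report test AUC per condition.

    ``eval_labels`` may supply independent evaluation labels (e.g. simulator
    ground truth) keyed by read_id; otherwise the held-out labeled reads are
    used.
    """
    from dataclasses import replace as dc_replace

    split = split or Split()
    results = {}
    for name in subsets:
        cfg = dc_replace(model_cfg, **FEATURE_SUBSETS[name])
        model, _, parts = train_on_split(feature_sets, cfg, train_cfg, split)
        results[name] = test_auc(model, parts["test"], train_cfg, eval_labels)
    return results


def test_auc(model, test_sets, train_cfg, eval_labels: Optional[dict[str, int]] = None) -> float:
    if eval_labels is not None:
        test_sets = [fs for fs in test_sets if fs.read_id in eval_labels]
        y = [eval_labels[fs.read_id] for fs in test_sets]
    else:
        y = [fs.label for fs in test_sets]
    prob = predict(model, test_sets, batch_size=train_cfg.batch_size, seed=train_cfg.seed)
    return evaluate_auc(y, prob)


def crop_experiment(
    reads,
    lengths_bp: Sequence[int],
    site_dist,
    atlas,
    labels: dict[str, int],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    eval_labels: Optional[dict[str, int]] = None,
    min_read_length: int = 15_000,
    seed: int = 0,
    split: Optional[Split] = None,
) -> dict[int, float]:
    """Read-length effect: train one model per crop length on reads >= 15 kb.

    Each condition crops the same labeled read set to a fixed length before
    feature extraction, trains a fresh model, and reports test AUC.
    """
    from .features import build_feature_sets
    from .simulate import crop_reads

    long_reads = [r for r in reads if r.reference_end - r.reference_start >= min_read_length]
    eligible = [r for r in long_reads if r.read_id in labels]
    results = {}
    for length in lengths_bp:
        cropped = crop_reads(eligible, length, seed=seed)
        fsets = build_feature_sets(cropped, site_dist, atlas, labels=labels)
        model, _, parts = train_on_split(fsets, model_cfg, train_cfg, split)
        results[int(length)] = test_auc(model, parts["test"], train_cfg, eval_labels)
    return results
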