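"""Base-learner training under the fixed hyperparameter regime, and
ranking of trained learners for ensemble membership.

The regime: Adam at an initial learning rate of 1e-4, mini-batches of one
image, combined focal+dice loss with inverse-frequency class weighting,
learning rate multiplied by 0.25 whenever the validation loss has not
improved for ten epochs (floored at 1e-7), one geometric augmentation op
drawn uniformly (identity included) per sample per epoch, and the
best-validation-loss weights checkpointed.  Learners are ranked by their
mean validation Jaccard across cross-validation folds and the top three
become ensemble members.
"""

from __future__ import annotations

import copy
import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .data_io import (AUGMENTATIONS, ClassWeights, DatasetManifest, FoldPlan,
                      LabeledSample, augment_sample, compute_class_weights)
from .losses import FocalParams, combined_loss_grad
from .metrics import evaluate_dataset
from .zoo import BaseLearner, build_base_learner, save_checkpoint

__all__ = ["TrainConfig", "TrainedLearner", "train_base_learner",
           "rank_base_learners", "cross_validate"]

DEFAULT_AUGMENT_OPS = tuple(AUGMENTATIONS)


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 1e-4
    plateau_factor: float = 0.25
    plateau_patience: int = 10
    min_lr: float = 1e-7
    batch_size: int = 1
    max_epochs: int = 100
    focal: FocalParams = field(default_factory=FocalParams)
    seed: int = 0
    augment_ops: tuple[str, ...] = DEFAULT_AUGMENT_OPS

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        unknown = set(self.augment_ops) - set(AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {"initial_lr": self.initial_lr,
                "plateau_factor": self.plateau_factor,
                "plateau_patience": self.plateau_patience,
                "min_lr": self.min_lr, "batch_size": self.batch_size,
                "max_epochs": self.max_epochs,
                "focal": {"alpha": self.focal.alpha, "gamma": self.focal.gamma},
                "seed": self.seed, "augment_ops": list(self.augment_ops)}


@dataclass
class TrainedLearner:
    base: BaseLearner
    history: list[dict]
    cv_scores: list[float]
    checkpoint_path: Path | None = None
    is_ensemble_member: bool = False

    @property
    def mean_cv_jaccard(self) -> float:
        if not self.cv_scores:
            raise ValueError("learner has no cross-validation scores")
        return float(np.mean(self.cv_scores))


def _as_samples(data) -> list[LabeledSample]:
    if isinstance(data, DatasetManifest):
        return list(data.iter_samples())
    return list(data)


def _epoch_pass(learner: BaseLearner, samples, config, class_weights, opt, rng,
                augment: bool) -> float:
    losses = []
    order = rng.permutation(len(samples))
    pending = 0
    for idx in order:
        sample = samples[idx]
        if augment:
            # one op per draw, identity included with equal probability
            choice = int(rng.integers(0, len(config.augment_ops) + 1))
            if choice < len(config.augment_ops):
                sample = augment_sample(sample, config.augment_ops[choice],
                                        seed=int(rng.integers(2 ** 31)))
        x = learner.prepare_input(sample.image)
        probs, ctx = learner.model.forward(x, training=True, record=True)
        loss, dprobs = combined_loss_grad(probs.transpose(1, 2, 0), sample.mask,
                                          config.focal, class_weights)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite training loss on sample {sample.id!r} "
                f"(lr={opt.lr:g}); aborting")
        losses.append(loss)
        grad = dprobs.transpose(2, 0, 1).astype(np.float32) / config.batch_size
        learner.model.backward(grad, ctx)
        pending += 1
        if pending == config.batch_size:
            opt.step()
            opt.zero_grad()
            pending = 0
    if pending:
        opt.step()
        opt.zero_grad()
    return float(np.mean(losses))


def _validate(learner: BaseLearner, samples, config, class_weights):
    losses, preds, truths = [], [], []
    for sample in samples:
        probs = learner.predict_proba(sample.image)
        loss, _ = combined_loss_grad(probs, sample.mask, config.focal,
                                     class_weights)
        losses.append(loss)
        preds.append(probs.argmax(axis=2))
        truths.append(sample.mask)
    n_classes = learner.n_classes
    from .synthetic import scheme_for  # local import to avoid cycle at import time
    report = evaluate_dataset(preds, truths, scheme_for(min(n_classes, 4)))
    return float(np.mean(losses)), report.mean_jaccard


def train_base_learner(learner: BaseLearner, train_data, val_data,
                       config: TrainConfig,
                       class_weights: ClassWeights | None = None,
                       run_dir: str | Path | None = None,
                       augment: bool = True) -> TrainedLearner:
    """Train one base-learner; returns it with history and the
    best-validation-loss weights restored."""
    train_samples = _as_samples(train_data)
    val_samples = _as_samples(val_data)
    if not train_samples or not val_samples:
        raise ValueError("training and validation data must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(learner.model.parameters(), lr=config.initial_lr)
    sched = nn.ReduceLROnPlateau(opt, factor=config.plateau_factor,
                                 patience=config.plateau_patience,
                                 min_lr=config.min_lr)
    history: list[dict] = []
    best_val = np.inf
    best_state = learner.model.state_dict()
    for epoch in range(config.max_epochs):
        train_loss = _epoch_pass(learner, train_samples, config, class_weights,
                                 opt, rng, augment)
        val_loss, val_jac = _validate(learner, val_samples, config, class_weights)
        if val_loss < best_val:
            best_val = val_loss
            best_state = learner.model.state_dict()
        lr = sched.step(val_loss)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "val_jaccard": val_jac, "lr": lr})
    learner.model.load_state_dict(best_state)
    _, final_jac = _validate(learner, val_samples, config, class_weights)
    trained = TrainedLearner(learner, history, cv_scores=[final_jac])
    if run_dir is not None:
        trained.checkpoint_path = _write_run(trained, config, Path(run_dir))
    return trained


def _write_run(trained: TrainedLearner, config: TrainConfig, run_dir: Path) -> Path:
    run_dir.mkdir(parents=True, exist_ok=True)
    name = trained.base.encoder.name
    (run_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    with open(run_dir / f"{name}_history.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss",
                                                "val_jaccard", "lr"])
        writer.writeheader()
        writer.writerows(trained.history)
    ckpt = run_dir / f"{name}_best.npz"
    save_checkpoint(trained.base, ckpt)
    (run_dir / f"{name}_scores.json").write_text(
        json.dumps({"cv_scores": trained.cv_scores}))
    return ckpt


def cross_validate(encoder_name: str, train_manifest: DatasetManifest,
                   plan: FoldPlan, config: TrainConfig,
                   class_weights: ClassWeights | None = None,
                   build_kwargs: dict | None = None,
                   run_dir: str | Path | None = None) -> TrainedLearner:
    """Train one encoder across the fold plan; cv_scores collects the
    per-fold validation mean Jaccard and the returned learner is the one
    refit on the first fold split (weights of the last fold are not
    averaged — the scores, not the weights, drive ensemble selection)."""
    if class_weights is None:
        class_weights = compute_class_weights(train_manifest)
    build_kwargs = build_kwargs or {}
    scores: list[float] = []
    kept: TrainedLearner | None = None
    for repeat in range(plan.repeats):
        for fold, (tr_ids, val_ids) in enumerate(plan.folds(repeat)):
            learner = build_base_learner(encoder_name,
                                         train_manifest.scheme.n_classes,
                                         seed=config.seed, **build_kwargs)
            fold_cfg = replace(config, seed=config.seed + repeat * plan.k + fold)
            trained = train_base_learner(learner, train_manifest.subset(tr_ids),
                                         train_manifest.subset(val_ids),
                                         fold_cfg, class_weights)
            scores.extend(trained.cv_scores)
            if kept is None:
                kept = trained
    assert kept is not None
    kept.cv_scores = scores
    if run_dir is not None:
        kept.checkpoint_path = _write_run(kept, config, Path(run_dir))
    return kept


def rank_base_learners(learners: list[TrainedLearner]) -> list[TrainedLearner]:
    """Descending by mean cross-validation Jaccard (stable under ties);
    the top min(3, n) are flagged as ensemble members."""
    if not learners:
        raise ValueError("no learners to rank")
    for lr in learners:
        if not lr.cv_scores:
            raise ValueError(
                f"learner {lr.base.encoder.name!r} has no cv scores")
    order = sorted(range(len(learners)),
                   key=lambda i: -learners[i].mean_cv_jaccard)
    ranked = [learners[i] for i in order]
    for i, lr in enumerate(ranked):
        lr.is_ensemble_member = i < min(3, len(ranked))
    return ranked
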