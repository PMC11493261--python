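"""Robustness metrics and the end-to-end attack/defense experiment.

Metric conventions (all percentages on the 0-100 scale):

* ``accuracy_drop    = clean_accuracy - attacked_accuracy``
* ``attack_success_rate = 100 - attacked_accuracy`` (so accuracy and
  success rate always sum to 100)
* ``accuracy_improve = defended_accuracy - attacked_accuracy`` (may be
  negative when the defense hurts)
* precision/recall/F1 are per-class values averaged with weights equal to
  each class's true-sample support; 0/0 is defined as 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .attacks import AttackSpec, attack
from .autoencoder import (DenoiserTrainConfig, build_denoiser, denoise,
                          reconstruction_mse, train_denoiser)
from .backbones import BackboneSpec, build_backbone
from .classifiers import (ClassifierModel, ClassifierTrainConfig,
                          build_stack_model, build_transfer_classifier,
                          train_classifier)
from .config import ExperimentConfig, stage_seed
from .data import (DatasetSplits, ImageBatch, load_image_folder,
                   make_synthetic_dataset, SyntheticConfig)
from .errors import ConfigError, DataError

logger = logging.getLogger("advdefend")

N_CLASSES = 3


@dataclass
class ConfusionMatrix:
    """3x3 count grid: rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CLASSES, N_CLASSES):
            raise DataError(f"confusion matrix must be {N_CLASSES}x{N_CLASSES}")
        if (self.counts < 0).any():
            raise DataError("confusion matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        """Percent correct."""
        if self.total == 0:
            raise DataError("empty confusion matrix has no accuracy")
        return float(np.trace(self.counts) / self.total * 100.0)


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs into a 3x3 grid."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise DataError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise DataError(f"{name} labels out of range 0..{N_CLASSES - 1}")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts)


def weighted_prf(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Support-weighted average precision, recall and F1 (fractions).

    Per class: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their
    harmonic mean; any 0/0 is taken as 0.  Averaged with weights equal to
    the true-class supports.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    if total == 0:
        raise DataError("cannot compute metrics on an empty confusion matrix")
    tp = np.diag(c)
    support = c.sum(axis=1)
    pred = c.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred > 0, tp / pred, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / pr, 0.0)
    w = support / total
    return (float(w @ precision), float(w @ recall), float(w @ f1))


def _check_pct(name: str, value: float) -> None:
    if not 0.0 <= value <= 100.0:
        raise DataError(f"{name} must be a percentage in [0, 100]; got {value}")


def attack_report(clean_acc: float, attacked_acc: float) -> tuple[float, float]:
    """(accuracy drop, attack success rate), both in percent."""
    _check_pct("clean accuracy", clean_acc)
    _check_pct("attacked accuracy", attacked_acc)
    return clean_acc - attacked_acc, 100.0 - attacked_acc


def defense_report(attacked_acc: float, defended_acc: float) -> float:
    """Accuracy improvement from the defense (percent; may be negative)."""
    _check_pct("attacked accuracy", attacked_acc)
    _check_pct("defended accuracy", defended_acc)
    return defended_acc - attacked_acc


@dataclass
class EvaluationReport:
    """All robustness metrics for one (model, attack, eps, defense) cell."""

    context: dict
    accuracy: float
    confusion: ConfusionMatrix
    precision: float
    recall: float
    f1: float
    accuracy_drop: float | None = None
    attack_success_rate: float | None = None
    accuracy_improve: float | None = None

    def to_row(self) -> dict:
        row = dict(self.context)
        row.update(accuracy=self.accuracy, accuracy_drop=self.accuracy_drop,
                   attack_success_rate=self.attack_success_rate,
                   accuracy_improve=self.accuracy_improve,
                   precision=self.precision, recall=self.recall, f1=self.f1,
                   n=self.confusion.total)
        return row


def evaluate_classifier(model: ClassifierModel, batch: ImageBatch,
                        context: dict | None = None) -> EvaluationReport:
    """Accuracy, confusion matrix and weighted P/R/F1 on one batch."""
    _, pred = model.predict(batch)
    cm = confusion_matrix(batch.labels, pred)
    p, r, f1 = weighted_prf(cm)
    return EvaluationReport(context=context or {}, accuracy=cm.accuracy(),
                            confusion=cm, precision=p, recall=r, f1=f1)


# ---------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------

def _load_dataset(config: ExperimentConfig) -> DatasetSplits:
    ds = config.dataset
    if ds.source == "folder":
        if not ds.root:
            raise ConfigError("dataset.source 'folder' needs dataset.root")
        return load_image_folder(ds.root, ds.image_size)
    return make_synthetic_dataset(SyntheticConfig(
        n_per_class_per_split=dict(ds.n_per_class_per_split),
        image_size=ds.image_size, noise_sd=ds.noise_sd,
        seed=stage_seed(config.seed, "synthetic-data")))


def _build_classifier(config: ExperimentConfig) -> ClassifierModel:
    cb = config.classifier
    seed = stage_seed(config.seed, "classifier-init")
    spec = BackboneSpec(name=cb.backbone, input_size=config.dataset.image_size,
                        frozen=False, width=cb.width)
    if cb.stacked:
        spec2 = BackboneSpec(name=cb.second_backbone,
                             input_size=config.dataset.image_size,
                             frozen=False, width=cb.width)
        return build_stack_model(build_backbone(spec, seed=seed),
                                 build_backbone(spec2, seed=seed + 1),
                                 seed=seed)
    return build_transfer_classifier(spec, seed=seed)


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None
                   ) -> pd.DataFrame:
    """Train -> attack -> defend -> report, one row per evaluation cell.

    Stages: train the classifier on the train split, train the denoiser on
    clean train images, evaluate clean accuracy on the evaluation split,
    then for every (family, epsilon) evaluate the attacked and (if the
    denoiser is enabled) the defended accuracy.  Returns a DataFrame with
    one row per (model, attack, epsilon, defense state); writes
    ``report.csv`` / ``report.json`` under ``out_dir`` when given.
    """
    splits = _load_dataset(config)
    eval_batch = splits.split(config.evaluation.split)

    logger.info("training classifier (%s)", config.classifier.backbone)
    model = _build_classifier(config)
    tc = ClassifierTrainConfig(
        learning_rate=config.classifier.learning_rate,
        epochs=config.classifier.epochs,
        batch_size=config.classifier.batch_size,
        seed=stage_seed(config.seed, "classifier-train"))
    model, _ = train_classifier(model, splits.train, splits.validation, tc)

    denoiser = None
    if config.denoiser.enabled:
        logger.info("training denoiser")
        db = config.denoiser
        dseed = stage_seed(config.seed, "denoiser-train")
        denoiser = build_denoiser(config.dataset.image_size, seed=dseed)
        rng = np.random.default_rng(dseed)
        n = len(splits.train)
        n_val = max(1, int(round(db.val_fraction * n)))
        perm = rng.permutation(n)
        dtrain = splits.train.subset(perm[n_val:])
        dval = splits.train.subset(perm[:n_val])
        dcfg = DenoiserTrainConfig(learning_rate=db.learning_rate,
                                   epochs=db.epochs, batch_size=db.batch_size,
                                   seed=dseed)
        denoiser, _ = train_denoiser(denoiser, dtrain, dval, dcfg,
                                     noisy_input=db.noisy_input)

    model_name = model.name
    reports: list[EvaluationReport] = []

    clean_rep = evaluate_classifier(model, eval_batch, {
        "model": model_name, "attack": "none", "epsilon": 0.0,
        "defense": "none"})
    clean_acc = clean_rep.accuracy
    clean_rep.accuracy_drop = 0.0
    clean_rep.attack_success_rate = 100.0 - clean_acc
    reports.append(clean_rep)
    if denoiser is not None and config.evaluation.apply_denoiser_to_clean:
        rep = evaluate_classifier(model, denoise(denoiser, eval_batch), {
            "model": model_name, "attack": "none", "epsilon": 0.0,
            "defense": "autoencoder"})
        rep.accuracy_improve = defense_report(clean_acc, rep.accuracy)
        reports.append(rep)

    ab = config.attack
    for family in ab.families:
        for eps in ab.epsilons:
            spec = AttackSpec(family=family, epsilon=eps, n_iter=ab.n_iter,
                              step_size=ab.step_size,
                              random_start=ab.random_start,
                              seed=stage_seed(config.seed, f"attack-{family}"))
            logger.info("attacking: %s eps=%g", family, eps)
            adv = attack(model, eval_batch, spec)
            rep = evaluate_classifier(model, adv.perturbed, {
                "model": model_name, "attack": family, "epsilon": eps,
                "defense": "none"})
            drop, success = attack_report(clean_acc, rep.accuracy)
            rep.accuracy_drop, rep.attack_success_rate = drop, success
            reports.append(rep)
            if denoiser is not None:
                defended = denoise(denoiser, adv.perturbed)
                drep = evaluate_classifier(model, defended, {
                    "model": model_name, "attack": family, "epsilon": eps,
                    "defense": "autoencoder"})
                drep.accuracy_drop, drep.attack_success_rate = attack_report(
                    clean_acc, drep.accuracy)
                drep.accuracy_improve = defense_report(rep.accuracy,
                                                       drep.accuracy)
                _, mse_adv = reconstruction_mse(adv.perturbed, eval_batch)
                _, mse_def = reconstruction_mse(defended, eval_batch)
                drep.context["mse_adversarial_vs_clean"] = mse_adv
                drep.context["mse_defended_vs_clean"] = mse_def
                reports.append(drep)

    frame = pd.DataFrame([r.to_row() for r in reports])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "report.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(frame.to_dict(orient="records"), indent=2))
    return frame
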