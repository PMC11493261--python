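"""Untargeted FGSM and PGD attacks in the L-infinity ball.

Both attacks maximize the classifier's cross-entropy against the *true*
label (untargeted), perturb in [0, 1] grayscale pixel space, and never
touch the clean input tensor.  The perturbation budget epsilon is measured
on the [0, 1] scale; the canonical magnitude grid is
(0.001, 0.006, 0.05, 0.1, 0.4).

FGSM is the single-step attack ``x + eps * sign(dL/dx)`` clipped to [0, 1];
PGD iterates smaller signed-gradient steps, after each one projecting back
onto the eps-ball around the clean image intersected with [0, 1].  With one
iteration, step >= eps and no random start, PGD reduces exactly to FGSM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CLASS_NAMES, SPLIT_NAMES, DatasetSplits, ImageBatch
from .errors import CapabilityError, DataError

DEFAULT_EPSILONS: tuple[float, ...] = (0.001, 0.006, 0.05, 0.1, 0.4)
DEFAULT_PER_CLASS_COUNTS: dict[str, int] = {
    "train": 250, "test": 100, "validation": 100}
_TOL = 1e-6


@dataclass(frozen=True)
class AttackSpec:
    """One attack configuration: family, budget, and PGD schedule.

    ``step_size=None`` means the conventional eps/4 default for PGD.
    """

    family: str
    epsilon: float
    n_iter: int = 10
    step_size: float | None = None
    random_start: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("fgsm", "pgd"):
            raise DataError(f"unknown attack family '{self.family}'")
        if self.epsilon < 0:
            raise DataError("epsilon must be >= 0")
        if self.family == "pgd":
            if self.n_iter < 1:
                raise DataError("PGD needs n_iter >= 1")
            if self.step_size is not None and self.step_size <= 0:
                raise DataError("PGD step_size must be > 0")

    @property
    def resolved_step(self) -> float:
        return self.epsilon / 4.0 if self.step_size is None else self.step_size


@dataclass
class AdversarialBatch:
    """Clean/perturbed image pair with the realized per-image L-inf norms."""

    clean: ImageBatch
    perturbed: ImageBatch
    spec: AttackSpec
    linf: np.ndarray

    def __post_init__(self) -> None:
        if not np.array_equal(self.clean.labels, self.perturbed.labels):
            raise DataError("attack must not alter ground-truth labels")
        if np.any(self.linf > self.spec.epsilon + _TOL):
            raise DataError("perturbation exceeds the epsilon budget")


def _require_gradient_model(model) -> None:
    if not hasattr(model, "input_gradient"):
        raise CapabilityError(
            f"model {model!r} exposes no input_gradient; white-box attacks "
            "need a differentiable classifier handle")


def _finish(clean: ImageBatch, x_adv: np.ndarray, spec: AttackSpec
            ) -> AdversarialBatch:
    linf = np.abs(x_adv - clean.pixels).max(axis=(1, 2, 3))
    perturbed = ImageBatch(x_adv, clean.labels.copy(), clean.ids)
    return AdversarialBatch(clean=clean, perturbed=perturbed, spec=spec,
                            linf=linf)


def fgsm(model, batch: ImageBatch, spec: AttackSpec) -> AdversarialBatch:
    """One signed-gradient step of size epsilon, clipped to [0, 1].

    ``sign(0) = 0``: pixels with zero loss gradient are left untouched.
    """
    if spec.family != "fgsm":
        raise DataError(f"fgsm() called with family '{spec.family}'")
    _require_gradient_model(model)
    grad = model.input_gradient(batch.pixels, batch.labels)
    x_adv = np.clip(batch.pixels + spec.epsilon * np.sign(grad), 0.0, 1.0)
    return _finish(batch, x_adv.astype(batch.pixels.dtype), spec)


def pgd(model, batch: ImageBatch, spec: AttackSpec) -> AdversarialBatch:
    """Iterated signed-gradient ascent with per-step projection.

    Projection order: clamp to the eps-ball around the clean pixels, then
    to [0, 1].  Optional uniform random start inside the ball (seeded from
    ``spec.seed``).
    """
    if spec.family != "pgd":
        raise DataError(f"pgd() called with family '{spec.family}'")
    _require_gradient_model(model)
    clean = batch.pixels
    eps, step = spec.epsilon, spec.resolved_step
    x = clean.copy()
    if spec.random_start and eps > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xAD]))
        x = x + rng.uniform(-eps, eps, size=x.shape).astype(x.dtype)
        x = np.clip(np.clip(x, clean - eps, clean + eps), 0.0, 1.0)
    for _ in range(spec.n_iter):
        grad = model.input_gradient(x, batch.labels)
        x = x + step * np.sign(grad)
        x = np.clip(np.clip(x, clean - eps, clean + eps), 0.0, 1.0)
        assert np.abs(x - clean).max() <= eps + _TOL  # projection contract
    return _finish(batch, x.astype(clean.dtype), spec)


def attack(model, batch: ImageBatch, spec: AttackSpec) -> AdversarialBatch:
    """Dispatch to fgsm or pgd based on the AttackSpec family."""
    return fgsm(model, batch, spec) if spec.family == "fgsm" \
        else pgd(model, batch, spec)


def generate_attack_suite(model, splits: DatasetSplits,
                          specs: list[AttackSpec],
                          per_class_counts: dict[str, int] | None = None
                          ) -> dict:
    """Attack a deterministic image selection for every spec.

    Selects the first-k images per (split, class) by sorted id (the
    published run uses 250 train / 100 test / 100 validation per class),
    attacks each selection at every spec, and returns a map keyed
    ``(family, epsilon, split, class_name) -> ImageBatch`` ready for
    :func:`advdefend.data.write_attack_hierarchy`.
    """
    counts = dict(DEFAULT_PER_CLASS_COUNTS if per_class_counts is None
                  else per_class_counts)
    selections: dict[tuple[str, str], ImageBatch] = {}
    for split in SPLIT_NAMES:
        batch = splits.split(split)
        for label, cls in enumerate(CLASS_NAMES):
            cls_batch = batch.select_class(label)
            k = counts[split]
            if len(cls_batch) < k:
                raise DataError(
                    f"split '{split}' class '{cls}' has {len(cls_batch)} "
                    f"images; {k} requested")
            order = np.argsort(np.asarray(cls_batch.ids))[:k]
            selections[(split, cls)] = cls_batch.subset(order)
    out = {}
    for spec in specs:
        for (split, cls), selection in selections.items():
            adv = attack(model, selection, spec)
            out[(spec.family, spec.epsilon, split, cls)] = adv.perturbed
    return out


def specs_for_grid(family: str, epsilons=DEFAULT_EPSILONS, **kwargs
                   ) -> list[AttackSpec]:
    """One AttackSpec per epsilon in the grid."""
    return [AttackSpec(family=family, epsilon=e, **kwargs) for e in epsilons]
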