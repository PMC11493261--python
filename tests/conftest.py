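"""Shared fixtures: small synthetic datasets, a trained desk-scale model,
and the session-scoped 3-seed robustness benchmark."""

from __future__ import annotations

import numpy as np
import pytest

from advdefend import (ClassifierTrainConfig, SyntheticConfig,
                       build_transfer_classifier, make_synthetic_dataset,
                       train_classifier)
from advdefend.backbones import BackboneSpec
from advdefend.benchmark import run_robustness_benchmark

BENCH_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A quick 16px dataset (12 per class per split) for plumbing tests."""
    return make_synthetic_dataset(SyntheticConfig(
        n_per_class_per_split={"train": 12, "test": 12, "validation": 12},
        image_size=16, seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """The 32px benchmark-sized dataset, seed 7."""
    return make_synthetic_dataset(SyntheticConfig(image_size=32, seed=7))


@pytest.fixture(scope="session")
def trained_classifier(small_dataset):
    """A tinycnn classifier trained to high accuracy on the 32px data."""
    model = build_transfer_classifier(
        BackboneSpec(name="tinycnn", input_size=32, frozen=False), seed=7)
    model, history = train_classifier(
        model, small_dataset.train, small_dataset.validation,
        ClassifierTrainConfig(learning_rate=2e-3, epochs=20, batch_size=21,
                              seed=7))
    return model, history


@pytest.fixture(scope="session")
def untrained_tiny_model():
    """An untrained 16px classifier (gradients defined, accuracy random)."""
    return build_transfer_classifier(
        BackboneSpec(name="tinycnn", input_size=16, frozen=False, width=8),
        seed=0)


@pytest.fixture(scope="session")
def benchmark_reports():
    """Per-seed report tables from the full 3-seed robustness benchmark."""
    return {seed: run_robustness_benchmark(seed) for seed in BENCH_SEEDS}


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
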