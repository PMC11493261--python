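"""The desk-scale robustness benchmark preset.

One call runs the full pipeline — synthetic data, tinycnn classifier,
autoencoder, both attack families over an epsilon grid — at a problem size
a single CPU handles in about a minute: 100 images per class per split at
32x32, 20 classifier epochs, 20 denoiser epochs.  The qualitative pattern
of interest (large accuracy drops at eps >= 0.05 from a >= 90% clean
baseline, partial recovery through the denoiser) is stable at this scale;
the headline numbers from full-scale ImageNet-backbone runs on real
radiographs are not expected to transfer numerically.
"""

from __future__ import annotations

import pandas as pd

from .config import ExperimentConfig, parse_config
from .evaluation import run_experiment

BENCHMARK_IMAGE_SIZE = 32
BENCHMARK_EPSILONS = (0.001, 0.006, 0.05, 0.1, 0.4)


def benchmark_config(seed: int, *, image_size: int = BENCHMARK_IMAGE_SIZE,
                     epsilons=BENCHMARK_EPSILONS,
                     families=("fgsm", "pgd")) -> ExperimentConfig:
    """The benchmark's experiment configuration for one seed."""
    return parse_config(None, overrides={
        "dataset": {"image_size": image_size},
        "attack": {"families": list(families),
                   "epsilons": [float(e) for e in epsilons]},
        "seed": seed,
    })


def run_robustness_benchmark(seed: int, **kwargs) -> pd.DataFrame:
    """Run the benchmark for one seed; returns the evaluation report table."""
    return run_experiment(benchmark_config(seed, **kwargs))


def summarize_over_seeds(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean metrics over per-seed report tables, keyed by evaluation cell."""
    all_rows = pd.concat(frames, ignore_index=True)
    keys = ["model", "attack", "epsilon", "defense"]
    metrics = ["accuracy", "accuracy_drop", "attack_success_rate",
               "accuracy_improve", "precision", "recall", "f1"]
    present = [m for m in metrics if m in all_rows.columns]
    return all_rows.groupby(keys, as_index=False)[present].mean()
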