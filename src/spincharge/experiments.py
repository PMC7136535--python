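"""Canonical end-to-end experiment: generate, split, train, evaluate.

Bundles the standard protocol used throughout the package's validation:
synthetic frames from the default generator, a half/half frame-wise split,
per-atom per-spin forests (B=200, m=5) on symmetry functions, and the
per-atom/per-spin evaluation report on the held-out half.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import EvaluationReport, evaluate_model
from .forest import FeaturizerSpec, ForestConfig, TrainedChargeModel, split_dataset, train_all
from .structure import Dataset
from .synthetic import GeneratorParams, generate_dataset


@dataclass
class ExperimentResult:
    model: TrainedChargeModel
    report: EvaluationReport
    train: Dataset
    test: Dataset
    dataset: Dataset


def run_reference_experiment(
    n_frames: int = 4000,
    seed: int = 0,
    n_trees: int = 200,
    m_spec=5,
    charge_noise_sigma: float = 0.01,
    scheme: str = "sf",
) -> ExperimentResult:
    """Run the full pipeline at the stated problem size and return everything."""
    params = GeneratorParams(
        n_frames=n_frames, seed=seed, charge_noise_sigma=charge_noise_sigma
    )
    dataset = generate_dataset(params)
    train, test = split_dataset(dataset, 0.5, seed=seed)
    if scheme == "sf":
        spec = FeaturizerSpec.symmetry_functions(
            dataset.structures[0].composition()
        )
    else:
        spec = FeaturizerSpec.internal()
    config = ForestConfig(n_trees=n_trees, m_spec=m_spec, seed=seed)
    model = train_all(train, spec, config)
    report = evaluate_model(model, test)
    return ExperimentResult(model, report, train, test, dataset)
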