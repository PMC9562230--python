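"""Reusable study-scale experiments.

Two validation experiments recur across the analysis scripts, the test
suite, and the acceptance script, so they live here as library functions:

* parameter recovery -- generate model-consistent studies from a known
  (alpha, n, k) truth and check the grid search finds it;
* end-to-end network validation -- augment a model-consistent study to 1000
  synthetic rows, train a network preset on them, and measure MAE on the 18
  original wines (all of them, and the 6 held out of augmentation,
  separately).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .augmentation import AugmentationPlan, smote_augment, split_dataset
from .dnn import evaluate_mae, normalize_features, preset_spec, train
from .modulators import DEFAULT_ASSIGNMENT, ModulatorSet
from .quality import grid_search, pis_from_chemistry
from .synthetic import ModelTruth, generate_model_consistent

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_N_GRID",
    "RecoveryOutcome",
    "recovery_experiment",
    "EndToEndOutcome",
    "end_to_end_network",
]

#: Default calibration grids: alpha in 0.50..1.20 step 0.01, n in 0.50..1.50
#: step 0.02 (both inclusive), covering the published (alpha, n) combinations.
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.50, 1.2001, 0.01), 2))
DEFAULT_N_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.50, 1.5001, 0.02), 2))


@dataclass(frozen=True)
class RecoveryOutcome:
    seed: int
    best_alpha: float
    best_n: float
    distance: float


def _default_sets() -> list[ModulatorSet]:
    return [ModulatorSet(label, members) for label, members in DEFAULT_ASSIGNMENT.items()]


def recovery_experiment(
    truth: ModelTruth,
    seeds: Sequence[int],
    noise_sd: float = 0.0,
    n_wines: int = 18,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    n_grid: Sequence[float] = DEFAULT_N_GRID,
) -> list[RecoveryOutcome]:
    """Grid-search recovery of a known truth, one outcome per seed."""
    sets = _default_sets()
    outcomes = []
    for seed in seeds:
        study = generate_model_consistent(
            n_wines, truth, noise_sd=noise_sd, seed=int(seed)
        )
        pis = pis_from_chemistry(study.chemistry, sets, truth.pi_forms)
        res = grid_search(
            pis, study.quality.to_numpy(), alpha_grid, n_grid, k=truth.k, top_m=1
        )
        outcomes.append(
            RecoveryOutcome(
                seed=int(seed),
                best_alpha=res.best.alpha,
                best_n=res.best.n,
                distance=res.best.distance,
            )
        )
    return outcomes


@dataclass(frozen=True)
class EndToEndOutcome:
    preset: str
    data_seed: int
    train_seed: int
    stopping_epoch: int
    test_mae_all: float
    test_mae_holdout: float
    n_train_rows: int


def end_to_end_network(
    truth: ModelTruth,
    preset: str = "data1",
    data_seed: int = 0,
    train_seed: int = 0,
    noise_sd: float = 0.1,
    n_wines: int = 18,
    n_synth: int = 1000,
    max_epochs: int = 2000,
) -> EndToEndOutcome:
    """Simulate, augment, train, and evaluate one preset once.

    The study's 18 wines are split 12/6; only the 12 source wines feed the
    interpolation, and only the synthetic rows are trained on.  MAE is
    reported both over all 18 originals and over the 6 wines the
    augmentation never saw.
    """
    study = generate_model_consistent(
        n_wines, truth, noise_sd=noise_sd, seed=int(data_seed)
    )
    table = study.chemistry.copy()
    table["quality"] = study.quality
    plan = AugmentationPlan(
        n_source=12, n_holdout=n_wines - 12, n_synth=n_synth, seed=int(data_seed)
    )
    source, holdout = split_dataset(table, plan)
    augmented = smote_augment(source, plan)
    feat_cols = [c for c in augmented.data.columns if c != "quality"]
    spec = preset_spec(preset, input_dim=len(feat_cols), max_epochs=max_epochs)
    train_scaled, (test_scaled,), _ = normalize_features(
        augmented.data[feat_cols], [table[feat_cols]]
    )
    model = train(
        spec, train_scaled, augmented.data["quality"].to_numpy(), seed=int(train_seed)
    )
    return EndToEndOutcome(
        preset=preset,
        data_seed=int(data_seed),
        train_seed=int(train_seed),
        stopping_epoch=model.stopping_epoch,
        test_mae_all=evaluate_mae(model, test_scaled, table["quality"].to_numpy()),
        test_mae_holdout=evaluate_mae(
            model, test_scaled.loc[holdout.index], holdout["quality"].to_numpy()
        ),
        n_train_rows=len(augmented.data),
    )
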