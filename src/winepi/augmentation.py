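"""Nearest-neighbour interpolation ("SMOTE") augmentation of small wine tables.

An 18-wine table is split 12/6; the 12 source wines are inflated to ~1000
synthetic rows by interpolating each seed row toward one of its k nearest
neighbours.  Two interpolation formulas are available:

* ``paper-abs`` (default): x' = x + gap * |x - x_k| coordinate-wise -- a
  one-sided variant that never moves a coordinate below its seed value and
  can extrapolate upward past the neighbour;
* ``standard-signed``: x' = x + gap * (x_k - x), the canonical SMOTE segment
  interpolation, kept as an option since the one-sided variant deviates from
  common practice.

One gap is drawn per synthetic row (not per coordinate), so a synthetic
point lies on the ray/segment through its seed.  Neighbour search runs in
z-scored feature space so ug/L-scale compounds do not dominate pH-scale
features; the quality column is interpolated with the same formula and gap
but excluded from the distance.  Holdout rows never touch the augmentation
or its normalisation statistics.

``dummy_class_augment`` reproduces the published construction literally:
append a majority class of all-zero rows, oversample the 12-row minority
class with class-targeted SMOTE, then drop the class column, the zero rows,
and the original rows -- leaving exactly the synthetic rows, element-wise
identical to :func:`smote_augment` under shared draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "AugmentationPlan",
    "AugmentedDataset",
    "split_dataset",
    "smote_augment",
    "dummy_class_augment",
    "write_provenance",
]

FORMULAS = ("paper-abs", "standard-signed")


@dataclass(frozen=True)
class AugmentationPlan:
    """How to split and inflate one study table."""

    n_source: int = 12
    n_holdout: int = 6
    n_synth: int = 1000
    k_neighbors: int = 5
    formula: str = "paper-abs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_source < 2 or self.n_holdout < 0:
            raise ValueError("need at least two source rows")
        if self.n_synth < 0:
            raise ValueError("n_synth must be non-negative")
        if not (0 < self.k_neighbors < self.n_source):
            raise ValueError("k_neighbors must be in (0, n_source)")
        if self.formula not in FORMULAS:
            raise ValueError(f"formula must be one of {FORMULAS}")


@dataclass(frozen=True)
class AugmentedDataset:
    """Synthetic rows plus per-row provenance (seed row, neighbour, gap)."""

    data: pd.DataFrame
    provenance: pd.DataFrame
    plan: AugmentationPlan

    def __post_init__(self) -> None:
        if len(self.data) != len(self.provenance):
            raise ValueError("each synthetic row needs a provenance record")
        if len(self.data) != self.plan.n_synth:
            raise ValueError(
                f"expected {self.plan.n_synth} synthetic rows, got {len(self.data)}"
            )


def split_dataset(
    rows: pd.DataFrame, plan: AugmentationPlan
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-deterministic disjoint split into (source, holdout)."""
    if len(rows) != plan.n_source + plan.n_holdout:
        raise ValueError(
            f"table has {len(rows)} rows; plan wants "
            f"{plan.n_source} + {plan.n_holdout}"
        )
    rng = np.random.default_rng(plan.seed)
    perm = rng.permutation(len(rows))
    source = rows.iloc[np.sort(perm[: plan.n_source])]
    holdout = rows.iloc[np.sort(perm[plan.n_source :])]
    return source, holdout


def _feature_columns(source: pd.DataFrame, quality_col: str) -> list[str]:
    cols = [c for c in source.columns if c != quality_col]
    bad = [c for c in cols if not np.issubdtype(source[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric feature columns: {bad}")
    return cols


def _neighbour_table(features: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbours of each row, in z-scored space."""
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    z = (features - mu) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    idx = nn.kneighbors(z, return_distance=False)
    # first column is the row itself; keep the k true neighbours
    return idx[:, 1 : k + 1]


def _draws(plan: AugmentationPlan) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The shared random draw log: seed row, neighbour rank, gap per row."""
    rng = np.random.default_rng(plan.seed)
    seed_idx = rng.integers(plan.n_source, size=plan.n_synth)
    nbr_rank = rng.integers(plan.k_neighbors, size=plan.n_synth)
    gaps = rng.random(plan.n_synth)
    return seed_idx, nbr_rank, gaps


def _interpolate(
    values: np.ndarray,
    seed_idx: np.ndarray,
    nbr_idx: np.ndarray,
    gaps: np.ndarray,
    formula: str,
) -> np.ndarray:
    x = values[seed_idx]
    xk = values[nbr_idx]
    if formula == "paper-abs":
        return x + gaps[:, None] * np.abs(x - xk)
    return x + gaps[:, None] * (xk - x)


def _augment(
    source: pd.DataFrame, plan: AugmentationPlan, quality_col: str
) -> AugmentedDataset:
    if len(source) < plan.k_neighbors + 1:
        raise ValueError(
            f"need at least {plan.k_neighbors + 1} source rows, got {len(source)}"
        )
    if len(source) != plan.n_source:
        raise ValueError(
            f"source has {len(source)} rows but the plan says {plan.n_source}"
        )
    feat_cols = _feature_columns(source, quality_col)
    features = source[feat_cols].to_numpy(dtype=float)
    nbr_table = _neighbour_table(features, plan.k_neighbors)
    seed_idx, nbr_rank, gaps = _draws(plan)
    nbr_idx = nbr_table[seed_idx, nbr_rank]
    cols = feat_cols + ([quality_col] if quality_col in source.columns else [])
    values = source[cols].to_numpy(dtype=float)
    synth = _interpolate(values, seed_idx, nbr_idx, gaps, plan.formula)
    data = pd.DataFrame(
        synth,
        columns=cols,
        index=pd.Index([f"synth{i + 1:04d}" for i in range(plan.n_synth)], name="row_id"),
    )
    provenance = pd.DataFrame(
        {
            "seed_index": seed_idx,
            "seed_row": source.index[seed_idx],
            "neighbor_index": nbr_idx,
            "neighbor_row": source.index[nbr_idx],
            "gap": gaps,
        },
        index=data.index,
    )
    return AugmentedDataset(data=data, provenance=provenance, plan=plan)


def smote_augment(
    source: pd.DataFrame,
    plan: AugmentationPlan,
    quality_col: str = "quality",
) -> AugmentedDataset:
    """Inflate the source table to exactly ``plan.n_synth`` synthetic rows."""
    return _augment(source, plan, quality_col)


def dummy_class_augment(
    source: pd.DataFrame,
    plan: AugmentationPlan,
    quality_col: str = "quality",
) -> AugmentedDataset:
    """The published dummy-class route to the same synthetic rows.

    Builds the literal intermediate frame -- source rows as minority class 0
    on top of ``n_synth`` manually inserted all-zero rows as majority class 1
    -- runs minority-targeted SMOTE oversampling within class 0, then removes
    the class column, every all-zero row, and the original source rows.
    """
    if plan.n_synth == 0:
        empty = source.iloc[0:0].copy()
        plan0 = plan
        return AugmentedDataset(
            data=empty,
            provenance=pd.DataFrame(
                columns=["seed_index", "seed_row", "neighbor_index", "neighbor_row", "gap"]
            ),
            plan=plan0,
        )
    zeros = pd.DataFrame(
        0.0,
        index=pd.Index([f"zero{i + 1:04d}" for i in range(plan.n_synth)], name="row_id"),
        columns=source.columns,
    )
    dummy = pd.concat([source, zeros])
    dummy["class"] = [0] * len(source) + [1] * plan.n_synth
    # class-targeted oversampling: interpolate within the minority class only
    minority = dummy.loc[dummy["class"] == 0].drop(columns="class")
    oversampled = _augment(minority, plan, quality_col)
    enlarged = pd.concat([dummy, oversampled.data.assign(**{"class": 0})])
    # tear the construction back down: drop class column, zero rows, originals
    enlarged = enlarged.drop(columns="class")
    nonzero = enlarged.loc[~(enlarged == 0).all(axis=1)]
    synthetic = nonzero.drop(index=source.index)
    return AugmentedDataset(
        data=synthetic, provenance=oversampled.provenance, plan=plan
    )


def write_provenance(dataset: AugmentedDataset, path: str | Path) -> Path:
    """One JSON record per synthetic row (seed row, neighbour, gap)."""
    path = Path(path)
    with path.open("w") as fh:
        for row_id, rec in dataset.provenance.iterrows():
            fh.write(
                json.dumps(
                    {
                        "row_id": str(row_id),
                        "seed_index": int(rec["seed_index"]),
                        "seed_row": str(rec["seed_row"]),
                        "neighbor_index": int(rec["neighbor_index"]),
                        "neighbor_row": str(rec["neighbor_row"]),
                        "gap": float(rec["gap"]),
                    }
                )
                + "\n"
            )
    return path
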