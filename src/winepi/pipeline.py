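"""End-to-end pipeline driver.

Runs the stages in order -- simulate/load, modulator assembly, pi-term
evaluation, (alpha, n) grid search, report, SMOTE augmentation, network
training, evaluation -- writing each stage's artefacts plus a manifest with
enough provenance (seeds, input hashes, version) to reproduce every file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augmentation import AugmentationPlan, dummy_class_augment, split_dataset, write_provenance
from .dnn import evaluate_mae, normalize_features, predict, preset_spec, train
from .modulators import (
    DEFAULT_ASSIGNMENT,
    CompoundRecord,
    assemble_modulators,
    select_compounds,
)
from .quality import grid_search, quality_report, pis_from_chemistry, two_group_case_study
from .synthetic import (
    DEFAULT_PI_FORMS,
    calibrated_truth,
    default_compound_specs,
    generate_model_consistent,
    generate_sensory,
    write_study,
)

logger = logging.getLogger("winepi")

__all__ = ["RunConfig", "run_pipeline", "parse_grid", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def parse_grid(text: str) -> list[float]:
    """Parse an inclusive ``start:stop:step`` grid, or a comma list."""
    if ":" in text:
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"grid must be start:stop:step, got {text!r}")
        start, stop, step = map(float, parts)
        if step <= 0 or stop < start:
            raise ValueError(f"bad grid bounds {text!r}")
        count = int(round((stop - start) / step))
        grid = [start + i * step for i in range(count + 1)]
        return [g for g in grid if g <= stop + 1e-12]
    return [float(x) for x in text.split(",")]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; CLI flags override these fields."""

    outdir: str = "results/run"
    n_wines: int = 18
    seed: int = 0
    # synthetic block (used when chemistry_path is None): "sensory" draws
    # panel quality, "model-consistent" generates quality from a calibrated
    # known truth (for recovery-style validation runs)
    model_consistent: bool = False
    noise_sd: float = 0.1
    # or load from files
    chemistry_path: str | None = None
    quality_path: str | None = None
    physiochem_path: str | None = None
    # modulators / pi-terms
    pi_forms: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PI_FORMS))
    # grid search
    alpha_grid: Sequence[float] = field(default_factory=lambda: parse_grid("0.5:1.2:0.01"))
    n_grid: Sequence[float] = field(default_factory=lambda: parse_grid("0.5:1.5:0.02"))
    k: float = 1.0
    k_mode: str = "calibrated"
    top_m: int = 5
    # augmentation
    n_synth: int = 1000
    k_neighbors: int = 5
    formula: str = "paper-abs"
    # network
    preset: str = "data1"
    max_epochs: int = 2000
    train_seeds: Sequence[int] = (0,)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    stage = "simulate"
    try:
        specs = default_compound_specs()
        physiochem = None
        if config.chemistry_path:
            chemistry = pd.read_csv(config.chemistry_path, index_col="wine_id")
            quality = pd.read_csv(config.quality_path, index_col="wine_id")["quality"]
            if config.physiochem_path:
                physiochem = pd.read_csv(config.physiochem_path, index_col="wine_id")
            truth = None
            logger.info("load: %d wines, %d compounds", *chemistry.shape)
        elif config.model_consistent:
            truth = calibrated_truth(pi_forms=config.pi_forms)
            study = generate_model_consistent(
                config.n_wines,
                truth,
                specs,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
            chemistry, quality = study.chemistry, study.quality
            physiochem = study.physiochem
            write_study(study, outdir / "study")
            logger.info(
                "simulate: model-consistent, %d wines, truth alpha=%.3g n=%.3g k=%.3g",
                config.n_wines, truth.alpha, truth.n, truth.k,
            )
        else:
            from .synthetic import generate_chemistry

            chemistry = generate_chemistry(config.n_wines, specs, seed=config.seed)
            _, quality = generate_sensory(config.n_wines, seed=config.seed + 1)
            truth = None
            logger.info("simulate: sensory quality, %d wines", config.n_wines)
        manifest["stages"].append(stage)

        stage = "modulators"
        # selection is range-based: a compound counts as aroma-active when
        # its OAV exceeds 1 in at least one wine
        max_conc = chemistry.max(axis=0)
        records = [
            CompoundRecord(name=s.name, concentration=float(max_conc[s.name]), odt=s.odt)
            for s in specs
        ]
        selected = select_compounds(records)
        sets = assemble_modulators(selected, DEFAULT_ASSIGNMENT)
        mod_path = outdir / "modulators.json"
        mod_path.write_text(
            json.dumps(
                {
                    "selected": selected,
                    "modulators": {m.label: list(m.members) for m in sets},
                    "oav": {r.name: r.oav for r in records},
                },
                indent=2,
            )
        )
        manifest["stages"].append(stage)
        logger.info("modulators: %d compounds selected, %d sets", len(selected), len(sets))

        stage = "pi-terms"
        pis = pis_from_chemistry(chemistry, sets, config.pi_forms)
        pis.to_csv(outdir / "pi_terms.csv")
        manifest["stages"].append(stage)

        stage = "grid-search"
        result = grid_search(
            pis,
            quality.to_numpy(),
            config.alpha_grid,
            config.n_grid,
            k=config.k,
            top_m=config.top_m,
            k_mode=config.k_mode,
        )
        best = result.best
        logger.info(
            "grid-search: best alpha=%.3g n=%.3g distance=%.4g",
            best.alpha, best.n, best.distance,
        )
        manifest["grid_search"] = [
            {"alpha": p.alpha, "n": p.n, "k": p.k, "distance": p.distance}
            for p in result.ranked
        ]
        manifest["stages"].append(stage)

        stage = "report"
        report = quality_report(result.models(), pis, quality.to_numpy(), list(chemistry.index))
        report.to_csv(outdir / "quality_report.csv")
        manifest["stages"].append(stage)

        stage = "case-study"
        if physiochem is not None:
            case, case_pis = two_group_case_study(
                physiochem,
                quality.to_numpy(),
                config.n_grid,
                k=config.k,
                k_mode=config.k_mode,
                top_m=config.top_m,
            )
            case_pis.to_csv(outdir / "case_study_pis.csv")
            manifest["case_study"] = [
                {"n": p.n, "k": p.k, "distance": p.distance} for p in case.ranked
            ]
            logger.info(
                "case-study: best n=%.3g k=%.3g distance=%.4g",
                case.best.n, case.best.k, case.best.distance,
            )
            manifest["stages"].append(stage)
        else:
            manifest["skipped"] = manifest.get("skipped", []) + [stage]
            logger.info("case-study: no physiochemical table, stage skipped")

        stage = "augment"
        table = chemistry.copy()
        table["quality"] = quality
        plan = AugmentationPlan(
            n_source=12,
            n_holdout=len(table) - 12,
            n_synth=config.n_synth,
            k_neighbors=config.k_neighbors,
            formula=config.formula,
            seed=config.seed,
        )
        source, holdout = split_dataset(table, plan)
        augmented = dummy_class_augment(source, plan)
        augmented.data.to_csv(outdir / "augmented.csv")
        write_provenance(augmented, outdir / "augmented_provenance.jsonl")
        manifest["augmentation"] = {
            "n_synth": len(augmented.data),
            "source_rows": list(map(str, source.index)),
            "holdout_rows": list(map(str, holdout.index)),
        }
        manifest["stages"].append(stage)
        logger.info("augment: %d synthetic rows from %d source wines", len(augmented.data), len(source))

        stage = "train"
        feat_cols = [c for c in augmented.data.columns if c != "quality"]
        spec = preset_spec(
            config.preset, input_dim=len(feat_cols), max_epochs=config.max_epochs
        )
        train_X = augmented.data[feat_cols]
        train_y = augmented.data["quality"].to_numpy()
        test_X = table[feat_cols]
        train_Xs, (test_Xs,), norm = normalize_features(train_X, [test_X])
        maes = {}
        predictions = None
        for train_seed in config.train_seeds:
            model = train(spec, train_Xs, train_y, seed=int(train_seed))
            model.normalization = norm
            pred = predict(model, test_Xs)
            maes[int(train_seed)] = {
                "test_mae_all": evaluate_mae(model, test_Xs, table["quality"].to_numpy()),
                "test_mae_holdout": evaluate_mae(
                    model,
                    test_Xs.loc[holdout.index],
                    holdout["quality"].to_numpy(),
                ),
                "stopping_epoch": model.stopping_epoch,
            }
            predictions = pd.DataFrame(
                {
                    "observed": table["quality"],
                    "predicted": pred,
                    "absolute_error": np.abs(pred - table["quality"].to_numpy()),
                },
                index=table.index,
            )
            logger.info(
                "train: seed=%d stopped at epoch %d, test MAE %.3f",
                train_seed, model.stopping_epoch, maes[int(train_seed)]["test_mae_all"],
            )
        manifest["stages"].append(stage)

        stage = "evaluate"
        assert predictions is not None
        predictions.to_csv(outdir / "predictions.csv")
        manifest["network"] = {
            "preset": config.preset,
            "input_dim": spec.input_dim,
            "optimizer": spec.optimizer,
            "mae": maes,
        }
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
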