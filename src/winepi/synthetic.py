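"""Synthetic study generator.

The chemistry, physiochemical, and sensory tables this module emits have the
statistical structure the downstream analysis assumes, standing in for an
18-wine Pinot noir panel whose measured tables are not public:

* compound concentrations are log-uniform within per-compound ranges -- the
  published ranges where stated, documented oenological defaults otherwise
  (flagged by :attr:`CompoundSpec.source`);
* physiochemical variables are uniform within configurable ranges;
* panel ratings follow an additive model (grand mean + wine effect +
  panelist effect + noise) clamped to the 1-10 category scale, and perceived
  quality is the per-wine mean rating;
* model-consistent studies draw chemistry as above and set quality to the
  exponent-weighted quality proxy of a known (alpha, n, k, pi-form) truth,
  plus optional Gaussian noise -- the fixture for parameter-recovery tests.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .modulators import DEFAULT_ASSIGNMENT, MODULATOR_LABELS, ModulatorSet
from .quality import QualityModel, exponent_schedule, pis_from_chemistry, quality_proxy

__all__ = [
    "CompoundSpec",
    "ModelTruth",
    "SyntheticStudy",
    "DEFAULT_PHYSIOCHEM_RANGES",
    "DEFAULT_PI_FORMS",
    "default_compound_specs",
    "generate_chemistry",
    "generate_physiochem",
    "generate_sensory",
    "generate_model_consistent",
    "calibrated_truth",
    "write_study",
]

RATING_MIN, RATING_MAX = 1.0, 10.0


@dataclass(frozen=True)
class CompoundSpec:
    """Concentration range and detection threshold for one compound.

    ``source`` records provenance: ``"printed"`` ranges are published values,
    ``"derived"`` ranges are reconstructed from published OAV x ODT spans,
    and ``"default"`` ranges are this package's documented stand-ins.
    """

    name: str
    modulator: str
    conc_low: float  # ug/L
    conc_high: float  # ug/L
    odt: float  # ug/L, point value (lower bound when a range is published)
    source: str = "default"

    def __post_init__(self) -> None:
        if not (0 < self.conc_low <= self.conc_high):
            raise ValueError(
                f"{self.name}: need 0 < conc_low <= conc_high, "
                f"got [{self.conc_low}, {self.conc_high}]"
            )
        if not (self.odt > 0):
            raise ValueError(f"{self.name}: odt must be positive, got {self.odt}")
        if self.modulator not in MODULATOR_LABELS:
            raise ValueError(f"{self.name}: unknown modulator {self.modulator!r}")


def default_compound_specs() -> list[CompoundSpec]:
    """Specs for the modulator compounds of the published membership list.

    The three ethyl esters share the published group range 18.5-874 ug/L with
    the group ODT collapsed to its lower bound (2 ug/L).  Eugenol and
    guaiacol concentrations are reconstructed from the published OAV span
    0.32-14.4 at ODT 5 ug/L.  The herbal alcohols, benzaldehyde, and phenol
    have no published ranges; their defaults are chosen so that the herbal
    compounds typically exceed OAV 1 while the three override-selected
    compounds (benzaldehyde, heptan-1-ol, phenol) typically do not.
    """
    P, D, V = "printed", "default", "derived"
    return [
        CompoundSpec("ethyl octanoate", "fruity", 18.5, 874.0, 2.0, P),
        CompoundSpec("ethyl butanoate", "fruity", 18.5, 874.0, 2.0, P),
        CompoundSpec("ethyl hexanoate", "fruity", 18.5, 874.0, 2.0, P),
        CompoundSpec("hexan-1-ol", "herbal", 1500.0, 12000.0, 1100.0, D),
        CompoundSpec("(E)-hex-3-en-1-ol", "herbal", 500.0, 2000.0, 400.0, D),
        CompoundSpec("heptan-1-ol", "herbal", 10.0, 200.0, 1000.0, D),
        CompoundSpec("beta-damascenone", "floral", 0.2, 102.0, 0.05, P),
        CompoundSpec("2-phenylethan-1-ol", "floral", 236.0, 158473.0, 10000.0, P),
        CompoundSpec("linalool", "floral", 0.83, 170.0, 25.0, P),
        CompoundSpec("eugenol", "woody", 1.6, 144.0, 5.0, V),
        CompoundSpec("benzaldehyde", "woody", 3.0, 60.0, 2000.0, D),
        CompoundSpec("guaiacol", "woody", 1.6, 144.0, 5.0, V),
        CompoundSpec("phenol", "other", 5.0, 50.0, 5900.0, D),
    ]


#: Documented oenological default ranges for the six physiochemical
#: variables (not published values): total sulphur and total phenolics in
#: mg/L, titratable acidity and residual sugar in g/L, ethanol in % v/v.
DEFAULT_PHYSIOCHEM_RANGES: dict[str, tuple[float, float]] = {
    "total_sulphur": (40.0, 150.0),
    "total_phenolics": (1200.0, 2600.0),
    "titratable_acidity": (4.5, 7.0),
    "sugar": (0.5, 5.0),
    "ethanol": (12.5, 14.5),
    "pH": (3.3, 3.9),
}

#: Default Pi-form per modulator: the leading additive prototype, the sum of
#: the first two members over the third.
DEFAULT_PI_FORMS: dict[str, str] = {label: "(x1+x2)/x3" for label in MODULATOR_LABELS}


def _wine_ids(n_wines: int) -> list[str]:
    return [f"wine{i + 1:02d}" for i in range(n_wines)]


def generate_chemistry(
    n_wines: int,
    specs: Sequence[CompoundSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Wine x compound concentration table, log-uniform within spec ranges.

    Log-uniform sampling keeps low concentrations represented even when a
    range spans three orders of magnitude (e.g. 236-158,473 ug/L).
    """
    if n_wines < 0:
        raise ValueError("n_wines must be non-negative")
    if specs is None:
        specs = default_compound_specs()
    if not specs:
        raise ValueError("need at least one compound spec")
    rng = np.random.default_rng(seed)
    lo = np.log([s.conc_low for s in specs])
    hi = np.log([s.conc_high for s in specs])
    draws = np.exp(rng.uniform(lo, hi, size=(n_wines, len(specs))))
    return pd.DataFrame(
        draws,
        index=pd.Index(_wine_ids(n_wines), name="wine_id"),
        columns=[s.name for s in specs],
    )


def generate_physiochem(
    n_wines: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Wine x 6 physiochemical table, uniform within per-variable ranges."""
    if n_wines < 0:
        raise ValueError("n_wines must be non-negative")
    if ranges is None:
        ranges = DEFAULT_PHYSIOCHEM_RANGES
    missing = set(DEFAULT_PHYSIOCHEM_RANGES) - set(ranges)
    if missing:
        raise ValueError(f"missing physiochemical variables: {sorted(missing)}")
    if len(ranges) != 6:
        raise ValueError("exactly six physiochemical variables are expected")
    for var, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"{var}: need low < high, got [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    cols = list(ranges)
    lo = np.array([ranges[v][0] for v in cols])
    hi = np.array([ranges[v][1] for v in cols])
    draws = rng.uniform(lo, hi, size=(n_wines, len(cols)))
    return pd.DataFrame(
        draws, index=pd.Index(_wine_ids(n_wines), name="wine_id"), columns=cols
    )


def generate_sensory(
    n_wines: int,
    n_panelists: int = 22,
    wine_effect_sd: float = 0.6,
    panelist_effect_sd: float = 0.5,
    noise_sd: float = 1.0,
    grand_mean: float = 5.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Panel ratings and per-wine perceived quality.

    rating[p, w] = grand_mean + wine_effect[w] + panelist_effect[p] + noise,
    clamped to the 1-10 category scale; quality is the per-wine mean rating.
    The defaults mirror a 22-professional panel whose quality ratings spread
    with sd ~0.6 across wines.
    """
    if n_wines < 1 or n_panelists < 1:
        raise ValueError("need at least one wine and one panelist")
    if min(wine_effect_sd, panelist_effect_sd, noise_sd) < 0:
        raise ValueError("effect standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    wine_eff = rng.normal(0.0, wine_effect_sd, size=n_wines)
    panelist_eff = rng.normal(0.0, panelist_effect_sd, size=n_panelists)
    noise = rng.normal(0.0, noise_sd, size=(n_panelists, n_wines))
    ratings = grand_mean + wine_eff[None, :] + panelist_eff[:, None] + noise
    ratings = np.clip(ratings, RATING_MIN, RATING_MAX)
    frame = pd.DataFrame(
        ratings,
        index=pd.Index([f"panelist{p + 1:02d}" for p in range(n_panelists)], name="panelist"),
        columns=pd.Index(_wine_ids(n_wines), name="wine_id"),
    )
    quality = frame.mean(axis=0)
    quality.name = "perceived_quality"
    return frame, quality


@dataclass(frozen=True)
class ModelTruth:
    """Known generating parameters of a model-consistent study."""

    alpha: float
    n: float
    k: float
    pi_forms: Mapping[str, str]

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.n > 0 and self.k > 0):
            raise ValueError("alpha, n, k must all be positive")


@dataclass(frozen=True)
class SyntheticStudy:
    """One synthetic 18-wine-style study: aligned tables plus provenance."""

    wine_ids: tuple[str, ...]
    chemistry: pd.DataFrame
    physiochem: pd.DataFrame
    quality: pd.Series
    seed: int
    truth: ModelTruth | None = None

    def __post_init__(self) -> None:
        for table in (self.chemistry, self.physiochem):
            if list(table.index) != list(self.wine_ids):
                raise ValueError("tables must share the wine index")
        if list(self.quality.index) != list(self.wine_ids):
            raise ValueError("quality must share the wine index")


def _modulator_sets(
    specs: Sequence[CompoundSpec],
    assignment: Mapping[str, Sequence[str]],
) -> list[ModulatorSet]:
    names = {s.name for s in specs}
    return [
        ModulatorSet(label=label, members=tuple(m for m in members if m in names))
        for label, members in assignment.items()
    ]


def generate_model_consistent(
    n_wines: int,
    truth: ModelTruth,
    specs: Sequence[CompoundSpec] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    assignment: Mapping[str, Sequence[str]] | None = None,
) -> SyntheticStudy:
    """Study whose quality is the quality proxy of a known truth.

    Chemistry is drawn as in :func:`generate_chemistry`; quality is
    QP(alpha, n, k) on that chemistry plus Gaussian noise of sd ``noise_sd``.
    With ``noise_sd=0`` the quality column reproduces the proxy exactly, the
    identity the parameter-recovery tests rely on, so no rating-scale clamp
    is applied here.
    """
    if specs is None:
        specs = default_compound_specs()
    if assignment is None:
        assignment = DEFAULT_ASSIGNMENT
    rng = np.random.default_rng(seed)
    chemistry = generate_chemistry(n_wines, specs, seed=rng.integers(2**31))
    physiochem = generate_physiochem(n_wines, seed=rng.integers(2**31))
    sets = _modulator_sets(specs, assignment)
    pis = pis_from_chemistry(chemistry, sets, truth.pi_forms)
    model = QualityModel(
        pi_forms=tuple(truth.pi_forms[s.label] for s in sets),
        schedule=exponent_schedule(truth.alpha, truth.n, len(sets)),
        k=truth.k,
    )
    qp = np.asarray(quality_proxy(pis.to_numpy(), model))
    quality = pd.Series(
        qp + rng.normal(0.0, noise_sd, size=n_wines) if noise_sd > 0 else qp,
        index=chemistry.index,
        name="quality",
    )
    return SyntheticStudy(
        wine_ids=tuple(chemistry.index),
        chemistry=chemistry,
        physiochem=physiochem,
        quality=quality,
        seed=int(seed),
        truth=truth,
    )


def calibrated_truth(
    alpha: float = 0.8,
    target_sd: float = 0.6,
    target_median: float = 5.5,
    specs: Sequence[CompoundSpec] | None = None,
    pi_forms: Mapping[str, str] | None = None,
    assignment: Mapping[str, Sequence[str]] | None = None,
    n_sample: int = 4000,
    seed: int = 20160918,
) -> ModelTruth:
    """Choose (n, k) so model-consistent quality looks like panel quality.

    The base exponent n is set so the proxy's spread across default-chemistry
    wines matches ``target_sd`` (0.6 rating units, the spread real panels
    show on the 10-point quality scale), using sd(QP) ~ median(QP) *
    sd(log QP); k then centres the median at ``target_median``.  The
    calibration sample is internal and fixed by ``seed``, so the returned
    truth is deterministic.
    """
    if specs is None:
        specs = default_compound_specs()
    if pi_forms is None:
        pi_forms = DEFAULT_PI_FORMS
    if assignment is None:
        assignment = DEFAULT_ASSIGNMENT
    chemistry = generate_chemistry(n_sample, specs, seed=seed)
    sets = _modulator_sets(specs, assignment)
    pis = pis_from_chemistry(chemistry, sets, pi_forms)
    z = np.log(pis.to_numpy()) @ np.asarray(
        [alpha**i for i in range(len(sets))], dtype=float
    )
    sigma = target_sd / target_median  # sd of log QP for the target spread
    n = sigma / float(np.std(z))
    k = target_median / float(np.exp(n * np.median(z)))
    return ModelTruth(alpha=float(alpha), n=float(n), k=float(k), pi_forms=dict(pi_forms))


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write chemistry/physiochem/quality CSVs plus a JSON sidecar.

    The sidecar records the seed and, for model-consistent studies, the
    generating truth, so a study can be regenerated bit-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chemistry": outdir / "chemistry.csv",
        "physiochem": outdir / "physiochem.csv",
        "quality": outdir / "quality.csv",
        "meta": outdir / "study_meta.json",
    }
    study.chemistry.to_csv(paths["chemistry"])
    study.physiochem.to_csv(paths["physiochem"])
    study.quality.rename("quality").to_frame().to_csv(paths["quality"])
    meta: dict = {"seed": study.seed, "n_wines": len(study.wine_ids)}
    if study.truth is not None:
        meta["truth"] = {
            **{f: getattr(study.truth, f) for f in ("alpha", "n", "k")},
            "pi_forms": dict(study.truth.pi_forms),
        }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths
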