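"""Synthetic strain-panel diet-challenge studies with known ground truth.

Emulates the design of a recombinant-inbred diet study: ``a`` inbred
strains, each contributing sibling trios housed together at baseline,
with one sibling per trio randomized to each experimental diet; mice
processed in weekly batches.  Phenotypes follow the additive
random-effects model

    y = mu + diet_shift + s_i + (sd)_ij + b_k + c_l + eps

with strain, strain-by-diet interaction, batch, cage and residual terms
drawn independently Gaussian with configurable variances.  The realized
effects are returned as :class:`GroundTruth`, so every downstream
estimator can be validated by parameter recovery without any external
data.

Draws are keyed by ``(seed, trait)`` through independent RNG streams:
adding a trait to a config never perturbs the draws of existing traits.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_data import (
    BASELINE_DIET,
    EXPERIMENTAL_DIETS,
    PHENOTYPE_COLUMNS,
    PhenotypeTable,
)

__all__ = [
    "TraitSpec",
    "CalorimetrySpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_study",
    "expected_intraclass",
    "simulate_calorimetry",
    "cc22_config",
    "tiny_config",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class TraitSpec:
    """Generative parameters for one trait (trait units throughout)."""

    mu: float = 0.0
    diet_shift: Mapping[str, float] = field(default_factory=dict)
    var_strain: float = 1.0
    var_interaction: float = 0.0
    var_diet: float = 0.0
    var_batch: float = 0.0
    var_cage: float = 0.0
    var_residual: float = 1.0
    units: str = "au"

    def __post_init__(self) -> None:
        if self.var_residual <= 0:
            raise ConfigError("var_residual must be > 0")
        for name in ("var_strain", "var_interaction", "var_diet", "var_batch", "var_cage"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CalorimetrySpec:
    """Diurnal/nocturnal generative levels for one calorimetry measure.

    ``night_shift`` is added to the day mean during the dark cycle
    (nocturnal animals run higher metabolic levels at night).
    ``integer_counts`` marks beam-break style measures emitted as
    Poisson counts.
    """

    day_mean: float
    night_shift: float = 0.0
    sd: float = 0.0
    integer_counts: bool = False
    nonnegative: bool = False  # clip noise excursions below zero (feed, water)


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated study."""

    seed: int
    a: int = 22
    diets: tuple[str, ...] = EXPERIMENTAL_DIETS
    mice_per_strain_per_diet: int | Sequence[int] = 5
    n_batches: int = 7
    trait_specs: Mapping[str, TraitSpec] = field(default_factory=dict)
    calorimetry_specs: Mapping[str, CalorimetrySpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a < 2:
            raise ConfigError("need at least 2 strains")
        if self.n_batches < 1:
            raise ConfigError("need at least 1 batch")
        if not set(self.diets) <= set(EXPERIMENTAL_DIETS):
            raise ConfigError(f"experimental diets must be within {EXPERIMENTAL_DIETS}")

    def trios_per_strain(self) -> np.ndarray:
        m = self.mice_per_strain_per_diet
        if np.isscalar(m):
            return np.full(self.a, int(m), dtype=int)
        arr = np.asarray(m, dtype=int)
        if len(arr) != self.a:
            raise ConfigError("per-strain counts must have one entry per strain")
        return arr

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["trait_specs"] = {
            t: TraitSpec(**s) for t, s in raw.get("trait_specs", {}).items()}
        raw["calorimetry_specs"] = {
            m: CalorimetrySpec(**s) for m, s in raw.get("calorimetry_specs", {}).items()}
        if "diets" in raw:
            raw["diets"] = tuple(raw["diets"])
        return cls(**raw)


@dataclass(frozen=True)
class GroundTruth:
    """Realized random effects of one simulated study, keyed per trait."""

    strain_effects: dict        # trait -> {strain: effect}
    interaction_effects: dict   # trait -> {(strain, diet): effect}
    batch_effects: dict         # trait -> {batch: effect}
    cage_effects: dict          # trait -> {cage: effect}
    diet_effects: dict = field(default_factory=dict)  # trait -> {diet: random effect}

    def realized_strain_variance(self, trait: str) -> float:
        vals = np.fromiter(self.strain_effects[trait].values(), dtype=float)
        return float(vals.var(ddof=1)) if len(vals) > 1 else 0.0


def _trait_rng(seed: int, trait: str, channel: str = "pheno") -> np.random.Generator:
    key = zlib.crc32(f"{channel}:{trait}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _design_frame(config: SimulationConfig) -> pd.DataFrame:
    """One row per mouse: strain, diet, batch, cages.  Deterministic per seed."""
    rng = _trait_rng(config.seed, "", channel="design")
    trios = config.trios_per_strain()
    strains = [f"S{i + 1:02d}" for i in range(config.a)]

    rows = []
    mouse_no = 0
    for s_idx, strain in enumerate(strains):
        for trio in range(trios[s_idx]):
            cage_base = f"B_{strain}_T{trio + 1}"
            # one sibling of the trio goes to each experimental diet
            for diet in config.diets:
                mouse_no += 1
                rows.append({
                    "mouse_id": f"M{mouse_no:04d}",
                    "strain": strain,
                    "diet": diet,
                    "cage_baseline": cage_base,
                })
    df = pd.DataFrame(rows)

    # each strain's sibling trios are dealt round-robin over batches from a
    # random offset: siblings share a batch, batches stay balanced, and batch
    # is guaranteed crossed with strain (never aliased) whenever a strain has
    # at least as many trios as there are batches minus one
    trio_batch = {}
    for s_idx, strain in enumerate(strains):
        offset = int(rng.integers(config.n_batches))
        for trio in range(trios[s_idx]):
            trio_batch[f"B_{strain}_T{trio + 1}"] = \
                (offset + trio) % config.n_batches + 1
    df["batch"] = df["cage_baseline"].map(trio_batch)

    # randomization cages: within each diet, shuffled mice housed three per cage
    df["cage_randomized"] = ""
    for diet in config.diets:
        idx = df.index[df["diet"] == diet].to_numpy()
        idx = rng.permutation(idx)
        for c, start in enumerate(range(0, len(idx), 3)):
            df.loc[idx[start:start + 3], "cage_randomized"] = f"R_{diet}_C{c + 1}"
    return df


def simulate_study(config: SimulationConfig) -> tuple[PhenotypeTable, GroundTruth]:
    """Draw one study: baseline + post-diet rows for every configured trait.

    Baseline rows use the baseline diet with no diet shift or
    interaction effect and the baseline-cage effect; post-diet rows add
    the diet shift, the strain-by-diet interaction and the
    randomized-cage effect.  Strain and batch effects persist across
    timepoints for each mouse.
    """
    if not config.trait_specs:
        raise ConfigError("no trait_specs configured")
    design = _design_frame(config)
    strains = sorted(design["strain"].unique())
    batches = sorted(design["batch"].unique())
    cages = sorted(set(design["cage_baseline"]) | set(design["cage_randomized"]))

    strain_fx: dict = {}
    inter_fx: dict = {}
    batch_fx: dict = {}
    cage_fx: dict = {}
    diet_fx: dict = {}
    frames = []
    for trait, spec in config.trait_specs.items():
        rng = _trait_rng(config.seed, trait)
        s_eff = dict(zip(strains, rng.normal(0, np.sqrt(spec.var_strain), len(strains))))
        i_eff = {
            (s, d): e
            for (s, d), e in zip(
                [(s, d) for s in strains for d in config.diets],
                rng.normal(0, np.sqrt(spec.var_interaction),
                           len(strains) * len(config.diets)))
        }
        b_eff = dict(zip(batches, rng.normal(0, np.sqrt(spec.var_batch), len(batches))))
        c_eff = dict(zip(cages, rng.normal(0, np.sqrt(spec.var_cage), len(cages))))
        d_eff = dict(zip(config.diets,
                         rng.normal(0, np.sqrt(spec.var_diet), len(config.diets))))
        strain_fx[trait] = s_eff
        inter_fx[trait] = i_eff
        batch_fx[trait] = b_eff
        cage_fx[trait] = c_eff
        diet_fx[trait] = d_eff

        eps = rng.normal(0, np.sqrt(spec.var_residual), (len(design), 2))
        base_shift = float(spec.diet_shift.get(BASELINE_DIET, 0.0))
        for tp_idx, timepoint in enumerate(("baseline", "postdiet")):
            df = design.copy()
            df["timepoint"] = timepoint
            df["trait"] = trait
            df["units"] = spec.units
            common = (spec.mu
                      + df["strain"].map(s_eff).to_numpy()
                      + df["batch"].map(b_eff).to_numpy())
            if timepoint == "baseline":
                value = (common + base_shift
                         + df["cage_baseline"].map(c_eff).to_numpy()
                         + eps[:, tp_idx])
                df["diet"] = BASELINE_DIET
            else:
                shift = df["diet"].map(
                    lambda d: float(spec.diet_shift.get(d, 0.0)) + d_eff[d])
                ieff = [inter_fx[trait][(s, d)]
                        for s, d in zip(df["strain"], df["diet"])]
                # shared-litter (baseline cage) environment persists post-diet
                # alongside the new randomized-cage environment
                value = (common + shift.to_numpy() + np.asarray(ieff)
                         + df["cage_randomized"].map(c_eff).to_numpy()
                         + df["cage_baseline"].map(c_eff).to_numpy()
                         + eps[:, tp_idx])
            df["value"] = value
            frames.append(df)

    out = pd.concat(frames, ignore_index=True)[PHENOTYPE_COLUMNS]
    out = out.sort_values(["trait", "timepoint", "mouse_id"]).reset_index(drop=True)
    truth = GroundTruth(strain_fx, inter_fx, batch_fx, cage_fx, diet_fx)
    return PhenotypeTable(out), truth


#: variance bookkeeping per heritability model variant: {key: weight} for the
#: numerator (between-strain) and denominator-remainder sides.  Strain-by-diet
#: interaction counts toward the strain variance in single-diet variants
#: (within one diet the two are confounded); post-diet rows carry both the
#: persistent litter (baseline-cage) and the randomized-cage effects, hence
#: the weight of 2 on the cage variance there.
_VARIANT_RULES = {
    "baseline": ({"var_strain": 1}, {"var_cage": 1, "var_residual": 1}),
    "full": ({"var_strain": 1},
             {"var_interaction": 1, "var_cage": 2, "var_residual": 1}),
    "partial": ({"var_strain": 1},
                {"var_interaction": 1, "var_diet": 1, "var_cage": 2,
                 "var_residual": 1}),
    "HP": ({"var_strain": 1, "var_interaction": 1},
           {"var_cage": 2, "var_residual": 1}),
    "HS": ({"var_strain": 1, "var_interaction": 1},
           {"var_cage": 2, "var_residual": 1}),
    "unadjusted": ({"var_strain": 1},
                   {"var_batch": 1, "var_cage": 1, "var_residual": 1}),
}


def expected_intraclass(config: SimulationConfig, trait: str,
                        variant: str = "baseline") -> float:
    """Analytic intraclass correlation implied by the configured variances.

    Returns ``var_between / (var_between + var_other)`` where the
    bookkeeping of which components enter each side depends on the model
    variant: batch is removed by the week covariate in every variant
    except ``unadjusted``; the strain-by-diet interaction inflates the
    between-strain variance in single-diet variants and the residual
    otherwise.  Fixed diet shifts contribute to neither side (they are
    either modelled or a mean shift, not a variance component).
    """
    if trait not in config.trait_specs:
        raise ValueError(f"unknown trait {trait!r}")
    try:
        num_keys, den_keys = _VARIANT_RULES[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}") from None
    spec = config.trait_specs[trait]
    num = sum(w * getattr(spec, k) for k, w in num_keys.items())
    other = sum(w * getattr(spec, k) for k, w in den_keys.items())
    if num == 0:
        return 0.0
    return num / (num + other)


def simulate_calorimetry(
    config: SimulationConfig,
    total_hours: float = 48.0,
    sampling_minutes: int = 42,
    lights_on: float = 6.0,
    lights_off: float = 18.0,
    start_clock: float = 10.0,
    start_date: str = "2016-06-01",
    n_mice: int | None = None,
) -> pd.DataFrame:
    """Per-mouse calorimetry time series with configured day/night levels.

    One record per mouse every ``sampling_minutes`` over ``total_hours``.
    During the dark cycle each measure runs at ``day_mean +
    night_shift``; Gaussian noise with the configured SD is added
    (Poisson sampling for count-type measures).  The returned frame has
    ``mouse_id``, ``timestamp`` and one column per configured measure;
    cycle labelling is left to the calorimetry module.
    """
    if not config.calorimetry_specs:
        raise ConfigError("no calorimetry_specs configured")
    if total_hours <= 0:
        raise ConfigError("observation window must have positive length")
    if sampling_minutes <= 0:
        raise ConfigError("sampling interval must be positive")

    # partial trailing interval is not recorded (floor semantics)
    n_records = int(total_hours * 60 // sampling_minutes)
    if n_records == 0:
        raise ConfigError("observation window shorter than one sampling interval")
    offsets = pd.to_timedelta(np.arange(n_records) * sampling_minutes, unit="m")
    t0 = pd.Timestamp(start_date) + pd.Timedelta(hours=start_clock)
    timestamps = t0 + offsets
    clock = (timestamps.hour + timestamps.minute / 60.0
             + timestamps.second / 3600.0).to_numpy()
    is_day = (clock >= lights_on) & (clock < lights_off)

    design = _design_frame(config)
    mouse_ids = design["mouse_id"].tolist()
    if n_mice is not None:
        mouse_ids = mouse_ids[:n_mice]

    frames = []
    for measure, spec in config.calorimetry_specs.items():
        rng = _trait_rng(config.seed, measure, channel="calorimetry")
        level = np.where(is_day, spec.day_mean, spec.day_mean + spec.night_shift)
        cols = {}
        for mid in mouse_ids:
            if spec.integer_counts:
                vals = rng.poisson(np.clip(level, 0, None)).astype(float)
            else:
                vals = level + rng.normal(0, spec.sd, n_records) if spec.sd > 0 \
                    else level.astype(float).copy()
                if spec.nonnegative:
                    vals = np.clip(vals, 0.0, None)
            cols[mid] = vals
        long = pd.DataFrame(cols, index=timestamps).stack().rename(measure)
        frames.append(long)

    wide = pd.concat(frames, axis=1).reset_index()
    wide.columns = ["timestamp", "mouse_id"] + list(config.calorimetry_specs)
    wide = wide.sort_values(["mouse_id", "timestamp"]).reset_index(drop=True)
    return wide[["mouse_id", "timestamp"] + list(config.calorimetry_specs)]


# ---------------------------------------------------------------------------
# presets

_DEFAULT_TRAITS = {
    "body_fat_pct": TraitSpec(mu=12.0, diet_shift={"HP": 5.0, "HS": 7.5},
                              var_strain=18.0, var_interaction=3.0, var_batch=1.0,
                              var_cage=0.5, var_residual=12.0, units="%"),
    "total_weight": TraitSpec(mu=18.0, diet_shift={"HP": 3.8, "HS": 6.0},
                              var_strain=7.0, var_interaction=1.0, var_batch=0.5,
                              var_cage=0.3, var_residual=5.0, units="g"),
    "cholesterol": TraitSpec(mu=95.0, diet_shift={"HP": 20.0, "HS": 45.0},
                             var_strain=450.0, var_interaction=60.0, var_batch=30.0,
                             var_cage=10.0, var_residual=420.0, units="mg/dL"),
    "tg": TraitSpec(mu=95.0, diet_shift={"HP": 9.0, "HS": 18.0},
                    var_strain=900.0, var_interaction=150.0, var_batch=50.0,
                    var_cage=20.0, var_residual=1100.0, units="mg/dL"),
    "glucose": TraitSpec(mu=165.0, diet_shift={"HP": 8.0, "HS": 20.0},
                         var_strain=900.0, var_interaction=120.0, var_batch=60.0,
                         var_cage=25.0, var_residual=1500.0, units="mg/dL"),
    "insulin": TraitSpec(mu=0.9, diet_shift={"HP": 0.13, "HS": 0.27},
                         var_strain=0.12, var_interaction=0.03, var_batch=0.01,
                         var_cage=0.005, var_residual=0.20, units="ng/ml"),
    "glucose_insulin_ratio": TraitSpec(mu=200.0, diet_shift={"HP": -15.0, "HS": -30.0},
                                       var_strain=2500.0, var_interaction=400.0,
                                       var_batch=150.0, var_cage=60.0,
                                       var_residual=3500.0, units="mg/dL per ng/ml"),
}

_DEFAULT_CALORIMETRY = {
    "rer": CalorimetrySpec(day_mean=0.85, night_shift=0.08, sd=0.03),
    "heat_total": CalorimetrySpec(day_mean=14.0, night_shift=3.0, sd=1.2),
    "heat_lean": CalorimetrySpec(day_mean=16.0, night_shift=3.5, sd=1.4),
    "feed_g": CalorimetrySpec(day_mean=0.10, night_shift=0.12, sd=0.04, nonnegative=True),
    "water_g": CalorimetrySpec(day_mean=0.12, night_shift=0.14, sd=0.05, nonnegative=True),
    "beams_x": CalorimetrySpec(day_mean=120.0, night_shift=180.0, integer_counts=True),
    "beams_y": CalorimetrySpec(day_mean=100.0, night_shift=150.0, integer_counts=True),
    "beams_z": CalorimetrySpec(day_mean=30.0, night_shift=60.0, integer_counts=True),
}

#: per-diet trio counts of the cc22 preset: 16 strains with 5, 5 with 4 and one
#: with 2 mice per diet — 102 mice per diet, 204 in total across 7 batches.
CC22_TRIOS = (5,) * 16 + (4,) * 5 + (2,)


def cc22_config(seed: int, trait_specs: Mapping[str, TraitSpec] | None = None,
                **overrides) -> SimulationConfig:
    """The default study-shaped preset: 22 strains, 2 diets, 204 mice, 7 batches."""
    cfg = SimulationConfig(
        seed=seed,
        a=22,
        diets=EXPERIMENTAL_DIETS,
        mice_per_strain_per_diet=CC22_TRIOS,
        n_batches=7,
        trait_specs=dict(trait_specs) if trait_specs is not None else dict(_DEFAULT_TRAITS),
        calorimetry_specs=dict(_DEFAULT_CALORIMETRY),
    )
    return replace(cfg, **overrides) if overrides else cfg


def tiny_config(seed: int) -> SimulationConfig:
    """A 3-strain miniature for tests and docs (12 mice, 2 traits)."""
    return SimulationConfig(
        seed=seed,
        a=3,
        diets=EXPERIMENTAL_DIETS,
        mice_per_strain_per_diet=2,
        n_batches=2,
        trait_specs={
            "body_fat_pct": _DEFAULT_TRAITS["body_fat_pct"],
            "cholesterol": _DEFAULT_TRAITS["cholesterol"],
        },
        calorimetry_specs={
            "rer": _DEFAULT_CALORIMETRY["rer"],
            "feed_g": _DEFAULT_CALORIMETRY["feed_g"],
            "beams_x": _DEFAULT_CALORIMETRY["beams_x"],
            "beams_y": _DEFAULT_CALORIMETRY["beams_y"],
            "beams_z": _DEFAULT_CALORIMETRY["beams_z"],
        },
    )
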