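"""End-to-end orchestration and simulation-based validation experiments.

``run_pipeline`` drives the full analysis on either a user-supplied
phenotype CSV or a simulated study: normalization, heritability tables,
diet effect sizes and health scores, gene-by-diet mixed models and
variance partitioning, calorimetry summaries and trait correlation
matrices, with a reproducible manifest.

The ``*_recovery`` / ``*_calibration`` helpers run the repeated
simulation experiments that validate each estimator against the
generator's known ground truth (parameter recovery, type-I error
calibration); they are used by the test-suite and the acceptance
script.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, calorimetry, core_data, effects_scores, heritability
from . import mixed_models, synthetic_data, transforms
from .core_data import PhenotypeTable, DEFAULT_RISK_TRAITS
from .synthetic_data import SimulationConfig, TraitSpec, cc22_config, tiny_config

logger = logging.getLogger("ccdiet")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "make_fixtures",
    "normalize_table",
    "intraclass_recovery",
    "mixed_model_null_calibration",
    "mixed_model_power",
    "variance_partition_recovery",
    "day_night_rejection_rate",
]

#: example energy table; kcal densities and fractions beyond the documented
#: high-protein example are synthetic placeholders users must replace
EXAMPLE_ENERGY_TABLE = calorimetry.DietEnergyTable({
    "HP": {"kcal_per_g": 4.1,
           "protein_g_per_g": calorimetry.EXAMPLE_HP_PROTEIN_FRACTION,
           "carbohydrate_g_per_g": 0.41, "fat_g_per_g": 0.09},
    "HS": {"kcal_per_g": 4.6, "protein_g_per_g": 0.19,
           "carbohydrate_g_per_g": 0.58, "fat_g_per_g": 0.16},
})


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    seed: int = 0
    preset: str | None = "cc22"
    phenotype_csv: str | None = None
    traits: tuple[str, ...] | None = None
    gate_alpha: float = 0.05
    bh_alpha: float = 0.05
    p_thresh: float = 0.05
    g_thresh: float = 0.8
    sign_convention: str = "post_minus_baseline"
    run_calorimetry: bool = True
    energy_table: calorimetry.DietEnergyTable = field(
        default_factory=lambda: EXAMPLE_ENERGY_TABLE)
    outdir: str = "ccdiet_out"

    def validate(self) -> None:
        if self.preset is None and self.phenotype_csv is None:
            raise ValueError("either a simulation preset or a phenotype CSV is required")
        if self.phenotype_csv is not None and not Path(self.phenotype_csv).exists():
            raise FileNotFoundError(self.phenotype_csv)
        if self.run_calorimetry and not self.energy_table.entries:
            raise ValueError("calorimetry requested but energy table is empty")


def _preset_config(preset: str, seed: int) -> SimulationConfig:
    if preset == "cc22":
        return cc22_config(seed)
    if preset == "tiny":
        return tiny_config(seed)
    raise ValueError(f"unknown preset {preset!r}; expected 'cc22' or 'tiny'")


def normalize_table(table: PhenotypeTable, alpha: float = 0.05
                    ) -> tuple[PhenotypeTable, list[transforms.TransformRecord]]:
    """Gate/transform every trait x timepoint vector; return transformed table.

    Whole-trait vectors (all strains and diets jointly) are transformed
    per timepoint, mirroring pre-model normalization practice.
    """
    df = table.data.copy()
    records = []
    for (trait, tp), idx in df[df["value"].notna()].groupby(["trait", "timepoint"]).groups.items():
        vals = df.loc[idx, "value"].to_numpy()
        out, rec = transforms.normalize(vals, trait=f"{trait}@{tp}", alpha=alpha)
        df.loc[idx, "value"] = out
        records.append(rec)
    return PhenotypeTable(df), records


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage; write artifacts under ``config.outdir``.

    Returns a manifest dict (also written as JSON) listing the seed, a
    hash of the configuration, and the artifact paths.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings = {}
    artifacts = {}

    def _stage(name):
        timings[name] = time.time()
        logger.info("stage %s", name)

    def _done(name):
        timings[name] = round(time.time() - timings[name], 3)

    # -- input ----------------------------------------------------------
    _stage("input")
    if config.phenotype_csv is not None:
        table = core_data.read_phenotype_table(config.phenotype_csv)
        sim_config = None
    else:
        sim_config = _preset_config(config.preset, config.seed)
        table, truth = synthetic_data.simulate_study(sim_config)
        core_data.write_phenotype_table(table, outdir / "phenotypes.csv")
        artifacts["phenotypes"] = "phenotypes.csv"
    traits = list(config.traits) if config.traits else table.traits
    _done("input")

    # -- normalization --------------------------------------------------
    _stage("normalize")
    norm_table, records = normalize_table(table, alpha=config.gate_alpha)
    with open(outdir / "transform_log.jsonl", "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")
    artifacts["transform_log"] = "transform_log.jsonl"
    _done("normalize")

    # -- heritability ----------------------------------------------------
    _stage("heritability")
    herit = heritability.heritability_table(norm_table, traits=traits)
    herit.to_csv(outdir / "heritability.csv", index=False)
    artifacts["heritability"] = "heritability.csv"
    _done("heritability")

    # -- effect sizes and health scores ---------------------------------
    _stage("effects")
    effect_sizes = effects_scores.hedges_g_table(
        table, traits=traits, sign_convention=config.sign_convention)
    eff_df = pd.DataFrame([{
        "trait": e.trait, "diet": e.diet, "g": e.g, "pooled_sd": e.pooled_sd,
        "ci_low": e.ci95[0], "ci_high": e.ci95[1], "magnitude": e.magnitude,
        "n1": e.n1, "n2": e.n2} for e in effect_sizes])
    eff_df.to_csv(outdir / "effect_sizes.csv", index=False)
    artifacts["effect_sizes"] = "effect_sizes.csv"

    score_rows = []
    risk = [t for t in DEFAULT_RISK_TRAITS if t in traits]
    if len(risk) >= 2:
        for tp in ("baseline", "postdiet"):
            for r in effects_scores.health_score(table, risk, timepoint=tp):
                score_rows.append({
                    "mouse_id": r.mouse_id, "timepoint": r.timepoint,
                    "stratum": r.stratum, "score": r.score,
                    **{f"z_{k}": v for k, v in r.component_z.items()}})
        pd.DataFrame(score_rows).to_csv(outdir / "health_scores.csv", index=False)
        artifacts["health_scores"] = "health_scores.csv"
    _done("effects")

    # -- mixed models ----------------------------------------------------
    _stage("mixed_models")
    mm_rows, vp_rows, interaction_tests = [], [], []
    for trait in traits:
        diet_t = mixed_models.test_diet_effect(norm_table, trait)
        inter_t = mixed_models.test_strain_diet_interaction(norm_table, trait)
        interaction_tests.append(inter_t)
        for t in (diet_t, inter_t):
            mm_rows.append({"trait": t.trait, "term": t.term, "F": t.F,
                            "ddf": t.ddf, "ndf": t.ndf, "p": t.p,
                            "singular": t.singular, "converged": t.converged})
        vp = mixed_models.variance_partition(norm_table, trait)
        row = {"trait": trait}
        row.update({f"var_{k}": v for k, v in vp.variances.items()})
        row.update({f"prop_{k}": v for k, v in vp.proportions.items()})
        vp_rows.append(row)
    pd.DataFrame(mm_rows).to_csv(outdir / "mixed_model_tests.csv", index=False)
    pd.DataFrame(vp_rows).to_csv(outdir / "variance_partition.csv", index=False)
    artifacts["mixed_model_tests"] = "mixed_model_tests.csv"
    artifacts["variance_partition"] = "variance_partition.csv"

    link = mixed_models.gxd_effectsize_link(
        interaction_tests, effect_sizes,
        p_thresh=config.p_thresh, g_thresh=config.g_thresh)
    with open(outdir / "gxd_link.json", "w", encoding="utf-8") as fh:
        json.dump({
            "spearman": link["spearman"],
            "table2x2": link["table2x2"].tolist(),
            "chi2_p": link["chi2_p"],
            "degenerate": link["degenerate"],
        }, fh, indent=2, sort_keys=True)
    artifacts["gxd_link"] = "gxd_link.json"
    _done("mixed_models")

    # -- calorimetry -----------------------------------------------------
    if config.run_calorimetry and sim_config is not None and sim_config.calorimetry_specs:
        _stage("calorimetry")
        series = synthetic_data.simulate_calorimetry(sim_config)
        labelled = calorimetry.label_cycles(series)
        means = calorimetry.cycle_means(labelled)
        means.drop(columns="date_means").to_csv(outdir / "cycle_means.csv", index=False)
        artifacts["cycle_means"] = "cycle_means.csv"
        dn_report = {}
        for measure in sorted(means["measure"].unique()):
            sub = means[means["measure"] == measure]
            res = calorimetry.day_night_test(
                sub["diurnal_mean"].to_numpy(), sub["nocturnal_mean"].to_numpy())
            dn_report[measure] = {
                "V": res.V, "p": res.p, "pseudomedian": res.pseudomedian,
                "ci95": list(res.ci95), "n": res.n_used, "degenerate": res.degenerate}
        with open(outdir / "day_night_tests.json", "w", encoding="utf-8") as fh:
            json.dump(dn_report, fh, indent=2, sort_keys=True)
        artifacts["day_night_tests"] = "day_night_tests.json"

        if "feed_g" in labelled.columns:
            mouse_diet = (table.data[table.data["timepoint"] == "postdiet"]
                          .drop_duplicates("mouse_id").set_index("mouse_id")["diet"])
            feed = (labelled[labelled["cycle"] != "acclimation"]
                    .groupby("mouse_id")["feed_g"].sum())
            rows = []
            for mid, grams in feed.items():
                diet = mouse_diet.get(mid)
                if diet is None or diet not in config.energy_table.entries:
                    continue
                rows.append({
                    "mouse_id": mid, "diet": diet, "feed_g": grams,
                    "energy_kcal": calorimetry.energy_intake(
                        grams, diet, config.energy_table),
                    **{f"{m}_g": calorimetry.macronutrient_intake(
                        grams, diet, m, config.energy_table)
                       for m in calorimetry.MACROS},
                })
            if rows:
                pd.DataFrame(rows).to_csv(outdir / "energy_intake.csv", index=False)
                artifacts["energy_intake"] = "energy_intake.csv"
        _done("calorimetry")

    # -- correlations ----------------------------------------------------
    _stage("correlations")
    for name, kwargs in (("baseline", {"timepoint": "baseline"}),
                         ("postdiet_HP", {"timepoint": "postdiet", "stratum": "HP"}),
                         ("postdiet_HS", {"timepoint": "postdiet", "stratum": "HS"})):
        mat = association.spearman_matrix(table, traits=traits, **kwargs)
        mat.to_long().to_csv(outdir / f"correlations_{name}.csv", index=False)
        artifacts[f"correlations_{name}"] = f"correlations_{name}.csv"
    _done("correlations")

    cfg_for_hash = asdict(replace(config, energy_table=None))
    cfg_for_hash["energy_table"] = dict(config.energy_table.entries)
    manifest = {
        "seed": config.seed,
        "preset": config.preset,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_for_hash, sort_keys=True, default=str).encode()).hexdigest(),
        "traits": traits,
        "artifacts": artifacts,
        "stage_seconds": timings,
        "total_seconds": round(time.time() - t_start, 3),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def make_fixtures(preset: str, seed: int, outdir) -> dict:
    """Write small phenotype/calorimetry CSVs plus ground truth for tests/docs."""
    cfg = _preset_config(preset, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, truth = synthetic_data.simulate_study(cfg)
    core_data.write_phenotype_table(table, outdir / "phenotypes.csv")
    series = synthetic_data.simulate_calorimetry(
        cfg, n_mice=4 if preset == "tiny" else None)
    series.to_csv(outdir / "calorimetry.csv", index=False)
    truth_json = {
        "strain_effects": truth.strain_effects,
        "diet_effects": truth.diet_effects,
        "interaction_effects": {
            t: {f"{s}:{d}": v for (s, d), v in eff.items()}
            for t, eff in truth.interaction_effects.items()},
        "batch_effects": {t: {str(k): v for k, v in eff.items()}
                          for t, eff in truth.batch_effects.items()},
        "cage_effects": truth.cage_effects,
    }
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True)
    return {"phenotypes": str(outdir / "phenotypes.csv"),
            "calorimetry": str(outdir / "calorimetry.csv"),
            "ground_truth": str(outdir / "ground_truth.json")}


# ---------------------------------------------------------------------------
# simulation-based validation experiments


def _single_trait_config(seed: int, spec: TraitSpec, a: int = 22,
                         mice=None, n_batches: int = 7) -> SimulationConfig:
    if mice is None:
        mice = synthetic_data.CC22_TRIOS if a == 22 else 3
    return SimulationConfig(seed=seed, a=a, mice_per_strain_per_diet=mice,
                            n_batches=n_batches, trait_specs={"y": spec})


def intraclass_recovery(fraction: float, n_reps: int = 200, seed: int = 0,
                        a: int = 22) -> dict:
    """Mean baseline r_I over replicate studies at a true strain-variance fraction.

    Simulates strain variance ``fraction`` and residual ``1 - fraction``
    (no batch/cage/interaction variance) on the study-shaped design and
    averages the intraclass correlation recovered by the baseline ANOVA
    estimator.
    """
    spec = TraitSpec(var_strain=fraction, var_residual=1.0 - fraction)
    estimates = np.empty(n_reps)
    ss = np.random.SeedSequence([int(seed), 914])
    rep_seeds = ss.generate_state(n_reps) >> 1  # keep below 2^31
    for r in range(n_reps):
        cfg = _single_trait_config(int(rep_seeds[r]), spec, a=a)
        table, _ = synthetic_data.simulate_study(cfg)
        anova = heritability.fit_strain_anova(table, "y", "baseline")
        n_eff = core_data.summarize_design(table, "y", "baseline").n_effective
        estimates[r] = heritability.intraclass_correlation(anova.MSB, anova.MSW, n_eff)
    return {"fraction": fraction, "mean_r_I": float(estimates.mean()),
            "sd": float(estimates.std(ddof=1)), "n_reps": n_reps}


def mixed_model_null_calibration(n_reps: int = 300, seed: int = 0, a: int = 10,
                                 mice_per_strain_per_diet: int = 8,
                                 n_batches: int = 4, alpha: float = 0.05) -> dict:
    """Type-I error of the diet and interaction Satterthwaite F tests.

    Studies are simulated with zero diet shift and zero strain-by-diet
    interaction variance (strain and cage variance retained) and both
    tests are run on each study.  The default design is reduced from the
    study preset (10 strains) but keeps generous within-cell replication
    (8 mice per strain-diet cell), the regime the Satterthwaite
    approximation needs; see the methods note for its small-sample
    behaviour at sparser designs.  Returns rejection rates at ``alpha``
    plus the raw p-value vectors.
    """
    spec = TraitSpec(var_strain=0.3, var_interaction=0.0, var_cage=0.05,
                     var_batch=0.05, var_residual=1.0)
    ss = np.random.SeedSequence([int(seed), 2718])
    rep_seeds = ss.generate_state(n_reps) >> 1
    p_diet = np.empty(n_reps)
    p_inter = np.empty(n_reps)
    for r in range(n_reps):
        cfg = _single_trait_config(int(rep_seeds[r]), spec, a=a,
                                   mice=mice_per_strain_per_diet, n_batches=n_batches)
        table, _ = synthetic_data.simulate_study(cfg)
        p_diet[r] = mixed_models.test_diet_effect(table, "y").p
        p_inter[r] = mixed_models.test_strain_diet_interaction(table, "y").p
    return {"alpha": alpha, "n_reps": n_reps,
            "diet_rejection_rate": float((p_diet < alpha).mean()),
            "interaction_rejection_rate": float((p_inter < alpha).mean()),
            "diet_p": p_diet, "interaction_p": p_inter}


def mixed_model_power(n_reps: int = 100, seed: int = 0, which: str = "diet",
                      alpha: float = 0.05) -> float:
    """Rejection rate under an effect: a 2-residual-SD diet shift, or an
    interaction variance equal to the residual variance, at study scale."""
    if which == "diet":
        spec = TraitSpec(var_strain=0.3, var_cage=0.05, var_residual=1.0,
                         diet_shift={"HS": 2.0})
    elif which == "interaction":
        spec = TraitSpec(var_strain=0.3, var_interaction=1.0, var_cage=0.05,
                         var_residual=1.0)
    else:
        raise ValueError("which must be 'diet' or 'interaction'")
    ss = np.random.SeedSequence([int(seed), 577])
    rep_seeds = ss.generate_state(n_reps) >> 1
    hits = 0
    for r in range(n_reps):
        cfg = _single_trait_config(int(rep_seeds[r]), spec)
        table, _ = synthetic_data.simulate_study(cfg)
        test = (mixed_models.test_diet_effect if which == "diet"
                else mixed_models.test_strain_diet_interaction)(table, "y")
        hits += test.p < alpha
    return hits / n_reps


def variance_partition_recovery(proportions=(0.5, 0.2, 0.1, 0.2),
                                n_reps: int = 100, seed: int = 0) -> dict:
    """Mean recovered variance proportions at the study-shaped design.

    ``proportions`` are the true (strain, diet, interaction, residual)
    shares; diet effects are drawn as a random intercept so the diet
    share is a genuine variance component.
    """
    p_strain, p_diet, p_inter, p_resid = proportions
    spec = TraitSpec(var_strain=p_strain, var_diet=p_diet,
                     var_interaction=p_inter, var_residual=p_resid)
    ss = np.random.SeedSequence([int(seed), 1414])
    rep_seeds = ss.generate_state(n_reps) >> 1
    acc = {"strain": [], "diet": [], "strain:diet": [], "residual": []}
    for r in range(n_reps):
        cfg = _single_trait_config(int(rep_seeds[r]), spec)
        table, _ = synthetic_data.simulate_study(cfg)
        vp = mixed_models.variance_partition(table, "y")
        for k in acc:
            acc[k].append(vp.proportions[k])
    return {
        "true": {"strain": p_strain, "diet": p_diet,
                 "strain:diet": p_inter, "residual": p_resid},
        "mean": {k: float(np.mean(v)) for k, v in acc.items()},
        "n_reps": n_reps,
    }


def day_night_rejection_rate(n_seeds: int = 100, seed: int = 0, n_mice: int = 20,
                             night_shift: float = 0.1, sd: float = 0.03,
                             alpha: float = 0.05) -> float:
    """Fraction of simulated calorimetry runs where the day-night RER test rejects."""
    ss = np.random.SeedSequence([int(seed), 8080])
    rep_seeds = ss.generate_state(n_seeds) >> 1
    hits = 0
    for r in range(n_seeds):
        cfg = SimulationConfig(
            seed=int(rep_seeds[r]), a=max(2, n_mice // 4),
            mice_per_strain_per_diet=2, n_batches=1,
            trait_specs={"y": TraitSpec()},
            calorimetry_specs={"rer": synthetic_data.CalorimetrySpec(
                day_mean=0.85, night_shift=night_shift, sd=sd)},
        )
        series = synthetic_data.simulate_calorimetry(cfg, n_mice=n_mice)
        labelled = calorimetry.label_cycles(series)
        means = calorimetry.cycle_means(labelled, measures=["rer"])
        res = calorimetry.day_night_test(
            means["diurnal_mean"].to_numpy(), means["nocturnal_mean"].to_numpy())
        hits += (not res.degenerate) and res.p < alpha
    return hits / n_seeds
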