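import numpy as np
import pandas as pd
import pytest

from ccdiet.core_data import DesignError, PhenotypeTable, summarize_design
from ccdiet.heritability import (
    diet_icc,
    f_from_intraclass,
    fit_strain_anova,
    genetic_determination,
    heritability_table,
    intraclass_correlation,
)
from ccdiet.synthetic_data import SimulationConfig, TraitSpec, simulate_study

from conftest import balanced_layout, make_table, one_way_table


def textbook_icc1(groups: dict[str, list[float]]) -> float:
    """Independent one-way ANOVA ICC(1) from group means (oracle path)."""
    all_vals = np.concatenate([np.asarray(v, float) for v in groups.values()])
    a = len(groups)
    n = len(next(iter(groups.values())))  # balanced
    grand = all_vals.mean()
    msb = n * sum((np.mean(v) - grand) ** 2 for v in groups.values()) / (a - 1)
    msw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values()) \
        / (a * (n - 1))
    return (msb - msw) / (msb + (n - 1) * msw)


class TestFitStrainAnova:
    def test_hand_computed_one_way_anova(self):
        table = one_way_table({"A": [1, 2, 3], "B": [4, 5, 6]})
        res = fit_strain_anova(table, "y", "baseline")
        assert res.MSB == pytest.approx(13.5, abs=1e-10)
        assert res.MSW == pytest.approx(1.0, abs=1e-10)
        assert res.F == pytest.approx(13.5, abs=1e-10)
        assert res.df_between == 1
        assert res.df_within == 4

    def test_type_i_error_with_no_strain_effect(self):
        spec = TraitSpec(var_strain=0.0, var_residual=1.0)
        rejections = 0
        n_reps = 500
        for rep in range(n_reps):
            cfg = SimulationConfig(seed=3_000 + rep, a=5, mice_per_strain_per_diet=2,
                                   n_batches=2, trait_specs={"y": spec})
            table, _ = simulate_study(cfg)
            rejections += fit_strain_anova(table, "y", "baseline").p < 0.05
        # binomial 95% interval around 0.05 with 500 draws
        lo, hi = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n_reps), \
            0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
        assert lo <= rejections / n_reps <= hi

    def test_orthogonal_batch_covariate_leaves_strain_ms_unchanged(self):
        # full factorial strain x batch: covariate orthogonal to strain
        rng = np.random.default_rng(0)
        rows = []
        i = 0
        for strain in "ABC":
            for batch in (1, 2):
                for _ in range(3):
                    rows.append({"mouse_id": f"m{i}", "strain": strain,
                                 "batch": batch, "value": float(rng.normal())})
                    i += 1
        with_batch = fit_strain_anova(make_table(rows), "y", "baseline")
        no_batch = make_table([{**r, "batch": 1} for r in rows])
        without = fit_strain_anova(no_batch, "y", "baseline")
        assert with_batch.MSB == pytest.approx(without.MSB, abs=1e-8)

    def test_aliased_batch_is_confounding_error(self):
        # every strain entirely inside its own batch
        rows = []
        i = 0
        for batch, strain in enumerate("ABC", start=1):
            for _ in range(3):
                rows.append({"mouse_id": f"m{i}", "strain": strain, "batch": batch,
                             "value": float(i)})
                i += 1
        with pytest.raises(DesignError, match="alias|rank"):
            fit_strain_anova(make_table(rows), "y", "baseline")

    def test_unknown_variant_rejected(self, cc22_table):
        table, _ = cc22_table
        with pytest.raises(ValueError):
            fit_strain_anova(table, "body_fat_pct", "bogus")


class TestEstimators:
    def test_equal_mean_squares_give_exact_zero(self):
        assert intraclass_correlation(2.0, 2.0, 5.0) == 0.0
        assert genetic_determination(2.0, 2.0, 5.0) == 0.0

    def test_hand_computed_values(self):
        assert intraclass_correlation(13.5, 1.0, 3.0) == pytest.approx(12.5 / 15.5)
        assert genetic_determination(13.5, 1.0, 3.0) == pytest.approx(12.5 / 18.5)

    def test_vanishing_msw_limit_is_one(self):
        assert intraclass_correlation(1.0, 1e-12, 3.0) == pytest.approx(1.0, abs=1e-9)

    def test_g2_below_r_i_for_heritable_traits(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            msb = rng.uniform(1, 10)
            msw = rng.uniform(0.01, msb)  # MSB > MSW
            n = rng.uniform(2, 12)
            assert genetic_determination(msb, msw, n) < intraclass_correlation(msb, msw, n)

    def test_negative_estimates_not_truncated(self):
        assert intraclass_correlation(0.5, 1.0, 4.0) < 0

    def test_f_inversion_round_trip(self):
        for f in (1.5, 5.0, 12.44):
            r = (f - 1) / (f + 8.26)  # n_eff = 9.26
            assert f_from_intraclass(r, 9.26) == pytest.approx(f, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            intraclass_correlation(1.0, 0.0, 3.0)
        with pytest.raises(ValueError):
            genetic_determination(1.0, 1.0, 1.0)


class TestOracleEquivalence:
    def test_matches_textbook_icc1_on_balanced_layouts(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            table, groups = balanced_layout(rng, a=6, n=4)
            res = fit_strain_anova(table, "y", "baseline")
            r_i = intraclass_correlation(res.MSB, res.MSW, 4.0)
            assert r_i == pytest.approx(textbook_icc1(groups), abs=1e-10)

    def test_affine_invariance_of_r_i_and_g2(self, cc22_table):
        table, _ = cc22_table
        res = fit_strain_anova(table, "body_fat_pct", "baseline")
        n_eff = summarize_design(table, "body_fat_pct", "baseline").n_effective
        r1 = intraclass_correlation(res.MSB, res.MSW, n_eff)
        df = table.data.copy()
        df["value"] = 3.7 * df["value"] - 11.0
        res2 = fit_strain_anova(PhenotypeTable(df), "body_fat_pct", "baseline")
        r2 = intraclass_correlation(res2.MSB, res2.MSW, n_eff)
        assert r1 == pytest.approx(r2, abs=1e-10)
        g1 = genetic_determination(res.MSB, res.MSW, n_eff)
        g2 = genetic_determination(res2.MSB, res2.MSW, n_eff)
        assert g1 == pytest.approx(g2, abs=1e-10)


class TestDietICC:
    def test_identical_diet_groups_give_zero(self):
        # both diets see the exact same values: diet explains nothing
        rows = []
        i = 0
        for diet in ("HP", "HS"):
            for strain, vals in (("A", [1.0, 2.0, 3.0]), ("B", [4.0, 5.0, 6.0])):
                for v in vals:
                    rows.append({"mouse_id": f"m{i}", "strain": strain, "diet": diet,
                                 "timepoint": "postdiet", "value": v})
                    i += 1
        icc = diet_icc(make_table(rows), "y")
        assert icc <= 0 or icc == pytest.approx(0.0, abs=1e-10)

    def test_null_diet_shift_gives_near_zero_mean(self):
        spec = TraitSpec(var_strain=0.5, var_residual=0.5)
        iccs = []
        for rep in range(200):
            cfg = SimulationConfig(seed=6_000 + rep, a=6, mice_per_strain_per_diet=3,
                                   n_batches=2, trait_specs={"y": spec})
            table, _ = simulate_study(cfg)
            iccs.append(diet_icc(table, "y"))
        assert abs(np.mean(iccs)) < 0.02

    def test_dominant_diet_shift_approaches_one(self):
        spec = TraitSpec(var_strain=0.01, var_residual=0.01,
                         diet_shift={"HP": 0.0, "HS": 10.0})
        cfg = SimulationConfig(seed=1, a=6, mice_per_strain_per_diet=4,
                               n_batches=2, trait_specs={"y": spec})
        table, _ = simulate_study(cfg)
        assert diet_icc(table, "y") > 0.95

    def test_single_diet_is_design_error(self):
        rows = [{"mouse_id": f"m{i}", "strain": s, "diet": "HP",
                 "timepoint": "postdiet", "value": float(i)}
                for i, s in enumerate("AABB")]
        with pytest.raises(DesignError):
            diet_icc(make_table(rows), "y")


class TestHeritabilityTable:
    def test_variant_bookkeeping_on_study_table(self, cc22_table):
        table, _ = cc22_table
        out = heritability_table(table, traits=["body_fat_pct"])
        assert set(out["variant"]) == {"baseline", "full", "partial", "HP", "HS"}
        by_variant = out.set_index("variant")
        # single-diet variants model half the mice
        assert by_variant.loc["HP", "df_within"] < by_variant.loc["full", "df_within"]
        n_full = by_variant.loc["full", "n_effective"]
        n_hp = by_variant.loc["HP", "n_effective"]
        assert n_hp < n_full
        # diet ICC only attached to the full variant
        assert np.isfinite(by_variant.loc["full", "diet_icc"])
        assert np.isnan(by_variant.loc["baseline", "diet_icc"])

    def test_null_trait_has_small_r_i_everywhere(self):
        spec = TraitSpec(var_strain=0.0, var_residual=1.0)
        cfg = SimulationConfig(seed=8, a=10, mice_per_strain_per_diet=4,
                               n_batches=2, trait_specs={"y": spec})
        table, _ = simulate_study(cfg)
        out = heritability_table(table, traits=["y"])
        assert (out["r_I"].abs() < 0.35).all()
        assert (out["g2"].abs() <= out["r_I"].abs() + 1e-12).all()
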