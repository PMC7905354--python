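import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccdiet.calorimetry import (
    DietEnergyTable,
    EXAMPLE_HP_PROTEIN_FRACTION,
    cycle_means,
    day_night_test,
    energy_intake,
    label_cycles,
    macronutrient_intake,
    total_activity,
)
from ccdiet.pipeline import day_night_rejection_rate
from ccdiet.synthetic_data import simulate_calorimetry, tiny_config


def series_at(clock_hours, mouse="m1", value=1.0, start="2020-01-01"):
    base = pd.Timestamp(start)
    return pd.DataFrame({
        "mouse_id": mouse,
        "timestamp": [base + pd.Timedelta(hours=h) for h in clock_hours],
        "rer": value,
    })


ENERGY = DietEnergyTable({
    "HP": {"kcal_per_g": 4.1, "protein_g_per_g": EXAMPLE_HP_PROTEIN_FRACTION,
           "carbohydrate_g_per_g": 0.41, "fat_g_per_g": 0.09},
})


class TestLabelCycles:
    def test_half_open_light_window_boundaries(self):
        # lights on at 6:00, off at 18:00; acclimation disabled
        s = series_at([6.0, 17.99, 18.0, 23.0, 31.0])
        out = label_cycles(s, acclimation_hours=0.0)
        assert list(out["cycle"]) == ["light", "light", "dark", "dark", "light"]

    def test_acclimation_window_flagged_first(self):
        s = series_at(np.arange(0, 12.0, 1.0))
        out = label_cycles(s, acclimation_hours=8.0)
        assert (out["cycle"][:8] == "acclimation").all()
        assert (out["cycle"][8:] != "acclimation").all()

    def test_unsorted_timestamps_rejected(self):
        s = series_at([5.0, 3.0, 7.0])
        with pytest.raises(ValueError, match="sorted"):
            label_cycles(s)

    def test_simulated_run_has_68_records_before_trimming(self):
        series = simulate_calorimetry(tiny_config(0), total_hours=48.0,
                                      sampling_minutes=42, n_mice=1)
        out = label_cycles(series)
        assert len(out) == 68
        assert (out["cycle"] == "acclimation").sum() == 12  # ceil(8h / 42min)


class TestCycleMeans:
    def test_constant_series_has_equal_cycle_means(self):
        s = series_at(np.arange(0, 48, 0.7), value=0.9)
        out = cycle_means(label_cycles(s), measures=["rer"])
        assert out.loc[0, "diurnal_mean"] == pytest.approx(0.9)
        assert out.loc[0, "nocturnal_mean"] == pytest.approx(0.9)

    def test_acclimation_points_do_not_affect_means(self):
        s1 = series_at(np.arange(0, 48, 0.7), value=1.0)
        s2 = s1.copy()
        first8 = (s2["timestamp"] - s2["timestamp"].min()).dt.total_seconds() < 8 * 3600
        s2.loc[first8, "rer"] = 99.0
        m1 = cycle_means(label_cycles(s1), measures=["rer"])
        m2 = cycle_means(label_cycles(s2), measures=["rer"])
        assert m1.loc[0, "diurnal_mean"] == m2.loc[0, "diurnal_mean"]
        assert m1.loc[0, "nocturnal_mean"] == m2.loc[0, "nocturnal_mean"]

    def test_record_order_does_not_matter(self):
        rng = np.random.default_rng(0)
        s = series_at(np.arange(0, 48, 0.7))
        s["rer"] = rng.uniform(0.7, 1.0, len(s))
        labelled = label_cycles(s)
        shuffled = labelled.sample(frac=1.0, random_state=1)
        m1 = cycle_means(labelled, measures=["rer"])
        m2 = cycle_means(shuffled, measures=["rer"])
        assert m1.loc[0, "diurnal_mean"] == pytest.approx(m2.loc[0, "diurnal_mean"])
        assert m1.loc[0, "nocturnal_mean"] == pytest.approx(m2.loc[0, "nocturnal_mean"])

    def test_night_shift_recovered_in_cycle_means(self):
        from ccdiet.synthetic_data import CalorimetrySpec, SimulationConfig, TraitSpec

        cfg = SimulationConfig(seed=3, a=2, mice_per_strain_per_diet=2, n_batches=1,
                               trait_specs={"y": TraitSpec()},
                               calorimetry_specs={"rer": CalorimetrySpec(
                                   day_mean=0.8, night_shift=5.0, sd=0.01)})
        series = simulate_calorimetry(cfg, n_mice=4)
        means = cycle_means(label_cycles(series), measures=["rer"])
        gap = means["nocturnal_mean"] - means["diurnal_mean"]
        assert np.allclose(gap, 5.0, atol=0.05)

    def test_empty_cycle_is_flagged(self):
        s = series_at([1.0, 2.0, 3.0])  # all inside acclimation window
        s2 = series_at([9.0, 10.0], mouse="m2")  # light only after acclim start 9h?
        out = cycle_means(label_cycles(pd.concat([s, s2]), acclimation_hours=0.0),
                          measures=["rer"])
        # m1 has only dark points (1-3 am), m2 only light
        m1 = out[out["mouse_id"] == "m1"].iloc[0]
        assert m1["empty_cycle"]
        assert np.isnan(m1["diurnal_mean"])


class TestIntakeArithmetic:
    def test_energy_intake_values_and_linearity(self):
        assert energy_intake(0.0, "HP", ENERGY) == 0.0
        assert energy_intake(2.0, "HP", ENERGY) == pytest.approx(8.2)
        a, b = 1.3, 2.9
        assert energy_intake(a + b, "HP", ENERGY) == pytest.approx(
            energy_intake(a, "HP", ENERGY) + energy_intake(b, "HP", ENERGY))

    def test_protein_fraction_example(self):
        # 1 g of high-protein feed carries 40.6/90.3 g protein
        got = macronutrient_intake(1.0, "HP", "protein", ENERGY)
        assert got == pytest.approx(0.4496, abs=5e-5)

    def test_fractions_sum_below_one(self):
        total = sum(ENERGY.fraction("HP", m)
                    for m in ("protein", "carbohydrate", "fat"))
        assert total <= 1.0

    def test_unknown_diet_and_macro_rejected(self):
        with pytest.raises(KeyError):
            energy_intake(1.0, "CHOW", ENERGY)
        with pytest.raises(ValueError):
            macronutrient_intake(1.0, "HP", "fiber", ENERGY)

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValueError):
            DietEnergyTable({"X": {"kcal_per_g": 4, "protein_g_per_g": 1.2,
                                   "carbohydrate_g_per_g": 0, "fat_g_per_g": 0}})


class TestTotalActivity:
    def test_sum_and_rearing(self):
        out = total_activity([1], [2], [3])
        assert out["total"][0] == 6
        assert out["rearing"][0] == 3

    def test_zero_counts(self):
        out = total_activity([0], [0], [0])
        assert out["total"][0] == 0 and out["rearing"][0] == 0

    def test_xy_permutation_preserves_total(self):
        a = total_activity([5], [9], [2])
        b = total_activity([9], [5], [2])
        assert a["total"][0] == b["total"][0]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            total_activity([-1], [0], [0])


def exact_wilcoxon_p(d):
    """Brute-force two-sided paired signed-rank p over all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws, float)
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestDayNightTest:
    def test_all_equal_pairs_is_degenerate(self):
        res = day_night_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert np.isnan(res.p)

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(0)
        day = rng.normal(0.85, 0.02, 30)
        night = day + 0.1
        res = day_night_test(day, night)
        assert res.p < 0.01
        assert res.pseudomedian == pytest.approx(0.1, abs=1e-9)
        assert res.ci95[0] <= res.pseudomedian <= res.ci95[1]

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_matches_exact_enumeration_at_small_n(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            day = rng.normal(size=n)
            night = day + rng.normal(0.3, 1.0, n)
            res = day_night_test(day, night)
            assert res.p == pytest.approx(exact_wilcoxon_p(night - day), abs=1e-10)

    def test_ci_frozen_against_reference_implementation(self):
        # R: wilcox.test(night, day, paired=TRUE, conf.int=TRUE) on these data
        day = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        night = day + np.array([0.5, 0.8, -0.1, 0.9, 0.4, 0.7, 0.2, 1.1])
        res = day_night_test(day, night)
        assert res.p == pytest.approx(0.015625, abs=1e-10)
        assert res.pseudomedian == pytest.approx(0.575, abs=1e-9)
        assert res.ci95[0] == pytest.approx(0.2, abs=1e-9)
        assert res.ci95[1] == pytest.approx(0.9, abs=1e-9)

    def test_power_with_simulated_night_shift(self):
        rate = day_night_rejection_rate(n_seeds=100, seed=0, n_mice=20,
                                        night_shift=0.1, sd=0.03)
        assert rate >= 0.95

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            day_night_test([1.0, 2.0], [1.0])
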