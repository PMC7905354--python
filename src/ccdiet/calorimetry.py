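"""Indirect-calorimetry post-processing.

Cycle labelling (light/dark with an initial acclimation window),
diurnal/nocturnal means per mouse, energy and macronutrient intake
arithmetic, activity aggregation from beam-break counts, and the paired
day-night Wilcoxon signed-rank test with a Hodges-Lehmann
pseudo-median confidence interval.

Heat production values are consumed as exported by the instrument
software (total-mass and lean-adjusted kcal/h/kg); they are never
recomputed from gas exchange here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "MEASURE_COLUMNS",
    "RER_PLAUSIBLE",
    "DietEnergyTable",
    "DayNightResult",
    "label_cycles",
    "cycle_means",
    "energy_intake",
    "macronutrient_intake",
    "total_activity",
    "day_night_test",
]

MEASURE_COLUMNS = ("heat_total", "heat_lean", "rer", "feed_g", "water_g",
                   "beams_x", "beams_y", "beams_z")
RER_PLAUSIBLE = (0.6, 1.3)
EXACT_WILCOXON_MAX_N = 25

MACROS = ("protein", "carbohydrate", "fat")


@dataclass(frozen=True)
class DietEnergyTable:
    """Energy density and macronutrient gram fractions per diet.

    ``kcal_per_g`` converts feed grams to kcal; the gram fractions are
    grams of macronutrient per gram of feed (e.g. the high-protein
    example 40.6 g protein per 90.3 g feed).
    """

    entries: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for diet, row in self.entries.items():
            fracs = [row.get(f"{m}_g_per_g", 0.0) for m in MACROS]
            if any(f < 0 or f > 1 for f in fracs):
                raise ValueError(f"diet {diet!r}: macronutrient fractions must be in [0, 1]")
            if sum(fracs) > 1 + 1e-9:
                raise ValueError(f"diet {diet!r}: macronutrient fractions sum above 1")

    def kcal_per_g(self, diet: str) -> float:
        try:
            return float(self.entries[diet]["kcal_per_g"])
        except KeyError:
            raise KeyError(f"diet {diet!r} not in energy table") from None

    def fraction(self, diet: str, macro: str) -> float:
        if macro not in MACROS:
            raise ValueError(f"unknown macronutrient {macro!r}; expected one of {MACROS}")
        if diet not in self.entries:
            raise KeyError(f"diet {diet!r} not in energy table")
        return float(self.entries[diet][f"{macro}_g_per_g"])

    @classmethod
    def from_yaml(cls, path) -> "DietEnergyTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))


#: shipped example: high-protein feed with 40.6 g protein per 90.3 g feed.
#: All other values are study-specific and must be configured by the user.
EXAMPLE_HP_PROTEIN_FRACTION = 40.6 / 90.3


def label_cycles(records: pd.DataFrame, lights_on: float = 6.0,
                 lights_off: float = 18.0, acclimation_hours: float = 8.0
                 ) -> pd.DataFrame:
    """Attach a ``cycle`` column: acclimation, then light/dark by clock time.

    The first ``acclimation_hours`` of each mouse's series are flagged
    ``acclimation`` and excluded from all downstream means.  The light
    window is half-open, ``[lights_on, lights_off)``, so a timestamp at
    exactly lights-on is light and one at exactly lights-off is dark.
    Also logs (does not drop) RER values outside the plausibility band.
    """
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if (df.groupby("mouse_id")["timestamp"].apply(
            lambda s: not s.is_monotonic_increasing)).any():
        raise ValueError("timestamps must be sorted within each mouse")

    start = df.groupby("mouse_id")["timestamp"].transform("min")
    elapsed_h = (df["timestamp"] - start).dt.total_seconds() / 3600.0
    clock = (df["timestamp"].dt.hour + df["timestamp"].dt.minute / 60.0
             + df["timestamp"].dt.second / 3600.0)
    is_light = (clock >= lights_on) & (clock < lights_off)
    df["cycle"] = np.where(elapsed_h < acclimation_hours, "acclimation",
                           np.where(is_light, "light", "dark"))
    if "rer" in df.columns:
        lo, hi = RER_PLAUSIBLE
        n_bad = int(((df["rer"] < lo) | (df["rer"] > hi)).sum())
        if n_bad:
            import logging
            logging.getLogger(__name__).warning(
                "%d RER values outside plausibility band [%.2f, %.2f]", n_bad, lo, hi)
    return df


def cycle_means(records: pd.DataFrame, measures=None) -> pd.DataFrame:
    """Per-mouse diurnal and nocturnal means, plus per-date means.

    Acclimation points are excluded.  Returns a long frame with columns
    ``mouse_id, measure, diurnal_mean, nocturnal_mean`` and one wide
    ``date_means`` mapping per row; mice with an empty cycle get NaN
    for that cycle's mean.
    """
    if "cycle" not in records.columns:
        raise ValueError("records must be labelled with label_cycles first")
    df = records[records["cycle"] != "acclimation"].copy()
    if measures is None:
        measures = [c for c in MEASURE_COLUMNS if c in df.columns]
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date.astype(str)

    rows = []
    for mid, sub in df.groupby("mouse_id"):
        for measure in measures:
            light = sub.loc[sub["cycle"] == "light", measure]
            dark = sub.loc[sub["cycle"] == "dark", measure]
            by_date = sub.groupby("date")[measure].mean().to_dict()
            rows.append({
                "mouse_id": mid,
                "measure": measure,
                "diurnal_mean": float(light.mean()) if len(light) else np.nan,
                "nocturnal_mean": float(dark.mean()) if len(dark) else np.nan,
                "date_means": by_date,
                "empty_cycle": (len(light) == 0) or (len(dark) == 0),
            })
    return pd.DataFrame(rows)


def energy_intake(feed_g: float, diet: str, energy_table: DietEnergyTable) -> float:
    """kcal consumed: feed grams times the diet's energy density."""
    if feed_g < 0:
        raise ValueError("feed consumption cannot be negative")
    return feed_g * energy_table.kcal_per_g(diet)


def macronutrient_intake(feed_g: float, diet: str, macro: str,
                         energy_table: DietEnergyTable) -> float:
    """Grams of macronutrient consumed: feed grams times the gram fraction."""
    if feed_g < 0:
        raise ValueError("feed consumption cannot be negative")
    return feed_g * energy_table.fraction(diet, macro)


def total_activity(beams_x, beams_y, beams_z) -> dict:
    """Total activity = x + y + z beam breaks; rearing = z-axis breaks."""
    x = np.asarray(beams_x, dtype=float)
    y = np.asarray(beams_y, dtype=float)
    z = np.asarray(beams_z, dtype=float)
    if (x < 0).any() or (y < 0).any() or (z < 0).any():
        raise ValueError("beam-break counts cannot be negative")
    return {"total": x + y + z, "rearing": z}


@dataclass(frozen=True)
class DayNightResult:
    """Paired Wilcoxon signed-rank result for a day-vs-night comparison."""

    V: float
    p: float
    pseudomedian: float
    ci95: tuple[float, float]
    n_used: int
    degenerate: bool = False


def _signed_rank_cdf_table(n: int) -> np.ndarray:
    """Exact null pmf support of the signed-rank statistic W+ for n pairs."""
    # polynomial product: prod_k (1 + x^k) / 2^n
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[:-k].copy()
    return counts / counts.sum()


def _signed_rank_quantile(n: int, alpha: float) -> int:
    """Largest w with P(W+ <= w) <= alpha/2 under the exact null."""
    pmf = _signed_rank_cdf_table(n)
    cdf = np.cumsum(pmf)
    idx = np.searchsorted(cdf, alpha / 2.0, side="right") - 1
    return max(int(idx), 0)


def _walsh_averages(d: np.ndarray) -> np.ndarray:
    pairs = [(d[i] + d[j]) / 2.0 for i, j in
             itertools.combinations_with_replacement(range(len(d)), 2)]
    return np.sort(np.asarray(pairs))


def day_night_test(day_means, night_means, conf_level: float = 0.95) -> DayNightResult:
    """Two-sided paired Wilcoxon signed-rank test of night vs day means.

    Differences are ``night - day``; zero differences are dropped before
    ranking.  The p-value is exact for up to 25 non-zero pairs (ties
    permitting), otherwise a normal approximation with continuity
    correction.  The point estimate and CI are the Hodges-Lehmann
    pseudo-median of the differences with signed-rank-inverted bounds,
    matching the conventional paired Wilcoxon report.
    """
    day = np.asarray(day_means, dtype=float)
    night = np.asarray(night_means, dtype=float)
    if day.shape != night.shape:
        raise ValueError("day and night vectors must be paired (equal length)")
    keep = ~(np.isnan(day) | np.isnan(night))
    d = (night - day)[keep]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return DayNightResult(np.nan, np.nan, 0.0, (np.nan, np.nan), 0, degenerate=True)

    has_ties = len(np.unique(np.abs(d))) < n
    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = stats.wilcoxon(d, correction=True, method="exact")
    else:
        res = stats.wilcoxon(d, correction=True, method="approx")

    walsh = _walsh_averages(d)
    pseudomedian = float(np.median(walsh))
    alpha = 1.0 - conf_level
    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        k = _signed_rank_quantile(n, alpha)
    else:
        mu = n * (n + 1) / 4.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        k = int(np.floor(mu + stats.norm.ppf(alpha / 2.0) * sigma))
        k = max(k, 0)
    m = len(walsh)
    lo = walsh[k] if k < m else walsh[0]
    hi = walsh[m - 1 - k] if k < m else walsh[-1]
    return DayNightResult(float(res.statistic), float(res.pvalue),
                          pseudomedian, (float(lo), float(hi)), n)
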