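"""Diet effect sizes (Hedges' g) and the composite metabolic health score.

Hedges' g standardizes the baseline-to-post-diet mean difference by the
sample-size-weighted pooled SD and applies the small-sample bias
correction J = 1 - 3/(4(n1+n2) - 9).  The sign convention is
positive = phenotype increased post-diet relative to baseline (a
``baseline_minus_post`` convention is exposed for the reversed
formula reading).

The metabolic health score is the negated sum of within-stratum Z
scores over six metabolic risk factors (glucose, insulin,
glucose/insulin ratio, cholesterol, TG, body fat %): lower score, worse
metabolic health.  The baseline stratum is all baseline mice; post-diet
mice are standardized within their own diet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import BASELINE_DIET, DEFAULT_RISK_TRAITS, PhenotypeTable
from .transforms import DegenerateInputError, zscore

__all__ = [
    "MAGNITUDE_CUTOFFS",
    "EffectSizeResult",
    "HealthScoreResult",
    "pooled_sd",
    "hedges_g",
    "hedges_g_table",
    "classify_magnitude",
    "health_score",
]

#: |g| cut-offs: negligible < 0.2 <= small < 0.5 <= medium < 0.8 <= large
MAGNITUDE_CUTOFFS = (0.2, 0.5, 0.8)
MAGNITUDE_LABELS = ("negligible", "small", "medium", "large")


@dataclass(frozen=True)
class EffectSizeResult:
    trait: str
    diet: str
    g: float
    pooled_sd: float
    ci95: tuple[float, float]
    magnitude: str
    n1: int
    n2: int


@dataclass(frozen=True)
class HealthScoreResult:
    mouse_id: str
    timepoint: str
    stratum: str
    score: float
    component_z: dict[str, float]


def pooled_sd(sd1: float, n1: int, sd2: float, n2: int) -> float:
    """Sample-size-weighted pooled SD:
    sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1 + n2 - 2))."""
    if n1 + n2 <= 2:
        raise ValueError("need n1 + n2 > 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    if sd1 == 0 and sd2 == 0:
        raise DegenerateInputError("both group SDs are zero")
    return float(np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)))


def classify_magnitude(g: float) -> str:
    """Magnitude label for |g| with boundaries assigned upward."""
    if not np.isfinite(g):
        raise ValueError("g must be finite")
    a = abs(g)
    for cut, label in zip(MAGNITUDE_CUTOFFS, MAGNITUDE_LABELS):
        if a < cut:
            return label
    return MAGNITUDE_LABELS[-1]


def hedges_g(baseline, postdiet, trait: str = "", diet: str = "",
             sign_convention: str = "post_minus_baseline") -> EffectSizeResult:
    """Bias-corrected standardized mean difference between two groups.

    ``g = J (mean(post) - mean(baseline)) / pooled_sd`` with
    ``J = 1 - 3/(4(n1+n2) - 9)``; the 95% CI uses the large-sample
    variance ``(n1+n2)/(n1 n2) + g^2/(2(n1+n2))``.  NaNs are dropped
    per group.
    """
    x1 = np.asarray(baseline, dtype=float)
    x2 = np.asarray(postdiet, dtype=float)
    x1, x2 = x1[~np.isnan(x1)], x2[~np.isnan(x2)]
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    sd_p = pooled_sd(x1.std(ddof=1), n1, x2.std(ddof=1), n2)
    diff = x2.mean() - x1.mean()
    if sign_convention == "baseline_minus_post":
        diff = -diff
    elif sign_convention != "post_minus_baseline":
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = J * diff / sd_p
    se = float(np.sqrt((n1 + n2) / (n1 * n2) + g ** 2 / (2.0 * (n1 + n2))))
    ci = (g - 1.959963984540054 * se, g + 1.959963984540054 * se)
    return EffectSizeResult(trait, diet, float(g), sd_p, ci,
                            classify_magnitude(g), n1, n2)


def hedges_g_table(table: PhenotypeTable, traits: Sequence[str] | None = None,
                   sign_convention: str = "post_minus_baseline"
                   ) -> list[EffectSizeResult]:
    """Hedges' g for every trait x experimental diet, baseline as reference.

    For each diet, the baseline group is the baseline measurement of
    the mice later assigned to that diet (the study compares each diet
    arm to its own baseline values).
    """
    traits = list(traits) if traits is not None else table.traits
    post = table.data[(table.data["timepoint"] == "postdiet")]
    results = []
    for trait in traits:
        base_df = table.trait_values(trait, "baseline")
        for diet in sorted(post["diet"].unique()):
            mice = post.loc[post["diet"] == diet, "mouse_id"].unique()
            base_vals = base_df.loc[base_df["mouse_id"].isin(mice), "value"]
            post_vals = table.trait_values(trait, "postdiet", diet=diet)["value"]
            if len(base_vals) < 2 or len(post_vals) < 2:
                continue
            results.append(hedges_g(base_vals, post_vals, trait, diet,
                                    sign_convention=sign_convention))
    return results


def health_score(table: PhenotypeTable,
                 risk_traits: Sequence[str] = DEFAULT_RISK_TRAITS,
                 timepoint: str = "baseline") -> list[HealthScoreResult]:
    """Composite metabolic health score per mouse at one timepoint.

    Each risk trait is Z-scored within its stratum — all mice at
    baseline, mice of the same diet post-diet — and the score is the
    negated sum of the component Z scores, so below-average risk-factor
    levels yield a positive (healthier) score.  Mice missing any
    component are dropped from scoring.
    """
    df = table.subset(timepoint=timepoint)
    df = df[df["trait"].isin(risk_traits) & df["value"].notna()]
    if df.empty:
        raise ValueError(f"no risk-trait data at timepoint {timepoint!r}")
    strata = ["__all__"] if timepoint == "baseline" else sorted(df["diet"].unique())

    results: list[HealthScoreResult] = []
    for stratum in strata:
        sub = df if stratum == "__all__" else df[df["diet"] == stratum]
        wide = sub.pivot(index="mouse_id", columns="trait", values="value")
        missing_traits = [t for t in risk_traits if t not in wide.columns]
        if missing_traits:
            raise ValueError(f"risk traits absent at {timepoint!r}: {missing_traits}")
        wide = wide[list(risk_traits)]
        complete = wide.dropna()
        z = pd.DataFrame(
            {t: zscore(complete[t].to_numpy(), complete[t].to_numpy())
             for t in risk_traits},
            index=complete.index,
        )
        scores = -z.sum(axis=1)
        label = "all_baseline" if stratum == "__all__" else stratum
        for mid in complete.index:
            results.append(HealthScoreResult(
                mouse_id=str(mid), timepoint=timepoint, stratum=label,
                score=float(scores.loc[mid]),
                component_z={t: float(z.loc[mid, t]) for t in risk_traits},
            ))
    return results
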