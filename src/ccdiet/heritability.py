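"""Strain ANOVA and broad-sense heritability estimators for inbred panels.

For an inbred strain panel, every mouse of a strain is a genetic
replicate, so the between-strain spread of a trait relative to the
within-strain spread measures broad-sense heritability.  From the
between- and within-strain mean squares (MSB, MSW) of a linear model and
the unequal-group effective sample size ``n``:

    r_I = (MSB - MSW) / (MSB + (n - 1)  MSW)   intraclass correlation
    g2  = (MSB - MSW) / (MSB + (2n - 1) MSW)   coefficient of genetic
                                               determination (additive
                                               variance doubles under
                                               inbreeding)

Five model variants are supported: ``baseline`` (strain + week at
baseline), and post-diet ``full`` (strain + diet + week), ``partial``
(strain + week), ``HP`` and ``HS`` (strain + week within one diet).
Mean squares are sequential (type-I) with covariates entered before
strain, so MSB is the strain-after-covariates mean square.  The same
full model's diet term feeds the diet intraclass correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .core_data import DesignError, PhenotypeTable, effective_n

__all__ = [
    "VARIANTS",
    "AnovaDecomposition",
    "HeritabilityEstimate",
    "fit_strain_anova",
    "intraclass_correlation",
    "genetic_determination",
    "f_from_intraclass",
    "diet_icc",
    "heritability_table",
]

#: model variant -> (timepoint, diet filter, covariate terms before strain)
VARIANTS = {
    "baseline": ("baseline", None, ("C(batch)",)),
    "full": ("postdiet", None, ("C(batch)", "C(diet)")),
    "partial": ("postdiet", None, ("C(batch)",)),
    "HP": ("postdiet", "HP", ("C(batch)",)),
    "HS": ("postdiet", "HS", ("C(batch)",)),
}


@dataclass(frozen=True)
class AnovaDecomposition:
    """Sequential ANOVA mean squares for one trait under one model variant."""

    trait: str
    variant: str
    MSB: float
    MSW: float
    df_between: int
    df_within: int
    F: float
    p: float

    @property
    def table_row(self) -> dict:
        return {
            "trait": self.trait, "variant": self.variant, "MSB": self.MSB,
            "MSW": self.MSW, "df_between": self.df_between,
            "df_within": self.df_within, "F": self.F, "p": self.p,
        }


@dataclass(frozen=True)
class HeritabilityEstimate:
    trait: str
    variant: str
    r_I: float
    g2: float
    n_effective: float
    negative: bool = False


def _variant_frame(table: PhenotypeTable, trait: str, variant: str) -> pd.DataFrame:
    try:
        timepoint, diet, _ = VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown model variant {variant!r}") from None
    df = table.trait_values(trait, timepoint, diet=diet)
    if df["strain"].nunique() < 2:
        raise DesignError(f"trait {trait!r} ({variant}): need >=2 strains with data")
    return df


def _check_estimable(df: pd.DataFrame, formula: str, terms) -> None:
    X = patsy.dmatrix(" + ".join(terms), df)
    if np.linalg.matrix_rank(np.asarray(X)) < X.shape[1]:
        raise DesignError(f"aliased model terms {terms}: rank-deficient design")


def fit_strain_anova(table: PhenotypeTable, trait: str, variant: str = "baseline",
                     values: np.ndarray | None = None) -> AnovaDecomposition:
    """Sequential ANOVA of one trait; MSB is the strain-after-covariates term.

    Covariates (week/batch, and diet in the full model) enter before
    strain, so the strain mean square is adjusted for them; MSW is the
    residual mean square of the same model.  ``values`` optionally
    substitutes a transformed version of the trait vector (row-aligned
    with the variant's complete-case frame).
    """
    df = _variant_frame(table, trait, variant).copy()
    if values is not None:
        df["value"] = np.asarray(values, dtype=float)
    _, _, covariates = VARIANTS[variant]
    # drop covariates with a single observed level (e.g. single-batch subsets)
    active = [c for c in covariates
              if df[c.split("(")[1].rstrip(")")].nunique() > 1]
    terms = list(active) + ["C(strain)"]
    _check_estimable(df, "value", terms)
    model = smf.ols("value ~ " + " + ".join(terms), data=df).fit()
    tab = anova_lm(model, typ=1)
    strain_row = tab.loc["C(strain)"]
    resid_row = tab.loc["Residual"]
    return AnovaDecomposition(
        trait=trait, variant=variant,
        MSB=float(strain_row["sum_sq"] / strain_row["df"]),
        MSW=float(resid_row["sum_sq"] / resid_row["df"]),
        df_between=int(strain_row["df"]), df_within=int(resid_row["df"]),
        F=float(strain_row["F"]), p=float(strain_row["PR(>F)"]),
    )


def intraclass_correlation(MSB: float, MSW: float, n_effective: float) -> float:
    """r_I = (MSB - MSW) / (MSB + (n - 1) MSW); negative values not truncated."""
    if MSW <= 0:
        raise ValueError("MSW must be positive")
    if n_effective <= 1:
        raise ValueError("effective n must exceed 1")
    return (MSB - MSW) / (MSB + (n_effective - 1) * MSW)


def genetic_determination(MSB: float, MSW: float, n_effective: float) -> float:
    """g2 = (MSB - MSW) / (MSB + (2n - 1) MSW); the inbred-panel estimator."""
    if MSW <= 0:
        raise ValueError("MSW must be positive")
    if n_effective <= 1:
        raise ValueError("effective n must exceed 1")
    return (MSB - MSW) / (MSB + (2 * n_effective - 1) * MSW)


def f_from_intraclass(r_I: float, n_effective: float) -> float:
    """Invert the intraclass correlation back to the strain F ratio.

    From r_I = (F - 1)/(F + n - 1) (dividing the r_I formula through by
    MSW): F = (1 + (n - 1) r_I) / (1 - r_I).  Useful for consistency
    checks against reported F statistics.
    """
    if r_I >= 1:
        raise ValueError("r_I must be < 1")
    return (1.0 + (n_effective - 1.0) * r_I) / (1.0 - r_I)


def _strain_effective_n(df: pd.DataFrame) -> float:
    counts = df.groupby("strain")["value"].count()
    return effective_n(counts[counts > 0].to_numpy())


def diet_icc(table: PhenotypeTable, trait: str,
             values: np.ndarray | None = None) -> float:
    """Intraclass correlation over diet groups: diet's share of total variation.

    The diet mean square comes from the full post-diet model
    (week + diet + strain, sequential), the within mean square is that
    model's residual, and ``n`` is the effective per-diet count (the
    unequal-group formula with the diets as groups).
    """
    df = _variant_frame(table, trait, "full").copy()
    if df["diet"].nunique() < 2:
        raise DesignError(f"trait {trait!r}: both experimental diets required for diet ICC")
    if values is not None:
        df["value"] = np.asarray(values, dtype=float)
    active = [c for c in ("C(batch)",) if df["batch"].nunique() > 1]
    terms = active + ["C(diet)", "C(strain)"]
    _check_estimable(df, "value", terms)
    model = smf.ols("value ~ " + " + ".join(terms), data=df).fit()
    tab = anova_lm(model, typ=1)
    msb = float(tab.loc["C(diet)", "sum_sq"] / tab.loc["C(diet)", "df"])
    msw = float(tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"])
    n_diet = effective_n(df.groupby("diet")["value"].count().to_numpy())
    return intraclass_correlation(msb, msw, n_diet)


def heritability_table(table: PhenotypeTable,
                       variants=("baseline", "full", "partial", "HP", "HS"),
                       traits=None) -> pd.DataFrame:
    """One row per trait x variant: ANOVA summary, effective n, r_I and g2.

    Effective n is recomputed per trait and variant from the rows
    actually modelled, so per-trait missingness and per-diet subsetting
    are reflected.  The full variant's rows also carry the diet ICC.
    """
    traits = list(traits) if traits is not None else table.traits
    rows = []
    for trait in traits:
        for variant in variants:
            anova = fit_strain_anova(table, trait, variant)
            df = _variant_frame(table, trait, variant)
            n_eff = _strain_effective_n(df)
            r_i = intraclass_correlation(anova.MSB, anova.MSW, n_eff)
            g2 = genetic_determination(anova.MSB, anova.MSW, n_eff)
            row = anova.table_row
            row.update({
                "n_effective": n_eff, "r_I": r_i, "g2": g2,
                "negative": r_i < 0,
                "diet_icc": diet_icc(table, trait) if variant == "full" else np.nan,
            })
            rows.append(row)
    return pd.DataFrame(rows)
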