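"""Domain types and tidy-table I/O for strain-panel diet-challenge phenotype data.

The central container is the :class:`PhenotypeTable`: one row per
mouse x timepoint x trait, carrying the design metadata (strain, diet,
batch week, baseline and randomized cage) that every downstream
estimator needs.  This module also owns the design summary used by all
heritability estimators, in particular the unequal-group-size effective
sample size

    n = (1/(a-1)) * (N - sum_i n_i^2 / N)

where ``a`` is the number of strains, ``n_i`` the per-strain counts and
``N`` the total count for the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DIETS",
    "BASELINE_DIET",
    "EXPERIMENTAL_DIETS",
    "TIMEPOINTS",
    "PHENOTYPE_COLUMNS",
    "SchemaError",
    "IntegrityError",
    "DesignError",
    "PhenotypeTable",
    "DesignSummary",
    "TraitCatalog",
    "read_phenotype_table",
    "write_phenotype_table",
    "effective_n",
    "summarize_design",
    "strain_diet_summary",
    "percent_change",
]

DIETS = ("AIN76A", "HP", "HS")
BASELINE_DIET = "AIN76A"
EXPERIMENTAL_DIETS = ("HP", "HS")
TIMEPOINTS = ("baseline", "postdiet")

PHENOTYPE_COLUMNS = [
    "mouse_id",
    "strain",
    "diet",
    "batch",
    "cage_baseline",
    "cage_randomized",
    "timepoint",
    "trait",
    "value",
    "units",
]

MISSING_TOKEN = "NA"


class SchemaError(ValueError):
    """The CSV does not match the phenotype-table schema."""


class IntegrityError(ValueError):
    """The table violates a structural invariant (duplicates, diet/timepoint mismatch...)."""


class DesignError(ValueError):
    """The design is too degenerate for the requested computation (e.g. <2 strains)."""


@dataclass(frozen=True)
class PhenotypeTable:
    """Validated tidy phenotype table.

    Wraps a :class:`pandas.DataFrame` with the schema in
    :data:`PHENOTYPE_COLUMNS` and enforces:

    * ``(mouse_id, timepoint, trait)`` unique;
    * baseline rows carry the baseline diet, post-diet rows an
      experimental diet;
    * each mouse has exactly one strain and one batch.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_phenotype_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def strains(self) -> list[str]:
        return sorted(self.data["strain"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    def subset(self, *, timepoint: str | None = None, trait: str | None = None,
               diet: str | None = None) -> pd.DataFrame:
        """Rows matching the given keys, missing values retained."""
        df = self.data
        if timepoint is not None:
            df = df[df["timepoint"] == timepoint]
        if trait is not None:
            df = df[df["trait"] == trait]
        if diet is not None:
            df = df[df["diet"] == diet]
        return df

    def trait_values(self, trait: str, timepoint: str,
                     diet: str | None = None) -> pd.DataFrame:
        """Complete-case rows for one trait at one timepoint (listwise per trait)."""
        df = self.subset(timepoint=timepoint, trait=trait, diet=diet)
        return df[df["value"].notna()]


@dataclass(frozen=True)
class DesignSummary:
    """Per-trait design bookkeeping for the heritability estimators."""

    a: int
    n_i: Mapping[str, int]
    N: int
    n_effective: float

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "n_i": dict(self.n_i),
            "N": self.N,
            "n_effective": self.n_effective,
        }


DEFAULT_RISK_TRAITS = (
    "glucose",
    "insulin",
    "glucose_insulin_ratio",
    "cholesterol",
    "tg",
    "body_fat_pct",
)

_CATALOG_CATEGORIES = {
    "body_composition",
    "clinical_chemistry",
    "one_carbon_metabolite",
    "calorimetry",
    "score",
}
_RISK_DIRECTIONS = {"higher_is_worse", "lower_is_worse", "neutral"}


@dataclass
class TraitCatalog:
    """Maps each trait to its units, category and health-risk direction."""

    entries: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait, meta in self.entries.items():
            if meta.get("category") not in _CATALOG_CATEGORIES:
                raise ValueError(f"unknown category for trait {trait!r}: {meta.get('category')!r}")
            if meta.get("risk_direction") not in _RISK_DIRECTIONS:
                raise ValueError(
                    f"unknown risk_direction for trait {trait!r}: {meta.get('risk_direction')!r}")

    def __contains__(self, trait: str) -> bool:
        return trait in self.entries

    def units(self, trait: str) -> str:
        return self.entries[trait]["units"]

    def check_table(self, table: PhenotypeTable) -> None:
        missing = [t for t in table.traits if t not in self.entries]
        if missing:
            raise KeyError(f"traits absent from catalog: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "TraitCatalog":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.entries, fh, sort_keys=True)


def _validate_phenotype_frame(df: pd.DataFrame) -> None:
    missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")

    problems: list[str] = []

    bad_diet = set(df["diet"].unique()) - set(DIETS)
    if bad_diet:
        raise ValueError(f"unknown diet levels: {sorted(bad_diet)}")
    bad_tp = set(df["timepoint"].unique()) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")

    dup = df.duplicated(subset=["mouse_id", "timepoint", "trait"])
    if dup.any():
        keys = df.loc[dup, ["mouse_id", "timepoint", "trait"]].head(5).to_dict("records")
        problems.append(f"duplicate (mouse_id, timepoint, trait) rows, e.g. {keys}")

    base = df[df["timepoint"] == "baseline"]
    if (base["diet"] != BASELINE_DIET).any():
        bad = base.loc[base["diet"] != BASELINE_DIET, "mouse_id"].unique()[:5]
        problems.append(f"baseline rows with non-{BASELINE_DIET} diet for mice {list(bad)}")
    post = df[df["timepoint"] == "postdiet"]
    if (~post["diet"].isin(EXPERIMENTAL_DIETS)).any():
        bad = post.loc[~post["diet"].isin(EXPERIMENTAL_DIETS), "mouse_id"].unique()[:5]
        problems.append(f"postdiet rows without experimental diet for mice {list(bad)}")

    for col in ("strain", "batch"):
        per_mouse = df.groupby("mouse_id", sort=False)[col].nunique()
        multi = per_mouse[per_mouse > 1]
        if len(multi):
            problems.append(f"mice with more than one {col}: {list(multi.index[:5])}")

    if problems:
        raise IntegrityError("phenotype table invariant violations: " + "; ".join(problems))


def read_phenotype_table(path) -> PhenotypeTable:
    """Read and validate a tidy phenotype CSV.

    Dialect: comma-separated, ``.`` decimal point, ``NA`` for missing
    values, UTF-8.
    """
    header = pd.read_csv(path, nrows=0, encoding="utf-8")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in header.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = pd.read_csv(
        path,
        dtype={
            "mouse_id": str, "strain": str, "diet": str, "batch": "int64",
            "cage_baseline": str, "cage_randomized": str, "timepoint": str,
            "trait": str, "value": float, "units": str,
        },
        na_values=[MISSING_TOKEN],
        keep_default_na=False,
        encoding="utf-8",
    )
    return PhenotypeTable(df[PHENOTYPE_COLUMNS])


def write_phenotype_table(table: PhenotypeTable, path) -> None:
    """Write the table in the exchange dialect read by :func:`read_phenotype_table`.

    Floats use repr-level precision so a round-trip is value-identical.
    """
    table.data.to_csv(path, index=False, na_rep=MISSING_TOKEN,
                      float_format="%.17g", encoding="utf-8")


def effective_n(n_i: Iterable[int]) -> float:
    """Unequal-group-size effective sample size.

    ``n = (1/(a-1)) * (N - sum n_i^2 / N)``.  Reduces to the common group
    size on a balanced design and is maximised by the balanced
    allocation for fixed ``N`` and ``a``.
    """
    counts = np.asarray(list(n_i), dtype=float)
    a = len(counts)
    if a < 2:
        raise DesignError(f"effective n requires >=2 groups, got {a}")
    if (counts <= 0).any():
        raise DesignError("all group counts must be positive")
    N = counts.sum()
    return float((N - (counts ** 2).sum() / N) / (a - 1))


def summarize_design(table: PhenotypeTable, trait: str, timepoint: str) -> DesignSummary:
    """Per-strain sample counts and effective n for one trait at one timepoint.

    Missing values are excluded per trait (listwise within the trait)
    before any count enters the formula, so traits with different
    missingness get different effective n.
    """
    df = table.trait_values(trait, timepoint)
    counts = df.groupby("strain")["value"].count()
    counts = counts[counts > 0]
    if len(counts) < 2:
        raise DesignError(
            f"trait {trait!r} at {timepoint!r} has {len(counts)} strain(s) with data; need >=2")
    n_i = {s: int(c) for s, c in counts.sort_index().items()}
    return DesignSummary(
        a=len(n_i), n_i=n_i, N=int(counts.sum()),
        n_effective=effective_n(n_i.values()),
    )


def strain_diet_summary(table: PhenotypeTable,
                        sort_by_trait: str | None = None) -> pd.DataFrame:
    """Mean and standard error per (strain, diet, timepoint, trait).

    SE = sample SD / sqrt(n); groups with a single observation report
    ``NaN`` SE.  Rows are ordered lexicographically by strain unless
    ``sort_by_trait`` is given, in which case strains are ordered by
    their grand mean of that trait (ascending, least to greatest).
    """
    df = table.data[table.data["value"].notna()]
    if df.empty:
        raise ValueError("empty phenotype table")
    g = df.groupby(["strain", "diet", "timepoint", "trait"])["value"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "se"] = np.nan
    out = out.drop(columns="sd")
    if sort_by_trait is not None:
        order = (df[df["trait"] == sort_by_trait]
                 .groupby("strain")["value"].mean().sort_values().index)
        rank = {s: i for i, s in enumerate(order)}
        out = out.sort_values(
            by=["strain", "diet", "timepoint", "trait"],
            key=lambda col: col.map(rank) if col.name == "strain" else col,
        )
    else:
        out = out.sort_values(["strain", "diet", "timepoint", "trait"])
    return out.reset_index(drop=True)


def percent_change(reference: float, value: float) -> float:
    """Percent change of ``value`` relative to ``reference``: 100*(value-reference)/reference."""
    if reference == 0:
        raise ZeroDivisionError("percent change undefined for zero reference")
    return 100.0 * (value - reference) / reference
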