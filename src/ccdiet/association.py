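"""Trait-trait Spearman correlation matrices with Benjamini-Hochberg control.

Correlations use average ranks for ties and pairwise-complete
observations (per-trait missingness differs, so listwise deletion would
discard usable pairs).  p-values come from the t approximation for
n > 10 and from exact enumeration of rank permutations at n <= 10.
One BH family per matrix: the unique off-diagonal cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import PhenotypeTable

__all__ = [
    "CorrelationMatrix",
    "spearman",
    "spearman_matrix",
    "bh_adjust",
    "filter_significant",
]

EXACT_SPEARMAN_MAX_N = 10
MIN_COMPLETE_PAIRS = 3


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p for the rank correlation, full enumeration.

    The statistic sum(rank(x) * perm(rank(y))) is a monotone function of
    rho for fixed margins, so enumerating permutations of one rank
    vector gives the exact conditional null (valid with ties).
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    obs = abs(float(rx_c @ ry_c))
    count = 0
    total = 0
    chunk: list = []
    chunk_size = 100_000

    def flush(chunk_rows):
        nonlocal count, total
        perms = np.asarray(chunk_rows, dtype=np.intp)
        vals = np.abs(ry_c[perms] @ rx_c)
        count += int((vals >= obs - 1e-12).sum())
        total += len(perms)

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with ties-averaged ranks.

    Returns ``(rho, p)``; pairwise-complete observations only, NaN for
    both when fewer than 3 complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < MIN_COMPLETE_PAIRS:
        return float("nan"), float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(x, y)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Spearman matrix with raw and BH-adjusted p-values."""

    traits: tuple[str, ...]
    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n_pairs: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Unique off-diagonal cells as a long frame."""
        rows = []
        for i, a in enumerate(self.traits):
            for b in self.traits[i + 1:]:
                rows.append({
                    "trait_a": a, "trait_b": b,
                    "rho": self.rho.loc[a, b],
                    "p_raw": self.p_raw.loc[a, b],
                    "p_adj": self.p_adj.loc[a, b],
                    "n": int(self.n_pairs.loc[a, b]),
                })
        return pd.DataFrame(rows)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``p_adj_(i) = min_{j >= i} p_(j) m / j`` over the sorted vector,
    capped at 1; NaNs pass through and do not count toward the family
    size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(vals)
    if m == 0:
        return out
    order = np.argsort(vals, kind="mergesort")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[mask] = restored
    return out


def spearman_matrix(table: PhenotypeTable, traits=None, timepoint: str = "baseline",
                    stratum: str | None = None) -> CorrelationMatrix:
    """All-pairs Spearman correlations of traits at one timepoint.

    ``stratum`` optionally restricts to one experimental diet.  Cells
    with fewer than 3 complete pairs are NaN and excluded from the BH
    family.
    """
    df = table.subset(timepoint=timepoint, diet=stratum)
    traits = list(traits) if traits is not None else sorted(df["trait"].unique())
    wide = df.pivot(index="mouse_id", columns="trait", values="value")
    for t in traits:
        if t not in wide.columns:
            raise KeyError(f"trait {t!r} absent at timepoint {timepoint!r}")
    wide = wide[traits]

    k = len(traits)
    rho = np.eye(k)
    p_raw = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    np.fill_diagonal(n_pairs, wide.notna().sum().to_numpy())
    for i in range(k):
        for j in range(i + 1, k):
            x = wide[traits[i]].to_numpy()
            y = wide[traits[j]].to_numpy()
            keep = ~(np.isnan(x) | np.isnan(y))
            n_pairs[i, j] = n_pairs[j, i] = int(keep.sum())
            r, p = spearman(x, y)
            rho[i, j] = rho[j, i] = r
            p_raw[i, j] = p_raw[j, i] = p

    iu = np.triu_indices(k, 1)
    adj_flat = bh_adjust(p_raw[iu])
    p_adj = np.full((k, k), np.nan)
    p_adj[iu] = adj_flat
    p_adj.T[iu] = adj_flat

    idx = pd.Index(traits, name="trait")
    return CorrelationMatrix(
        traits=tuple(traits),
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p_raw=pd.DataFrame(p_raw, index=idx, columns=idx),
        p_adj=pd.DataFrame(p_adj, index=idx, columns=idx),
        n_pairs=pd.DataFrame(n_pairs, index=idx, columns=idx),
    )


def filter_significant(matrix: CorrelationMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Mask rho cells whose adjusted p is not below alpha; keep the diagonal."""
    masked = matrix.rho.copy()
    off = ~np.eye(len(matrix.traits), dtype=bool)
    fail = (matrix.p_adj >= alpha) | matrix.p_adj.isna()
    masked[fail.to_numpy() & off] = np.nan
    return masked
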