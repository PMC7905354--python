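"""Normality gating, pre-model transformations and stratified Z-scoring.

Traits are gated with the Shapiro–Wilk test; traits that fail are
power-transformed (Box–Cox with an automatic positivity shift), and
traits that still fail fall back to rank-based inverse-normal scores.
Every stage is recorded in a :class:`TransformRecord` so the provenance
of each modelled vector is auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DegenerateInputError",
    "TransformRecord",
    "shapiro_gate",
    "power_transform",
    "rank_inverse_normal",
    "zscore",
    "normalize",
]

GATE_ALPHA = 0.05
BLOM_OFFSET = 3.0 / 8.0


class DegenerateInputError(ValueError):
    """Input too degenerate to transform (constant, or too short)."""


@dataclass(frozen=True)
class TransformRecord:
    """Audit record of the transformation applied to one trait vector."""

    trait: str
    method: str                 # identity | power | rank_inverse_normal
    lmbda: float | None
    shift: float | None
    shapiro_p_before: float
    shapiro_p_after: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _check_vector(values, min_len: int = 3) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < min_len:
        raise DegenerateInputError(f"need at least {min_len} non-missing values, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant vector")
    return x


def shapiro_gate(values, alpha: float = GATE_ALPHA) -> tuple[bool, float]:
    """Shapiro–Wilk normality gate: passes iff p >= alpha."""
    x = _check_vector(values)
    if len(x) > 5000:
        x = x[:5000]  # test statistic undefined beyond implementation limit
    p = float(stats.shapiro(x).pvalue)
    return p >= alpha, p


def power_transform(values) -> tuple[np.ndarray, float, float]:
    """Box–Cox power transform with maximum-likelihood lambda.

    Non-positive inputs are first shifted by ``1 - min(x)`` so the
    smallest value maps to 1.  Returns ``(transformed, lambda, shift)``;
    the map is strictly monotone in the input.
    """
    x = _check_vector(values)
    shift = 0.0
    if x.min() <= 0:
        shift = 1.0 - float(x.min())
    transformed, lmbda = stats.boxcox(x + shift)
    return np.asarray(transformed, dtype=float), float(lmbda), shift


def rank_inverse_normal(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Rank-based inverse-normal scores with Blom offset.

    ``Phi^-1((r - c) / (n + 1 - 2c))`` with average ranks for ties, so
    tied inputs share a score and distinct inputs keep their order.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 values for rank normalization")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (len(x) + 1 - 2 * offset))


def zscore(values, reference=None) -> np.ndarray:
    """Standardize against a reference distribution (sample SD, n-1).

    ``reference`` defaults to the values themselves (self-standardize).
    """
    x = np.asarray(values, dtype=float)
    ref = x if reference is None else np.asarray(reference, dtype=float)
    ref = ref[~np.isnan(ref)]
    sd = ref.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateInputError("reference SD is zero or undefined")
    return (x - ref.mean()) / sd


def normalize(values, trait: str = "", alpha: float = GATE_ALPHA
              ) -> tuple[np.ndarray, TransformRecord]:
    """Two-stage normalization pipeline: gate -> power -> gate -> rank-INT.

    Returns the vector to model and the audit record.  A vector that
    already passes the Shapiro gate is returned unchanged; one that
    fails is Box–Cox transformed; if the transform still fails the gate,
    rank-based inverse-normal scores are used.
    """
    x = _check_vector(values)
    ok, p_before = shapiro_gate(x, alpha)
    if ok:
        return x, TransformRecord(trait, "identity", None, None, p_before, p_before)
    transformed, lmbda, shift = power_transform(x)
    ok2, p_after = shapiro_gate(transformed, alpha)
    if ok2:
        return transformed, TransformRecord(trait, "power", lmbda, shift, p_before, p_after)
    scores = rank_inverse_normal(x)
    _, p_int = shapiro_gate(scores, alpha)
    return scores, TransformRecord(trait, "rank_inverse_normal", None, None, p_before, p_int)
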