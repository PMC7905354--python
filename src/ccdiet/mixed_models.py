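"""Gene-by-diet mixed models: Satterthwaite F tests and variance partitioning.

Fits Gaussian linear mixed models with crossed/nested random intercepts
by direct restricted maximum likelihood on the marginal covariance

    V(theta) = sigma2_eps I + sum_k sigma2_k Z_k Z_k'

(dense algebra; study-scale designs have a few hundred rows).  Fixed
effects are tested with F statistics whose denominator degrees of
freedom come from the Satterthwaite approximation: the covariance of
the variance-parameter estimates is the inverse observed information
(finite-difference Hessian of the REML deviance), the gradient of each
contrast variance is analytic, and multi-df terms are pooled over
eigencontrasts — the Fai & Cornelius construction as popularised by
lmerTest.

Two model families mirror the study's analysis:

* significance models — diet (or strain-by-diet interaction) as fixed
  effects with strain, strain x diet and the two cage structures as
  random intercepts;
* a partition model — strain, diet and strain x diet all random, whose
  variance components are reported as proportions of the total
  (residual included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats, optimize
from scipy.linalg import cho_factor, cho_solve

from .core_data import PhenotypeTable, DesignError

__all__ = [
    "MixedModelSpec",
    "FixedEffectTest",
    "VarianceComponents",
    "REMLFit",
    "FitError",
    "fit_mixed_model",
    "test_diet_effect",
    "test_strain_diet_interaction",
    "variance_partition",
    "gxd_effectsize_link",
    "DIET_EFFECT_SPEC",
    "INTERACTION_SPEC",
    "PARTITION_SPEC",
]


class FitError(RuntimeError):
    """REML optimization failed to converge."""


@dataclass(frozen=True)
class MixedModelSpec:
    """Model description: patsy fixed-effect formula terms and random intercepts.

    Random intercepts are colon-joined column names; nesting is implicit
    in the labels (cage identifiers already embed their parent diet or
    strain).
    """

    fixed_terms: tuple[str, ...]
    random_intercepts: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.fixed_terms) & set(self.random_intercepts)
        if overlap:
            raise ValueError(f"terms in both fixed and random lists: {sorted(overlap)}")

    @property
    def formula(self) -> str:
        return "value ~ " + " + ".join(self.fixed_terms)

    @classmethod
    def from_yaml(cls, path) -> "MixedModelSpec":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(fixed_terms=tuple(raw["fixed_terms"]),
                   random_intercepts=tuple(raw["random_intercepts"]))


#: diet significance model: diet and batch fixed; strain, strain x diet and
#: both cage structures as random intercepts
DIET_EFFECT_SPEC = MixedModelSpec(
    fixed_terms=("C(diet)", "C(batch)"),
    random_intercepts=("strain", "strain:diet", "cage_randomized", "cage_baseline"),
)

#: interaction significance model: strain, diet, strain x diet and batch fixed;
#: cages random
INTERACTION_SPEC = MixedModelSpec(
    fixed_terms=("C(strain)", "C(diet)", "C(strain):C(diet)", "C(batch)"),
    random_intercepts=("cage_randomized", "cage_baseline"),
)

#: variance partition model: strain, diet and interaction all random
PARTITION_SPEC = MixedModelSpec(
    fixed_terms=("1",),
    random_intercepts=("strain", "diet", "strain:diet"),
)


@dataclass(frozen=True)
class FixedEffectTest:
    trait: str
    term: str
    F: float
    ddf: float
    ndf: int
    p: float
    singular: bool
    converged: bool


@dataclass(frozen=True)
class VarianceComponents:
    trait: str
    variances: dict[str, float]
    proportions: dict[str, float]
    boundary: tuple[str, ...] = ()


@dataclass
class REMLFit:
    """Converged REML fit with everything the Satterthwaite tests need."""

    spec: MixedModelSpec
    beta: np.ndarray
    fe_names: list[str]
    term_slices: dict[str, slice]
    sigma2: dict[str, float]          # per random term + "residual"
    cov_beta: np.ndarray              # C = (X' V^-1 X)^-1
    theta: np.ndarray                 # variance parameters, residual last
    theta_names: list[str]
    grad_cov_beta: list[np.ndarray]   # dC/dtheta_i, one per variance parameter
    n: int = 0
    converged: bool = True
    singular: bool = False
    _y: np.ndarray | None = None
    _X: np.ndarray | None = None
    _Gs: list | None = None
    _cov_varpar: np.ndarray | None = None

    @property
    def varpar(self) -> np.ndarray:
        """Variance parameters on the relative-SD scale: (sqrt(sigma2_k /
        sigma2_eps), ..., sqrt(sigma2_eps)).

        The REML deviance is smooth (and even in each relative SD) on
        this scale, so the observed information is well defined even for
        boundary fits where a variance estimate is exactly zero.
        """
        s2e = self.theta[-1]
        return np.append(np.sqrt(self.theta[:-1] / s2e), np.sqrt(s2e))

    @property
    def cov_varpar(self) -> np.ndarray:
        """Asymptotic covariance of the relative-SD variance parameters:
        twice the inverse observed information (finite-difference Hessian
        of the REML deviance at the estimate)."""
        if self._cov_varpar is None:
            def dev(vp):
                sigma2 = vp[-1] ** 2
                theta = np.append(vp[:-1] ** 2 * sigma2, sigma2)
                return _reml_deviance_theta(theta, self._y, self._X, self._Gs)

            H = _fd_hessian(dev, self.varpar)
            self._cov_varpar = 2.0 * np.linalg.pinv(H)
        return self._cov_varpar

    def wald_F(self, term: str) -> tuple[float, float, int, float]:
        """Satterthwaite F test of one fixed-effect term.

        Returns ``(F, ddf, ndf, p)``.  The denominator df follow the
        multi-df construction: eigendecompose the contrast covariance,
        Satterthwaite each eigencontrast via the delta method against
        the variance-parameter covariance, then pool.
        """
        sl = self.term_slices[term]
        idx = np.arange(len(self.beta))[sl]
        L = np.eye(len(self.beta))[idx]
        C = self.cov_beta
        M = L @ C @ L.T
        q = len(idx)
        Lb = L @ self.beta
        F = float(Lb @ np.linalg.solve(M, Lb) / q)

        lam, U = np.linalg.eigh(M)
        # chain rule from the variance scale to the relative-SD scale:
        # sigma2_k = vp_k^2 vp_s^2, sigma2_eps = vp_s^2
        vp = self.varpar
        s2e = self.theta[-1]
        W = self.cov_varpar
        nus = []
        for m in range(q):
            l_m = U[:, m] @ L
            d_var = np.array([l_m @ dC @ l_m for dC in self.grad_cov_beta])
            grad = np.empty_like(d_var)
            grad[:-1] = d_var[:-1] * 2.0 * vp[:-1] * s2e
            grad[-1] = (d_var[:-1] @ (vp[:-1] ** 2) + d_var[-1]) * 2.0 * vp[-1]
            denom = float(grad @ W @ grad)
            if denom <= 0 or lam[m] <= 0:
                continue
            nus.append(2.0 * lam[m] ** 2 / denom)
        E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
        if E > q:
            ddf = 2.0 * E / (E - q)
        else:  # degenerate Satterthwaite; fall back to residual df
            ddf = float(self.n - len(self.beta))
        p = float(stats.f.sf(F, q, ddf))
        return F, ddf, q, p


def _random_design(df: pd.DataFrame, term: str) -> np.ndarray:
    factors = term.split(":")
    labels = df[factors[0]].astype(str)
    for f in factors[1:]:
        labels = labels.str.cat(df[f].astype(str), sep=":")
    return pd.get_dummies(labels, dtype=float).to_numpy()


def _reml_deviance_theta(theta, y, X, Gs):
    """REML deviance (-2 restricted log-likelihood, constants dropped) on the
    variance scale, residual variance last."""
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], Gs):
        V += t * G
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    A = X.T @ Vi_X
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    b = X.T @ Vi_y
    yPy = float(y @ Vi_y - b @ np.linalg.solve(A, b))
    return logdet_v + logdet_a + yPy


def _fd_hessian(f, x, rel_step: float = 1e-4):
    """Central finite-difference Hessian with one-sided fallback.

    Step sizes scale with each coordinate (floored at ``rel_step`` times
    the largest parameter so boundary zeros get a usable step).
    """
    x = np.asarray(x, dtype=float)
    k = len(x)
    scale = max(np.max(np.abs(x)), 1e-8)
    h = np.maximum(np.abs(x) * rel_step, scale * rel_step)

    f0 = f(x)

    def ev(delta):
        val = f(x + delta)
        # rare infeasible excursion (V not PD): flatten toward f0
        return val if np.isfinite(val) else f0
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        fp, fm = ev(ei), ev(-ei)
        H[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            fpp, fpm = ev(ei + ej), ev(ei - ej)
            fmp, fmm = ev(-ei + ej), ev(-ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _profiled_deviance(gamma, y, X, Gs):
    n, p = X.shape
    V0 = np.eye(n)
    for g, G in zip(gamma, Gs):
        V0 += g * G
    try:
        cf = cho_factor(V0, lower=True)
    except np.linalg.LinAlgError:
        return np.inf, np.nan, None
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    A = X.T @ Vi_X
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, np.nan, None
    b = X.T @ Vi_y
    beta = np.linalg.solve(A, b)
    rss = float(y @ Vi_y - b @ beta)
    if rss <= 0:
        return np.inf, np.nan, None
    sigma2 = rss / (n - p)
    dev = (n - p) * np.log(sigma2) + logdet_v + logdet_a
    return dev, sigma2, beta


def fit_mixed_model(df: pd.DataFrame, spec: MixedModelSpec, trait: str = "") -> REMLFit:
    """REML fit of ``value`` on the given design frame.

    Variance components are constrained non-negative; estimates on the
    zero boundary are flagged singular rather than fatal.
    """
    df = df[df["value"].notna()].reset_index(drop=True)
    y_dm, X_dm = patsy.dmatrices(spec.formula, df, return_type="dataframe")
    X = X_dm.to_numpy()
    y = y_dm.to_numpy().ravel()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(
            f"rank-deficient fixed-effect design for terms {spec.fixed_terms}; "
            "check for aliased factors (e.g. batch confounded with strain)")
    Zs = [_random_design(df, t) for t in spec.random_intercepts]
    Gs = [Z @ Z.T for Z in Zs]
    n, p = X.shape
    K = len(Gs)

    best = None
    for x0 in (np.full(K, 0.1), np.full(K, 1.0)):
        res = optimize.minimize(
            lambda g: _profiled_deviance(g, y, X, Gs)[0],
            x0, method="L-BFGS-B", bounds=[(0.0, None)] * K,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) and np.isfinite(best.fun)
    if not np.isfinite(best.fun):
        raise FitError(f"REML optimization failed for trait {trait!r}: {best.message}")
    gamma = np.clip(best.x, 0.0, None)
    _, sigma2_eps, beta = _profiled_deviance(gamma, y, X, Gs)
    theta = np.append(gamma * sigma2_eps, sigma2_eps)

    # post-fit quantities on the variance scale
    V = sigma2_eps * np.eye(n)
    for t, G in zip(theta[:-1], Gs):
        V += t * G
    cf = cho_factor(V, lower=True)
    Vi_X = cho_solve(cf, X)
    A = X.T @ Vi_X
    C = np.linalg.inv(A)

    # dC/dtheta_i = C X' V^-1 G_i V^-1 X C
    grad_C = []
    for G in Gs + [np.eye(n)]:
        B = Vi_X.T @ G @ Vi_X
        grad_C.append(C @ B @ C)

    design_info = X_dm.design_info
    term_slices = {t: design_info.term_name_slices[t] for t in design_info.term_names}
    sigma2 = {t: float(v) for t, v in zip(spec.random_intercepts, theta[:-1])}
    sigma2["residual"] = float(sigma2_eps)
    return REMLFit(
        spec=spec, beta=beta, fe_names=list(X_dm.columns),
        term_slices=term_slices, sigma2=sigma2, cov_beta=C,
        theta=theta, theta_names=list(spec.random_intercepts) + ["residual"],
        grad_cov_beta=grad_C, n=n, converged=converged,
        singular=bool((gamma == 0).any()),
        _y=y, _X=X, _Gs=Gs,
    )


def _postdiet_frame(table: PhenotypeTable, trait: str) -> pd.DataFrame:
    df = table.trait_values(trait, "postdiet")
    if df["diet"].nunique() < 2:
        raise DesignError(f"trait {trait!r}: both experimental diets required")
    if df["strain"].nunique() < 2:
        raise DesignError(f"trait {trait!r}: at least two strains required")
    return df


def test_diet_effect(table: PhenotypeTable, trait: str) -> FixedEffectTest:
    """Satterthwaite F test of the diet fixed effect.

    Strain, strain x diet, randomization cage (nested in diet) and
    baseline cage (nested in strain) enter as random intercepts.
    """
    df = _postdiet_frame(table, trait)
    fit = fit_mixed_model(df, DIET_EFFECT_SPEC, trait)
    F, ddf, q, p = fit.wald_F("C(diet)")
    return FixedEffectTest(trait, "diet", F, ddf, q, p, fit.singular, fit.converged)


def test_strain_diet_interaction(table: PhenotypeTable, trait: str) -> FixedEffectTest:
    """Satterthwaite F test of the strain x diet interaction (cages random)."""
    df = _postdiet_frame(table, trait)
    fit = fit_mixed_model(df, INTERACTION_SPEC, trait)
    F, ddf, q, p = fit.wald_F("C(strain):C(diet)")
    return FixedEffectTest(trait, "strain:diet", F, ddf, q, p, fit.singular, fit.converged)


def variance_partition(table: PhenotypeTable, trait: str) -> VarianceComponents:
    """Proportion of phenotypic variance from strain, diet and strain x diet.

    All three enter as random intercepts; proportions divide each
    REML variance by the total including the residual, so they sum
    to one.  Zero-variance components sit on the boundary and are
    reported as exact zeros.
    """
    df = _postdiet_frame(table, trait)
    fit = fit_mixed_model(df, PARTITION_SPEC, trait)
    total = sum(fit.sigma2.values())
    props = {k: v / total for k, v in fit.sigma2.items()}
    boundary = tuple(k for k, v in fit.sigma2.items() if v == 0.0)
    return VarianceComponents(trait, dict(fit.sigma2), props, boundary)


def gxd_effectsize_link(
    interaction_tests,
    effect_sizes,
    p_thresh: float = 0.05,
    g_thresh: float = 0.8,
) -> dict:
    """Relate interaction significance to the magnitude of the diet effect.

    Spearman correlation (per diet) of each trait's interaction F
    statistic against |g|, plus a 2x2 contingency table over all
    trait-diet pairs — largely diet-affected (|g| > g_thresh) or not,
    against interaction-significant (p < p_thresh) or not — tested by
    chi-square with continuity correction.  A table with an empty
    margin is flagged degenerate and its p reported as NaN.
    """
    from .association import spearman  # local import to avoid cycle

    f_by_trait = {t.trait: t for t in interaction_tests}
    rows = [(e.trait, e.diet, abs(e.g), f_by_trait[e.trait].F, f_by_trait[e.trait].p)
            for e in effect_sizes if e.trait in f_by_trait]
    if not rows:
        raise ValueError("no traits shared between interaction tests and effect sizes")
    df = pd.DataFrame(rows, columns=["trait", "diet", "abs_g", "F", "p_interaction"])

    spearman_by_diet = {}
    for diet, sub in df.groupby("diet"):
        rho, p = spearman(sub["F"].to_numpy(), sub["abs_g"].to_numpy())
        spearman_by_diet[diet] = {"rho": rho, "p": p, "n": len(sub)}

    large = df["abs_g"] > g_thresh
    sig = df["p_interaction"] < p_thresh
    table2x2 = np.array([
        [int((large & sig).sum()), int((large & ~sig).sum())],
        [int((~large & sig).sum()), int((~large & ~sig).sum())],
    ])
    degenerate = bool((table2x2.sum(axis=0) == 0).any() or (table2x2.sum(axis=1) == 0).any())
    if degenerate:
        chi2_p = float("nan")
    else:
        chi2_p = float(stats.chi2_contingency(table2x2, correction=True).pvalue)
    return {
        "spearman": spearman_by_diet,
        "table2x2": table2x2,
        "chi2_p": chi2_p,
        "degenerate": degenerate,
    }
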