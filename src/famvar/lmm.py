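"""Kinship-adjusted linear mixed model for single-variant association.

Model: y = X b + g beta + u + e with u ~ N(0, sigma2_g * 2*Phi) and
e ~ N(0, sigma2_e * I). After an eigendecomposition 2*Phi = U S U' the
covariance is diagonal in the rotated basis, so the variance components are
fit by a one-dimensional profile (RE)ML optimization over the ratio
gamma = sigma2_g / sigma2_e; the fixed effects follow by GLS and the
genotype effect is tested by a two-sided Wald z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KinshipEigen",
    "LmmFit",
    "AssociationResult",
    "fit_lmm",
    "fit_null_lmm",
    "genomic_control",
    "bonferroni_threshold",
    "mac_partition",
    "qq_plot_data",
]

_GAMMA_MAX = 1e4


@dataclass
class KinshipEigen:
    """Cached eigendecomposition of K = 2*Phi, reused across variants."""

    individuals: list
    values: np.ndarray = field(repr=False)
    vectors: np.ndarray = field(repr=False)

    @classmethod
    def from_kinship(cls, kinship) -> "KinshipEigen":
        K = 2.0 * np.asarray(kinship.phi, dtype=float)
        vals, vecs = np.linalg.eigh(K)
        if vals.min() < -1e-8:
            raise ValueError(f"2*Phi is not PSD (min eigenvalue {vals.min():.3g})")
        return cls(list(kinship.individuals), np.clip(vals, 0.0, None), vecs)

    def subset(self, individuals) -> "KinshipEigen":
        """Re-decompose for a subset of individuals (complete-case filtering)."""
        idx = [self.individuals.index(i) for i in individuals]
        K = (self.vectors * self.values) @ self.vectors.T
        K = K[np.ix_(idx, idx)]
        vals, vecs = np.linalg.eigh(K)
        return KinshipEigen(list(individuals), np.clip(vals, 0.0, None), vecs)


@dataclass
class LmmFit:
    """Variance components and GLS fixed effects at the (RE)ML optimum."""

    beta: np.ndarray
    beta_cov: np.ndarray
    sigma2_g: float
    sigma2_e: float
    gamma: float
    loglik: float
    method: str
    converged: bool
    eigen: KinshipEigen = field(repr=False)
    resid_rotated: np.ndarray = field(repr=False)  # U'(y - X beta)
    weights: np.ndarray = field(repr=False)        # 1 / (gamma * s_i + 1)

    @property
    def heritability(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


@dataclass
class AssociationResult:
    variant: object
    beta: float
    se: float
    p: float
    n: int
    maf: float
    mac: int
    converged: bool
    sigma2_g: float = np.nan
    sigma2_e: float = np.nan


def _profile_neg_loglik(log_gamma, yt, Xt, s, reml):
    gamma = np.exp(log_gamma)
    d = gamma * s + 1.0
    w = 1.0 / d
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = yt - Xt @ beta
    rss = float(r @ (w * r))
    n, p = Xt.shape
    if rss <= 0:
        return np.inf
    if reml:
        dof = n - p
        sigma2 = rss / dof
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        nll = 0.5 * (dof * np.log(sigma2) + np.log(d).sum() + logdet_xwx + dof)
    else:
        sigma2 = rss / n
        nll = 0.5 * (n * np.log(sigma2) + np.log(d).sum() + n)
    return nll


def _fit_components(yt, Xt, s, reml: bool):
    """1-D profile optimization over log gamma, with a coarse grid then Brent."""
    grid = np.concatenate(([-np.inf], np.linspace(np.log(1e-4), np.log(_GAMMA_MAX), 25)))

    def nll_at(lg):
        if np.isneginf(lg):
            return _profile_neg_loglik(np.log(1e-12), yt, Xt, s, reml)
        return _profile_neg_loglik(lg, yt, Xt, s, reml)

    vals = np.array([nll_at(lg) for lg in grid])
    k = int(np.nanargmin(vals))
    converged = True
    if k == 0:
        log_gamma = np.log(1e-12)
    else:
        lo = grid[max(k - 1, 1)] if k > 1 else np.log(1e-12)
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            _profile_neg_loglik,
            bounds=(lo, hi),
            args=(yt, Xt, s, reml),
            method="bounded",
            options={"xatol": 1e-8},
        )
        log_gamma = float(res.x)
        if _profile_neg_loglik(log_gamma, yt, Xt, s, reml) > vals[k] + 1e-9:
            log_gamma = grid[k]
        converged = bool(np.isfinite(_profile_neg_loglik(log_gamma, yt, Xt, s, reml)))
    gamma = np.exp(log_gamma)
    if gamma < 1e-10:
        gamma = 0.0
    return gamma, converged


def fit_null_lmm(
    y: np.ndarray,
    X: np.ndarray,
    eigen: KinshipEigen,
    method: str = "reml",
) -> LmmFit:
    """Fit the polygenic null model y = X b + u + e (no genotype term)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in y or X; filter rows first")
    reml = method.lower() == "reml"
    U, s = eigen.vectors, eigen.values
    yt = U.T @ y
    Xt = U.T @ X
    gamma, converged = _fit_components(yt, Xt, s, reml)
    d = gamma * s + 1.0
    w = 1.0 / d
    Xw = Xt * w[:, None]
    XtWX = Xt.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yt)
    r = yt - Xt @ beta
    rss = float(r @ (w * r))
    n, p = Xt.shape
    sigma2_e = rss / (n - p) if reml else rss / n
    sigma2_g = gamma * sigma2_e
    beta_cov = sigma2_e * np.linalg.inv(XtWX)
    nll = _profile_neg_loglik(np.log(gamma) if gamma > 0 else np.log(1e-12), yt, Xt, s, reml)
    return LmmFit(
        beta=beta,
        beta_cov=beta_cov,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        gamma=gamma,
        loglik=-nll,
        method="reml" if reml else "ml",
        converged=converged,
        eigen=eigen,
        resid_rotated=r,
        weights=w,
    )


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    g: np.ndarray,
    eigen: KinshipEigen,
    method: str = "reml",
    variant=None,
) -> AssociationResult:
    """Single-variant mixed-model association.

    ``X`` is the covariate design including the intercept; ``g`` the additive
    dosage vector (no missing values — apply complete-case filtering and
    eigen.subset first). Returns the Wald test of the genotype effect.
    """
    g = np.asarray(g, dtype=float)
    if np.isnan(g).any():
        raise ValueError("missing genotypes; filter to complete cases first")
    if np.nanstd(g) == 0:
        raise ValueError("monomorphic genotype vector")
    from .qc import compute_maf

    maf, mac = compute_maf(g)
    design = np.column_stack([np.atleast_2d(np.asarray(X, dtype=float)), g])
    fit = fit_null_lmm(y, design, eigen, method=method)
    beta = float(fit.beta[-1])
    se = float(np.sqrt(fit.beta_cov[-1, -1]))
    if not fit.converged or not np.isfinite(se) or se <= 0:
        return AssociationResult(variant, beta, se, np.nan, len(y), maf, mac, False)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = max(p, np.finfo(float).tiny)
    return AssociationResult(
        variant, beta, se, p, len(y), maf, mac, True,
        sigma2_g=fit.sigma2_g, sigma2_e=fit.sigma2_e,
    )


def genomic_control(pvalues) -> float:
    """Genomic-control lambda: median observed p over the expected median 0.5."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no valid p-values")
    return float(np.median(p) / 0.5)


def bonferroni_threshold(n_tests: int) -> float:
    """Family-wise 0.05 threshold: 0.05 divided by the number of tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 0.05 / n_tests


def mac_partition(results, min_mac: int = 10) -> tuple[list, list]:
    """Split association results into stable (mac >= 10) and unstable (mac < 10).

    Mixed-model Wald tests are unreliable below ~10 minor-allele copies; the
    boundary mac = 10 is assigned to the stable set.
    """
    stable = [r for r in results if r.mac >= min_mac]
    unstable = [r for r in results if r.mac < min_mac]
    return stable, unstable


def qq_plot_data(pvalues) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot (i/(n+1) quantiles)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    n = p.size
    if n == 0:
        return pd.DataFrame(columns=["expected", "observed"])
    obs = np.sort(-np.log10(p))
    exp = np.sort(-np.log10(np.arange(1, n + 1) / (n + 1.0)))
    return pd.DataFrame({"expected": exp, "observed": obs})
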