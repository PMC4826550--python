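"""Gene-level rare-variant tests with family structure.

Four tests over a gene's rare functional variants:

* UWSS — unweighted sum score: the count of minor alleles a subject carries,
  regressed on the phenotype in a kinship LMM (Wald test, ML components).
* WSS — frequency-weighted sum score with Madsen-Browning-style weights
  from control allele frequencies.
* famSKAT — variance-component kernel test whose null model carries the
  polygenic kinship random effect; p from a mixture of chi-squares.
* PWST — adaptive p-value-weighted sum test with a family-aware permutation
  null (decorrelate residuals by the null covariance, permute, re-estimate
  the adaptive weights every round).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .lmm import KinshipEigen, fit_lmm, fit_null_lmm

__all__ = [
    "BurdenResult",
    "uwss",
    "wss",
    "madsen_browning_weights",
    "burden_lm",
    "famskat",
    "pwst",
    "gene_scan",
    "chi2_mixture_sf",
    "beta_maf_weights",
]


@dataclass
class BurdenResult:
    gene: object
    test: str
    statistic: float
    p: float
    n_variants: int
    n_carriers: int
    details: dict = field(default_factory=dict)


def _impute_missing(G: np.ndarray) -> np.ndarray:
    """Missing dosages are imputed to twice the variant's MAF (its mean under HWE)."""
    from .qc import compute_maf

    G = np.asarray(G, dtype=float).copy()
    for j in range(G.shape[1]):
        col = G[:, j]
        miss = np.isnan(col)
        if miss.any():
            if miss.all():
                raise ValueError(f"variant column {j} entirely missing")
            maf, _ = compute_maf(col[~miss])
            col[miss] = 2.0 * maf
    return G


def uwss(G) -> np.ndarray:
    """Unweighted sum score: per-individual total count of variant alleles."""
    return _impute_missing(G).sum(axis=1)


def madsen_browning_weights(G, control_mask) -> np.ndarray:
    """Per-variant weights 1/sqrt(n_c * q_j * (1 - q_j)) from smoothed
    control minor-allele frequencies q_j = (m_j + 1) / (2 n_c + 2)."""
    G = np.asarray(G, dtype=float)
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.sum() == 0:
        raise ValueError(
            "no control individuals for WSS weights; pass control_mask covering "
            "married-in spouses or use all-sample frequencies explicitly"
        )
    Gc = G[control_mask]
    w = np.empty(G.shape[1])
    for j in range(G.shape[1]):
        col = Gc[:, j]
        obs = col[~np.isnan(col)]
        n_c = obs.size if obs.size else control_mask.sum()
        m_j = obs.sum()
        q = (m_j + 1.0) / (2.0 * n_c + 2.0)
        w[j] = 1.0 / np.sqrt(n_c * q * (1.0 - q))
    return w


def wss(G, control_mask=None, weights=None) -> np.ndarray:
    """Weighted sum score: per-individual weighted count of minor alleles."""
    Gi = _impute_missing(G)
    if weights is None:
        weights = madsen_browning_weights(G, control_mask)
    return Gi @ np.asarray(weights, dtype=float)


def burden_lm(
    score: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    eigen: KinshipEigen,
    gene=None,
    test: str = "UWSS",
    method: str = "ml",
) -> BurdenResult:
    """Kinship LMM with the collapsed score as the single genetic predictor.

    Variance components by maximum likelihood; the score effect is tested
    by a Wald test.
    """
    score = np.asarray(score, dtype=float)
    if np.nanstd(score) == 0:
        raise ValueError("burden score is constant; nothing to test")
    design = np.column_stack([np.atleast_2d(np.asarray(X, dtype=float)), score])
    fit = fit_null_lmm(np.asarray(y, dtype=float), design, eigen, method=method)
    beta = float(fit.beta[-1])
    se = float(np.sqrt(fit.beta_cov[-1, -1]))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BurdenResult(
        gene=gene,
        test=test,
        statistic=z**2,
        p=max(p, np.finfo(float).tiny),
        n_variants=0,
        n_carriers=int((score > 0).sum()),
        details={"beta": beta, "se": se, "method": method},
    )


# ---------------------------------------------------------------------------
# mixture-of-chi-squares tail probability


def _ruben_sf(q: float, lam: np.ndarray, max_terms: int = 12_000, tol: float = 1e-12):
    """Tail probability of sum(lam_j * chi2_1) by Ruben's series of central
    chi-square CDFs.

    With beta < min(lam) the coefficients a_k are positive and sum to 1, so
    the truncation error is bounded by the remaining mass 1 - sum(a_k); the
    series is exact to the requested tolerance when it converges.
    """
    m = lam.size
    beta = 0.90625 * lam.min()
    d = 1.0 - beta / lam  # each in [0, 1)
    a = np.zeros(max_terms)
    a[0] = np.exp(0.5 * np.sum(np.log(beta / lam)))
    total = a[0]
    dk = np.ones_like(lam)
    g = np.zeros(max_terms)
    k_used = max_terms - 1
    for k in range(1, max_terms):
        dk *= d
        g[k] = dk.sum()
        a[k] = np.dot(g[1 : k + 1], a[k - 1 :: -1]) / (2.0 * k)
        total += a[k]
        if 1.0 - total < tol:
            k_used = k
            break
    mass_gap = 1.0 - total
    if mass_gap > 1e-8:
        return np.nan  # series too slow for this eigenvalue spread
    ks = np.arange(k_used + 1)
    cdf = float(np.dot(a[: k_used + 1], stats.chi2.cdf(q / beta, m + 2 * ks)))
    return 1.0 - min(cdf + 0.0, 1.0)


def _saddlepoint_sf(q: float, lam: np.ndarray) -> float:
    """Kuonen saddlepoint (Lugannani-Rice) tail approximation."""
    mean = lam.sum()
    if abs(q - mean) < 1e-10 * max(mean, 1.0):
        return 0.5
    tmax = 1.0 / (2.0 * lam.max()) - 1e-10

    def kprime_minus_q(t):
        return np.sum(lam / (1.0 - 2.0 * t * lam)) - q

    lo, hi = (-1e4, tmax) if q > mean else (-1e8, 0.0)
    if q > mean:
        lo = 0.0
    try:
        t = optimize.brentq(kprime_minus_q, lo + 1e-12, hi - 1e-12 if hi > 0 else hi, maxiter=200)
    except ValueError:
        return np.nan
    K = -0.5 * np.sum(np.log1p(-2.0 * t * lam))
    Kpp = np.sum(2.0 * lam**2 / (1.0 - 2.0 * t * lam) ** 2)
    w = np.sign(t) * np.sqrt(max(2.0 * (t * q - K), 0.0))
    v = t * np.sqrt(Kpp)
    if w == 0 or v == 0:
        return 0.5
    return float(stats.norm.sf(w + np.log(v / w) / w))


def _satterthwaite_sf(q: float, lam: np.ndarray) -> float:
    a = np.sum(lam**2) / np.sum(lam)
    nu = np.sum(lam) ** 2 / np.sum(lam**2)
    return float(stats.chi2.sf(q / a, nu))


def chi2_mixture_sf(q: float, lambdas, method: str = "auto") -> tuple[float, str]:
    """P(sum lambda_j chi2_1 > q): Ruben's exact series, Kuonen saddlepoint
    for extreme tails or slowly converging eigenvalue spreads, Satterthwaite
    as last resort.

    Returns (p, method_used). p is clipped to (0, 1].
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12 * max(lam.max(initial=0.0), 1.0)]
    if lam.size == 0 or q <= 0:
        return 1.0, "degenerate"
    if method in ("auto", "ruben"):
        try:
            p = _ruben_sf(q, lam)
        except Exception:
            p = np.nan
        # below ~1e-10 the 1 - CDF subtraction loses precision: use the
        # saddlepoint, which has small *relative* error in the far tail
        if np.isfinite(p) and 1e-10 < p <= 1.0:
            return float(min(p, 1.0)), "ruben"
    if method in ("auto", "ruben", "saddlepoint"):
        p = _saddlepoint_sf(q, lam)
        if np.isfinite(p) and 0.0 < p <= 1.0:
            return float(p), "saddlepoint"
    p = _satterthwaite_sf(q, lam)
    return float(min(max(p, np.finfo(float).tiny), 1.0)), "satterthwaite"


def beta_maf_weights(mafs, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Per-variant Beta(a, b) density weights on MAF (default Beta(1, 25),
    upweighting the rarest variants)."""
    return stats.beta.pdf(np.asarray(mafs, dtype=float), a, b)


def famskat(
    y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray,
    eigen: KinshipEigen,
    weights=None,
    gene=None,
    method: str = "reml",
    null_fit=None,
) -> BurdenResult:
    """Family-based SKAT: kernel variance-component score test under a
    polygenic null model.

    Q = r' V^-1 G W^2 G' V^-1 r with V the fitted null covariance and W the
    diagonal per-variant weights (default Beta(1,25) on MAF). The null
    distribution is the chi-square mixture with eigenvalues of W G' P G W,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = _impute_missing(G)
    if weights is None:
        from .qc import compute_maf

        mafs = np.array([compute_maf(G[:, j])[0] for j in range(G.shape[1])])
        weights = beta_maf_weights(mafs)
    w = np.asarray(weights, dtype=float)
    if np.all(w == 0):
        raise ValueError("all famSKAT variant weights are zero")
    fit = null_fit if null_fit is not None else fit_null_lmm(y, X, eigen, method=method)
    U, s = fit.eigen.vectors, fit.eigen.values
    d = fit.gamma * s + 1.0
    inv_v_diag = 1.0 / (d * fit.sigma2_e)  # V^-1 in the rotated basis
    Gt = U.T @ G
    Xt = U.T @ X
    # V^-1 r in the rotated basis
    vinv_r = inv_v_diag * fit.resid_rotated
    t = (Gt.T @ vinv_r) * w
    Q = float(t @ t)
    # half-weighted matrices for the eigenvalue problem
    sq = np.sqrt(inv_v_diag)
    A = (Gt * sq[:, None]) * w[None, :]     # V^-1/2 G W
    B = Xt * sq[:, None]                    # V^-1/2 X
    BtB = B.T @ B
    AtB = A.T @ B
    M = A.T @ A - AtB @ np.linalg.solve(BtB, AtB.T)
    lam = np.linalg.eigvalsh((M + M.T) / 2.0)
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1.0)]
    if Q <= 0 or lam.size == 0:
        p, pmethod = 1.0, "degenerate"
    else:
        p, pmethod = chi2_mixture_sf(Q, lam)
    return BurdenResult(
        gene=gene,
        test="famSKAT",
        statistic=Q,
        p=p,
        n_variants=G.shape[1],
        n_carriers=int((np.nan_to_num(G) > 0).any(axis=1).sum()),
        details={"p_method": pmethod, "sigma2_g": fit.sigma2_g, "sigma2_e": fit.sigma2_e},
    )


def pwst(
    y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray,
    eigen: KinshipEigen,
    n_perm: int = 1000,
    seed: int = 0,
    gene=None,
    method: str = "ml",
    permute_raw: bool = False,
    null_fit=None,
) -> BurdenResult:
    """P-value-weighted sum test with a family-aware permutation null.

    Adaptive weights a_j = sign(beta_j) * (-log10 p_j) come from per-variant
    score tests under the fitted polygenic null; the observed statistic is
    the Wald z^2 of the a-weighted burden score. The null is built by
    decorrelating the phenotype residuals with the null covariance
    (r~ = V^-1/2 r), permuting them, back-transforming, and re-estimating
    the weights and statistic each round — re-estimation per permutation is
    what neutralizes the overfitting of the adaptive score. With
    ``permute_raw`` the raw residuals are permuted instead (ignores family
    correlation; for comparison only).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable permutation p-value")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = _impute_missing(G)
    fit = null_fit if null_fit is not None else fit_null_lmm(y, X, eigen, method=method)
    U, s = fit.eigen.vectors, fit.eigen.values
    d = fit.gamma * s + 1.0
    sqw = 1.0 / np.sqrt(d * fit.sigma2_e)  # rows of V^-1/2 in the rotated basis
    # star space: V^-1/2-transformed data, where GLS is plain OLS
    ys = sqw * (U.T @ y)
    Xs = sqw[:, None] * (U.T @ X)
    Gs = sqw[:, None] * (U.T @ G)
    Qx, _ = np.linalg.qr(Xs)
    def resid_x(v):
        return v - Qx @ (Qx.T @ v)
    Gp = Gs - Qx @ (Qx.T @ Gs)
    gnorm2 = (Gp**2).sum(axis=0)
    keep = gnorm2 > 1e-12
    if not keep.any():
        raise ValueError("all variants collinear with covariates")
    Gp = Gp[:, keep]
    gnorm2 = gnorm2[keep]
    e_obs = resid_x(ys)
    n, p_cov = Xs.shape
    dof = n - p_cov - 1

    def statistic(e):
        # per-variant GLS slope tests
        bt = (Gp.T @ e) / gnorm2
        rss = (e @ e) - bt**2 * gnorm2
        se = np.sqrt(np.maximum(rss, 1e-300) / dof / gnorm2)
        z = bt / se
        pj = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
        a = np.sign(bt) * (-np.log10(pj))
        b = Gp @ a
        bb = float(b @ b)
        if bb <= 1e-300:
            return 0.0
        bhat = float(b @ e) / bb
        rss_b = float(e @ e) - bhat**2 * bb
        se_b = np.sqrt(max(rss_b, 1e-300) / dof / bb)
        return (bhat / se_b) ** 2

    obs = statistic(e_obs)
    if permute_raw:
        # permute raw-scale residuals, then decorrelate
        r_raw = U @ fit.resid_rotated
        exceed = 0
        bad = 0
        for _ in range(n_perm):
            e = resid_x(sqw * (U.T @ rng.permutation(r_raw)))
            st = statistic(e)
            if not np.isfinite(st):
                bad += 1
                continue
            if st >= obs:
                exceed += 1
    else:
        exceed = 0
        bad = 0
        for _ in range(n_perm):
            e = resid_x(rng.permutation(e_obs))
            st = statistic(e)
            if not np.isfinite(st):
                bad += 1
                continue
            if st >= obs:
                exceed += 1
    details = {"n_perm": n_perm, "seed": seed, "n_nonfinite": bad}
    if bad > 0.05 * n_perm:
        details["flagged"] = "non-finite statistic in > 5 % of permutations"
    p = (1.0 + exceed) / (n_perm + 1.0)
    return BurdenResult(
        gene=gene,
        test="PWST",
        statistic=obs,
        p=p,
        n_variants=int(keep.sum()),
        n_carriers=int((G > 0).any(axis=1).sum()),
        details=details,
    )


def gene_scan(
    gene_sets: dict,
    y: np.ndarray,
    X: np.ndarray,
    eigen: KinshipEigen,
    tests=("famskat", "pwst"),
    control_mask=None,
    n_perm: int = 1000,
    seed: int = 0,
    suggestive: float = 1.0e-3,
) -> pd.DataFrame:
    """Run the requested gene-level tests for every gene.

    ``gene_sets`` maps gene -> (individuals x variants) dosage block of
    post-QC rare functional variants. Genes with < 2 variants are reported
    with a skip flag rather than tested. The significance threshold is the
    Bonferroni 0.05 / n_genes; ``suggestive`` is a fixed secondary tier.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    genes = list(gene_sets)
    n_genes = len(genes)
    threshold = 0.05 / n_genes if n_genes else np.nan
    null_reml = fit_null_lmm(y, X, eigen, method="reml")
    null_ml = fit_null_lmm(y, X, eigen, method="ml")
    rows = []
    for k, gene in enumerate(genes):
        G = np.asarray(gene_sets[gene], dtype=float)
        if G.ndim != 2 or G.shape[1] < 2:
            rows.append({"gene": gene, "test": None, "statistic": np.nan, "p": np.nan,
                         "n_variants": 0 if G.ndim != 2 else G.shape[1],
                         "skipped": True, "tier": "skipped"})
            continue
        results = []
        for test in tests:
            t = test.lower()
            if t == "famskat":
                results.append(famskat(y, X, G, eigen, gene=gene, null_fit=null_reml))
            elif t == "pwst":
                results.append(
                    pwst(y, X, G, eigen, n_perm=n_perm, seed=seed + k, gene=gene,
                         null_fit=null_ml)
                )
            elif t == "uwss":
                results.append(burden_lm(uwss(G), y, X, eigen, gene=gene, test="UWSS"))
            elif t == "wss":
                score = wss(G, control_mask=control_mask)
                results.append(burden_lm(score, y, X, eigen, gene=gene, test="WSS"))
            else:
                raise ValueError(f"unknown test {test!r}")
        for r in results:
            tier = (
                "significant" if r.p < threshold
                else "suggestive" if r.p < suggestive
                else "ns"
            )
            rows.append({"gene": r.gene, "test": r.test, "statistic": r.statistic,
                         "p": r.p, "n_variants": r.n_variants,
                         "n_carriers": r.n_carriers, "skipped": False, "tier": tier})
    out = pd.DataFrame(rows)
    out.attrs["significance_threshold"] = threshold
    out.attrs["suggestive_threshold"] = suggestive
    return out
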