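"""Gene-level burden and kernel tests: scores, famSKAT, PWST."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import integrate, stats

from famvar.burden import (
    burden_lm,
    chi2_mixture_sf,
    famskat,
    gene_scan,
    madsen_browning_weights,
    pwst,
    uwss,
    wss,
)
from famvar.lmm import KinshipEigen, fit_null_lmm
from famvar.pedigree import KinshipMatrix, compute_kinship
from famvar.simulate import SimulationConfig, simulate_genotypes, simulate_pedigrees


def identity_eigen(n):
    return KinshipEigen.from_kinship(
        KinshipMatrix([f"i{k}" for k in range(n)], 0.5 * np.eye(n))
    )


def rare_genotypes(rng, n, m, maf=0.03):
    G = rng.binomial(1, maf, size=(n, m)).astype(float) + rng.binomial(
        1, maf, size=(n, m)
    )
    # ensure non-constant columns
    for j in range(m):
        if G[:, j].std() == 0:
            G[rng.integers(n), j] = 1.0
    return G


@pytest.fixture(scope="module")
def family_setup():
    ped = simulate_pedigrees(SimulationConfig(seed=31, n_families=50))
    kin = compute_kinship(ped)
    eigen = KinshipEigen.from_kinship(kin)
    L = np.linalg.cholesky(2 * kin.phi + 1e-10 * np.eye(len(kin.individuals)))
    return ped, kin, eigen, L


class TestScores:
    def test_uwss_row_sums(self):
        G = np.array([[0.0, 1.0, 2.0, 0.0], [0.0, 0.0, 0.0, 0.0]])
        assert list(uwss(G)) == [3.0, 0.0]

    def test_uwss_missing_imputed_to_2maf(self):
        # column 2 has one alt allele among 100 non-missing genotypes: maf 0.005
        G = np.zeros((101, 3))
        G[0] = [0.0, np.nan, 1.0]
        G[1, 1] = 1.0  # defines column-1 maf = 1/200 = 0.005
        out = uwss(G)
        assert out[0] == pytest.approx(1.0 + 2.0 * 0.005)

    def test_wss_weight_closed_form(self):
        # 100 controls all heterozygous: q = (100+1)/202 = 0.5, w = 1/sqrt(25)
        G = np.ones((150, 1))
        mask = np.zeros(150, dtype=bool)
        mask[:100] = True
        w = madsen_browning_weights(G, mask)
        assert w[0] == pytest.approx(0.2)

    def test_wss_weights_decrease_with_frequency(self):
        n_c = 200
        ws = []
        for mac in (1, 10, 60, 150):
            G = np.zeros((n_c, 1))
            G[:mac] = 1.0
            ws.append(madsen_browning_weights(G, np.ones(n_c, dtype=bool))[0])
        assert np.all(np.diff(ws) < 0)

    def test_wss_zero_genotypes_zero_scores(self):
        G = np.zeros((50, 3))
        mask = np.ones(50, dtype=bool)
        assert np.all(wss(G, mask) == 0.0)

    def test_wss_with_unit_weights_equals_uwss(self):
        rng = np.random.default_rng(0)
        G = rare_genotypes(rng, 80, 5)
        assert np.allclose(wss(G, weights=np.ones(5)), uwss(G))

    def test_no_controls_errors(self):
        with pytest.raises(ValueError, match="control"):
            madsen_browning_weights(np.ones((10, 1)), np.zeros(10, dtype=bool))


class TestBurdenLm:
    def test_constant_score_rejected(self):
        eigen = identity_eigen(20)
        with pytest.raises(ValueError, match="constant"):
            burden_lm(np.ones(20), np.zeros(20), np.ones((20, 1)), eigen)

    def test_matches_ols_when_unrelated(self):
        rng = np.random.default_rng(1)
        n = 150
        eigen = identity_eigen(n)
        score = uwss(rare_genotypes(rng, n, 6))
        y = 0.3 * score + rng.standard_normal(n)
        X = np.ones((n, 1))
        res = burden_lm(score, y, X, eigen)
        ols = sm.OLS(y, np.column_stack([X, score])).fit()
        assert res.details["beta"] == pytest.approx(ols.params[-1], rel=1e-6)

    def test_effect_recovery(self, family_setup):
        _, _, eigen, L = family_setup
        rng = np.random.default_rng(2)
        n = len(eigen.individuals)
        betas = []
        for _ in range(25):
            score = uwss(rare_genotypes(rng, n, 8))
            y = 0.3 * score + 0.5 * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
            betas.append(burden_lm(score, y, np.ones((n, 1)), eigen).details["beta"])
        assert abs(np.mean(betas) - 0.3) < 0.05


def oracle_skat_p(y, X, G, w):
    """From-scratch standard SKAT under independence: OLS null model,
    Q = (r/s2)' G W^2 G' (r/s2), chi-square-mixture tail by high-precision
    oscillatory quadrature of Imhof's inversion integral (mpmath)."""
    import mpmath as mp

    n, p = X.shape
    bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ bhat
    s2 = (r @ r) / (n - p)
    Q = (r / s2) @ G @ np.diag(w**2) @ G.T @ (r / s2)
    H = X @ np.linalg.solve(X.T @ X, X.T)
    P = (np.eye(n) - H) / s2
    M = np.diag(w) @ G.T @ P @ G @ np.diag(w)
    lam = np.linalg.eigvalsh((M + M.T) / 2)
    lam = [mp.mpf(x) for x in lam[lam > 1e-10 * lam.max()]]
    q = mp.mpf(float(Q))

    def integrand(u):
        theta = mp.mpf(0.5) * mp.fsum(mp.atan(l * u) for l in lam) - mp.mpf(0.5) * q * u
        rho = mp.exp(mp.mpf(0.25) * mp.fsum(mp.log(1 + (l * u) ** 2) for l in lam))
        return mp.sin(theta) / (u * rho)

    val = mp.quadosc(integrand, [0, mp.inf], period=4 * mp.pi / q)
    return float(mp.mpf(0.5) + val / mp.pi)


class TestFamskat:
    def test_equals_skat_under_independence(self):
        """With identity relatedness famSKAT reduces to standard SKAT."""
        rng = np.random.default_rng(3)
        for rep in range(20):
            n, m = 120, 6
            eigen = identity_eigen(n)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            G = rare_genotypes(rng, n, m)
            y = rng.standard_normal(n)
            w = np.ones(m)
            res = famskat(y, X, G, eigen, weights=w)
            p_oracle = oracle_skat_p(y, X, G, w)
            assert abs(res.p - p_oracle) < 1e-6

    def test_orthogonal_residuals_give_q_zero(self):
        n = 60
        eigen = identity_eigen(n)
        X = np.ones((n, 1))
        # residuals after the intercept are y - mean(y); make them zero at
        # every carrier so r is orthogonal to each genotype column
        noise = np.sin(np.arange(n - 2))
        y = np.empty(n)
        y[2:] = 5.0 + (noise - noise.mean())
        y[0] = y[1] = 5.0  # carriers sit exactly at the overall mean
        G = np.zeros((n, 2))
        G[0, 0] = 1.0
        G[1, 1] = 1.0
        res = famskat(y, X, G, eigen, weights=np.ones(2))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_column_order_invariance(self, family_setup):
        _, _, eigen, L = family_setup
        rng = np.random.default_rng(4)
        n = len(eigen.individuals)
        G = rare_genotypes(rng, n, 7)
        y = 0.4 * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
        X = np.ones((n, 1))
        w = np.linspace(1.0, 2.0, 7)
        perm = rng.permutation(7)
        r1 = famskat(y, X, G, eigen, weights=w)
        r2 = famskat(y, X, G[:, perm], eigen, weights=w[perm])
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-10)
        assert r1.p == pytest.approx(r2.p, rel=1e-8)

    def test_single_variant_matches_score_test_quadratic(self):
        # one variant + flat weight: famSKAT Q is the squared score, and the
        # mixture collapses to a scaled 1-df chi-square
        rng = np.random.default_rng(5)
        n = 200
        eigen = identity_eigen(n)
        X = np.ones((n, 1))
        g = rng.binomial(2, 0.1, n).astype(float)
        y = rng.standard_normal(n)
        res = famskat(y, X, g[:, None], eigen, weights=np.ones(1))
        # independent 1-df computation: z^2 of the score statistic
        bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ bhat
        s2 = (r @ r) / (n - 1)
        gc = g - g.mean()
        z2 = (gc @ r) ** 2 / (s2 * (gc @ gc))
        assert res.p == pytest.approx(stats.chi2.sf(z2, 1), abs=1e-6)

    def test_zero_weights_rejected(self):
        eigen = identity_eigen(10)
        with pytest.raises(ValueError, match="weights"):
            famskat(np.zeros(10), np.ones((10, 1)), np.zeros((10, 2)) + np.eye(10)[:, :2],
                    eigen, weights=np.zeros(2))


class TestChi2Mixture:
    def test_single_component_is_chi2(self):
        for q in (0.5, 2.0, 8.0):
            p, _ = chi2_mixture_sf(q, [1.0])
            assert p == pytest.approx(stats.chi2.sf(q, 1), abs=1e-8)

    def test_equal_components_chi2_k(self):
        p, _ = chi2_mixture_sf(10.0, [2.0, 2.0, 2.0])
        assert p == pytest.approx(stats.chi2.sf(5.0, 3), abs=1e-8)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(6)
        lam = np.array([3.0, 1.0, 0.5, 0.1])
        draws = (rng.standard_normal((200_000, 4)) ** 2) @ lam
        q = 8.0
        p_mc = (draws > q).mean()
        p, _ = chi2_mixture_sf(q, lam)
        se = np.sqrt(p_mc * (1 - p_mc) / draws.shape[0])
        assert abs(p - p_mc) < 4 * se

    def test_extreme_tail_uses_fallback_sanely(self):
        p, method = chi2_mixture_sf(500.0, [1.0, 0.5])
        assert 0 < p < 1e-20


class TestPwst:
    def test_seed_reproducibility(self, family_setup):
        _, _, eigen, L = family_setup
        rng = np.random.default_rng(7)
        n = len(eigen.individuals)
        G = rare_genotypes(rng, n, 6)
        y = 0.4 * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
        X = np.ones((n, 1))
        r1 = pwst(y, X, G, eigen, n_perm=150, seed=99)
        r2 = pwst(y, X, G, eigen, n_perm=150, seed=99)
        assert r1.p == r2.p and r1.statistic == r2.statistic

    def test_p_floor(self, family_setup):
        _, _, eigen, L = family_setup
        rng = np.random.default_rng(8)
        n = len(eigen.individuals)
        G = rare_genotypes(rng, n, 6)
        # overwhelming signal: p attains its 1/(n_perm+1) floor
        y = 3.0 * uwss(G) + 0.1 * rng.standard_normal(n)
        res = pwst(y, np.ones((n, 1)), G, eigen, n_perm=100, seed=1)
        assert res.p >= 1.0 / 101.0
        assert res.p == pytest.approx(1.0 / 101.0)

    def test_nperm_minimum_enforced(self, family_setup):
        _, _, eigen, _ = family_setup
        n = len(eigen.individuals)
        with pytest.raises(ValueError, match="n_perm"):
            pwst(np.zeros(n), np.ones((n, 1)), np.zeros((n, 2)), eigen, n_perm=50)

    def test_power_exceeds_null(self, family_setup):
        """All-causal genes give systematically smaller p than matched nulls."""
        _, _, eigen, L = family_setup
        rng = np.random.default_rng(9)
        n = len(eigen.individuals)
        p_causal, p_null = [], []
        for rep in range(10):
            G = rare_genotypes(rng, n, 6)
            u = 0.5 * (L @ rng.standard_normal(n))
            y1 = 0.5 * uwss(G) + u + rng.standard_normal(n)
            y0 = u + rng.standard_normal(n)
            p_causal.append(pwst(y1, np.ones((n, 1)), G, eigen, n_perm=150, seed=rep).p)
            p_null.append(pwst(y0, np.ones((n, 1)), G, eigen, n_perm=150, seed=rep).p)
        assert np.median(p_causal) < np.median(p_null)


class TestGeneScan:
    def test_thresholds_and_skips(self, family_setup):
        _, _, eigen, L = family_setup
        rng = np.random.default_rng(10)
        n = len(eigen.individuals)
        gene_sets = {
            "GENE_OK": rare_genotypes(rng, n, 5),
            "GENE_TINY": rare_genotypes(rng, n, 1),
        }
        y = 0.5 * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
        out = gene_scan(gene_sets, y, np.ones((n, 1)), eigen,
                        tests=("famskat",), n_perm=100)
        assert out.attrs["significance_threshold"] == pytest.approx(0.05 / 2)
        skipped = out[out["gene"] == "GENE_TINY"]
        assert bool(skipped["skipped"].iloc[0])
        tested = out[(out["gene"] == "GENE_OK") & (out["test"] == "famSKAT")]
        assert 0 < tested["p"].iloc[0] <= 1

    def test_spiked_gene_detected(self, family_setup):
        _, _, eigen, L = family_setup
        rng = np.random.default_rng(11)
        n = len(eigen.individuals)
        gene_sets = {f"G{k}": rare_genotypes(rng, n, 5) for k in range(10)}
        y = (
            0.6 * uwss(gene_sets["G3"])
            + 0.5 * (L @ rng.standard_normal(n))
            + rng.standard_normal(n)
        )
        out = gene_scan(gene_sets, y, np.ones((n, 1)), eigen, tests=("famskat",))
        sub = out[out["test"] == "famSKAT"].set_index("gene")
        assert sub["p"].idxmin() == "G3"
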