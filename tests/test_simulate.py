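"""Synthetic-data generator: structure, determinism, and ground truth."""

import numpy as np
import pytest
from scipy import stats

from famvar.pedigree import compute_kinship, find_mendel_errors
from famvar.qc import compute_maf
from famvar.simulate import (
    SimulationConfig,
    inject_artifacts,
    simulate_dataset,
    simulate_genotypes,
    simulate_lifetable,
    simulate_pedigrees,
    simulate_phenotypes,
)


class TestPedigreeStructure:
    def test_minimum_family_size_and_invariants(self, small_dataset):
        ped = small_dataset.pedigree
        sizes = ped.table.groupby("family").size()
        assert (sizes >= 3).all()
        # construction already enforces Pedigree invariants; check generations
        assert set(ped.table["generation"]) <= {0, 1, 2}

    def test_spouses_unrelated_to_blood_relatives(self, small_dataset):
        ped = small_dataset.pedigree
        phen = small_dataset.phenotypes.set_index("individual")
        kin = compute_kinship(ped)
        spouses = phen.index[phen["role"] == "spouse_control"]
        bloods = phen.index[phen["role"].isin(["founder_parent", "proband_gen"])]
        fam = ped.table.set_index("individual")["family"]
        for s in list(spouses)[:10]:
            for b in bloods[fam[bloods] == fam[s]][:5]:
                assert kin.get(s, b) == 0.0

    def test_sibship_has_at_least_two(self):
        ped = simulate_pedigrees(SimulationConfig(seed=3, n_families=10))
        t = ped.table
        parents = t.dropna(subset=["father"])
        gen1 = parents[parents["generation"] == 1]
        sib_counts = gen1.groupby(["family", "father", "mother"]).size()
        assert (sib_counts >= 2).all()


class TestGenotypes:
    def test_transmission_frequency(self):
        """A heterozygous founder transmits the alt allele half the time."""
        cfg = SimulationConfig(seed=5, n_families=1, mean_extra_sibs=0,
                               mean_extra_offspring=0, n_genes=1,
                               mean_variants_per_gene=2, n_causal_genes=0)
        rng = np.random.default_rng(0)
        transmitted = 0
        total = 0
        # binomial oracle over many simulated meioses via gene dropping
        for seed in range(300):
            cfg2 = SimulationConfig(seed=seed, n_families=5, mean_extra_sibs=1,
                                    mean_extra_offspring=1, n_genes=2,
                                    mean_variants_per_gene=3, n_causal_genes=0,
                                    private_fraction=1.0, rare_fraction=0.0)
            ped = simulate_pedigrees(cfg2)
            gm, _ = simulate_genotypes(ped, cfg2)
            t = ped.table.set_index("individual")
            idx = {i: k for k, i in enumerate(gm.individuals)}
            for j in range(gm.n_variants):
                col = gm.dosages[:, j]
                carriers = [gm.individuals[k] for k in np.nonzero(col == 1)[0]]
                for c in carriers:
                    if not t.loc[c, "founder"]:
                        continue
                    kids = t[(t["father"] == c) | (t["mother"] == c)].index
                    for kid in kids:
                        total += 1
                        transmitted += col[idx[kid]] >= 1
        assert total > 1000
        se = np.sqrt(0.25 / total)
        assert abs(transmitted / total - 0.5) < 4 * se

    def test_monomorphic_without_carriers(self):
        cfg = SimulationConfig(seed=7, n_families=5, n_genes=3,
                               private_fraction=0.0, rare_fraction=1.0,
                               rare_maf_range=(1e-9, 2e-9), n_causal_genes=0)
        ped = simulate_pedigrees(cfg)
        gm, _ = simulate_genotypes(ped, cfg)
        assert np.all(gm.dosages == 0)

    def test_clean_background_has_no_mendel_errors(self, small_dataset):
        report = find_mendel_errors(small_dataset.genotypes, small_dataset.pedigree)
        assert len(report.errors) == 0

    def test_private_variants_single_family(self):
        cfg = SimulationConfig(seed=9, n_families=20, n_genes=10,
                               private_fraction=1.0, rare_fraction=0.0,
                               n_causal_genes=0)
        ped = simulate_pedigrees(cfg)
        gm, _ = simulate_genotypes(ped, cfg)
        fam = ped.table.set_index("individual")["family"]
        for j in range(gm.n_variants):
            carriers = [gm.individuals[k] for k in np.nonzero(gm.dosages[:, j] > 0)[0]]
            assert len(set(fam[c] for c in carriers)) <= 1


class TestPhenotypes:
    def test_zero_heritability_zero_polygenic(self):
        cfg = SimulationConfig(seed=11, n_families=10, heritability=0.0)
        ped = simulate_pedigrees(cfg)
        gm, truth = simulate_genotypes(ped, cfg)
        _, truth = simulate_phenotypes(ped, gm, cfg, truth)
        assert np.all(truth.polygenic_values.to_numpy() == 0.0)

    def test_heritability_recovered_by_he_regression(self):
        """Haseman-Elston-style regression of trait cross-products on 2*phi
        recovers sigma2_g = h2 within 20 %."""
        cfg = SimulationConfig(seed=13, n_families=120, heritability=0.5,
                               n_genes=2, n_causal_genes=0)
        ped = simulate_pedigrees(cfg)
        gm, truth = simulate_genotypes(ped, cfg)
        phen, truth = simulate_phenotypes(ped, gm, cfg, truth)
        kin = truth.true_kinship
        y = phen["trait"].to_numpy()
        y = (y - y.mean())
        K = 2 * kin.phi
        n = len(y)
        iu = np.triu_indices(n, k=1)
        x = K[iu]
        keep = x > 0  # related pairs carry the signal
        cp = (y[:, None] * y[None, :])[iu]
        slope = np.polyfit(x[keep], cp[keep], 1)[0]
        assert slope == pytest.approx(0.5, rel=0.2)

    def test_roles_cover_three_generations(self, small_dataset):
        roles = set(small_dataset.phenotypes["role"])
        assert {"founder_parent", "proband_gen", "spouse_control", "offspring"} <= roles


class TestLifetable:
    def test_s0_is_one_and_monotone(self):
        lt = simulate_lifetable(SimulationConfig(seed=1))
        assert lt.survival[0] == 1.0
        assert np.all(np.diff(lt.survival) <= 0)

    def test_exponential_limit(self):
        cfg = SimulationConfig(seed=1, gompertz={"male": (0.01, 1e-8),
                                                 "female": (0.01, 1e-8)})
        lt = simulate_lifetable(cfg, sex="male")
        expected = np.exp(-0.01 * lt.ages)
        assert np.max(np.abs(lt.survival - expected)) < 1e-6

    def test_hazard_doubling_time(self):
        """Finite-difference hazard from the emitted table doubles every ln2/b."""
        cfg = SimulationConfig(seed=1)
        a, b = cfg.gompertz["male"]
        lt = simulate_lifetable(cfg, sex="male", step=0.25)
        s = lt.survival
        haz = -np.diff(np.log(s)) / 0.25
        ages = lt.ages[:-1]
        lo = np.searchsorted(ages, 50.0)
        hi = np.searchsorted(ages, 50.0 + np.log(2) / b)
        assert haz[hi] / haz[lo] == pytest.approx(2.0, rel=0.02)


class TestArtifacts:
    def test_zero_rates_identity(self, small_dataset):
        cfg = small_dataset.config
        gm2, _ = inject_artifacts(small_dataset.genotypes, small_dataset.pedigree, cfg)
        assert np.array_equal(gm2.dosages, small_dataset.genotypes.dosages,
                              equal_nan=True)

    def test_missingness_rate(self):
        cfg = SimulationConfig(seed=17, n_families=40, n_genes=10,
                               missingness_rate=0.5)
        ped = simulate_pedigrees(cfg)
        gm, truth = simulate_genotypes(ped, cfg)
        gm2, _ = inject_artifacts(gm, ped, cfg, truth)
        rate = np.isnan(gm2.dosages).mean()
        assert rate == pytest.approx(0.5, abs=0.03)

    def test_injected_family_counts(self, degraded_dataset):
        from famvar.pedigree import mendel_family_counts

        ds = degraded_dataset
        counts = mendel_family_counts(find_mendel_errors(ds.genotypes, ds.pedigree))
        for var, fams in ds.truth.injected_error_families.items():
            assert counts[var] >= len(fams)

    def test_capture_gap_zero_call_rate(self, degraded_dataset):
        gm = degraded_dataset.genotypes
        gap = degraded_dataset.truth.degraded_variants["capture_gap"]
        assert len(gap) > 0
        vlist = list(gm.variants["variant"])
        for v in gap:
            assert np.isnan(gm.dosages[:, vlist.index(v)]).all()


class TestDeterminism:
    def test_identical_seed_identical_dataset(self):
        cfg = dict(seed=19, n_families=8, n_genes=5, mendel_error_rate=0.001,
                   missingness_rate=0.02)
        a = simulate_dataset(SimulationConfig(**cfg))
        b = simulate_dataset(SimulationConfig(**cfg))
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages, equal_nan=True)
        assert a.pedigree.table.equals(b.pedigree.table)
        assert a.phenotypes.equals(b.phenotypes)
        assert a.truth.causal_variants == b.truth.causal_variants

    def test_different_seed_differs(self):
        a = simulate_dataset(SimulationConfig(seed=1, n_families=8, n_genes=5))
        b = simulate_dataset(SimulationConfig(seed=2, n_families=8, n_genes=5))
        assert not np.array_equal(a.genotypes.dosages, b.genotypes.dosages)

    def test_mostly_rare_and_private(self, small_dataset):
        """Defaults reproduce the qualitative spectrum: most variants rare."""
        gm = small_dataset.genotypes
        mafs = []
        for j in range(gm.n_variants):
            col = gm.dosages[:, j]
            if np.isnan(col).all():
                continue
            maf, mac = compute_maf(col)
            if mac > 0:
                mafs.append(maf)
        mafs = np.array(mafs)
        assert (mafs < 0.01).mean() > 0.5
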