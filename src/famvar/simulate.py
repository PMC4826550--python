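"""Synthetic three-generation family cohort with known ground truth.

Emulates the structure of a long-lived family cohort: an (optionally
recorded) founder parent couple, a proband-generation sibship with
married-in spouse controls, and an offspring generation. Genotypes arise by
gene dropping from founder alleles drawn from a rare-shifted site-frequency
spectrum with pedigree-private singletons; phenotypes follow the additive
model y = G beta + u + e with a kinship-structured polygenic term
u ~ N(0, 2*Phi*sigma2_g). Life tables are Gompertz. QC artifacts (Mendel
errors, missingness, low coverage/quality, capture gaps) are injected with
recorded ground truth so filter behaviour is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptionality import LifeTable
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree, compute_kinship

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_pedigrees",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_lifetable",
    "inject_artifacts",
    "simulate_dataset",
]

#: functional-class sampling probabilities, shaped to the qualitative mix of a
#: candidate-gene capture panel (about 37 % coding, half UTR, most of the rest
#: splicing/ncRNA/intronic)
CLASS_PROBS = {
    "nsyn-exonic": 0.200,
    "syn-exonic": 0.168,
    "stopgain": 0.004,
    "stoploss": 0.002,
    "UTR3": 0.300,
    "UTR5": 0.207,
    "splicing": 0.010,
    "ncRNA": 0.020,
    "intronic": 0.070,
    "intergenic": 0.019,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator. The seed is mandatory for reproducibility."""

    seed: int
    n_families: int = 50
    mean_extra_sibs: float = 1.0        # sibship size = 2 + Poisson(mean)
    mean_extra_offspring: float = 1.0   # offspring per sib couple = 1 + Poisson(mean)
    spouse_inclusion: bool = True
    include_founder_parents: bool = True
    n_genes: int = 100
    mean_variants_per_gene: float = 8.0
    private_fraction: float = 0.55      # singleton founder carrier
    rare_fraction: float = 0.35         # Beta-tail MAF in [0.0005, 0.05]
    rare_maf_range: tuple = (0.0005, 0.05)
    n_causal_genes: int = 1
    causal_variants_per_gene: int = 10
    causal_effect: float = 1.0
    heritability: float = 0.3
    residual_sd: float | None = None    # default sqrt(1 - h^2)
    gompertz: dict = field(
        default_factory=lambda: {"male": (7.0e-5, 0.09), "female": (4.5e-5, 0.09)}
    )
    mendel_error_rate: float = 0.0      # fraction of (trio, variant) cells corrupted
    missingness_rate: float = 0.0
    low_coverage_fraction: float = 0.0
    low_quality_fraction: float = 0.0
    capture_gap_fraction: float = 0.0
    center_effect_sd: float = 0.0       # field-center offsets on the trait

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("private_fraction", "rare_fraction", "mendel_error_rate",
                     "missingness_rate", "low_coverage_fraction",
                     "low_quality_fraction", "capture_gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.heritability < 1.0:
            raise ValueError("heritability must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    causal_variants: list = field(default_factory=list)
    causal_effects: dict = field(default_factory=dict)
    causal_genes: list = field(default_factory=list)
    polygenic_values: pd.Series | None = None
    injected_error_trios: pd.DataFrame | None = None
    injected_error_families: dict = field(default_factory=dict)
    true_kinship: object = None
    center_effects: dict = field(default_factory=dict)
    degraded_variants: dict = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    lifetables: dict
    gene_map: pd.DataFrame
    truth: GroundTruth


def _rng(seed, salt: int) -> np.random.Generator:
    return np.random.default_rng((int(seed) * 1_000_003 + salt) % 2**31)


def simulate_pedigrees(config: SimulationConfig) -> Pedigree:
    """Three-generation families: founder parents, proband sibship with
    married-in spouses, and offspring. Minimum family size 3."""
    rng = _rng(config.seed, 1)
    rows = []
    for f in range(config.n_families):
        fam = f"F{f + 1:03d}"
        counter = 0

        def new_id():
            nonlocal counter
            counter += 1
            return f"{fam}_I{counter:02d}"

        father = mother = None
        if config.include_founder_parents:
            father, mother = new_id(), new_id()
            rows.append((fam, father, None, None, "male"))
            rows.append((fam, mother, None, None, "female"))
        n_sibs = 2 + rng.poisson(config.mean_extra_sibs)
        for _ in range(n_sibs):
            sib = new_id()
            sex = "male" if rng.random() < 0.5 else "female"
            rows.append((fam, sib, father, mother, sex))
            spouse = None
            if config.spouse_inclusion:
                spouse = new_id()
                rows.append((fam, spouse, None, None,
                             "female" if sex == "male" else "male"))
            n_off = 1 + rng.poisson(config.mean_extra_offspring)
            for _ in range(n_off):
                kid = new_id()
                kid_sex = "male" if rng.random() < 0.5 else "female"
                if spouse is not None:
                    pa = sib if sex == "male" else spouse
                    ma = spouse if sex == "male" else sib
                else:
                    pa = sib if sex == "male" else None
                    ma = sib if sex == "female" else None
                rows.append((fam, kid, pa, ma, kid_sex))
    table = pd.DataFrame(rows, columns=["family", "individual", "father", "mother", "sex"])
    return Pedigree(table)


def _founder_mafs(rng, n_variants: int, config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant founder MAF and a flag for pedigree-private singletons."""
    u = rng.random(n_variants)
    private = u < config.private_fraction
    rare = (~private) & (u < config.private_fraction + config.rare_fraction)
    lo, hi = config.rare_maf_range
    maf = np.empty(n_variants)
    maf[private] = 0.0  # handled by explicit singleton carrier
    maf[rare] = lo + (hi - lo) * rng.beta(0.5, 3.0, size=int(rare.sum()))
    common = ~(private | rare)
    maf[common] = rng.uniform(0.05, 0.5, size=int(common.sum()))
    return maf, private


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Founder alleles at configured frequencies, descendants by gene dropping."""
    rng = _rng(config.seed, 2)
    t = pedigree.table.sort_values("generation", kind="stable").reset_index(drop=True)
    ids = list(t["individual"])
    pos = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)

    n_per_gene = np.maximum(2, rng.poisson(config.mean_variants_per_gene, size=config.n_genes))
    causal_genes = sorted(rng.choice(config.n_genes, size=config.n_causal_genes, replace=False))
    for g in causal_genes:
        n_per_gene[g] = max(n_per_gene[g], config.causal_variants_per_gene + 2)
    genes = [f"GENE{g + 1:04d}" for g in range(config.n_genes)]
    gene_of = np.repeat(np.arange(config.n_genes), n_per_gene)
    m = int(n_per_gene.sum())

    maf, private = _founder_mafs(rng, m, config)
    classes = rng.choice(list(CLASS_PROBS), size=m, p=list(CLASS_PROBS.values()))

    # choose causal variants: rare + functional within each causal gene
    causal_idx = []
    for g in causal_genes:
        in_gene = np.nonzero(gene_of == g)[0]
        chosen = in_gene[: config.causal_variants_per_gene]
        # causal variants emulate pedigree-specific rare variation: founder MAF
        # low enough that the realized cohort MAF stays below the burden-mode
        # rarity cutoff (0.01) even after within-family amplification
        maf[chosen] = rng.uniform(0.001, 0.004, size=len(chosen))
        private[chosen] = False
        classes[chosen] = "nsyn-exonic"
        causal_idx.extend(chosen.tolist())

    founder_rows = np.nonzero(t["founder"].to_numpy())[0]
    alleles = np.zeros((n, 2, m), dtype=np.int8)
    # founder alleles by frequency
    for a in (0, 1):
        alleles[founder_rows, a, :] = (
            rng.random((len(founder_rows), m)) < maf[None, :]
        ).astype(np.int8)
    # pedigree-private singletons: one heterozygous founder carrier
    for j in np.nonzero(private)[0]:
        carrier = founder_rows[rng.integers(len(founder_rows))]
        alleles[carrier, rng.integers(2), j] = 1
    # every spiked causal variant segregates: assign a founder carrier when
    # binomial sampling at its (very low) MAF produced none
    for j in causal_idx:
        if alleles[founder_rows, :, j].sum() == 0:
            carrier = founder_rows[rng.integers(len(founder_rows))]
            alleles[carrier, rng.integers(2), j] = 1
    # gene dropping in generation order
    fathers = [pos.get(fv) if pd.notna(fv) else None for fv in t["father"]]
    mothers = [pos.get(mv) if pd.notna(mv) else None for mv in t["mother"]]
    for i in range(n):
        fi, mi = fathers[i], mothers[i]
        if fi is None and mi is None:
            continue
        if fi is not None:
            pick = rng.integers(0, 2, size=m)
            alleles[i, 0, :] = alleles[fi, pick, np.arange(m)]
        if mi is not None:
            pick = rng.integers(0, 2, size=m)
            alleles[i, 1, :] = alleles[mi, pick, np.arange(m)]
    dosages = alleles.sum(axis=1).astype(float)

    # variant metadata: 1-based positions on per-gene "chromosomes"
    chroms = (gene_of % 22 + 1).astype(str)
    positions = np.zeros(m, dtype=int)
    for g in range(config.n_genes):
        in_gene = np.nonzero(gene_of == g)[0]
        start = 1_000_000 * (g + 1)
        positions[in_gene] = start + np.sort(
            rng.choice(np.arange(1, 50_000), size=len(in_gene), replace=False)
        )
    refs = rng.choice(list("ACGT"), size=m)
    alts = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in refs])
    variant_ids = [f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(chroms, positions, refs, alts)]
    variants = pd.DataFrame(
        {
            "variant": variant_ids,
            "chrom": chroms,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "gene": [genes[g] for g in gene_of],
            "function_class": classes,
        }
    )
    # per-variant sequencing summaries shaped like a filtered capture panel
    variants["mean_coverage"] = np.clip(rng.normal(47.0, 20.0, size=m), 5.5, None)
    variants["quality"] = np.clip(rng.normal(175.0, 53.0, size=m), 46.0, None)

    order = [pos[i] for i in pedigree.individuals]
    gm = GenotypeMatrix(list(pedigree.individuals), variants, dosages[order, :])
    truth = GroundTruth(
        causal_variants=[variant_ids[j] for j in causal_idx],
        causal_effects={variant_ids[j]: config.causal_effect for j in causal_idx},
        causal_genes=[genes[g] for g in causal_genes],
    )
    return gm, truth


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Phenotype table with the additive analysis trait plus realistic
    clinical columns for the derivation stage."""
    rng = _rng(config.seed, 3)
    truth = truth or GroundTruth()
    t = pedigree.table
    n = len(t)
    ids = list(t["individual"])

    kin = compute_kinship(pedigree)
    K = 2.0 * kin.phi
    h2 = config.heritability
    sigma_e = config.residual_sd if config.residual_sd is not None else float(np.sqrt(1.0 - h2))
    if h2 > 0:
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        u = np.sqrt(h2) * (L @ rng.standard_normal(n))
    else:
        u = np.zeros(n)

    gvec = np.zeros(n)
    if truth.causal_variants:
        vidx = {v: j for j, v in enumerate(genotypes.variants["variant"])}
        gidx = {ind: i for i, ind in enumerate(genotypes.individuals)}
        row_order = [gidx[i] for i in ids]
        for v in truth.causal_variants:
            gvec += truth.causal_effects[v] * np.nan_to_num(
                genotypes.dosages[row_order, vidx[v]]
            )

    centers = np.array(["boston", "columbia", "pittsburgh", "denmark"])
    center = rng.choice(centers, size=n)
    center_fx = {c: rng.normal(0.0, config.center_effect_sd) for c in centers}
    center_term = np.array([center_fx[c] for c in center])

    trait = gvec + u + center_term + sigma_e * rng.standard_normal(n)

    gen = t["generation"].to_numpy()
    # married-in spouses: founders who are parents of generation-2 individuals
    gen2_parents = set(
        t.loc[t["generation"] >= 2, "father"].dropna()
    ) | set(t.loc[t["generation"] >= 2, "mother"].dropna())
    is_spouse = (t["founder"] & t["individual"].isin(gen2_parents)).to_numpy()
    role = np.where(
        is_spouse, "spouse_control",
        np.where(gen == 0, "founder_parent", np.where(gen == 1, "proband_gen", "offspring")),
    )

    # spouses marry into the proband generation, so they share its age range
    age = np.where(
        role == "founder_parent", rng.normal(97.0, 4.0, n),
        np.where(role == "offspring", rng.normal(58.0, 8.0, n), rng.normal(88.0, 5.0, n)),
    )
    age = np.clip(age, 41.0, 110.0)
    sex = t["sex"].to_numpy()
    birth_year = 2008 - np.round(age).astype(int)
    birth_cohort = (birth_year // 10) * 10

    sbp = 118.0 + 0.5 * (age - 70.0) + rng.normal(0, 14, n)
    dbp = sbp - np.clip(40.0 + rng.normal(0, 8, n), 15.0, None)
    fvc = np.clip(3.6 - 0.025 * (age - 70.0) + rng.normal(0, 0.6, n), 0.6, None)
    creat = np.clip(rng.lognormal(np.log(0.95), 0.2, n) + 0.004 * (age - 70.0), 0.3, None)
    gluc = np.clip(rng.normal(95.0, 14.0, n), 55.0, None)
    mmse = np.clip(np.round(29.0 - 0.08 * (age - 70.0) + rng.normal(0, 1.8, n)), 0, 30)
    total_chol = np.clip(rng.normal(200.0, 35.0, n), 90.0, None)
    hdl = np.clip(rng.normal(55.0, 14.0, n), 20.0, None)
    trig = np.clip(rng.lognormal(np.log(110.0), 0.45, n), 30.0, None)
    weight = np.where(sex == "male", rng.normal(80.0, 13.0, n), rng.normal(68.0, 12.0, n))
    height = np.where(sex == "male", rng.normal(1.76, 0.07, n), rng.normal(1.63, 0.06, n))
    ts_ratio = np.clip(rng.normal(1.05 - 0.004 * (age - 70.0), 0.18, n), 0.05, None)
    meds = rng.random(n) < 0.08
    cancer = rng.random(n) < 0.15
    onset = np.where(cancer, np.clip(rng.normal(66.0, 9.0, n), 35.0, age - 1.0), np.nan)

    phen = pd.DataFrame(
        {
            "individual": ids,
            "family": t["family"],
            "sex": sex,
            "generation": gen,
            "role": role,
            "age": np.round(age, 1),
            "age_last": np.round(age, 1),
            "birth_year": birth_year,
            "birth_cohort": birth_cohort,
            "field_center": center,
            "trait": trait,
            "systolic_bp": np.round(sbp, 1),
            "diastolic_bp": np.round(dbp, 1),
            "vital_capacity": np.round(fvc, 2),
            "creatinine": np.round(creat, 2),
            "fasting_glucose": np.round(gluc, 1),
            "mmse": mmse.astype(int),
            "total_chol": np.round(total_chol, 1),
            "hdl": np.round(hdl, 1),
            "trig": np.round(trig, 1),
            "weight_kg": np.round(weight, 1),
            "height_m": np.round(height, 3),
            "ts_ratio": np.round(ts_ratio, 3),
            "diabetes_meds": meds,
            "cancer_onset_age": np.round(onset, 1),
        }
    )
    truth.polygenic_values = pd.Series(u, index=ids)
    truth.true_kinship = kin
    truth.center_effects = center_fx
    return phen, truth


def simulate_lifetable(
    config: SimulationConfig, sex: str = "male", birth_year_cohort: int = 1910,
    max_age: float = 110.0, step: float = 1.0,
) -> LifeTable:
    """Gompertz cohort life table: S(t) = exp(-(a/b) (e^{bt} - 1))."""
    a, b = config.gompertz[sex]
    ages = np.arange(0.0, max_age + step / 2, step)
    if b > 0:
        surv = np.exp(-(a / b) * (np.expm1(b * ages)))
    else:
        surv = np.exp(-a * ages)
    return LifeTable(sex=sex, birth_year_cohort=birth_year_cohort, ages=ages, survival=surv)


def inject_artifacts(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Degrade a clean genotype matrix with recorded ground truth.

    Injects Mendel-inconsistent child genotypes, random missingness,
    low-coverage/low-quality variant summaries, and capture gaps (contiguous
    variant blocks entirely missing).
    """
    rng = _rng(config.seed, 4)
    truth = truth or GroundTruth()
    D = genotypes.dosages.copy()
    v = genotypes.variants.copy()
    n, m = D.shape
    idx = {ind: k for k, ind in enumerate(genotypes.individuals)}

    # missingness and capture gaps first, so injected Mendel errors are never
    # erased afterwards (a trio with a missing member is skipped by detection)
    if config.missingness_rate > 0:
        miss = rng.random(D.shape) < config.missingness_rate
        D[miss] = np.nan

    degraded: dict = {"low_coverage": [], "low_quality": [], "capture_gap": []}
    if config.capture_gap_fraction > 0:
        k = int(round(config.capture_gap_fraction * m))
        if k:
            start = int(rng.integers(0, max(m - k, 1)))
            D[:, start : start + k] = np.nan
            degraded["capture_gap"] = list(v["variant"].iloc[start : start + k])

    injected = []
    if config.mendel_error_rate > 0:
        trios = pedigree.trios()
        trios = trios[
            trios["child"].isin(idx) & trios["father"].isin(idx) & trios["mother"].isin(idx)
        ].reset_index(drop=True)
        n_cells = len(trios) * m
        n_inject = int(round(config.mendel_error_rate * n_cells))
        for _ in range(n_inject):
            ti = int(rng.integers(len(trios)))
            j = int(rng.integers(m))
            trow = trios.iloc[ti]
            ci, fi, mi = idx[trow["child"]], idx[trow["father"]], idx[trow["mother"]]
            f, mo = D[fi, j], D[mi, j]
            if np.isnan(f) or np.isnan(mo):
                continue
            lo = (f == 2) + (mo == 2)
            hi = (f >= 1) + (mo >= 1)
            impossible = [c for c in (0.0, 1.0, 2.0) if c < lo or c > hi]
            if not impossible:
                continue
            D[ci, j] = impossible[int(rng.integers(len(impossible)))]
            injected.append(
                {"variant": v["variant"].iloc[j], "family": trow["family"],
                 "child": trow["child"], "father": trow["father"], "mother": trow["mother"]}
            )
    truth.injected_error_trios = pd.DataFrame(
        injected, columns=["variant", "family", "child", "father", "mother"]
    )
    truth.injected_error_families = {
        var: set(grp["family"]) for var, grp in truth.injected_error_trios.groupby("variant")
    }

    if config.low_coverage_fraction > 0:
        k = int(round(config.low_coverage_fraction * m))
        cols = rng.choice(m, size=k, replace=False)
        v.loc[cols, "mean_coverage"] = rng.uniform(0.5, 4.9, size=k)
        degraded["low_coverage"] = list(v["variant"].iloc[cols])
    if config.low_quality_fraction > 0:
        candidates = np.setdiff1d(np.arange(m), np.nonzero(v["mean_coverage"] < 5)[0])
        k = min(int(round(config.low_quality_fraction * m)), len(candidates))
        cols = rng.choice(candidates, size=k, replace=False)
        v.loc[cols, "quality"] = rng.uniform(5.0, 44.9, size=k)
        degraded["low_quality"] = list(v["variant"].iloc[cols])
    truth.degraded_variants = degraded
    return GenotypeMatrix(list(genotypes.individuals), v, D), truth


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full synthetic dataset: pedigree, genotypes (degraded per config),
    phenotypes, per-sex life tables, gene map, and ground truth."""
    ped = simulate_pedigrees(config)
    gm, truth = simulate_genotypes(ped, config)
    phen, truth = simulate_phenotypes(ped, gm, config, truth)
    gm, truth = inject_artifacts(gm, ped, config, truth)
    tables = {}
    for sex in ("male", "female"):
        for cohort in sorted(set(phen["birth_cohort"])):
            lt = simulate_lifetable(config, sex=sex, birth_year_cohort=int(cohort))
            tables[(sex, int(cohort))] = lt
    gene_map = gm.variants[["gene", "variant"]].copy()
    return SyntheticDataset(
        config=config,
        pedigree=ped,
        genotypes=gm,
        phenotypes=phen,
        lifetables=tables,
        gene_map=gene_map,
        truth=truth,
    )
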