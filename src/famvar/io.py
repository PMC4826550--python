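"""Readers and writers for the standard formats, plus the pipeline driver.

Formats: VCF v4.2 (biallelic; multiallelics must be pre-split), PED
(whitespace-delimited family/individual/father/mother/sex with "0" for a
missing parent), tab-delimited tables with an "NA" missing token, and a
sex x birth-cohort life-table TSV. All genomic coordinates are 1-based.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .exceptionality import LifeTable
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_ped",
    "write_ped",
    "read_tsv_table",
    "write_tsv_table",
    "read_lifetable",
    "write_lifetable",
    "read_gene_map",
    "RunConfig",
    "pipeline_run",
]

_SEX_FROM_PED = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}


def read_vcf(path, coverage_field: str = "DP") -> GenotypeMatrix:
    """Load a biallelic VCF into a GenotypeMatrix.

    GT 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> missing. QUAL populates
    ``quality``; mean per-variant depth comes from FORMAT ``coverage_field``
    when present, else INFO, else NaN. Annotation columns (gene,
    function_class) present as INFO keys GENE/FUNC are carried through.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows = []
    dosages = []
    for k, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record at line ~{k} ({rec.CHROM}:{rec.POS}); "
                "pre-split multiallelics (e.g. bcftools norm -m -any)"
            )
        gt = rec.gt_types.astype(float)  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        dosages.append(dos)
        fmt_dp = None
        try:
            fmt_dp = rec.format(coverage_field)
        except KeyError:
            fmt_dp = None
        if fmt_dp is not None:
            vals = np.asarray(fmt_dp, dtype=float).ravel()
            mean_dp = float(np.nanmean(np.where(vals < 0, np.nan, vals)))
        else:
            # INFO-level depth is taken as the per-variant mean coverage
            info_dp = rec.INFO.get(coverage_field)
            mean_dp = float(info_dp) if info_dp is not None else np.nan
        rows.append(
            {
                "variant": f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "rsid": rec.ID,
                "quality": rec.QUAL if rec.QUAL is not None else np.nan,
                "mean_coverage": mean_dp,
                "gene": rec.INFO.get("GENE"),
                "function_class": rec.INFO.get("FUNC"),
            }
        )
    variants = pd.DataFrame(
        rows,
        columns=["variant", "chrom", "pos", "ref", "alt", "rsid", "quality",
                 "mean_coverage", "gene", "function_class"],
    )
    D = np.column_stack(dosages) if dosages else np.zeros((len(individuals), 0))
    return GenotypeMatrix(individuals, variants, D)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as VCF v4.2 with GT, QUAL, and GENE/FUNC INFO."""
    v = gm.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Float,Description="Mean per-sample depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in gm.individuals)
            + "\n"
        )
        gt_str = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(gm.n_variants):
            row = v.iloc[j]
            info = []
            if pd.notna(row.get("gene")):
                info.append(f"GENE={row['gene']}")
            if pd.notna(row.get("function_class")):
                info.append(f"FUNC={row['function_class']}")
            if pd.notna(row.get("mean_coverage")):
                info.append(f"DP={row['mean_coverage']:.6g}")
            qual = row.get("quality")
            qual_s = f"{qual:.6g}" if pd.notna(qual) else "."
            rsid = row.get("rsid")
            rsid_s = rsid if isinstance(rsid, str) and rsid else "."
            gts = "\t".join(
                gt_str.get(d, "./.") if not np.isnan(d) else "./."
                for d in gm.dosages[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{rsid_s}\t{row['ref']}\t{row['alt']}\t"
                f"{qual_s}\tPASS\t{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


def read_ped(path) -> Pedigree:
    """Whitespace/tab-delimited PED: family individual father mother sex."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"PED line has {len(parts)} fields, expected >= 5: {line!r}")
            fam, ind, fa, mo, sex = parts[:5]
            rows.append(
                {
                    "family": fam,
                    "individual": ind,
                    "father": None if fa == "0" else fa,
                    "mother": None if mo == "0" else mo,
                    "sex": _SEX_FROM_PED.get(sex, "unknown"),
                }
            )
    return Pedigree(pd.DataFrame(rows))


def write_ped(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for _, r in pedigree.table.iterrows():
            fa = r["father"] if pd.notna(r["father"]) else "0"
            mo = r["mother"] if pd.notna(r["mother"]) else "0"
            fh.write(f"{r['family']}\t{r['individual']}\t{fa}\t{mo}\t{_SEX_TO_PED[r['sex']]}\n")


def read_tsv_table(path, index_col: str | None = None, unique: str | None = None) -> pd.DataFrame:
    """Tab-delimited table with header row and "NA" missing token."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    check = unique or index_col
    if check is not None and df[check].duplicated().any():
        dup = df.loc[df[check].duplicated(), check].iloc[0]
        raise ValueError(f"duplicate {check} in {path}: {dup!r}")
    return df


def write_tsv_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_lifetable(path) -> dict:
    """Life-table TSV (sex, birth_year_cohort, age, survival) keyed by
    (sex, cohort); each table is validated (monotone, S(0)=1)."""
    df = read_tsv_table(path)
    tables = {}
    for (sex, cohort), grp in df.groupby(["sex", "birth_year_cohort"]):
        grp = grp.sort_values("age")
        tables[(sex, int(cohort))] = LifeTable(
            sex=sex,
            birth_year_cohort=int(cohort),
            ages=grp["age"].to_numpy(dtype=float),
            survival=grp["survival"].to_numpy(dtype=float),
        )
    return tables


def write_lifetable(tables: dict, path) -> None:
    rows = []
    for (sex, cohort), lt in tables.items():
        for a, s in zip(lt.ages, lt.survival):
            rows.append({"sex": sex, "birth_year_cohort": cohort, "age": a, "survival": s})
    write_tsv_table(pd.DataFrame(rows), path)


def read_gene_map(path) -> pd.DataFrame:
    """Gene grouping TSV: columns gene, variant (chrom:pos:ref:alt)."""
    df = read_tsv_table(path)
    for col in ("gene", "variant"):
        if col not in df.columns:
            raise ValueError(f"gene map must have a {col!r} column")
    return df


# ---------------------------------------------------------------------------
# run configuration and pipeline


_KNOWN_KEYS = {
    "seed", "out_dir", "phenotype", "covariates", "n_perm", "tests",
    "min_mac", "log_base", "simulation", "vcf", "ped", "phenotypes",
    "lifetable", "gene_map", "filter",
}


@dataclass
class RunConfig:
    """Typed run configuration; unknown keys are rejected at load."""

    seed: int = 1
    out_dir: str = "famvar_out"
    phenotype: str = "trait"
    covariates: list = field(default_factory=lambda: ["age", "sex"])
    n_perm: int = 1000
    tests: list = field(default_factory=lambda: ["famskat", "pwst"])
    min_mac: int = 1
    log_base: float = float(np.e)
    simulation: dict = field(default_factory=dict)
    vcf: str | None = None
    ped: str | None = None
    phenotypes: str | None = None
    lifetable: str | None = None
    gene_map: str | None = None
    filter: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def pipeline_run(config: RunConfig) -> dict:
    """Run the full pipeline on a synthetic (or loaded) dataset.

    Stages: simulate/load -> kinship -> Mendel errors -> QC (single + burden)
    -> phenotype derivation -> exceptionality scoring -> single-variant LMM
    -> gene-level burden/kernel scan. Writes TSV outputs and a JSON manifest
    with per-file checksums; deterministic given the seed.
    """
    from . import burden as burden_mod
    from . import exceptionality as exc
    from . import lmm as lmm_mod
    from . import phenotypes as ph
    from . import qc as qc_mod
    from .pedigree import compute_kinship, find_mendel_errors, mendel_family_counts
    from .simulate import SimulationConfig, simulate_dataset

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    if config.vcf is None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        sim_kwargs.setdefault("mendel_error_rate", 0.0005)
        sim_kwargs.setdefault("missingness_rate", 0.02)
        sim_kwargs.setdefault("low_coverage_fraction", 0.03)
        sim_kwargs.setdefault("low_quality_fraction", 0.03)
        if "gompertz" in sim_kwargs:
            sim_kwargs["gompertz"] = {k: tuple(v) for k, v in sim_kwargs["gompertz"].items()}
        sim_config = SimulationConfig(**sim_kwargs)
        ds = simulate_dataset(sim_config)
        ped, gm, phen = ds.pedigree, ds.genotypes, ds.phenotypes
        lifetables, gene_map = ds.lifetables, ds.gene_map
        write_vcf(gm, out / "genotypes.vcf")
        write_ped(ped, out / "pedigree.ped")
        write_tsv_table(phen, out / "phenotypes.tsv")
        write_lifetable(lifetables, out / "lifetable.tsv")
        write_tsv_table(gene_map, out / "genes.tsv")
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "causal_genes": ds.truth.causal_genes,
                    "causal_variants": ds.truth.causal_variants,
                    "causal_effects": ds.truth.causal_effects,
                },
                indent=2,
                sort_keys=True,
            )
        )
        (out / "config.json").write_text(
            json.dumps(sim_config.to_dict(), indent=2, sort_keys=True, default=str)
        )
        manifest["stages"]["simulate"] = {
            "n_individuals": gm.n_individuals,
            "n_variants": gm.n_variants,
            "n_families": len(ped.families),
        }
    else:
        gm = read_vcf(config.vcf)
        ped = read_ped(config.ped)
        phen = read_tsv_table(config.phenotypes, unique="individual")
        lifetables = read_lifetable(config.lifetable) if config.lifetable else {}
        gene_map = read_gene_map(config.gene_map) if config.gene_map else gm.variants[["gene", "variant"]]
        manifest["stages"]["load"] = {
            "n_individuals": gm.n_individuals, "n_variants": gm.n_variants
        }

    if config.phenotype == "survival_te" and not lifetables:
        raise ValueError(
            "survival exceptionality scoring requested but no life table was provided"
        )

    # kinship + Mendel errors
    kin = compute_kinship(ped)
    report = find_mendel_errors(gm, ped)
    counts = mendel_family_counts(report)
    gm = qc_mod.add_qc_columns(gm, counts)

    # QC cascades
    gm_nonmissing = gm.subset_variants(~np.isnan(gm.variants["maf"].to_numpy(dtype=float)))
    single_gm, single_log = qc_mod.apply_filters(gm_nonmissing, qc_mod.FilterConfig(mode="single"))
    burden_gm, burden_log = qc_mod.apply_filters(gm_nonmissing, qc_mod.FilterConfig(mode="burden"))
    # monomorphic sites cannot be tested
    single_gm = single_gm.subset_variants(single_gm.variants["mac"].to_numpy() > 0)
    burden_gm = burden_gm.subset_variants(burden_gm.variants["mac"].to_numpy() > 0)
    write_tsv_table(single_log, out / "qc_single_removals.tsv")
    write_tsv_table(burden_log, out / "qc_burden_removals.tsv")
    fractions = qc_mod.class_fractions(gm_nonmissing.variants)
    manifest["stages"]["qc"] = {
        "input_variants": gm.n_variants,
        "single_retained": single_gm.n_variants,
        "burden_retained": burden_gm.n_variants,
        "coding_fraction": fractions["coding_fraction"],
        "rare_fraction": fractions.get("rare_fraction"),
    }

    # phenotype derivation + exceptionality scores
    phen = phen.set_index("individual").loc[gm.individuals].reset_index()
    derived = phen.copy()
    derived["bmi"] = ph.bmi(phen["weight_kg"], phen["height_m"])
    derived["pulse_pressure"] = np.asarray(phen["systolic_bp"], float) - np.asarray(
        phen["diastolic_bp"], float
    )
    derived["ldl"] = ph.friedewald_ldl(phen["total_chol"], phen["hdl"], phen["trig"])
    derived["telomere_bp"] = ph.telomere_bp(phen["ts_ratio"])
    derived["t2d"] = ph.t2d_status(phen["diabetes_meds"], phen["fasting_glucose"])
    cutpoints = {
        name: ph.tertile_cutpoints(phen[name], age_adjusted=False)
        for name in ph.HAI_COMPONENTS
    }
    hai_vals, mwhai_vals = [], []
    for _, row in phen.iterrows():
        comp = {name: row[name] for name in ph.HAI_COMPONENTS}
        hai, scores = ph.hai_score(comp, cutpoints)
        hai_vals.append(hai)
        mwhai_vals.append(ph.mortality_weighted_hai(scores) if hai is not None else None)
    derived["hai"] = hai_vals
    derived["mwhai"] = mwhai_vals
    if lifetables:
        scores = []
        for _, row in phen.iterrows():
            key = (row["sex"], int(row["birth_cohort"]))
            if row["age_last"] >= 40 and key in lifetables:
                s = exc.survival_exceptionality(
                    row["age_last"], row["sex"], int(row["birth_cohort"]),
                    lifetables[key], log_base=config.log_base,
                )
                scores.append(s.score)
            else:
                scores.append(np.nan)
        derived["survival_te"] = scores
    write_tsv_table(derived, out / "derived_phenotypes.tsv")
    manifest["stages"]["derive"] = {"n_individuals": len(derived)}

    # analysis phenotype: inverse-normal transform + covariate residualization
    y_raw = derived[config.phenotype].to_numpy(dtype=float)
    y_int = ph.inverse_normal_transform(y_raw)
    covs = derived[[c for c in config.covariates if c in derived.columns]]
    y_adj = ph.adjust_covariates(y_int, covs, mode="full")
    ok = ~np.isnan(y_adj)
    individuals = [i for i, k in zip(gm.individuals, ok) if k]
    y = y_adj[ok]

    eigen = lmm_mod.KinshipEigen.from_kinship(kin.submatrix(individuals))
    X = np.ones((len(y), 1))

    # single-variant scan
    results = []
    idx = [gm.individuals.index(i) for i in individuals]
    for j in range(single_gm.n_variants):
        g = single_gm.dosages[idx, j]
        obs = ~np.isnan(g)
        if obs.sum() < 3 or np.nanstd(g) == 0:
            continue
        sub_ids = [individuals[k] for k in np.nonzero(obs)[0]]
        sub_eigen = eigen.subset(sub_ids) if not obs.all() else eigen
        try:
            r = lmm_mod.fit_lmm(
                y[obs], X[obs], g[obs], sub_eigen,
                variant=single_gm.variants["variant"].iloc[j],
            )
        except ValueError:
            continue
        if r.mac >= config.min_mac:
            results.append(r)
    assoc = pd.DataFrame([vars(r) for r in results])
    if len(assoc):
        assoc["bonferroni_threshold"] = lmm_mod.bonferroni_threshold(len(assoc))
        stable, unstable = lmm_mod.mac_partition(results)
        assoc["stability"] = np.where(assoc["mac"] >= 10, "stable", "unstable")
        lam = lmm_mod.genomic_control(assoc["p"])
    else:
        lam = np.nan
    write_tsv_table(assoc, out / "single_variant.tsv")
    manifest["stages"]["single_variant"] = {
        "n_tested": len(assoc), "genomic_control_lambda": lam
    }

    # gene-level scan on burden-filtered variants
    gene_sets = {}
    vset = set(burden_gm.variants["variant"])
    for gene, grp in gene_map.groupby("gene"):
        vids = [v for v in grp["variant"] if v in vset]
        if not vids:
            continue
        cols = [list(burden_gm.variants["variant"]).index(v) for v in vids]
        G = burden_gm.dosages[np.ix_(idx, cols)]
        if np.all(np.isnan(G)):
            continue
        gene_sets[gene] = G
    scan = burden_mod.gene_scan(
        gene_sets, y, X, eigen, tests=config.tests,
        n_perm=config.n_perm, seed=config.seed,
    )
    write_tsv_table(scan, out / "gene_burden.tsv")
    manifest["stages"]["burden"] = {
        "n_genes": len(gene_sets),
        "significance_threshold": scan.attrs.get("significance_threshold"),
    }

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
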