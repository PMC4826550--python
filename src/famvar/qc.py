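"""Variant quality-control cascade and per-variant summary statistics.

The cascade mirrors the sequencing-QC practice for family studies: drop
variants with low mean coverage, low call quality, low call rate, and
Mendelian inconsistencies observed in too many distinct pedigrees (with a
MAF-dependent family-count cutoff, since common variants are expected to
show occasional genotyping errors in more families by chance). The burden
mode additionally restricts to rare (MAF <= 0.01) putatively functional
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "FilterConfig",
    "FUNCTIONAL_CLASSES",
    "NONFUNCTIONAL_CLASSES",
    "compute_maf",
    "add_qc_columns",
    "mendel_cutoff_for",
    "apply_filters",
    "class_fractions",
]

FUNCTION_CLASSES = (
    "nsyn-exonic",
    "syn-exonic",
    "stopgain",
    "stoploss",
    "UTR3",
    "UTR5",
    "splicing",
    "ncRNA",
    "intronic",
    "intergenic",
)

#: classes kept by the burden-mode "functional" filter
FUNCTIONAL_CLASSES = frozenset(
    {"nsyn-exonic", "syn-exonic", "stopgain", "stoploss", "UTR3", "UTR5", "splicing", "ncRNA"}
)
NONFUNCTIONAL_CLASSES = frozenset({"intronic", "intergenic"})

#: (maf_low, maf_high, families required to exclude) — half-open bins covering [0, 0.51)
DEFAULT_MENDEL_CUTOFFS = (
    (0.00, 0.01, 3),
    (0.01, 0.05, 7),
    (0.05, 0.10, 12),
    (0.10, 0.20, 26),
    (0.20, 0.30, 30),
    (0.30, 0.40, 32),
    (0.40, 0.51, 38),
)


@dataclass
class FilterConfig:
    min_coverage: float = 5.0
    min_quality: float = 45.0
    min_call_rate: float = 0.60
    burden_max_maf: float = 0.01
    mendel_cutoffs: tuple = DEFAULT_MENDEL_CUTOFFS
    mode: str = "single"  # or "burden"

    def __post_init__(self) -> None:
        if self.mode not in ("single", "burden"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        bins = sorted(self.mendel_cutoffs)
        if bins[0][0] != 0.0 or bins[-1][1] < 0.51:
            raise ValueError("Mendel-cutoff MAF bins must cover [0, 0.51)")
        for (lo1, hi1, _), (lo2, _hi2, _) in zip(bins, bins[1:]):
            if hi1 != lo2:
                raise ValueError("Mendel-cutoff MAF bins must be contiguous")


def compute_maf(dosages) -> tuple[float, int]:
    """Minor-allele frequency and count from additive dosages.

    The alt-allele frequency is computed over non-missing alleles and folded
    to the minor allele; mac is the integer minor-allele count.
    """
    d = np.asarray(dosages, dtype=float)
    obs = d[~np.isnan(d)]
    if obs.size == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    n_alleles = 2 * obs.size
    alt = obs.sum()
    freq = alt / n_alleles
    if freq <= 0.5:
        return float(freq), int(round(alt))
    return float(1.0 - freq), int(round(n_alleles - alt))


def add_qc_columns(gm: GenotypeMatrix, mendel_counts: pd.Series | None = None) -> GenotypeMatrix:
    """Populate maf, mac, call_rate (and mendel_family_count) on the variant table."""
    v = gm.variants.copy()
    mafs = np.empty(gm.n_variants)
    macs = np.empty(gm.n_variants, dtype=int)
    for j in range(gm.n_variants):
        col = gm.dosages[:, j]
        if np.isnan(col).all():
            mafs[j], macs[j] = np.nan, 0
        else:
            mafs[j], macs[j] = compute_maf(col)
    v["maf"] = mafs
    v["mac"] = macs
    v["call_rate"] = gm.call_rates()
    if mendel_counts is not None:
        v["mendel_family_count"] = (
            mendel_counts.reindex(v["variant"]).fillna(0).astype(int).to_numpy()
        )
    elif "mendel_family_count" not in v.columns:
        v["mendel_family_count"] = 0
    return GenotypeMatrix(list(gm.individuals), v, gm.dosages)


def mendel_cutoff_for(maf: float, config: FilterConfig | None = None) -> int:
    """Minimum number of Mendel-error families that excludes a variant at this MAF."""
    config = config or FilterConfig()
    if not (0.0 <= maf < 0.51):
        raise ValueError(f"MAF {maf} outside [0, 0.51)")
    for lo, hi, cutoff in config.mendel_cutoffs:
        if lo <= maf < hi:
            return cutoff
    raise ValueError(f"MAF {maf} not covered by cutoff bins")  # pragma: no cover

def apply_filters(
    gm: GenotypeMatrix, config: FilterConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the filter cascade; return (retained matrix, removal log).

    Filters in order: 1 coverage, 2 quality, 3 call rate, 4 Mendel errors,
    then in burden mode 5 MAF > burden_max_maf and 6 nonfunctional class.
    The retained set is order-invariant; the log attributes each removal to
    the first failing filter.
    """
    v = gm.variants
    for col in ("mean_coverage", "quality", "call_rate", "maf", "mendel_family_count"):
        if col not in v.columns:
            raise ValueError(f"variant table lacks QC column {col!r}; run add_qc_columns")
    n = len(v)
    maf = v["maf"].to_numpy(dtype=float)
    cutoffs = np.array(
        [mendel_cutoff_for(m, config) if np.isfinite(m) else np.inf for m in maf]
    )
    checks = [
        ("coverage", v["mean_coverage"].to_numpy(dtype=float) < config.min_coverage,
         v["mean_coverage"], config.min_coverage),
        ("quality", v["quality"].to_numpy(dtype=float) < config.min_quality,
         v["quality"], config.min_quality),
        ("call_rate", v["call_rate"].to_numpy(dtype=float) < config.min_call_rate,
         v["call_rate"], config.min_call_rate),
        ("mendel", v["mendel_family_count"].to_numpy(dtype=float) >= cutoffs,
         v["mendel_family_count"], pd.Series(cutoffs)),
    ]
    if config.mode == "burden":
        if "function_class" not in v.columns:
            raise ValueError("burden mode requires a function_class column")
        checks.append(("maf", maf > config.burden_max_maf, v["maf"], config.burden_max_maf))
        checks.append(
            ("nonfunctional",
             ~v["function_class"].isin(FUNCTIONAL_CLASSES).to_numpy(),
             v["function_class"], "functional classes")
        )
    removed_by = np.full(n, "", dtype=object)
    log_rows = []
    for name, fails, values, threshold in checks:
        fresh = fails & (removed_by == "")
        removed_by[fresh] = name
        thr = threshold if np.ndim(threshold) else [threshold] * n
        for j in np.nonzero(fresh)[0]:
            log_rows.append(
                {
                    "variant": v["variant"].iloc[j],
                    "filter": name,
                    "value": values.iloc[j],
                    "threshold": thr[j] if np.ndim(threshold) else threshold,
                }
            )
    retained = gm.subset_variants(removed_by == "")
    log = pd.DataFrame(log_rows, columns=["variant", "filter", "value", "threshold"])
    return retained, log


def class_fractions(variants: pd.DataFrame) -> dict:
    """Summary fractions by functional class plus rare/singleton breakdown.

    Returns per-class fractions (summing to 1), the coding fraction
    (exonic classes), the rare fraction (maf < 0.01), and the singleton
    fraction (mac == 1) among rare variants. Percentages are fractions;
    multiply by 100 for display.
    """
    if len(variants) == 0:
        raise ValueError("class_fractions requires a non-empty variant set")
    n = len(variants)
    out: dict = {"n_variants": n}
    counts = variants["function_class"].value_counts()
    out["by_class"] = {cls: counts.get(cls, 0) / n for cls in counts.index}
    coding = {"nsyn-exonic", "syn-exonic", "stopgain", "stoploss"}
    out["coding_fraction"] = variants["function_class"].isin(coding).sum() / n
    out["nonsyn_or_nonsense_fraction"] = (
        variants["function_class"].isin({"nsyn-exonic", "stopgain", "stoploss"}).sum() / n
    )
    out["utr_fraction"] = variants["function_class"].isin({"UTR3", "UTR5"}).sum() / n
    if "maf" in variants.columns:
        rare = variants["maf"] < 0.01
        out["rare_fraction"] = rare.sum() / n
        n_rare = int(rare.sum())
        out["n_rare"] = n_rare
        if n_rare and "mac" in variants.columns:
            out["singleton_fraction_of_rare"] = (
                ((variants["mac"] == 1) & rare).sum() / n_rare
            )
    return out
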