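# famvar

Family-based candidate-gene association analysis for healthy-aging
phenotypes: pedigree-aware variant QC, derived phenotypes and trait
exceptionality scores, kinship-adjusted single-variant mixed models, and
gene-level rare-variant burden/kernel tests — with a synthetic-data
generator that provides ground truth for every stage.

## The problem

Cohorts of families clustered for exceptional survival are enriched for
rare, often pedigree-private variants that influence aging phenotypes
(survival, lipids, blood pressure, cognition, the composite Healthy Aging
Index). Testing such variants requires machinery that ordinary GWAS
pipelines lack:

* **kinship**: relatives are correlated, so every test carries a polygenic
  random effect with covariance `2Φσ²_g` (Φ the pedigree kinship matrix);
* **pedigree-aware QC**: Mendelian inconsistencies flag genotyping errors,
  with a MAF-dependent cutoff on the number of affected families;
* **trait exceptionality scores**: phenotypes are transformed to
  `−log P(outcome at least as favourable | matched reference population)` —
  for survival, the cohort-life-table probability of living past the
  observed age conditional on reaching 40;
* **rare-variant aggregation**: per-gene burden scores (UWSS, frequency-
  weighted WSS), a family-based kernel test (famSKAT) whose p-value comes
  from a mixture of chi-squares, and an adaptive p-value-weighted sum test
  (PWST) with a family-decorrelated permutation null.

## Core models

Single-variant test (LMM): `y = Xb + gβ + u + ε`, `u ~ N(0, 2Φσ²_g)`,
`ε ~ N(0, σ²_e I)`. Variance components by 1-D profile (RE)ML after an
eigendecomposition of `2Φ`; `β` by GLS; two-sided Wald `p`.

famSKAT: with the fitted null covariance `V̂ = 2Φσ̂²_g + σ̂²_e I`,
`Q = r'V̂⁻¹ G W² G' V̂⁻¹ r`; the null distribution is `Σ λ_j χ²₁` with
`λ_j` the eigenvalues of `W G' P G W`, `P` the null projection. Tail
probabilities via Ruben's exact series with saddlepoint/Satterthwaite
fallbacks.

PWST: per-variant score tests under the null LMM give signed adaptive
weights `a_j = sign(β_j)·(−log₁₀ p_j)`; the observed statistic is the Wald
`z²` of the `a`-weighted burden score; the null is built by decorrelating
residuals with `V̂^(−1/2)`, permuting, and re-estimating weights and
statistic every round.

## Worked example

```python
import numpy as np
from famvar import (SimulationConfig, simulate_dataset, compute_kinship,
                    KinshipEigen, gene_scan)
from famvar.qc import FilterConfig, add_qc_columns, apply_filters

ds = simulate_dataset(SimulationConfig(seed=2, n_families=50, n_genes=5))
gm = add_qc_columns(ds.genotypes)
gm = gm.subset_variants(~np.isnan(gm.variants["maf"].to_numpy(float)))
burden_gm, log = apply_filters(gm, FilterConfig(mode="burden"))
burden_gm = burden_gm.subset_variants(burden_gm.variants["mac"].to_numpy() > 0)

eigen = KinshipEigen.from_kinship(compute_kinship(ds.pedigree))
y = ds.phenotypes["trait"].to_numpy()
sets = {g: burden_gm.dosages[:, grp.index.to_numpy()]
        for g, grp in burden_gm.variants.groupby("gene") if len(grp) >= 2}
scan = gene_scan(sets, y, np.ones((len(y), 1)), eigen, tests=("famskat",))
print(scan[scan.test == "famSKAT"][["gene", "p"]].sort_values("p").head(3))
print("causal gene:", ds.truth.causal_genes)
```

prints (seed 2):

```
       gene         p
2  GENE0003  0.000007
3  GENE0004  0.047414
1  GENE0002  0.519177
causal gene: ['GENE0003']
```

The spiked causal gene (`GENE0003`, ten rare missense variants with
per-allele effect +1.0 on the standardized trait) attains famSKAT
p ≈ 7×10⁻⁶, two orders of magnitude below the best null gene — the kernel
test concentrates the pedigree-private rare-variant signal that
single-variant tests dilute.

A shell pipeline is available as `famvar` (subcommands `simulate`, `qc`,
`score`, `assoc-single`, `assoc-burden`, `run-all`):

```bash
famvar run-all --seed 7 --out results/
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline (synthetic cohort → kinship and Mendelian QC
→ filter cascade → derived phenotypes and survival exceptionality →
single-variant LMM scan with genomic control → famSKAT/PWST gene scan) from
scratch under the given seed and writes the acceptance JSON.
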