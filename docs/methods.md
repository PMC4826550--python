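# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `famvar`.

## Pedigree kinship

Kinship coefficients are computed by the recursive tabular method in
generation order: `φ(i,i) = ½(1 + φ(f_i, m_i))` and, for any `j` processed
before `i`, `φ(i,j) = ½(φ(f_i,j) + φ(m_i,j))`; founders are mutually
unrelated and a missing parent contributes 0 (treated as an unrelated
founder). The method is exact and O(n²) per family — appropriate for
three-generation study pedigrees, where path counting would be wasteful.
Cycles and cross-family parent links are rejected at load time.
`gene_drop_kinship` provides an independent Monte Carlo check: founders get
unique allele labels, descendants sample one allele per parent, and the
kinship of a pair is the average IBD indicator over the four allele
comparisons; the tests require agreement within 3 Monte Carlo SE.

Mendelian inconsistency: at a biallelic autosomal site a child dosage is
possible iff it lies in `[#parents homozygous-alt, #parents carrying alt]`.
Trios with any missing member are skipped rather than imputed — the
conservative choice; phantom errors are worse than missed ones for a filter
whose purpose is variant exclusion. X-linked inheritance is not modelled;
all sites are treated as autosomal.

## Variant QC

The cascade applies, in order: mean coverage < 5×, quality < 45, call rate
< 60 % (all strict inequalities — boundary values are retained), then a
Mendel-error filter whose exclusion threshold is the number of distinct
families carrying an inconsistency, binned by MAF:

| MAF bin | families that exclude |
|---|---|
| [0, 0.01) | ≥ 3 |
| [0.01, 0.05) | ≥ 7 |
| [0.05, 0.10) | ≥ 12 |
| [0.10, 0.20) | ≥ 26 |
| [0.20, 0.30) | ≥ 30 |
| [0.30, 0.40) | ≥ 32 |
| [0.40, 0.51) | ≥ 38 |

("more than 2 pedigrees" for the lowest bin is read as exclude-at-3, the
only reading consistent with the ≥-phrased higher bins.) Burden mode
additionally drops MAF > 0.01 and non-functional classes; "functional"
means exonic (missense, synonymous, stop gain/loss), UTR3/UTR5, splicing
and non-coding RNA — intronic and intergenic variants are excluded. The
retained set is order-invariant; only the removal log's attribution (first
failing filter) depends on the printed order. MAF is computed over all
genotyped subjects; per-variant *mean* coverage is thresholded (per-genotype
depth filtering is a caller concern, out of scope here).

## Derived phenotypes

* **HAI**: each of systolic BP, vital capacity, creatinine, fasting glucose
  and MMSE is scored 0/1/2 by tertile (0 = healthiest); the index is the
  sum, 0–10. Tertiles may be raw or age-adjusted (residuals from a linear
  age fit within sex — our reading of "approximate age-adjusted tertiles",
  configurable). Unhealthy directions (higher BP/creatinine/glucose, lower
  FVC/MMSE) are defaults with override. Ties go to the healthier score.
  A missing component makes the index missing: partial sums of a 5-item
  index are not comparable.
* **mwHAI**: `Σ w_t · score_t` with Cox-derived weights 0.17085 (SBP),
  0.38386 (FVC), 0.42873 (MMSE), 0.13397 (creatinine), 0.23880 (glucose).
* **Telomere length**: `bp = 1585 · (T/S) + 3582`.
* **Friedewald LDL**: `total − HDL − trig/5`, undefined at trig ≥ 400 mg/dL.
* **BMI, pulse pressure, T2D** (meds or fasting glucose ≥ 126 mg/dL).
* **Inverse-normal transform**: rank-based with Blom offset `c = 3/8`,
  ranks averaged at ties, missing values preserved.
* **Covariate adjustment**: OLS residualization (statsmodels), standardized
  to unit variance; stepwise mode is forward selection at α = 0.05 (the
  parameterization chosen where only "stepwise" is specified). Collinear
  designs raise an error naming the offending columns.

## Exceptionality scores

`score = −log_b(p)` (natural log by default, base 10 via config) with

* survival: `p = S(age_last)/S(40)` from the sex- and birth-cohort-matched
  life table, linearly interpolated on its age grid. Ages below 40 are
  rejected — the score is defined conditional on reaching 40.
* quantitative traits: one-sided tail probability in the beneficial
  direction (a two-sided option exists, off by default). Parametric normal
  or empirical references; empirical tail probabilities are `k/n` floored
  at `1/(n+1)` so a value beyond the reference range never yields −log 0.
* disease onset: `p = P(reference onset ≥ observed onset)` — later onset is
  more exceptional; unaffected individuals get a missing score, not zero.

If trait values are drawn from their reference distribution, `p` is uniform
and scores are Exponential(ln b); the test suite checks this by KS test.

## Single-variant mixed model

`y = Xb + gβ + u + ε` with `u ~ N(0, 2Φσ²_g)`. One eigendecomposition of
`2Φ` per phenotype is reused across variants; in the rotated basis the
covariance is diagonal, so the likelihood is profiled over
`γ = σ²_g/σ²_e` only: a 25-point log-spaced grid (plus γ = 0) brackets the
optimum, refined by bounded Brent to `xatol 1e-8`. REML is the default;
the burden tests use ML, following the source method's stated estimator.
`β` and its SE come from GLS at the optimum; `p` is a two-sided normal
(Wald) tail — the mixed-model convention at these sample sizes, not a t
reference. Missing genotypes drop the individual for that variant
(complete-case per variant; the kinship eigendecomposition is recomputed
for the subset). Monomorphic genotypes are an error, not a silent p = 1.

Genomic control is reported as `λ = median(p)/0.5` — the median-p
definition, not the usual median-χ² one — and no correction is applied to
the p-values; λ is diagnostic output. Bonferroni thresholds are
`0.05/n_tests`. Results partition into stable (MAC ≥ 10) and unstable
(MAC < 10) sets; the boundary MAC = 10 goes to the stable set.

## Rare-variant tests

* **UWSS**: per-individual count of minor alleles across the gene's rare
  functional variants; missing dosages imputed to `2·MAF`.
* **WSS**: weighted count with Madsen–Browning weights
  `w_j = 1/√(n_c q_j (1−q_j))`, `q_j = (m_j+1)/(2n_c+2)` from control
  (married-in spouse) allele counts; all-sample frequencies are the
  documented fallback when controls are absent.
* Both scores are tested as a single fixed effect in the kinship LMM with
  ML variance components and a Wald test.
* **famSKAT**: `Q = r'V̂⁻¹ G W² G' V̂⁻¹ r` under the polygenic null model;
  default weights are the Beta(1, 25) density on MAF (flat optional). The
  null distribution is `Σ λ_j χ²₁` with `λ_j` eigenvalues of `W G' P G W`,
  `P = V̂⁻¹ − V̂⁻¹X(X'V̂⁻¹X)⁻¹X'V̂⁻¹`. With identity relatedness this is
  exactly standard SKAT, which the tests verify against an independent
  from-scratch oracle to 1e-6.
* **PWST**: the adaptive weight of variant `j` is
  `a_j = sign(β̂_j)·(−log₁₀ p_j)` from per-variant score tests under the
  fitted null; the statistic is the Wald z² of the `a`-weighted burden
  score. The permutation null decorrelates the phenotype residuals by
  `V̂^(−1/2)` (so they are exchangeable despite family correlation),
  permutes them, and re-estimates both the weights and the statistic each
  round — re-estimation is what neutralizes the overfitting of the adaptive
  score. p = (1 + #{perm ≥ obs})/(n_perm + 1) ≥ 1/(n_perm+1). Variance
  components are held fixed at the observed-data null fit across
  permutations: refitting every round is cost-prohibitive and the fixed-V
  scheme treats observed and permuted data identically. An option to
  permute raw residuals (ignoring family structure) exists for comparison
  only. Gene-level significance uses `0.05/n_genes`, with a fixed
  suggestive tier at 1e-3.

### Chi-square-mixture tail probabilities

`P(Σ λ_j χ²₁ > q)` is computed by Ruben's series of central chi-square
CDFs with `β = 0.90625·λ_min`: coefficients are positive and sum to one, so
truncation error is bounded by the remaining mass (tolerance 1e-12,
≤ 12,000 terms). Below p ≈ 1e-10 the `1 − CDF` subtraction loses precision
and the Kuonen saddlepoint (Lugannani–Rice) takes over — its relative error
is small exactly where the series' absolute error is not. Satterthwaite
scaling is the last resort. The method used is recorded in each result.

## Synthetic data

The generator states a world resembling a long-lived family cohort:

* **Pedigrees**: per family, an optionally recorded founder parent couple;
  a proband sibship of 2 + Poisson(1) (a proband plus at least one
  sibling); a married-in spouse per sib (founders, the study's controls);
  1 + Poisson(1) offspring per couple. Minimum family size 3. Default 50
  families (≈ 420 individuals).
* **Genotypes**: 100 genes, ≈ 8 variants each. Founder MAFs: 55 %
  pedigree-private singletons (one heterozygous founder carrier), 35 %
  rare (scaled Beta(0.5, 3) on [0.0005, 0.05]), 10 % common (uniform
  [0.05, 0.5]) — most variants rare, the majority private to one family,
  matching the qualitative spectrum of a candidate-gene capture panel.
  Descendants receive alleles by gene dropping (each parental allele with
  probability ½), so pedigree consistency is exact by construction;
  population history (LD, recombination) is deliberately not modelled.
* **Causal spike**: one gene carries 10 rare missense variants (founder
  MAF 0.001–0.004, each guaranteed at least one founder carrier so the
  spike actually segregates) with per-allele effect +1.0 on the
  standardized trait. This emulates pedigree-specific rare variation and
  is calibrated so the spiked gene is reliably the top famSKAT hit in the
  default scan; the observed rare-variant effects in family studies of
  exceptional survival are several-fold larger, so the default is
  conservative as a realism claim and strong as a detection target.
* **Phenotypes**: `trait = Gβ + u + ε` with `u ~ N(0, 2Φ h²)` drawn through
  the Cholesky factor of the true kinship (h² = 0.3 default) and
  `ε ~ N(0, 1−h²)`; plus realistic clinical columns (blood pressure,
  lipids, glucose, MMSE, T/S ratio, anthropometry, onset ages) with mild
  age trends, for exercising the derivation stage. Optional field-center
  offsets test residualization.
* **Life tables**: Gompertz, `S(t) = exp(−(a/b)(e^{bt}−1))`, with
  a = 7×10⁻⁵ (male) and 4.5×10⁻⁵ (female), b = 0.09 — modal age at death
  ≈ 80 and 85, a plausible 20th-century cohort shape.
* **Artifacts**: random missingness and capture gaps (contiguous variant
  blocks fully missing) are injected *before* Mendel errors so injected
  errors are never erased; Mendel errors corrupt a child genotype to an
  impossible value given its parents, with the affected (variant, family,
  trio) recorded as ground truth. Low-coverage/low-quality variants get
  summary values below the respective thresholds. Note a corrupted child
  who is also a parent can cascade an inconsistency into its own offspring
  trio, so detection may flag a superset of the injected trios.

Everything is seeded; identical config + seed reproduces byte-identical
outputs. A green end-to-end test therefore establishes that the pipeline
machinery recovers what this stated world contains — not that real
sequencing data meet the generator's assumptions (no LD, no batch effects,
no genotype-calling error structure beyond the injected artifacts).

## Numerical and design notes

* Kinship eigenvalues are clipped at 0 (tolerance −1e-8 for PSD checks).
* Tertile ties score to the healthier side; deterministic and documented.
* The profile-likelihood grid spans γ ∈ [1e-4, 1e4] plus the γ = 0
  boundary; the optimum is verified against the grid in the tests.
* The permutation p-value floor means PWST can never report p below
  1/(n_perm+1); choose n_perm accordingly.
* Genes with fewer than two post-filter variants are reported with a skip
  flag, not tested.
* All coordinates are 1-based (VCF convention) end to end; multiallelic
  records must be pre-split (`bcftools norm -m -any`).

## Limitations

* Binary traits enter only through onset exceptionality scores; there is no
  GLMM for case/control outcomes.
* The PWST internals (weight form, permutation scheme, per-round
  re-estimation) are one principled interpretation of an under-specified
  method; each choice is switchable in the API.
* No medication corrections for lipids/blood pressure are computed;
  pre-corrected columns are accepted as input.
* Real SSA life tables and reference-population distributions are not
  bundled; the generator supplies Gompertz and normal/empirical stand-ins.
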