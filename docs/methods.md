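# Methods

This note documents the statistical procedures implemented in `mceqtl`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not establish.

## Study design emulated by the generator

The package targets cohort designs of roughly 130–150 genotyped
individuals (a patient-heavy mix of inflammatory-disease cases and healthy
volunteers) with expression measured in five purified leucocyte subsets,
where each cell type is available for only a subset of individuals.
`mceqtl.simulate.SimConfig` encodes these conditions as defaults:

| parameter | default | meaning |
|---|---|---|
| `n_individuals` | 140 | genotyped cohort size |
| `cell_types` | CD4, CD8, CD14, CD16, PLT | five subsets; labels arbitrary |
| `snps_per_gene` | 10 | cis SNPs per gene, in LD blocks of 5 |
| `maf_range` | [0.05, 0.5] | post-QC allele-frequency range |
| `ld_flip_prob` | 0.05 | per-individual flip rate inside an LD block |
| `config_probs` | 70% null; of eQTLs ~55% fully shared, ~25% singletons, ~20% lineage pairs | cross-cell-type configuration prior |
| `effect_sd_range` | [0.4, 0.9] | additive effect per dosage unit (expression sd units) |
| `disease_fraction` | 0.6 | patient-heavy case/control mix |
| `batch_count`, `batch_sd` | 3, 0.3 | additive per-gene batch offsets |
| `noise_sd` | 1.0 | residual sd |
| `dropout_per_cell_type` | 0.15 | whole-sample missingness per cell type |

LD is simulated by block-copy-with-flips: SNPs in a block copy the block
head's dosage vector, each call flipped back to the head's marginal with
probability `ld_flip_prob`. This produces the graded r² needed to exercise
proxy lookup and conditional analysis; it does **not** reproduce
coalescent LD decay, population structure, or realistic microarray
intensity distributions. Genotype×disease (G×D) genes carry their effect
only in the diseased stratum (`y = μ + β·g·d + …`), one of the several
biologically possible interaction shapes; see "Known limitations".
Residuals are independent across cell types by default (`residual_corr`
exposes an equicorrelated option); the real data's within-individual
correlation is therefore not emulated unless requested.

## Genotype and sample QC

SNP filters run in a fixed order — missingness > 5%, monomorphic,
Hardy–Weinberg exact p < 10⁻⁸, MAF < 5% — so per-filter removal counts are
reproducible. The HWE test is the exact conditional test (enumeration of
heterozygote counts given allele counts, via log-gamma), not the χ²
approximation: at the 10⁻⁸ tail where the filter operates the χ² tail is
unreliable. Sample QC drops missingness > 5%, heterozygosity outside
mean ± 3 sd, and for identity-by-state pairs above 0.9 the member with
higher missingness (resolved greedily, most-related pair first).
Sex-mismatch QC is deliberately absent: it needs chrX intensity data the
pipeline does not model.

## Expressed-probeset detection

A two-component Gaussian mixture is fitted by EM to the vector of mean
probeset expression per cell type. Initialization: equal weights, means at
the data's first and third quartiles, both sds at the sample sd;
convergence when the log-likelihood gain drops below 10⁻⁸ (max 1000
iterations); a component sd collapsing below 10⁻⁶ raises an error
suggesting jitter. The lower-mean component is "non-expressed" and the
detection threshold is its 95th percentile, μ_low + z₀.₉₅·σ_low, with
z₀.₉₅ computed from the normal quantile function, not hard-coded.

## Expression adjustment

Two modes, chosen per analysis:

* **factor** (used for scans and the joint model): each probeset is
  residualized on known confounders (batch, sex), then the top
  `n_factors` principal components of the residual matrix are removed —
  except components whose absolute correlation with a protected covariate
  (disease, by default) exceeds 0.3, so latent-factor removal cannot
  absorb the disease signal. This is a deterministic stand-in for
  iterative latent-factor methods; it implements the same contract
  (remove K unwanted factors, protect biology) without their inference
  machinery. The 0.3 protection threshold is our choice, configurable.
* **batch** (used for the interaction scan, where latent factors might
  eat genuine disease effects): fit protected covariates per probeset,
  equalize each batch's location and scale on the residuals, add the fit
  back. With simulated batches of ≥ 15 samples the empirical-Bayes
  shrinkage of full batch-correction methods is immaterial.

Before the joint model, expression is mapped per probeset to standard
normal quantiles, Φ⁻¹((rank − ½)/n), ties broken by a seeded random
permutation — making the per-cell-type summaries scale-free.

## Cis scan and plug-in FDR

The association test is the 1-df additive score test (see README for the
formula); β and its se come from the full OLS fit, so the Wald z² and the
score χ² are close but not identical. Missing dosages are mean-imputed
per SNP immediately before regression (QC sees true missingness).

The plug-in FDR permutes expression rows (and their covariates) against
genotype rows — one permutation per replicate applied matrix-wide, so
gene–gene correlation survives — and pools all permuted statistics. The
default B = 3 suffices because the estimator pools ~B × (number of pairs)
null statistics; for small scans (hundreds of pairs) B should be raised,
since the declared set's stability is limited by the null tail resolution.
The FDR universe is SNP–gene pairs by default; a per-gene-maximum variant
is exposed (`gene_level=True`). The FDR curve is monotonized to be
non-increasing in the threshold, and the threshold is the smallest
statistic whose estimated FDR meets the target.

## Joint Bayesian model averaging

Per (gene, SNP) and configuration γ, active cell types' effects are
modeled as b_s = b̄ + e_s with b̄ ~ N(0, ω²), e_s ~ N(0, φ²). Because the
alternative covariance is diag(V_s) + φ²I + ω²J, the Gaussian marginal
likelihood ratio has a closed form via a rank-one update, and a cell type
with no data contributes a factor of exactly 1. The grid spans total
variance φ²+ω² ∈ {0.01, 0.04, 0.16, 0.64, 2.56} × heterogeneity fraction
φ²/(φ²+ω²) ∈ {0, ¼, ½, ¾, 1} (25 points). Errors are treated as
independent across cell types even when individuals overlap — a
documented approximation; a full multivariate error model is out of
scope.

The hierarchical EM maximizes

    Σ_genes log[ π0 + (1−π0) · (1/m_g) Σ_snps Σ_γ Σ_k η_γ λ_k BF_{snp,γ,k} ]

over (π0, η, λ) with a uniform prior over each gene's m_g cis SNPs.
Fitting λ rather than fixing it uniform matters: with λ uniform, the
near-null grid points (total variance 0.01) let null genes leak into the
alternative and bias π0 downward by ~0.15 in our simulations; with λ
fitted the bias drops to ≤ 0.1 under a fully-shared truth. The
log-likelihood is non-decreasing by construction and is asserted so in
tests. When every Bayes factor equals 1 the likelihood is flat in π0; the
fit returns π0 = 1 with a warning. An EBF-style plug-in estimator
(fraction of genes with gene-level BF ≤ 1) is available as
`pi0_ebf_plugin` for comparison.

Posteriors per gene: PP(eQTL) from π0 and the gene-averaged BF; PP per
SNP ∝ its η-weighted BF; the configuration posterior at the best SNP; MAP
configuration with ties broken toward fewer active cell types
(configurations are enumerated sparsest-first, so `argmax` does this
deterministically); Shannon entropy (bits) of the configuration
posterior. The Bayes FDR declares the largest PP-ranked prefix whose mean
(1 − PP) is below target.

## Two-step interaction scan

Documented in the README; the statistical point is the step-1 filter:
regressing on genotype *without* disease as covariate makes the filter
statistic independent of the step-2 interaction t-statistic, so BH over
the step-2 tests is honest (verified: selected-pair step-2 p-values are
KS-uniform under a no-interaction simulation). Step 1 uses batch-adjusted
(not quantile-transformed) expression so interaction effects stay on the
expression scale. Candidates whose genotype×disease cells have fewer than
2 distinct genotype values are excluded from the BH universe (counted in
the output). Q-values use the Storey estimator with λ = 0.05…0.95 and a
cubic smoothing spline for π0. FDP in validation is reported as the mean
per-scan V/R (zero when nothing is declared) — the quantity BH controls;
pooled ratio-of-sums is unstable at the small declared counts these
sample sizes produce.

## Sharing, LD and overlap

Jaccard coefficients are computed at gene level (a pair-level flag covers
SNP–gene counting). Joint-model presence sets come from the MAP
configuration by default, or from per-cell-type activity PP > 0.5.
LD r² is the squared in-sample dosage correlation (composite LD), which
replaces reference-panel proxy lookup; this diverges from phased-panel r²
and is documented as such. GWAS overlap supports the basic criterion
(GWAS SNP or proxy with r² > 0.8 in the FDR set) and the stringent one
(additionally the gene's top cis SNP). Score-matrix clustering uses
1 − Pearson distance with average linkage (scale-invariant; choice
config-exposed, since no single convention is canonical).

## Validation: what it shows, and problem sizes

The validation suite (`tests/test_acceptance.py`, `scripts/acceptance.py`)
runs desk-scale replicas — 60–300 genes, 100–200 individuals, 10 cis SNPs
per gene, 5 cell types, 5 seeds for stochastic quantities — chosen so each
experiment completes in seconds to minutes while leaving enough events to
measure rates. Headline results: score test equals n·cor² to machine
precision and matches a likelihood-ratio test to |Δp| ≤ 10⁻³ at n = 800
(the score/LR gap is χ⁴/2n, so this agreement is asymptotic by nature and
is tested at a sample size where it genuinely holds); null scans are
KS-uniform; plug-in FDR holds its 5% target with slack; π0 is recovered
within ±0.1 and MAP configurations at ≈97% accuracy; with truth fully
shared, the joint model's fully-shared fraction (~0.98) far exceeds the
comparison-of-lists estimate (~0.4), and halving the sample size collapses
the naive Jaccard (0.74 → 0.22) but barely moves the joint one
(0.99 → 0.96); permuting one cell type's labels wipes out its declared
activity and its Jaccard with the others.

Passing these tests shows the machinery is correct and calibrated on data
satisfying the generator's assumptions; it does **not** show robustness to
probe-level artifacts, population structure, coalescent LD, correlated
residuals across cell types, or non-additive genetic effects, none of
which the generator produces.

## Known limitations

* **Two-step power for purely disease-restricted eQTLs is modest.** An
  effect of 0.75 sd present only in the diseased stratum (90 of 130) has
  a pooled step-1 noncentrality of ~11 against the χ² cutoff of 16.4
  implied by α₁ = 5×10⁻⁵, capping full-procedure power near 0.18; the
  validation reports the honest value. Interactions riding on a main
  effect, or stronger ones (≥ 1.5 sd), are detected with power > 0.8.
* π0 from the hierarchical EM remains downward-biased (~0.2) when true
  configurations mix singletons with full sharing at modest effect sizes;
  MAP-configuration accuracy is unaffected. Interpret π0 as a lower bound
  in that regime.
* The independent-errors approximation overstates joint evidence slightly
  when cell types share most individuals and residuals are correlated.
* In-sample LD r² on ≤ 200 individuals is noisy near the 0.8 proxy
  threshold.
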