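# Methods

## Model and procedure

`mstscan` detects variance-QTLs — SNPs whose genotype groups differ in
phenotypic dispersion — as an implicit test for gene–environment
interaction when exposures are unmeasured.

Per SNP, each of K traits is adjusted by OLS for genotype-group dummies and
covariates (intercept always included; one dummy when only two genotype
groups are observed). The dispersion measure is the squared deviation of
each residual from its trait-wise **median** (the interpolated midpoint
median for even n) — the median, not the mean, for robustness to skewed
residuals, as in the Brown–Forsythe scale test.

The multivariate scale test (MST) fits two multivariate linear models to
the n×K dispersion matrix D: intercept-only (reduced) and intercept plus
genotype dummies (larger). Σ̂0 and Σ̂1 are the residual
sums-of-squares-and-cross-products matrices — raw sums of outer products,
never divided by n; any common scaling cancels in the statistics. Pillai's
trace V = tr[(Σ̂0−Σ̂1)Σ̂0⁻¹] maps onto an F(df1, df2) reference via the
standard approximation with s = min(K, L−1), t = (|K−L+1|−1)/2,
u = (n−L−K−1)/2, df1 = s(2t+s+1), df2 = s(2u+s+1). The univariate test
(UST) for trait k is the one-way ANOVA F of D_k on genotype group, with
df3 = L−1 and df4 = n−L.

Two exact identities anchor the implementation and are enforced in tests:
at K = 1 the MST collapses to the UST (same F, same degrees of freedom,
same p), and on any instance the (V, F, df1, df2, p) tuple equals a
reference MANOVA implementation's Pillai output treating D as responses
and genotype as a factor.

Decision rules in a genome scan of M SNPs over a trait domain:

* **stage 1**: vQTL if MST p < α/(M × #domains);
* **stage 2 (ad hoc)**: trait k attributed if its UST p < α/M1, where M1
  is the number of stage-2 tests actually performed;
* the **one-stage UST comparator** flags trait k if UST p < α/(M × #traits);
* replication requires p < α/#discoveries in an independent cohort;
* greedy LD clumping reports independent loci: ascending p (ties by
  position), removing same-chromosome records within the window whose
  allele-count r² with the index SNP exceeds the cutoff.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `maf_min` | 0.05 | scan filter; low-frequency SNPs genotype/impute poorly and GxE at rare G×E cells does not replicate |
| `outlier_sd` | 5 | single-pass exclusion of samples > 5 SD from the mean residual on any trait |
| `alpha` | 0.05 | family-wise level entering every derived threshold |
| `n_domains`, `n_traits_total` | 8, 29 | multiplicity bookkeeping of the reference study design; config, never hard-coded |
| `min_group_n` | 1 | per-genotype-group minimum; the MAF filter is the primary guard |
| `clump_r2`, `clump_window_bp` | 0.01, 1 Mb | LD independence cutoff; the window default is our choice, as typical clumping windows go |

Thresholds are always derived from the current M / M1 / discovery count at
use time, never cached.

## Numerical choices

* p-values are computed through the F log-survival function; scan TSVs
  serialize them in scientific notation with six significant digits, so
  magnitudes of 1e−215 round-trip.
* V is clipped into [0, s] within 1e−10; a larger excursion raises an
  internal error. V = s (perfect separation) reports F = ∞, p = 0.
* A singular Σ̂0 (duplicated or constant trait) raises a "degenerate trait
  set" error; a within-group SS that is numerically zero relative to the
  total SS marks the univariate test degenerate (p = 0, flagged).
* Rank-deficient designs raise an error naming the first dependent column.
* Missing genotypes are handled complete-case per SNP; missing
  trait/covariate cells complete-case per trait set.
* Outlier screening uses genotype-free residuals computed once per trait
  set, not per SNP: a genome of per-SNP exclusions would be both
  incoherent (different samples per SNP) and expensive. The mean model is
  refit per SNP with the genotype dummies, exactly as specified above.

## The simulation engine

`simulate` generates one-SNP data sets: G ~ Binomial(2, MAF) under
Hardy–Weinberg, binary exposure E ~ Bernoulli(prevalence), and traits

    Y = 0.3·G + 0.3·E + βINT·G·E + ε,

with ε multivariate normal (unit variances, correlation matrix by
scenario), or — for the right-skewed family — ν·ε² elementwise with
ν = 0.5, giving ν·χ²(1) marginals (skewness 2.8, excess kurtosis 12).
βINT (default 0.3) applies only to the designated informative traits. The
exposure is never shown to the scale tests; detection must come through
genotype-dependent dispersion. Default cohort sizes are 93 708 (discovery)
and 25 200 (replication); MAF bins use the nine midpoints 0.075 … 0.475.

Correlation scenarios A–F form a ladder of common pairwise correlation
0, 0.15, 0.30, 0.45, 0.60, 0.75; F (0.75) is the canonical
high-correlation setting. G and H mimic trait sets where one trait is
inversely related to the others (e.g. HDL vs LDL/TG): trait 1 correlates
−0.15 (G) or −0.30 (H) with the rest, which correlate +0.15 / +0.30 among
themselves. Only F's value is externally anchored; A–E, G, H are package
defaults chosen to realise the intended ordering, and any K×K positive
definite matrix can be passed instead.

Genotypes are idealised draws at the bin midpoint rather than real
biobank SNPs, so LD structure, differential missingness, imputation error
and covariate confounding are *not* emulated; passing power/FDR checks
here demonstrates the statistical behaviour of the decision rules, not
robustness to those artefacts. Squaring correlated normals yields squared
variables with correlation ≈ ρ², so the chisq1 family's trait correlation
is weaker than the nominal ρ; we keep the plain squared-normal
construction and note the discrepancy rather than re-calibrating ρ.

Replication streams derive from a master seed through
`SeedSequence(seed, spawn_key=(scenario_index, maf_index, rep))`, so every
cell is reproducible independently of execution order.

Experiment defaults mirror the genome-wide design: MST α = 2.4E−9
(= 0.05/(2 570 487 × 8)), UST α = 6.7E−10 (= 0.05/(2 570 487 × 29)),
ad hoc α = 0.05/65. Pooled FDR divides false trait flags by all trait
flags pooled over cells and replications — per-replication FDR would be
undefined whenever a replication flags nothing. The bundled experiment
scripts use 15 replications per (8 scenarios × 9 MAF bins) cell, i.e.
1080 pooled replications per experiment, and 1000 per cell on reduced
subgrids for per-cell power comparisons; these sizes give the pooled
estimates stable denominators (hundreds of discoveries) while keeping a
full run in the minutes range.

## Known limitations

* The F reference for Pillai's trace is an approximation; with skewed
  dispersion (chisq1 traits) at low MAF the null p-values are visibly
  conservative (deflated), matching the behaviour the simulation engine
  reproduces. Scans of strongly skewed traits should restrict to common
  variants.
* Dosages are not supported: the scale tests are defined on discrete
  genotype groups, so VCF/PLINK input must carry hard calls.
* Relatedness is not modelled; input cohorts are assumed pruned to
  unrelated individuals upstream.
* The direct GxE test uses conventional OLS standard errors by default
  (a heteroskedasticity-robust switch exists, since dispersion effects are
  the very signal that brought a SNP to this stage).
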