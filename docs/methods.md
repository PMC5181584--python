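# Methods

This note documents the models implemented in `gxemap`, the numerical
choices behind them, what the synthetic generator does and does not
emulate, and the known limitations.

## Study design being modelled

The package targets a two-regime common-garden trial on a diversity panel:
~141 highly homozygous accessions drawn from three genetic groups (a small
wild-relative group, a large cultivated-cherry group, and an admixed
group), genotyped on a fixed SNP array (~6100 markers over 12
chromosomes), grown with two replicate plants per accession under a
control and a deficit-irrigation regime, in one or two locations analysed
separately. Quality traits (sugars, acids, vitamin C, fruit weight, vigor)
are measured per plant or per fruit pool.

## Genotype QC, kinship, structure, LD

* **Filtering order**: accessions with >25% missing calls are dropped
  first, then markers with >10% missingness, then markers with minor
  allele frequency <0.04 computed on the remaining non-missing calls. The
  order matters on heavily missing data and is fixed; filtering is
  idempotent.
* **Imputation**: missing dosages are replaced by the marker mean of the
  non-missing calls (equivalently twice the allele frequency on the dosage
  scale). This is the standard mean-dosage reading of "replace by the
  major-allele frequency" and keeps the design matrices of the linear
  models complete; it slightly shrinks marker variance at high
  missingness.
* **Kinship** is identity-by-state allele sharing,
  `K_ij = mean_m (1 - |x_im - x_jm| / 2)`, unit diagonal. IBS matrices can
  be indefinite, so `K` is bent to PSD by flooring eigenvalues at 1e-6
  before any REML. IBS also contains a sizeable identity-like component,
  which partially absorbs iid residual variance in the mixed model — the
  variance *split* (pseudo-heritability) is therefore weakly identified on
  accession means even though the GLS weighting, and hence the tests, are
  stable.
* **Structure**: classical PCoA (double-centered `-D²/2` with `D = 1-K`,
  eigendecomposition). The first 3 axes are used as fixed covariates
  downstream; with three ancestral groups two axes separate them and the
  third absorbs residual admixture.
* **LD** is the squared Pearson correlation of dosage vectors (composite
  LD). On a near-inbred panel (inbreeding F ≈ 0.95) dosages are almost
  haplotypes, so dosage r² tracks gametic r² closely; we document it as an
  approximation to the maximum-likelihood haplotype-frequency estimator.
  Zero-variance markers yield undefined r² and are excluded from
  percentile computations.
* **Critical LD threshold**: the 95th percentile of r² over up to 100 000
  distinct inter-chromosome marker pairs sampled uniformly without
  replacement. On an unstructured panel this approaches the chi-square
  null quantile 3.84/n; population structure inflates it severalfold,
  which is precisely why the empirical percentile, not the asymptote, is
  used.

## Phenotype statistics

* **Box-Cox**: λ is chosen on the grid −2…2 (step 0.25) to minimize the
  absolute sample skewness — a distribution-shape criterion rather than
  the Gaussian profile likelihood, because the mapping models only need
  symmetry, not full normality. Among λ within 0.02 skewness of the
  optimum the one closest to 1 is kept, so already-symmetric data pass
  through untransformed. Non-positive data are shifted minimally first.
  The transform is chosen once per trait × location on the pooled C+D
  accession means and shared by both regimes; Δ is computed on raw means.
* **ANOVA**: sequential (Type I) sums of squares in the fixed order
  Gr, Gr(G), W, Gr×W, Gr(G)×W, via incremental least-squares projections
  with rank tracking, so unbalanced data are handled exactly; F-tests use
  the residual mean square. Fractions are of the total corrected SS.
* **Heritability**: `value ~ group (fixed) + accession (random)` by REML
  (statsmodels MixedLM), per regime; `H2 = s2G/(s2G + s2e/n)` with `n` the
  mean replicate count for that trait. Because the group is fixed, `s2G`
  is within-group genetic variance. On balanced data the REML estimate
  coincides with the ANOVA method-of-moments estimator (tested).
* **Plasticity** `Δ = (D−C)/C` on raw accession means; a zero control mean
  gives a flagged missing value. Δ is scale-invariant by construction.
* **Interaction decomposition**: with genotypic SDs `s_C`, `s_D` of the
  accession means and their correlation `r`, the G×W interaction splits
  into a scale part `(s_C−s_D)²` and a re-ranking part `2 s_C s_D (1−r)`,
  reported as fractions of their sum; a numerically vanishing interaction
  returns (0, 0) rather than 0/0.

## Univariate mixed-model scan and MLMM

The model is `y = Xb + g + e`, `g ~ N(0, s2g K)`, `e ~ N(0, s2e I)` on
accession means. One eigendecomposition `K = U S U'` turns REML into a 1-D
problem in `δ = s2e/s2g`: a 100-point log10 grid on [−5, 5] plus bounded
refinement (`xatol` 1e-6). Scans hold the variance components of the
current null model fixed (EMMAX approximation within a step) and test each
marker by GLS with an F statistic on `n − p − 1` denominator df — F rather
than chi-square because the panel is small and the chi-square reference is
anticonservative at n ≈ 141. Markers collinear with the covariates or
cofactors are flagged missing. Under permutation and polygenic nulls the
scan is calibrated (type-I ≈ 5% at α = 0.05, genomic-control λ ≈ 0.99).

**Forward selection**: at each step the most significant marker (ties
broken by genome order) enters the fixed effects and variance components
are re-estimated; the path stops at 5 cofactors or when the
pseudo-heritability drops below 0.01. The retained model is the *largest*
along the path whose cofactors all keep a drop-one partial-F p-value below
1e-4 — the drop-one reading of "all cofactors significant" makes the
criterion a property of the final model rather than of entry order.
Forward-only steps are used; with at most five cofactors the backward
sweep of the original multi-locus scheme has no room to act.

**PVE**: the global PVE of a marker set is the variance of the fitted
fixed marker component over the covariate-adjusted phenotypic variance
(OLS after covariate projection); per-marker PVE in scan output is
`β² var(x) / var(y)`. Both are descriptive summaries, not variance
components, and can exceed the simulated target when effect estimates
absorb correlated polygenic signal.

## Bivariate (two-regime) model

Stacked phenotypes `[y_C; y_D]` with `cov(g) = Vg ⊗ K` (per-regime genetic
variances and cross-regime correlation ρ_g) and diagonal residual
`Ve ⊗ I`. The residual cross-covariance is fixed at zero because the two
regimes are measured on different plants, making it unidentifiable from
these data. After rotation by `U`, the 2n×2n covariance is block diagonal
in 2×2 blocks, so each REML evaluation is O(n); the five parameters are
optimized by Nelder-Mead on log-variance / atanh-correlation coordinates,
initialized from the two univariate fits (|ρ| bounded at 0.999).

Per marker, three nested fixed-effect models are compared under the
no-marker covariance (two-step approximation): none / one shared effect /
per-regime effects. The *global* test (shared vs none) and the *G×W* test
(per-regime vs shared) are 1-df F tests; PVEs are the corresponding
explained-variance fractions of the covariate-adjusted stacked variance.
The blocked computation is verified in the tests against a dense 2n×2n
GLS oracle to 1e-6.

**Degenerate inputs**: if `y_C` and `y_D` are numerically identical, the
between-regime difference subspace has zero sample variance and the REML
likelihood is unbounded (σe → 0, ρ → 1). The implementation detects this
and takes the exact factorized limit — the duplicate contributes no
information, so the global test is computed by the univariate engine on
the regime-mean trait and the G×W p-value is 1 (the interaction contrast
is identically zero).

## QTL records

Significant markers (MLMM cofactors of the retained models per regime and
on Δ; MTMM markers below 1e-4 on either test) are merged into unique QTLs
by single-linkage on pairwise r² above the critical threshold, within
chromosomes. Each QTL gets:

* an **interval** from the "last linked marker" rule — the most distal
  markers up- and downstream still in LD with the peak above the
  threshold, with gaps of unlinked markers allowed (intervals are monotone
  in the threshold by construction); a peak with no linked neighbor gets a
  degenerate single-bp interval;
* **allelic effects** per regime, `(minor-carrier mean − major mean)/2` on
  accession means, with heterozygous-rounded accessions counted as minor
  carriers (configurable choice; the near-homozygosity of the panel makes
  it almost moot);
* a **type**: interactive if flagged on Δ or the G×W test (subtype
  antagonist when the regime effects have opposite signs, else
  differential); otherwise constitutive if flagged in both regime scans or
  by the MTMM global test; otherwise control- or drought-specific.
  Interactive takes precedence so the type counts are mutually exclusive;
* optional **gene counts** from a GFF3 (`gene` features, 1-based inclusive
  spans, any overlap counts — an interval abutting a gene by one bp
  includes it).

Cross-population comparison pools related traits into 'acids' (pH, malic,
citric) and 'sugars' (SSC, glucose, fructose) and counts a QTL as common
when intervals on the same chromosome and trait group overlap by ≥1 bp,
ignoring QTL type and trial location; clusters of mutually overlapping
records count once.

## Synthetic data generator

* **Genotypes**: ancestral frequencies U(0.05, 0.95); group frequencies by
  a Balding-Nichols Beta draw with divergence parameter Fst (default 0.3,
  enough for two PCoA axes to separate three groups as in the emulated
  panel); haplotypes from a Gaussian-copula AR(1) field whose correlation
  decays as `exp(-d/L)` with distance (L = 2 Mb default), thresholded at
  the group frequency — markers on different chromosomes independent;
  per-locus exact homozygosity with probability F = 0.95. Optional uniform
  missingness for QC testing.
* **Phenotypes**: per regime, accession genetic value = planted marker
  effects + a polygenic term with covariance proportional to the realized
  kinship; the two regimes' polygenic terms share a configurable genetic
  correlation (default 0.9: the emulated trial shows genotype variance
  dominating G×W roughly 4:1 with re-ranking-dominated interaction, which
  a correlation near 0.9 reproduces; interaction partitions of the
  generated data come out ~90-99% re-ranking). Replicate noise is scaled
  to the *within-group* genetic variance so that the trial's own REML
  estimator (group fixed) recovers the configured H² (default 0.75, the
  upper-middle of the 0.30-0.92 range observed for major-QTL traits);
  between-group divergence then adds to the total-scale heritability.
* **QTL classes**: constitutive (equal effects), control/drought-specific
  (one zero), differential (same sign, 3:1 intensity ratio), antagonist
  (opposite signs). Effects are calibrated to a realized per-regime PVE
  target (default 15% on the pattern regime) by a closed-form warm start
  plus iterative rescaling against the realized genetic variance — the
  warm start alone undershoots when several strong QTLs and structure
  induce cross-covariances, hence the refinement passes (8, each O(n);
  realized PVE lands within ±0.01 of target). Causal positions snap to the
  nearest marker with MAF ≥ 0.05 so the planted architecture survives QC.
* **Trait scale**: the baseline mean is set to five total SDs (a
  metabolite-like signal-to-mean ratio; fruit-weight-like traits have
  lower ratios and correspondingly noisier Δ) and the deficit regime
  shifts the mean by +10% by default, emulating concentration of quality
  metabolites under drought.
* **What it does not emulate**: realistic demographic history or
  recombination maps, linked selection, multi-trait genetic correlations,
  location effects (a single location by default), non-Gaussian trait
  noise, and genotyping error beyond uniform missingness. Passing recovery
  tests therefore show the machinery is correct and calibrated under the
  declared covariance structure, not that real-data power will match.

## Validation studies and their honest outcome

`gxemap.validation` runs three studies used by the tests and the
acceptance script: permutation/polygenic-null calibration, null
forward-selection behavior, and a 50-seed recovery study planting one QTL
of each class at PVE 15%. Detection (a reported QTL tags the causal
marker at r² ≥ 0.5 or covers it) runs at ~95%. Correct *typing* is high
for constitutive and antagonist QTLs but structurally low for
control-specific ones: at PVE 15% the Δ scan and the G×W test are well
powered for *any* regime-asymmetric effect, and a specific QTL has a
larger cross-regime contrast than a differential one, so under the
interactive-takes-precedence rule most planted specific QTLs are re-typed
interactive. This is a property of the classification scheme itself — the
probability of an interactive flag is monotone in the effect contrast, so
no threshold can simultaneously flag differential QTLs and spare specific
ones — and the pooled typing rate (~0.65) is reported as measured.

## Numerical conventions

1-based inclusive genomic coordinates throughout; marker IDs
`S{chrom:02d}_{pos:08d}`; regimes coded C/D; dosages are minor/alt allele
counts in [0, 2]; p-value ties in selection broken by (chromosome,
position); all stochastic code takes explicit seeds and same-seed runs
are bit-identical, including the pipeline manifest.
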