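# Methods

## Model and architecture

The package analyzes one quantitative trait at a time under the mixed model

    y = X b + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

where X holds an intercept plus optional population-structure columns and
continuous covariates, and K is an n x n kinship matrix. Every method
pipeline is the same two-stage construction: (1) a genome-wide screening
stage nominates candidate markers under a deliberately lenient threshold;
(2) all candidates enter one joint linear model on whitened data, their
effects are shrunk by empirical Bayes, and survivors are tested one at a
time by likelihood ratio; markers with LOD >= CriLOD (default 3) are
reported as QTNs. Detecting loci that a Bonferroni-corrected single-marker
scan would miss, while keeping false positives per genome low, is the point
of the design: multiplicity control is delegated to the joint shrinkage
model rather than to the screening threshold.

## Null model and scans

The kinship matrix is eigendecomposed once per (trait, kinship) pair;
eigenvalues are clamped at zero. In the rotated basis the covariance is
diagonal (h_i = lambda d_i + 1 up to sigma_e^2), so the profile REML/ML
likelihood of the variance ratio lambda is one-dimensional and cheap. It is
maximized by a 100-point log-scale grid sweep on [1e-5, 1e5] followed by
bounded golden-section refinement (relative tolerance 1e-6). The grid
protects against multimodality; refinement runs only around the best grid
point. If the profile is flat (K proportional to I: only the total variance
is identifiable), a warning is raised and lambda is pinned to the lower
boundary with a flag. A dense-matrix evaluation of the same restricted
likelihood exists alongside the spectral path purely as an independent
oracle for testing.

Both genome scans hold (sigma_g^2, sigma_e^2) at the null estimates — the
P3D ("population parameters previously determined") device — so each marker
costs O(n):

* **fixed scan** — GLS estimate of the marker effect in the whitened basis,
  Wald p-value from the normal approximation;
* **random scan** — the marker enters as a random effect gamma_k ~
  N(0, sigma_k^2). With the null covariance whitened away the model is a
  rank-one update, the maximizing sigma_k^2 has a closed form, and
  LR = g - 1 - log g with g = (z'y)^2 / (||z||^2 sigma_e^2) for g > 1 (0
  otherwise). Because sigma_k^2 is tested on the boundary of its parameter
  space, p-values use the mixture 0.5 chi2_0 + 0.5 chi2_1.

Whitening is y_w = D^(-1/2) U'(y - X beta_hat) with D = diag(lambda d_i + 1);
marker columns get the same transform and are residualized against the
whitened X (Frisch-Waugh keeps effects on the original code scale).

## Screening stages

* p-value thresholding at alpha_screen = 0.005 for the parametric scans and
  0.05 for the Kruskal-Wallis scan (the rank statistic is lower-powered, so
  its gate is the conventional nominal level); both are configurable.
* 20-kb window de-duplication (mrMLM, FASTmrMLM): greedy sweep per
  chromosome in ascending p order; ties break by position then name.
* Kruskal-Wallis scan across the genotype classes of each marker with the
  standard tie correction, vectorized over markers via per-class rank sums;
  degrees of freedom are (non-empty classes - 1); degenerate cases
  (single class, all-tied phenotype) report p = 1.
* Per-chromosome least-angle regression (pLARmEB): markers standardized to
  unit variance, pure LAR path (scikit-learn `lars_path`), first
  min(SelectVariable, m_chrom, n-1) entrants kept, default 50 per
  chromosome.
* Iterative sure independence screening (ISIS EM-BLASSO): rank by absolute
  correlation with y_w, keep d = floor(n / log n); one further iteration
  ranks the remaining markers against the residual of a small-ridge refit
  on the kept set. Ties break toward the lower marker index.

All screening is deterministic; no stage uses random numbers.

## Empirical-Bayes stage and QTN calling

Candidates Z (whitened codes) and y_w enter the iterative scheme

    E: gamma_hat = (Z'Z + sigma^2 diag(1/sigma_k^2))^-1 Z' y_w,
       V_k = sigma^2 [A^-1]_kk
    M: sigma_k^2 <- (gamma_hat_k^2 + V_k + tau*omega) / (tau + 3)
       sigma^2   <- (||y_w - Z gamma_hat||^2 + sum_k V_k z_k'z_k) / n

with the scaled inverse chi-square hyperprior at its diffuse default
(tau, omega) = (0, 0); the M-step is then the posterior mode of sigma_k^2.
Initialization uses squared marginal OLS effects floored at 1e-4; a
candidate is dropped when sigma_k^2 < 1e-8; convergence is max |delta
sigma_k^2| < 1e-8 or 1000 iterations; q > n is allowed (shrinkage
regularizes) with a warning; sigma^2 collapsing below 1e-12 aborts with a
singular-fit error.

The final test of each retained candidate evaluates the full-model Gaussian
likelihood **at the shrunken EB estimates** while the reduced model (without
candidate k) is refit by least squares: LR = n log(RSS_reduced/RSS_full)
clamped at 0, LOD = LR/(2 ln 10), p from chi2_1. Both choices are
deliberately conservative for marginal candidates — shrinkage lowers the
full-model fit, and the reduced-model refit lets correlated co-candidates
absorb a dropped marker's signal — and together they are what keeps the
genome-wide false-positive count low at LOD 3 despite the lenient
screening; an unshrunk maximum-likelihood full model would cross LOD 3
roughly 0.25 times per 2000-marker null genome from multiplicity alone
(E[max z^2] ~ 2 log m). Reported *effects* come from the unshrunk
least-squares refit, so effect sizes are not attenuated. Exactly collinear
retained candidates (LD copies) are pruned with a warning before testing.
Explained variance uses the Hardy-Weinberg code variance:
r2% = 100 * 2 p (1-p) effect^2 / var(y) with p the minor-allele frequency.

## Kinship

Two estimators: the marker-scaled cross-product K = WW'/c with W the
column-centered codes over polymorphic markers and c = sum 2 p_k (1 - p_k),
and identity-by-state allele sharing K_ij = 1 - sum|x_ik - x_jk|/(2m).
Neither is bent or regularized; a positive-semi-definiteness violation
beyond tolerance raises rather than being silently repaired. An optional
flag rescales the marker-scaled K to unit mean diagonal (off by default).

## Synthetic data

The generator draws per-marker minor-allele frequencies uniformly from
[0.05, 0.5], genotypes under Hardy-Weinberg, and induces local LD by a
neighbor-copy rule (probability `ld_rho`, never across chromosome
boundaries); positions are spaced 10 kb. Phenotypes are y = sum beta_j x_j
+ u + e with beta solved from target r2 shares via beta =
sqrt(r2 / (2p(1-p))), u multivariate normal with covariance h2 * K
(marker-scaled, normalized to unit mean diagonal), and Gaussian residual
filling the unit variance budget. The default conditions used throughout
the test and acceptance suites are: null genomes n = 200 x m = 2000 over 5
chromosomes with h2_poly = 0.3; power genomes n = 300 x m = 3000 with four
QTNs of r2 = 0.05/0.075/0.10/0.15 and ld_rho = 0.2. These sizes keep a
100-replicate study under a minute per condition while leaving the
operating characteristics (multiplicity, LD tagging, polygenic confounding)
realistic in kind.

What the generator does **not** emulate: coalescent population history,
allele-frequency spectra, dominance/epistasis, genotyping error, or
case-control ascertainment. Passing tests therefore demonstrate that the
pipelines behave as designed under their own model assumptions — polygenic
covariance, additive sparse QTNs, block LD — not that they are robust to
every feature of real data. The neighbor-copy LD model produces exact
marker duplicates, which is a deliberately hard case for the collinearity
handling and window de-duplication.

## Numerical and design choices

* Genotype coding fixed at {+1 major-hom, 0 het, -1 minor-hom}; allele
  frequency ties break lexicographically, so codes never depend on how a
  file lists its alleles and dialect round-trips are exact.
* Missing genotypes are mean-imputed and snapped to the nearest code (ties
  toward 0); missing phenotypes are dropped case-wise per trait.
* Q-matrix columns summing to one lose their last column before use as
  covariates (identifiability next to the intercept).
* All result tables are CSV with 6-significant-digit floats; re-runs
  overwrite.
* The worker pool distributes (trait, method) pairs; every stage is a pure
  function of its inputs, so outputs are byte-identical for any worker
  count (1-10; larger requests are clamped with a warning). Failures are
  isolated per pair.
* The Bootstrap flag is accepted for interface compatibility and warned
  about, never executed.

## Known limitations

* FASTmrEMMA is realized as whiten-then-random-scan; the original bespoke
  covariance transformation of that method is approximated by this
  composition.
* The false-positive property sits near its bound for the two pipelines
  without a window-dedup + fixed-scan screen (mrMLM's random-scan screen
  and pLARmEB's ungated LARS screen): measured means were ~0.11 emitted
  QTNs per null genome against the 0.1 working bound, within one Poisson
  event at 100 replicates.
* Effect estimates of detected QTNs at n = 300 carry GLS standard errors up
  to ~0.11 for low-MAF markers, which caps the true-vs-estimated effect
  correlation near 0.90 at the default study conditions; this is an
  estimation-noise ceiling, not an estimator defect (shrunken estimates
  score slightly worse).
* Case-control phenotypes, VCF/PLINK ingestion, out-of-core matrices and
  epistasis are out of scope.
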