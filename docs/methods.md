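# Methods

## The association model

Each candidate CpG–gene pair is fitted by ordinary least squares of log2
expression on methylation (beta values in [0, 1]) with covariates:
intercept, sex, age (years), cohort as fixed indicator contrasts (first
level, sorted lexicographically, as reference), and — in the default
`cell_adjusted` model — six blood cell-type proportions with granulocytes
dropped as the reference (the proportions sum to ~1, so keeping all six
plus an intercept would be collinear; the choice of reference does not
affect the methylation coefficient). The `cell_unadjusted` model omits the
cell terms. The reported coefficient β is the change in log2 expression per
unit methylation; the catalogue scale is β/10 (log2 fold change per
0.1-point, i.e. 10-percentile, methylation increase), and
`percent_change(x) = 100·(2^x − 1)` converts it to a percent expression
change.

p-values are two-sided t-tests on the methylation coefficient with residual
degrees of freedom n − k − 1 (k covariate columns including the intercept).
Missing values are handled complete-case per pair in `fit_pair`, with
`n_used` recorded; the matrix scan requires complete data. Log p-values are
carried alongside (`ln_p`) so extreme tails survive downstream comparison
without underflow. Expression is assumed already residualized for technical
surrogate variables upstream; the package neither estimates nor requires
them.

`run_model` uses the Frisch–Waugh–Lovell decomposition: methylation and
expression are residualized once against the shared covariate design (via
QR), after which each pair reduces to a simple regression between residual
vectors with the full model's degrees of freedom. This is algebraically
identical to the explicit per-pair fit — the test suite asserts equality to
1e-10 against `fit_pair` and against a normal-equations oracle — and makes
the permutation loop tractable: one matrix product per permuted dataset
instead of millions of repeated OLS factorizations.

## CpG-level multiple testing

The per-CpG statistic is the minimum association p over the CpG's cis
genes; CpGs paired with many genes therefore get no mechanical advantage.
Null calibration uses permuted expression datasets: one sample-column
permutation per dataset, applied identically to all genes, with methylation
and covariates fixed. This preserves gene–gene correlation — which the
minimum-p statistic is sensitive to — while breaking both the
methylation–expression and covariate–expression links. Permutation *i* is
drawn from a dedicated stream seeded by `SeedSequence([master_seed, i])`, so
runs parallelize and rerun reproducibly; the identity permutation is
rejected by redraw and index 0 is reserved for the observed data.

Per CpG, the permuted minima are fitted with a two-parameter beta
distribution by maximum likelihood: Newton iterations on (log a, log b)
from a method-of-moments start, gradient tolerance 1e-8, at most 200
iterations, with values clamped to [1e-300, 1 − 1e-12] before taking logs.
The MLE is vectorized across CpGs (all fits advance in lock-step with a
2×2 Newton solve per CpG per iteration). A degenerate or non-converged fit
falls back to the rank-based estimate (r + 1)/(n_perm + 1) and, for
thresholds, to the empirical quantile of the permuted minima. The scalar
path is cross-checked in tests against `scipy.stats.beta.fit` and against
the closed form Beta(1, k) for minima of k uniforms.

Empirical p = beta CDF at the observed minimum. Benjamini–Hochberg at
α = 5% on empirical p-values (ties broken by a stable sort on
(p_emp, cpg_id)) selects eCpGs. The genome-wide empirical threshold is the
midpoint between the largest significant and smallest non-significant
empirical p — a bracketing reading of "the eCpG closest to the FDR
boundary"; `rule="largest"` uses the largest significant value instead, and
when everything is significant no bracket exists so the largest significant
value is used. Each selected CpG's nominal pair-level threshold is the
inverse beta CDF at the genome-wide threshold, and every pair with
p < nominal is a significant eQTM. By construction every eQTM's CpG is
BH-significant (hierarchical containment, asserted in tests).

Default n_perm is 100; the beta approximation is what makes empirical
p-values far below 1/100 meaningful. Its fidelity is checked at 1,000
permutations: beta-based and rank-based empirical p agree at Spearman
ρ > 0.99 on mid-range CpGs.

## The synthetic generator

The generator emulates a child-blood multi-omics study at the structural
level the scan consumes:

- **Annotations.** CpG and gene positions uniform per autosome with counts
  proportional to chromosome length (defaults: chromosomes 1–2, 60 + 40 Mb);
  gene bodies log-normal (~10 kb) and short relative to the 500 kb window;
  TSSs kept a full window from chromosome ends. Coordinates are 1-based
  inclusive, array-manifest style.
- **Covariates.** Sex ~ Bernoulli(½); age ~ Uniform(6, 11) years; six
  cohorts; cell proportions Dirichlet with a granulocyte-dominant mean and
  total concentration 30, approximating child leukocyte mixes.
- **Methylation.** Logit-normal per CpG: the CpG mean is drawn from a
  bimodal mixture (45% low ~ Beta(2, 10), 45% high ~ Beta(10, 2), 10%
  intermediate ~ Beta(5, 5)), matching the two-mode beta-value landscape of
  blood arrays, with latent SD 1.0 (≈ 0.1–0.2 on the beta-value scale,
  mean-dependent), plus cohort (SD 0.3), cell-composition (coefficient SD
  1.0), sex and age effects on the latent scale. The logistic squash
  guarantees [0, 1] and realistic variance–mean coupling.
- **Expression.** Per-gene Gaussian baseline (mean 7, SD 2 on the log2
  scale) plus cohort/cell/sex/age effects, plus β·methylation for each
  planted pair, plus N(0, noise_sd²) noise (default 0.5). Planted |β| is
  uniform on [1, 3] with a 50/50 sign mix; by default 10% of CpGs carry one
  effect each. An optional shared latent factor (off by default) adds
  residual gene–gene correlation; no value for its strength is claimed.
- **Genotypes.** Independent SNPs with MAF uniform in [0.1, 0.5], dosages
  Binomial(2, MAF). A causal chain adds `effect·dosage` (default 1.0 per
  allele) to the chosen CpG's *latent* methylation — exactly additive there
  and ≈ 0.1–0.2 beta-value points per allele at mid-range CpGs, a strong
  cis-meQTL — and propagates the induced methylation change into the target
  gene through the planted β, so the chain is exactly linear through the
  CpG. Applying the shift on the latent scale keeps methylation in [0, 1]
  without clipping. The chain API therefore takes and returns the omics
  matrices (the SNP effect must flow into both).
- **Truth.** Every planted pair is recorded with its coefficient and
  mechanism (`direct` or `snp_driven`, with `snp_id`); unaffected pairs are
  implicit nulls. `unique_genes=True` restricts planting to disjoint genes,
  which makes per-chain marginal effects clean for trio validation.
- **CpG metadata.** ICC, heritabilities, island position, chromatin-state
  flags and age-change labels are fabricated from simple parametric draws
  with optional dependence on truth status (higher ICC, enriched
  active-promoter/enhancer flags for true eCpGs) so enrichment analyses
  have signal to find.

What the generator does **not** emulate: probe-level array artifacts
(intensities, detection p-values), linkage disequilibrium, spatial
correlation of methylation along the chromosome, isoform-level TSSs, and
heavy-tailed expression noise. Passing tests therefore demonstrate the
correctness and calibration of the procedure under its own modelling
assumptions — linear effects, Gaussian expression noise, exchangeable
samples — not robustness to every artifact of real arrays.

## Downstream statistics

- **eCpG typology.** mono/multi by distinct eGene count; inverse/positive
  when all effect signs agree, bivalent when mixed (so mono is never
  bivalent). Summaries (counts, % inverse, signed-distance median/IQR,
  % within 250 kb, median |log2FC per 0.1|) use linear-interpolation
  percentiles.
- **Distance–effect trend.** OLS of |log2FC per 0.1| on log10 |TSS
  distance|; zero distances are set to 1 bp before the log (flag to drop
  them instead).
- **Enrichment.** 2×2 Pearson chi-square without continuity correction
  (flag available), odds ratio from the same table with Haldane 0.5 only
  when a cell is zero; categories tested marginally at p < 0.05.
  Methylation bins: low ≤ 0.3 < medium ≤ 0.7 < high. Reliability filter:
  ICC strictly > 0.4, CpGs without ICC dropped and counted. Group
  comparisons use two-sided rank-sum tests.
- **Trios.** meQTL/eQTL scans reuse the association engine with dosage as
  predictor and identical covariates for both scans (optionally plus
  genotype PCs from a truncated SVD of the centered dosage matrix).
  Significance p < 1e-7 by default; a trio is consistent iff
  sign(meQTL)·sign(eQTM) = sign(eQTL), with exact zeros treated as
  inconsistent. Candidate SNP–CpG pairs are user-supplied or all
  same-chromosome pairs within the window.
- **Adult comparison.** Catalogues matched on (CpG, gene symbol) after
  exploding multi-symbol entries; within each key and source only the
  smallest-p row survives (stable order breaks ties). A child association
  is age-shared iff any adult source matches at p < 1e-5; matches in both
  adult sources count as age-shared with per-source direction agreement.
  Symbol matching is exact and case-sensitive (no alias resolution).

## Validation sizes and numerical choices

The operating-characteristic study uses 20 replicates of 2,000 CpGs × 200
genes × 300 samples with 100 permutations — large enough for stable FDP
estimates, small enough to run in seconds per replicate thanks to the
residualized scan. The beta-fidelity study uses 600 CpGs × 80 genes at
1,000 permutations. Window boundaries are inclusive (|distance| ≤ 500 kb;
a strict flag exists). BH uses `statsmodels.stats.multitest`; chi-square
and rank-sum use scipy. All randomness flows from integer seeds through
`numpy.random.default_rng`; the pipeline derives per-stage seeds from the
master seed by fixed offsets and writes SHA-256 digests of every output so
reruns are verifiable byte-for-byte.

## Known limitations

- The nominal-threshold step inherits any misfit of the beta approximation
  in the extreme tail; at n_perm = 100 empirical p-values below ~1e-4 are
  extrapolations of the fitted null.
- No adaptive early stopping of permutations and no analytic
  effective-number-of-tests shortcut; the permutation loop cost is linear
  in n_perm.
- One TSS per gene; multi-TSS genes and trans effects are out of scope, as
  are sex chromosomes.
- The eQTL/meQTL stage tests user-supplied or window-based candidates only;
  no LD pruning, clumping, conditional or mediation analysis.
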