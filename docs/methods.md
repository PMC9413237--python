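# Methods

## Scope

`vitropop` implements a population-based *in vitro* variability analysis
for cytotoxicity screens of chemicals and defined mixtures across panels
of genotyped human donor cell lines: plate normalization and QC,
hierarchical Bayesian concentration–response fitting, EC10 points of
departure, the toxicodynamic variability factor TDVF₀₅, and single-variant
association mapping of the POD phenotype. A synthetic-screen generator
supplies inputs with the statistical structure the analysis assumes.

## Synthetic screen generator

The generator emulates a 384-well screen: each donor × substance is run
on 3 replicate plates, each carrying 16 vehicle (0.5% DMSO) wells, 8
positive-control wells (100 μM tetra-octyl ammonium bromide, complete
kill), and one treatment well per concentration at five 10× dilutions
spanning 0.01–100 μM. Vehicle wells fluctuate around a nominal mean with
10% CV; positive controls carry a ~0.2% residual signal.

Donor Hill parameters are lognormal: `ln EC50 ~ N(ln 10, 0.5²)` by
default (EC50 centred mid-range of the tested span; ln-SD 0.5 implies a
population TDVF₀₅ of ≈ 2.3, the scale typically seen for moderately
variable cytotoxicants), `ln y0 ~ N(0, 0.05²)` (baselines within ±10% of
vehicle), and `n = 1 + exp(z)`, `z ~ N(0, 0.5²)` (median Hill slope 2,
support strictly above 1 — reconciling normal random effects on a log
scale with the n ≥ 1 restriction without a hard truncation boundary).

The latent treatment response is `hill(x) + ε` with `ε = σ·t₅`, σ = 0.1
response-fraction units by default; raw counts are that response times
the *realized* same-plate vehicle mean, floored at zero (luminescence is
non-negative). Because normalization divides by the same vehicle mean,
post-normalization residuals follow the additive scaled-t error model the
fit assumes exactly, and with σ = 0 the normalized response equals the
Hill curve to machine precision. The zero floor truncates the error
distribution only where the curve is near complete kill and the noise
draw is large and negative; with the default σ this affects a small
fraction of top-dose wells and is invisible to the robust likelihood.

Genotypes are Hardy–Weinberg binomial draws at ancestral frequencies
uniform on a configurable MAF window; multiple ancestry groups drift
around the ancestral frequency by a Balding–Nichols Beta model with a
single Fst-like parameter. Causal variants shift `ln EC50` additively per
minor-allele copy. Mixture recipes allocate per-chemical mass fractions
proportional to user-supplied reference values (POD / RfD / exposure /
AC50 scenarios at "low" = median or "high" = 95th-percentile levels).

What the generator does *not* emulate: plate spatial effects (edge
drift), pipetting covariance between wells, batch effects, linkage
disequilibrium between SNPs, and non-Hill response shapes. Passing tests
therefore demonstrate correctness of the statistical machinery under the
model's own assumptions, not robustness to violations of them.

## Plate QC

Normalization divides each well by the mean of the same plate's vehicle
wells (stimulation above 1 is retained). A plate passes QC when the
vehicle CV — sample (n−1) SD over mean of the *raw* vehicle counts, since
the gate guards measurement quality prior to normalization — is strictly
below 20%, and the mean normalized response of the positive-control wells
is ≤ 0.05 ("complete kill"; the cutoff is configurable since no numeric
tolerance is standard). QC failure excludes the whole plate, not single
wells. Reproducibility is summarized by Pearson correlations between
paired response profiles; the inter-plate check pairs two of the
replicate plates chosen by a seeded RNG, and zero-variance profiles are
flagged invalid rather than returned as NaN.

## Hierarchical Bayesian Hill model

Parameters `θ_i = (ln y0_i, ln x0_i, ln(n_i−1))` have normal random
effects with population means μ and SDs τ. Priors: `μ_ln y0 ~ N(0, 2)`,
`μ_ln x0 ~ N(ln 30, 3)` (covers the tested decade span without forcing
activity), `μ_ln(n−1) ~ N(0, 1)`; `τ ~ HalfNormal(1)`;
`σ ~ HalfNormal(0.5)` truncated below at 1e−5 (far beneath plate-reader
resolution; keeps the posterior proper and the sampler mobile on
noise-free synthetic data). Wells from all replicate plates enter the
likelihood as independent observations; vehicle wells do not (they define
the normalization). Non-responsive donors are handled by hierarchical
shrinkage, not exclusion.

Sampling is adaptive Metropolis-within-Gibbs over vectorized chains:

- per-donor blocks move by random-walk MH with a proposal covariance
  learned during warm-up (Haario-style), because the three curve
  parameters ride a narrow correlated ridge when the data are precise;
- population means are drawn from their exact normal full conditionals;
- population SDs and σ move by MH on the log scale;
- two interweaving (ancillarity–sufficiency) moves per scale — a joint
  translation of (μ_d, all θ_id) and a joint rescale of (τ_d, all
  centered θ_id) — cross the hierarchical funnel that otherwise throttles
  mixing of the weakly identified Hill-coefficient effects.

Initialization is deterministic: a coarse (ln EC50 × n) grid search per
donor followed by bounded local least squares, with small per-chain
jitter. Step sizes adapt only during the discarded first half of each
chain. Convergence requires the classic Gelman–Rubin R̂ (between/within
chain variance) ≤ 1.2 for every stored parameter; otherwise the chain
length doubles (4000 → 8000 → 16,000 by default) with a fresh
deterministic seed per attempt, and a fit still failing at the cap is
returned flagged `converged=False`.

Numerical notes: the Hill curve is evaluated as a logistic in
`n·ln(x/x0)` (monotone and stable in the far tails); `ln(n−1)` is capped
at 30 inside the likelihood to avoid overflow during exploration. On
noise-free data the posterior collapses toward a point; estimates remain
accurate but R̂ can stay above threshold because within-chain variance
vanishes — the flag is reported honestly and downstream summaries remain
usable.

## POD, activity, TDVF₀₅

EC10 is closed-form per draw, `x0·(1/9)^(1/n)`, always below the EC50 for
n ≥ 1. The activity rule is strict: inactive iff population median EC10 >
3× the top tested concentration. "Population median EC10" defaults to the
median across donors of per-donor posterior medians; a per-draw variant
(median across donors within each MCMC sample, then the median over
samples) is available via `population_median_ec10(..., method="per_draw")`
since the phrasing is ambiguous between the two.

TDVF₀₅ takes, within every MCMC sample, the median and 5th-percentile
quantiles of EC10 across donors (linear interpolation between order
statistics — the numpy default) and returns the ratio's distribution; the
reported point estimate is its posterior median, with 90% CrI and flags
against the 10^½ and 10 benchmarks. The statistic uses the *measured*
donors' random effects, not hypothetical new draws from the
hyperdistribution. Quantile-convention caveat: at n = 146 donors the
interpolated 5th percentile sits between the 8th and 9th order statistics
and is biased slightly toward the center, so a single empirical TDVF₀₅
underestimates the population value by ~6% in expectation; the estimator
is consistent as the panel grows. Panels below 20 donors trigger a
warning (the 5th-percentile donor is then an extrapolation); a single
donor is an error. Cross-substance summaries report the Pearson
correlation between log10 median EC10 and log10 median TDVF₀₅, flagged
invalid under zero variance.

## GWAS

The phenotype defaults to log10 of the per-donor posterior-median EC10
(PODs act multiplicatively; a raw-scale option exists). SNPs are filtered
to MAF ≥ 0.05 computed over non-missing calls and re-coded to minor-allele
counts. PCs come from the SVD of the column-standardized (mean-imputed)
genotype matrix, sign-fixed by the largest-magnitude score; no LD pruning
is applied (panels here are small — a documented limitation). The scan is
OLS per SNP of phenotype on (intercept, allele count, sex 0/1, PCs) via
residualization against the shared covariate block; SNPs whose
residualized genotype has no variance are flagged untestable rather than
crashing the scan. Hit classes use the fixed thresholds 1e−5 (suggestive)
and 5e−8 (significant); no FDR machinery, by design.

Genomic-control λ is the median association chi-square over 0.4549, with
QQ data on the −log10 scale and an acceptability flag for [0.9, 1.1].
Note the estimator's sampling SD is ≈ 0.75/√m for m SNPs (≈ 0.053 at
m ≈ 2000), so the acceptability band is only ~±2 SD for small panels and
~±4 SD at 10,000 SNPs.

The GRM uses the standard standardized-genotype cross-product
(diagonal ≈ 1 under Hardy–Weinberg; fixed SNPs must be filtered first).
MLMA fits one variance component by profile REML in the GRM eigenbasis —
fixed effects profiled out by weighted least squares at each variance
ratio, bounded scalar optimization over the log-ratio — then tests every
SNP by GLS with the implied whitening; with an identity GRM (or a zero
genetic component) it reduces exactly to OLS. Groups under 10 samples are
refused. Meta-analysis combines per-group z scores with weights
`sqrt(n_g / Σ n_h)` (the standard sample-size-weighted scheme) and
classifies hits on the combined two-sided normal p; SNP sets must match
across groups. Regional views return position-ordered windows with
−log10(p) for locus plots, and the overlap report lists SNPs suggestive
in ≥ k phenotypes.

X-chromosome male dosage is taken as provided (no dosage-compensation
model), and batch-vs-PC association is available only as a diagnostic —
both documented simplifications.

## Pipeline

`vitropop.pipeline` orchestrates simulate → QC → fit → POD/TDVF → GWAS
from one config (YAML-loadable) with a single global seed from which each
stage derives its own stream (SHA-256 of seed:stage:index, keeping all
derived seeds below 2³¹); identical configs reproduce identical outputs,
recorded in a run manifest with config hash and per-stage status. A stage
failure halts the run with a stage-tagged error; partial outputs are
preserved. The thin click CLI (`vitropop simulate|run|qc`) exits 0 on
success, 2 on validation errors, 3 on stage failures.

## Problem sizes used in the validation suite

The test and acceptance workloads run hierarchical fits at 4–20 donors
with 4 chains × 2000–16,000 iterations, 20 replicate recovery fits, and
100-replicate GWAS panels of 146 × 2000 SNPs — sizes chosen so the whole
suite completes in a few minutes on a single CPU while every statistical
property remains measurable at its stated tolerance.

## Known limitations

- No upward (stimulatory) Hill branch and no model selection across
  curve shapes.
- The sampler is random-walk based; posteriors from very large panels
  (hundreds of donors) will mix more slowly than a gradient-based
  sampler would.
- TDVF₀₅ reflects toxicodynamic variability only; no toxicokinetics, no
  margin-of-exposure arithmetic, no mixture dose-addition reconstruction.
- GWAS assumes unrelated donors within groups apart from the GRM
  correction; no imputation, gene annotation, or external replication.
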