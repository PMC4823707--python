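# Methods

## Noise model

For a gene with expected read count μ across technical replicates, the
package works with three stochasticity models:

- **Poisson**: Var(Y) = μ. Adequate for low-read genes, where counting
  noise dominates.
- **Gamma(k, θ)**: mean kθ, variance kθ², hence Var(Y) = μ²/k — a constant
  coefficient of variation CV² = 1/k across genes. Adequate for high-read
  genes, where amplification noise dominates.
- **Poisson-gamma hierarchy** (the synthetic generator's default):
  Y ~ Poisson(Λ), Λ ~ Gamma(k, μ/k). By the law of total variance
  Var(Y) = μ + μ²/k, which interpolates the two regimes: Poisson-like for
  μ ≪ k, quadratic for μ ≫ k. One mechanism therefore reproduces both
  observed regimes, which is why it is the default rather than raw gamma
  draws. `pure_gamma_rounded` (gamma draws, round half to even so counts
  stay integral) and `pure_poisson` exist for calibration studies that need
  one regime uncontaminated by the other.

The regime boundary is operationalized as a mean-read threshold: a gene is
*high-read* when its replicate mean strictly exceeds `mean_threshold`
(default 10, the conventional cut for this data type; real samples can have
boundaries anywhere in roughly 10–30, so the threshold is configurable and
the filter can be applied per group or pooled).

## Diagnostics

**Moments.** Per gene and group, the sample mean and the unbiased (n−1)
variance across replicates; at least two replicates are required.

**Mean-variance line.** Ordinary least squares of log10(σ̂²+1) on
log10(μ̂+1) over genes above the mean threshold, with at least three genes
required. The +1 offsets keep zero-mean and zero-variance genes on the
plot; they flatten the extreme low end slightly, which is why the low-read
regime check uses genes with means up to ~5 and tolerates slopes in
[0.85, 1.2] rather than exactly 1. Plain OLS is used deliberately — the
line is a descriptive summary, not an estimator with error guarantees.

**Gamma parameter estimation.** Method of moments, k̂ = μ̂²/σ̂² and
θ̂ = σ̂²/μ̂: closed-form, defined whenever the sample variance is positive,
and stable at n = 6 where maximum likelihood often diverges for
near-constant data. MLE (`fit_gamma_mle`) is available as an opt-in
alternative. Degenerate inputs (zero variance or zero mean) raise in the
single-gene API and become NA in whole-matrix scans, so a scan never aborts
on one flat gene.

**Kolmogorov–Smirnov goodness of fit.** One-sample KS with *plug-in*
parameters estimated from the same data, no Lilliefors-type correction.
Plug-in estimation pulls the model CDF toward the empirical CDF, so both
tests are conservative: under the true model at n = 6 they reject at
nominal 0.05 well below 5% of the time (the acceptance script measures
this). That conservatism is acceptable here because the test is used as a
*lack-of-fit screen* — near-uniform p-values for the right model family,
collapsing p-values for the wrong one — not as a calibrated test.

For the continuous gamma model the statistic and p-value come from the
standard one-sample KS machinery. For the discrete Poisson model the sup
distance must respect the model CDF's jumps: at every support point b both
one-sided gaps across the jump are evaluated,
max(F(b) − F̂(b⁻), F̂(b) − F(b⁻)), and the p-value uses the asymptotic
Kolmogorov distribution. With heavily tied data (e.g. a constant vector)
this convention penalizes the discreteness and can reject an exact-looking
fit; combined with plug-in estimation the net behaviour remains
conservative at realistic λ.

## Differential expression

All three tests compare group means **on the raw count scale** (identity
link), because with a handful of technical replicates the variance must be
modeled as a function of the mean rather than estimated freely per gene.

The two-group identity-link GLM is saturated, so the maximum-likelihood
fitted means equal the sample means and the Wald statistics have closed
forms (given in the README). The closed forms are verified against an
independent iteratively reweighted least-squares fit (statsmodels GLM) to
1e-6 in the test suite; the package itself never calls an IRLS solver.
Conventions the GLM procedure implies but rarely prints:

- Poisson: dispersion fixed at 1, standard normal reference.
- Gamma: Pearson dispersion φ̂ = Σ(y−μ̂_g)²/μ̂_g² / (N−2), Student-t
  reference with N−2 degrees of freedom. The statistic is invariant to
  rescaling both groups, as a constant-CV family requires.
- Wald rather than likelihood-ratio tests: the closed forms above are exact
  for this design, and Wald is what a `glm` coefficient table reports.

The gamma family requires strictly positive values. Zeros are a hard error
with an explicit `pseudocount` option (0.5 by convention) applied to the
gamma inputs only — silent fudging of other methods' inputs is deliberately
impossible. The intended workflow avoids the issue entirely by filtering to
high-read genes first.

The cube-root t-test uses Welch by default (robust to unequal transformed
variances and the common modern default); the pooled variant is available.
Under gamma noise the cube root is variance-stabilizing enough that the
t-test tracks the gamma GLM rank-for-rank (Spearman of −log10 p > 0.95 on
mixed null/DE data), which is the practical point: ordinary normal-theory
tools become usable on counts.

Benjamini–Hochberg adjustment is optional (`adjust="bh"`, computed per
method across genes via statsmodels); raw p-values are the default output.

## PCR amplification model

A Galton–Watson branching process: each molecule independently duplicates
with probability p (the amplification efficiency) at every cycle, constant
across cycles, molecules and replicates. Simulation uses one binomial
thinning per cycle on the aggregate count — distributionally identical to
tracking lineages, O(cycles) per replicate. Exact moments: with growth
factor 1+p and offspring variance p(1−p),

    E[Z_n]   = m (1+p)^n
    Var[Z_n] = m p(1−p) (1+p)^{n−1} ((1+p)^n − 1) / p

for m starting molecules, verified against exhaustive enumeration of all
branching outcomes at small cycle counts. The amplified total over m
independent founder molecules has CV² ∝ 1/m, so relative noise shrinks as
template input grows — the "gamma shape grows with input copies"
interpretation. `gamma_convergence_report` quantifies, rather than assumes,
how gamma-like the final counts are at a given (m, n, p): the many-cycle
limit argument is asymptotic and its adequacy depends on the parameters.

**What the mechanism does and does not reproduce.** At m = 20 founders the
gamma fit passes KS screening in ≥ 90% of seeds, so the marginal
distribution of amplified counts is gamma-like. However, across *genes
differing only in template copy number*, the CV² ∝ 1/m law makes variance
proportional to the mean, so the across-gene log-log mean-variance slope of
libraries from `generate_from_pcr` sits near 1, not near 2 (the acceptance
script reports it as `pcr_library_mean_variance_slope`). A quadratic
*across-gene* law — constant CV across genes — additionally requires
noise shared by all molecules of a gene within a library (for example,
replicate-level efficiency or volume fluctuations that enter exponentially
over the cycles). Such library-level effects are intentionally not modeled
here; per-molecule independence with constant efficiency is the stated
scope. The corresponding acceptance check asserts the quadratic band for
this generator and fails by design of the model; the distributional
generator (`generate_matrix`), which encodes the constant-CV gamma
assumption directly, is the one that reproduces the across-gene regimes.
A further consequence of high efficiency is that the amplified-count
distribution is mildly left-skewed near p = 1 (runs can only fall short of
deterministic doubling), another reason the exponential/gamma picture is an
approximation whose quality the convergence report measures.

The optional multinomial read-sampling stage (`depth`) models the fixed
sequencing budget: reads are drawn with probabilities proportional to
amplified molecule counts. It is off by default and is an extension beyond
the amplification model itself.

## Synthetic data and what passing tests show

The generator emulates a sextuplicate technical-replicate design: defaults
of 6 replicates per group, gamma shape k = 10 (CV ≈ 32% in the high-read
regime — a mid-range value for library-prep noise; no canonical published
dispersion exists for this design, so k is a package default, not a
measured constant), baseline means log-uniform so both regimes are
populated, and DE genes created by multiplying the group-B mean by a fold
change. Truth tables record configured means, DE status and fold change
exactly.

Real data differ in ways the generator does not model: library-size
variation between replicates (beyond the optional multinomial stage), batch
effects, correlated genes, sequence-specific amplification efficiency, and
composition effects from highly expressed genes. Passing tests therefore
demonstrate internal consistency of the methods under the stated noise
model — calibration under the model, anticonservatism of the misspecified
Poisson test, agreement of the two gamma-respecting tests — not performance
guarantees on any particular real dataset.

Problem sizes in the test and acceptance runs (2,000–10,000 genes, 6
replicates, 10⁵ branching-process draws, 50-seed convergence sweeps) were
chosen so Monte-Carlo error is small relative to every asserted margin
(binomial 3-SE margins on all rate thresholds).

## Numerical and interface choices

- Counts are non-negative reals throughout; integer-only operations
  (Poisson KS, Poisson GLM) validate integrality themselves. This admits
  reads-per-million inputs.
- CPM normalization is optional and never implicit; whether replicate
  counts should be library-size normalized before testing is a judgement
  call left to the user (`--cpm`).
- Two-group order: groups are taken in order of first appearance over the
  sample columns; statistics are signed as group₁ − group₀.
- Determinism: a single seed drives each CLI run; replicate streams derive
  from it via `SeedSequence` spawning. Identical argv + seed reproduce
  byte-identical tables (no timestamps in output headers).
- Zero-variance and zero-mean degenerate cases: errors in single-gene APIs,
  NA with a warning in table-level scans.

## Limitations

- Two groups only; no covariates, no multi-factor designs.
- No negative-binomial machinery: biological (between-sample) variance on
  top of technical gamma noise is out of scope.
- The KS tests are screening tools, not calibrated hypothesis tests, for
  the plug-in and discreteness reasons above.
- The PCR model omits plateau-phase efficiency decay, primer/GC sequence
  effects, and library-level shared noise (see above).
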