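# Methods

## Model and assumptions

A variant's z-scores across `T` traits are treated as one draw from a
zero-mean multivariate normal whose covariance decomposes into independent
environmental and genetic components, `Σ = Σ_e + Σ_g`.

The environmental component has unit diagonal by construction (a z-score has
unit variance under its own null) and off-diagonals
`Σ_e[i,k] = N_shared[i,k]/√(N_i N_k) · ρe[i,k]`: environmental correlation
between traits leaks into z-score correlation only through shared samples.
The input `ρe` diagonal is ignored and the diagonal forced to exactly 1.

The genetic component comes from placing a Gaussian random-effect prior on
the per-variant effect size, `β_i ~ N(0, σg_i²)` with
`cov(β_i, β_k) = σg_{i,k}`; marginalising gives
`Σ_g[i,k] = √(N_i N_k) · σg_{i,k}`. Under the polygenic assumption
`σg = Σ_h² / M` (total heritability covariance spread over all `M` variants).
Sample overlap does not enter `Σ_g`.

Key assumptions: variants are tested independently (no LD modelling); the
genetic covariance is constant across the genome (a single global estimate);
`σg` and `ρe` are externally estimated inputs, typically from (cross-trait)
LD-score regression, and are never estimated here.

## The likelihood-ratio test and its calibration

The statistic is `log N(S; 0, Σ_e+Σ_g) − log N(S; 0, Σ_e)`, kept in log space
because the raw ratio overflows at genome-wide-significant z-scores. An
analytic χ²-mixture approximation is deliberately not used; significance
comes from simulated nulls. Ties with the critical value κ are not
significant (strict `>`).

Calibration draws `V ~ N(0, rΣ_e)` and weights each draw by the density
ratio `N(V;0,Σ_e)/N(V;0,rΣ_e)` computed in log space. The p-value of a
statistic `t` is the weighted mass of simulated statistics `≥ t` over the
total weight — a conservative step function with no interpolation, ties
counted toward the tail. κ(α) is the smallest simulated statistic whose
p-value is ≤ α; p-values smaller than the table can resolve are reported at
the table's floor (top weight / total weight), never as zero. Defaults
`n = 10⁶`, `r = 2` resolve `α = 5×10⁻⁸` stably; `r < 1` is rejected because
the proposal must fatten the tails. The max-|z| baseline is calibrated the
same way with statistic `max_i |V_i|`; its null simulations use the identity
covariance by default (the baseline is defined for disjoint cohorts), with a
flag to use `Σ_e` instead.

Each calibration table records a fingerprint of the `Σ_e` it was built
under; the test stage refuses a mismatched table.

## m-values and causal-count rescaling

For each configuration `c ∈ {0,1}^T`, `Σ_g(c)` keeps entry `(i,k)` iff
`c_i = c_k = 1`. The m-value of trait `i` is the ratio of the summed
likelihoods `N(S; 0, Σ_e + s·Σ_g(c))` over configurations with `c_i = 1` to
the sum over all `2^T` configurations (log-sum-exp, one Cholesky per
configuration, exact enumeration guarded at `T ≤ 15`). The prior over
configurations is uniform — the formula is an unweighted sum, and this is
stated explicitly as a modelling choice. The global-null configuration stays
in the denominator. A trait is "associated" iff `m_i > 0.9` strictly; the
0.9 threshold is a convention, and the m-value behaves as a conservative
bound on false assignment rather than a calibrated error rate.

The scale `s = M/Q` corrects for the fact that significant variants are
drawn from the causal minority: with `σg = Σ_h²/M` the alternative is nearly
indistinguishable from the null, so `Σ_g` is inflated to the effect size
expected of `Q` causal variants. `Q` is fitted by maximising
`Σ_i log N(S_i; 0, (M/Q)Σ_g + Σ_e)` over lead variants obtained by sampling
one significant variant per 100 kb window. Design choices, where the
procedure was genuinely open:

- windows are fixed genome bins (0-based half-open after converting the
  1-based positions), not variant-anchored intervals;
- the grid is 512 geometrically spaced integers on `[1, M]` (geometric
  because `M/Q` acts as a scale parameter), deduplicated, with one linear
  refinement pass between the neighbours of the optimum;
- ties in the grid break toward the smallest (most polygenic) `Q`;
- a single global `Q` is shared by all traits.

## Summary-statistics handling

Coordinates are 1-based in files; window arithmetic converts internally.
QC keeps biallelic SNPs with non-ambiguous strand (drops A/T and C/G pairs),
MAF > 0.01 and INFO > 0.80; with a filter enabled, a variant missing that
field fails closed by default (overridable). Harmonisation inner-joins on
`chr:pos:sorted-allele-pair` (robust to RSID drift and allele orientation),
takes the first trait as the reference orientation, negates z (and beta) for
swapped ref/alt, and drops variants whose allele pair matches neither
orientation. Per-variant sample sizes are collapsed to a per-trait median;
the covariance formulas use per-trait `N`.

## Numerical choices

Cholesky is the canonical factorisation; log-determinants come from it.
Matrices failing positive semi-definiteness by eigenvalues above
`−10⁻⁸·λ_max` are clipped to zero with a warning (externally estimated
covariances are noisy); anything more negative is a hard error, because a
silent large repair would hide an upstream bug. Importance weights are
exponentiated log-ratios (they cannot overflow for `r > 1`). Binomial
concordance p-values are exact log-gamma sums — the interesting values
(~10⁻¹⁸⁴) are far beyond normal-approximation validity.

## What the synthetic data emulates — and what it does not

The generator draws z-score rows i.i.d. from
`N(0, Σ_e + mask_c(√(N_i N_k)·Σ_h²[i,k]/causal))`: the marginal
(posterior-predictive) distribution of the model itself, rather than explicit
per-variant effect draws plus noise — the two are distributionally identical
under the model and the marginal is much faster. `causal` converts the
heritability covariance into per-variant effects (fewer causal variants,
larger effects).

`synthetic_trait_panel()` is a stand-in four-trait panel (BMI-like,
diastolic-BP-like, height-like, systolic-BP-like; N = 350,000, full overlap)
with plausible heritabilities (0.25/0.15/0.45/0.15) and correlation
structure: the blood-pressure pair strongly correlated genetically (0.75)
and environmentally (0.60), BMI moderately correlated with both, height
nearly uncorrelated environmentally with the rest. It is synthetic — chosen
once as a realistic panel, not fitted to any dataset — so simulation
experiments reproduce qualitative structure (power orderings, rejection
geometry, assignment accuracy), not any published count.

Because rows are i.i.d. and effects are Gaussian, the simulations do not
emulate LD between variants, winner's-curse bias, allele-frequency-dependent
architecture, non-Gaussian effect-size tails, or local (per-region)
covariance structure. Passing tests therefore validate the statistical
machinery under its own model, not robustness to those violations.

For experiments targeting a stated omnibus power (50% and 44% in the
interpretation-accuracy study), the generating genetic covariance is scaled
by a multiplier found by bisection against the fixed calibrated κ using
common random numbers — the only reproducible definition when a target power
rather than an effect size is specified.

## Problem sizes

Simulation components run at sizes chosen to keep Monte-Carlo error well
below the margins being tested: calibrations use 10⁶ draws (`r = 2`) at
genome-wide α and 2–4×10⁵ plain-MC draws at nominal α; type-I error and
generator moment checks use 10⁵ draws; the power study is a 1/10-scale
version of a 1.5M-variant design (135k null + 15 configurations × 500/300/200
variants at causal = 40k/24k/16k); the interpretation-accuracy experiment
uses 10⁵ causal variants; causal-count recovery fits 100 replicates of 100
lead variants each. The acceptance script completes in well under a minute
and the test suite in well under half an hour on one CPU.

## Known limitations

- Exact configuration enumeration limits interpretation to `T ≲ 15`;
  no stochastic approximation of m-values is provided.
- The proposal scale `r` is fixed, not adaptive, and no variance-reduction
  beyond importance sampling is implemented.
- Replication power assumes standardised genotype/phenotype and
  reference-panel MAFs; it is approximate by construction.
- A single global `Q` and genome-constant `Σ_g` ignore per-trait and local
  architecture.
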