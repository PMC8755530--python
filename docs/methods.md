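# Methods

This note documents the statistical model behind `mendelmr`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that affect
results.

## The two-sample MR model

For variant j, let γⱼ be its true effect on the exposure (per
effect-allele copy, exposure in SD units) and Γⱼ its true effect on the
outcome (log odds for binary outcomes).  Under the instrumental-variable
assumptions (relevance, independence from confounders, and exclusion
restriction), Γⱼ = β·γⱼ, where β is the causal effect of one SD of
exposure on the outcome.  Summary statistics supply estimates
(γ̂ⱼ, se_γⱼ) and (Γ̂ⱼ, se_Γⱼ) from two (possibly overlapping) samples.
Direct (pleiotropic) effects αⱼ enter as Γⱼ = β·γⱼ + αⱼ; the estimators
differ in how much pleiotropy they tolerate:

* **IVW** assumes all αⱼ = 0. It is the precision-weighted mean of the
  per-variant Wald ratios θ̂ⱼ = Γ̂ⱼ/γ̂ⱼ with weights wⱼ = γ̂ⱼ²/se_Γⱼ²,
  equivalently weighted least squares of Γ̂ on γ̂ through the origin.
* **Weighted median** is consistent when variants carrying more than
  half the total weight are valid (αⱼ = 0).
* **MR-Egger** fits Γ̂ⱼ = a + b·γ̂ⱼ with weights 1/se_Γⱼ²; the slope b
  is consistent for β under InSIDE (instrument strength independent of
  direct effects) even with a nonzero mean direct effect, which the
  intercept a estimates.
* **MR-RAPS (simple model)** maximises the profile log-likelihood
  ℓ(β) = −½ Σⱼ (Γ̂ⱼ − βγ̂ⱼ)²/(se_Γⱼ² + β²·se_γⱼ²), which accounts for
  sampling error on the exposure side that IVW ignores; no
  overdispersion parameter and no robust loss are fitted.

Heterogeneity is summarised by Cochran's Q = Σ wⱼ(θ̂ⱼ − β̂)².  IVW in
`auto` mode applies multiplicative random effects — SE inflation by
√max(1, Q/(J−1)) — when more than three instruments are available, and
fixed effects otherwise; with three or fewer instruments the dispersion
estimate is too unstable to be useful.  The dispersion factor is floored
at 1 so random-effects SEs never fall below fixed-effects SEs.

## Instrument selection

Candidates must pass a strict p-value threshold (default 5×10⁻⁸;
a liberal tier at 5×10⁻⁶ can be added, and its instrument set is by
construction a superset of the genome-wide set) and the weak-instrument
screen F = (β̂/se)² ≥ 10, the standard single-variant approximation to
the first-stage F statistic.  Clumping is greedy: keep the
smallest-p surviving candidate, discard everything in LD with it at
r² ≥ 0.001, repeat.  Ties in p are broken by (chromosome, position,
variant id) so the output is deterministic and invariant to input row
order.  Per-variant variance explained is 2p(1−p)β̂² (p = effect-allele
frequency, exposure standardised); the instrument-set total r² feeds the
power module unless an externally estimated value is configured.

## Harmonisation

Alleles are matched textually, then after strand complement; swapped
labels negate the outcome beta and complement its frequency.
Palindromic pairs (A/T, C/G) cannot be strand-resolved from labels:
they are dropped when the exposure effect-allele frequency is missing,
and otherwise aligned by frequency agreement provided both minor-allele
frequencies are below 0.42 (near 0.5 the orientation signal vanishes;
the window is configurable).  Proxy records substituting for missing
outcome variants are taken as already oriented to the index variant —
the simplest well-defined contract for a locally supplied proxy table —
and are relabelled to the index variant id in the audit log.  Dropped
records carry NaN outcome effects and are excluded by `kept_only`
before any estimator runs.

## Power approximation

An MR analysis on N outcome samples with instruments explaining r² of
the exposure behaves approximately like a direct exposure-outcome study
of size N·r².  For a binary outcome with case fraction K, the
detectable log odds ratio at two-sided level α and power 1−b is
(z₁₋α/₂ + z₁₋ᵦ)/√(N·r²·K(1−K)); the inverse direction gives power at a
specified OR.  z-quantiles are used at full floating-point precision.
The two functions are exact inverses; detectable |log OR| scales as
1/√r².  For continuous outcomes the same formula applies with K(1−K)
replaced by 1 (not exposed on the CLI).

## Synthetic-data generator

The generator emulates the summary statistics the estimators consume,
not the underlying genotypes:

* γⱼ ~ Normal(0, `gamma_sd`); EAF ~ Uniform(0.05, 0.95);
  se_γⱼ = 1/√(2p(1−p)·n_exposure), the precision of a standardised-trait
  GWAS; γ̂ⱼ = γⱼ + noise.
* Direct effects αⱼ ~ Normal(`pleiotropy_mean`, `pleiotropy_sd`),
  defined in the exposure-increasing allele orientation and mapped to
  the effect-allele frame by sign(γⱼ).  A positive mean models
  directional pleiotropy of the kind the Egger intercept estimates; an
  allele-frame mean would be cancelled by Egger's own orientation step
  and is not estimable by any method.  `inside_violation` correlates
  αⱼ with standardised |γⱼ| through a Gaussian construction, breaking
  InSIDE by one interpretable parameter.
* Γⱼ = β·γⱼ + αⱼ observed with se_Γⱼ = 1/√(2p(1−p)·n_outcome·K(1−K))
  for a binary outcome with case fraction K (the factor that links the
  generator to the power module), K(1−K) omitted for continuous
  outcomes.

Defaults are the study conditions of a small-exposure / huge-outcome
cytokine design: J = 100 variants, n_exposure = 3636,
n_outcome = 10⁶ with 4 % cases, causal log-OR −0.04 per SD.
`gamma_sd = 0.15` was fixed a priori so that the expected per-variant
F at n_exposure = 3636 is ≈ 31, matching the instrument strength such
exposure GWAS typically deliver; it is a free parameter of the
generator, not an estimate.  For balanced-pleiotropy calibration
experiments `pleiotropy_sd = 0.01` is used — the same order as the
outcome-association SEs at the default outcome size, so pleiotropy is a
visible but not dominant variance component.

Corruptions for harmonisation testing are information-preserving and
recorded in a manifest: allele-label swaps (beta negated, EAF
complemented), strand complements, conversion of the allele pair to A/T
in both panels (creating genuine palindromes), and masking of exposure
EAFs.  Strand flips are skipped for variants made palindromic in the
same call, because a strand complement of A/T is indistinguishable from
a swap and would make the round-trip check ill-defined.  Harmonising a
corrupted outcome against the matching exposure recovers the original
signed effects exactly, except for deliberate drops (palindromes with
masked or ambiguous frequencies).

LD is block-structured: consecutive blocks of `ld_block_size` variants
with within-block r² drawn Uniform(0.5, 1) and zero between blocks; the
proxy table lists block-mates in both directions, replaying a proxy
lookup service locally.

What the generator does **not** emulate: individual-level genotypes,
realistic LD decay from reference panels, sample overlap between the
two GWAS, winner's-curse selection of instruments from the same data,
allele-frequency differences between populations, indels and
multi-allelic sites.  Passing recovery tests therefore demonstrate that
the estimators and harmonisation logic are correct under the stated
model, not that any real-data analysis is free of those additional
complications.

## Randomness and reproducibility

Every stochastic component takes an explicit seed.  A
`SimulationConfig` seed heads one `SeedSequence` with three fixed child
streams — generation, corruption, LD — so each operation is reproducible
in isolation; within generation the draw order is fixed (γ, EAF,
pleiotropy, exposure noise, outcome noise).  The weighted-median
bootstrap seed is mandatory; the pipeline derives per-outcome bootstrap
seeds from the run seed via `SeedSequence` spawn keys.  Re-running a
pipeline config yields a byte-identical JSON report.

## Numerical choices

* Normal (not t) reference for all p-values and CIs; CI half-width uses
  z₀.₉₇₅ at full precision.
* Wald-ratio SE is first order (se_Γ/|γ̂|), consistent with the IVW
  weight definition; the exposure-error term is handled by MR-RAPS
  rather than a second-order expansion.
* The RAPS score equation is solved by bracketed Brent root-finding
  around the fixed-effects IVW estimate, widening the bracket
  geometrically (×4, up to 8 times) and failing loudly if no sign
  change is found or the root is not an interior maximum; the SE is the
  inverse square root of the numerical observed information (central
  difference of the analytic score).
* Weighted-median interpolation uses cumulative weight midpoints
  pⱼ = (Sⱼ − wⱼ/2)/S_J and linear interpolation at 0.5, clamping to the
  extreme ratio when the midpoints do not bracket 0.5.
* The Egger design is solved from the 2×2 weighted normal equations;
  all-equal exposure effects after orientation raise a collinearity
  error rather than returning a singular fit.

## Validation problem sizes

The repeated-simulation harness (`simulate_and_recover`) runs the full
generate → harmonise → estimate path per replicate.  Calibration checks
use 1000 replicates at the default study scale for IVW coverage/type-I
error and Egger intercept coverage, and 500 replicates for the
unbiasedness and directional-pleiotropy recovery checks; the
weighted-median bootstrap inside the harness defaults to 200 resamples
(the estimator's own default is 1000), sizes chosen to keep Monte-Carlo
error well below the widths of the acceptance bands while remaining
comfortable to run routinely.

## Known limitations

* The Egger intercept's directional-pleiotropy recovery degrades when
  near-null instruments enter the analysis (sign-ambiguous orientation
  dilutes the mean); in practice the significance screen removes such
  variants before estimation.
* MR-RAPS is the simple model only; overdispersed and robust-loss
  variants, MR-PRESSO, mode-based estimators and multivariable MR are
  out of scope.
* Proxy handling assumes the proxy table supplies index-oriented
  alleles; no on-the-fly LD phasing is attempted.
* No multiple-testing adjustment is applied across outcomes or methods;
  reported p-values are nominal.
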