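# Methods

## Model

A bulk sample pools `n` haploid individuals drawn from an effectively
infinite population carrying the R allele at frequency `p`. Three
stochastic layers connect `p` to the four observed Cq values:

1. **Sampling.** The carrier count is binomial, `m ~ Bin(n, p)`.
2. **DNA yield.** Each individual contributes a gamma-distributed
   template amount (shape `k`, scale θ). Sums of iid gammas are gamma,
   so `X_R ~ Ga(mk, θ)` and `X_S ~ Ga((n−m)k, θ)` independently, and the
   within-sample frequency `Y_R = X_R/(X_R+X_S) ~ Beta(mk, (n−m)k)`.
   The scale θ cancels from every observable and is fixed at 1 inside
   the likelihood; only `k` (yield dispersion: `k=1` exponential, large
   `k` near-constant) is estimable.
3. **Measurement.** Ideal exponential amplification with per-cycle
   efficiency `1+η` up to a fixed threshold gives each channel's Cq as a
   logarithm of its template amount divided by `ln(1+η)`, plus
   independent `N(0, σc²)` error per well. The test condition multiplies
   the template by `δB` (digestion loss) and retains a fraction `z` of
   the susceptible allele at the target locus; the target/housekeeping
   content ratio is `δT`. In the allele-specific-primer protocol the
   same equations apply with the pure-R control playing the role of the
   undigested condition — its unknown template amount cancels from ΔCq
   exactly as `δB` does, so one code path serves both protocols.

The two ΔCq observables per sample are then

    ΔτW ~ N(−ln δT / L, 2σc²),                       L = ln(1+η)
    ΔτD | m ~ N(−[ln δT + ln(z + Y(1−z))] / L, 2σc²),

and the per-sample likelihood marginalizes ΔτD over `m` (binomial
mixture with exact end components at `m = 0` and `m = n`) and over `Y`
(the beta integral ψB). ψG computes the same marginal as a double
integral over `(X_R, X_S)`; it is mathematically identical (the ratio of
independent same-scale gammas is beta) and is retained as a
compatibility path and as an independent numerical cross-check. ΔτW and
ΔτD of one sample share no Cq terms, so their error terms are
independent and the likelihood is their product.

`z > 0` is structurally important: it keeps the `m = 0` branch (no
carrier in the pool) at a finite mean, which is what makes rare-allele
data informative at all.

## Parameters

| parameter | meaning | units | default / start | estimated by |
|---|---|---|---|---|
| `p` | population R frequency | — | start: ΔΔCq-average estimate clipped to [1e-3, 1−1e-3] | frequency fit |
| `k` | gamma shape of individual yield | — | start: 1 | frequency fit (fixable) |
| `δT` | target/housekeeping content ratio | — | start: 1 | both fits |
| `σc` | Cq error SD | cycles | start: 0.3 | both fits |
| `z` | digestion residue / off-target fraction | — | must be calibrated | calibration |
| `η` | amplification efficiency − 1 | — | must be calibrated | calibration |
| `δB` | digestion template change | — | — | calibration |
| `mean_dna` | per-individual template / threshold | — | — | calibration |

`k` always starts at 1: overstating yield variability is the safe side,
the likelihood carries little information about large `k`, and starting
large can park the optimizer on a flat shelf. `p`, being bounded, is
optimized on the logit scale; all positive parameters on the log scale,
which also makes the calibration's Wald intervals multiplicatively
symmetric, the natural shape for positive quantities.

## Numerics

**Beta kernel.** ψB is evaluated in `u = ln(z + y(1−z))` coordinates,
where the measurement kernel is exactly Gaussian with centre
`u* = −L·ΔτD − ln δT` and SD `s = √2 σc L`, and the beta factor has
integrable endpoint singularities. A tanh-sinh (double-exponential)
rule spans the full interval `(ln z, 0)` with the node count scaled as
roughly 3 nodes per `s` (rounded up within a small cached set, capped at
3001). Below that cap's resolution — σc of order 0.01 and smaller — the
rule switches to a window of ±11 s around `u*`, outside which the
integrand is suppressed by `exp(−11²/2) ≈ 1e−26`; the sifting property
of the narrow Gaussian makes this exact for practical purposes. Nodes
use `expit(π sinh t)` so endpoint distances stay accurate to ~1e−86
(a plain `tanh` saturates in float64), and all mixture accumulation is
in log space, so binomial weights of rare alleles at large `n` never
underflow. For samples sharing a pool size the (sample × component ×
node) contraction is a BLAS matrix product in max-shifted exponential
space. Against adaptive QUADPACK integration of the same integral the
rule agrees to ~1e−10 relative over the stress grid used in the tests.

**Gamma kernel.** ψG uses nested adaptive quadrature in log-template
coordinates `(ln X_R, ln X_S)`, which turns the algebraic origin
singularities into smooth exponential tails. The integration bounds
extend beyond the gamma-distribution bulks to the ratio-saturation
layers the measurement kernel can drag the mass to (ratio → `z` as
X_R → 0, ratio → 1 as X_R ≫ X_S), with the bulk edges supplied as
breakpoints so the adaptive rule refines both regions; the outer (X_S)
bounds follow from the exact factorization `X_S = (1−Y)(X_R+X_S)`.

**Optimization.** BFGS on the transformed scale with finite-difference
gradients (gradient tolerance 1e−6, 200 iterations); evaluation
failures return a large finite penalty (1e12) so line searches survive
stray non-finite regions. The observed information is a central
finite-difference Hessian at the optimum (relative step 1e−4), inverted
for Wald intervals that are back-transformed — so `p`-intervals always
lie inside (0, 1).

**Interval availability.** Interval estimation is judged per parameter:
an indefinite information matrix can still carry usable curvature for
`p` while `k` is flat, and the per-parameter diagonal of the inverse
decides each interval. Additionally, a `p`-interval that covers the
whole band (1e−3, 1−1e−3) — every practically distinguishable
frequency — is reported as unavailable: this arises when the MLE runs to
the boundary (typically a dataset with no carrier at all), where the
curvature is formally positive but carries no information. Point
estimates are always reported; `converged` and `success` flags tell the
two failure modes apart.

**Calibration.** With known mixing ratios every Cq is Gaussian around a
closed-form mean, so σc profiles out exactly: the five structural
parameters are fitted by Levenberg–Marquardt least squares and
`σ̂c² = SS/n` in closed form, after which the full six-parameter Hessian
supplies the intervals. On noise-free data this recovers the generating
parameters to machine precision. Identifiability is checked up front
(≥2 distinct ratios; a digested target series below ratio 1 for `z`;
control wells for `δB`; both genes for `δT`) with the offending
parameter named in the error.

## Synthetic data

The generator draws `m`, then the two gamma amounts (exactly zero when
the shape is zero), then adds independent `N(0, σc²)` noise to each of
the four Cq values — the 4σc² variance of ΔΔCq emerges from the error
model rather than being injected. Defaults describe a working
restriction-digest assay: δT = 1.2, δB = 0.24, z = 0.0016, η = 0.97,
σc = 0.2, mean per-individual yield 1e−6 of the threshold, and
θ = 1e−6/k so that varying `k` changes dispersion at a fixed mean.

What it does not emulate: plateau-phase and inhibitor effects on
amplification (the exponential-with-threshold idealization), per-primer
efficiency differences (one shared η), genotype-dependent extraction
bias, technical-replicate structure, and diploid genotypes. Passing
tests therefore demonstrate the estimator's behaviour under the model's
own assumptions — homoscedastic Gaussian Cq error was verified
empirically for the motivating assay, but any real application should
check linearity and homoscedasticity with `linearity_diagnostics` on a
known-ratio series first.

The canonical simulation grid crosses p ∈ {0.01…0.75}, N ∈ {2…64},
n ∈ {1…64}, k ∈ {1, 3, 9, 27} with N·n ≤ 128, excluding the degenerate
(N=2, n=1) pair — 624 regions. Per-replicate random streams derive from
a master seed via `SeedSequence(seed, spawn_key=(region, replicate))`,
so regions and replicates are reproducible independently and in
parallel. Reported problem sizes in the test suite and the acceptance
script (hundreds of replicates per design rather than 1000; 2 per region
on the full grid) were chosen to keep a full run in the minutes range on
one CPU; all summary statistics are medians and rates that stabilize
quickly at these sizes.

## Known limitations

- Wald intervals degrade near boundaries; profile-likelihood intervals
  would behave better for rare alleles but are out of scope.
- The gamma-kernel path is an order of magnitude slower than the beta
  path and exists mainly as a cross-check; `k` is weakly identified
  under it and tends to stay near its starting value when the true
  dispersion is small (large `k`).
- Fixing `k = 1` is recommended practice when `N·n > 3/p`; it speeds up
  fitting considerably and barely moves the frequency estimate, but it
  will understate interval width if the true yield dispersion is far
  from exponential and the total sample size is small.
- Calibration assumes the mixing ratios are exact; pipetting error in
  the dilution series is absorbed into σc.
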