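# Methods

## Model

`sdlmap` maps viability-selection loci from the genotypes of surviving
individuals of an F2-type cross. Fitness is modelled as a latent liability

    y_j = X_j β + Σ_k Z_jk γ_k + ε_j,   ε_j ~ N(0, 1),

with survival iff `y_j > 0`. The residual scale is fixed at 1, which
identifies the model (only survivors are observed, so there is no
phenotypic scale to estimate) and means all effects are in residual-SD
units. There is no intercept: an intercept would only shift the overall
survival rate, which is not identifiable from a survivors-only sample.

Genotype design codes are `H = [[-1, -1], [0, 1], [1, -1]]` for
(A1A1, A1A2, A2A2) × (additive, dominance): the additive code is the
centred A2-allele count, so a positive `a_k` means each A2 copy raises
survival. Under the 1:2:1 F2 ratio these codes have variance 1/2
(additive) and 1 (dominance), giving the per-locus genetic variance
`VG_k = a_k²/2 + d_k²` and broad-sense liability heritability
`H = VG / (VG + 1)` used throughout `summaries`.

Given the linear predictor `η_j`, the penetrance is `Φ(η_j)` (probit,
default) or the logistic function. The post-selection genotype
distribution at locus k, conditional on everything else, is
`π_j(g) ∝ φ_g Φ(H_g γ_k + η_j(−k))`; the locus likelihood is the
multinomial log-likelihood `Σ_j Σ_g w_j(g) ln π_j(g)`. When `w_j` is a
multipoint probability triplet rather than an indicator (missing or
pseudo markers), this quantity is an expected complete-data
log-likelihood and all derivatives are taken of this weighted objective.

Co-factors must have known pre-selection distributions. A discrete ±1
co-factor with class priors (φ1, φ2) is handled with exactly the
genotype machinery (a 2-class "locus" with codes ±1 and a uniform effect
prior). For a normal co-factor X ~ N(μ, σ²) the normalising constant
`E_X[Φ(Xβ + η)]` has the closed form `Φ((μβ + η)/√(σ²β² + 1))`; the
identity is specific to the normal CDF, so under the logistic link this
expectation falls back to 64-node Gauss–Hermite quadrature and the β
derivatives to central finite differences.

## Estimation

Each `γ_k` has a zero-mean normal prior `N(0, Σ_k)` and each `Σ_k` an
inverse-Wishart(τ, ω) hyper-prior; the default (τ, ω) = (0, 0) is the
Jeffreys prior. Fitting is posterior-mode coordinate descent:

1. one safeguarded Newton–Raphson step per co-factor (likelihood only);
2. one step per locus in map order, Gauss–Seidel (the predictor `η`
   always reflects the latest values, maintained incrementally);
3. the conjugate update `Σ_k = (γ_k γ_kᵀ + V_k + ω)/((τ+1) + dim + 1)`,
   with `V_k` the inverse negative Hessian from step 2.

Sweeps repeat until the largest absolute parameter change (β, γ and Σ
entries) drops below `tol` (default 1e-6, max 200 sweeps; non-convergence
is flagged on the result, not raised). Gradients and Hessians are
analytic for both links; correctness is enforced by finite-difference
tests. Safeguards: if the negated Hessian is not positive definite a
ridge is added, doubling from 1e-6; if a step decreases the objective it
is halved up to 10 times. Σ_k is kept proper by flooring its spectrum at
1e-10. A locus whose Σ_k diagonal falls entirely below 1e-8 is pinned at
γ_k = 0 for the sweep, but its V_k and Σ_k keep updating so a locus can
in principle re-enter. Gauss–Seidel updating in map order means the
update path (not, empirically, the fixed point) depends on marker order;
the order is fixed and not configurable.

Initialisation is β = 0, γ_k = 0, Σ_k = I: starting Σ at zero would lock
every effect at the point-mass prior, whereas unit prior variance lets
the data speak in the first sweep, after which the Σ updates take over.

Evidence per scalar effect is the Wald-type LOD
`(estimate/SE)² / (2 ln 10)` with `SE = √diag(V_k)`. This definition
reproduces the published mouse-analysis LODs (25.69, 17.92, 0.0934) from
the corresponding printed estimate/SE pairs to within their rounding
(≤0.5%). No adjustment is made for the sequential updating, so SEs are
the usual curvature approximation at the mode.

## Multipoint genotype probabilities

Chromosomes are modelled as 3-state Markov chains on
{A1A1, A1A2, A2A2} with the Mendelian 1:2:1 start, transition matrices
built from two independent gamete chains at the Haldane recombination
fraction `r = (1 − e^(−2d/100))/2`. Haldane (no interference) is chosen
because it makes the genotype process along a chromosome exactly Markov.
Pseudo markers are inserted by subdividing every interval longer than
`max_spacing` (default 5 cM) into ⌈L/max_spacing⌉ equal pieces, named
deterministically `<chrom>_<pos with 2 decimals>`. Conditional genotype
probabilities at every position given all observed markers on the
chromosome are computed by the forward–backward algorithm (normalised per
step to avoid underflow); with fully observed flanking markers this
coincides with flanking-marker conditioning. Exactness is verified
against brute-force path enumeration on short chromosomes (≤1e-10).

## Simulator

`simulate` draws F2 genotypes as two independent gamete Markov chains per
chromosome, co-factors from their pre-selection distributions, builds
`y = Xβ + ΣZγ + ε` exactly, and keeps survivors (`y > 0`) by rejection
sampling until the requested count — matching the generative description
of truncation selection rather than truncated-normal shortcuts. A
survival probability below 1e-6 (estimated after 1e6 draws) aborts as an
infeasible regime.

The default design is the replicated study configuration: one 2400 cM
chromosome, 481 markers at 5 cM, six additive loci
(1.4135, −0.9993, 0.9993, −1.2048, 1.0, −1.41354) at
(50, 125, 360, 905, 1750, 2115) cM placed exactly at markers, a ±1 sex
co-factor with β = 1, a continuous N(0, 0.25) co-factor with β = 1, and
500 survivors. The continuous co-factor variance is 0.25 by default
because the design's stated variance proportions (co-factor share 0.0386,
total 0.8455) are consistent only with Var(X) = 0.25; a variance of 0.025
remains available by configuration. True effects are always placed at
marker positions.

What the simulator emulates: Markov recombination along a map, liability
selection, co-factor mixing. What it does not: crossover interference,
genotyping error, gametic (pre-zygotic) distortion, selfing/RIL/backcross
designs, linked-epistatic architectures. Passing tests therefore
demonstrate correct recovery under the model's own assumptions, not
robustness to these real-data complications.

## Evaluation protocol

`null_threshold` simulates unselected (pure Mendelian) populations, fits
the full scan, and takes an empirical quantile (default 95%) of the
genome-wide maximum LOD across all effects — the genome-wide maximum is
used because a single critical value for a whole-genome scan should
control family-wise error. `power_fpr` scores replicated fits: a true
locus is detected if any marker strictly within 15 cM (same chromosome)
exceeds the threshold; at 5 cM spacing the strict boundary makes this the
5-marker window (true marker ±2) whose count underlies the published
false-positive denominator `replicates × (481 − 5×6)`. Any exceedance
outside every window is a false positive; overlapping windows assign
markers to the nearest true locus. Reported per-locus estimates are taken
at the within-window peak-LOD marker.

Problem sizes used by the shipped tests and the acceptance script: the
power study runs 30 replicates of the full default design; the null
behaviour check uses a 600 cM / 121-marker / 300-individual design with a
20-replicate calibration; unit tests use maps of 2–60 markers. These
sizes were chosen so the whole suite completes in a few minutes while
keeping binomial noise on power estimates within a few percent.

## Numerical choices

- Penetrances are clipped to [1e-12, 1 − 1e-12] before logs; a strong
  locus genuinely drives penetrances to ~0 and the objective must stay
  finite.
- Σ_k spectrum floor 1e-10; shrink-out test at 1e-8 on the diagonal.
- Degenerate inputs: a genotype posterior whose three penetrances all sit
  at the clip floor raises an error (the predictor is meaningless there);
  zero map distance gives r = 0 and an exact copy of the neighbouring
  state distribution; a locus with γ = V = 0 yields the floored Σ.
- The inverse-Wishart denominator `(τ+1) + dim + 1` is applied with the
  actual dimension of γ_k (2 with dominance, 1 additive-only).
- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; replicate r of any study uses `seed + r`. Fits themselves are
  deterministic.

## Known limitations

- Standard errors ignore the sequential (coordinate-wise) estimation, so
  LODs near the detection threshold are approximate.
- Estimates are deliberately biased toward zero by the shrinkage prior;
  power is robust to this but effect sizes should be read as conservative.
- Adjacent markers compete for a signal that sits between them; the peak
  may land on a neighbouring marker of the true position (detection
  windows absorb this).
- F2 only in this version; the transition-matrix interface is the
  extension point for backcross/RIL designs.
- The closed-form continuous co-factor normaliser requires the probit
  link and exact normality of the pre-selection covariate distribution.
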