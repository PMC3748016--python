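# sdlmap

Genome-wide mapping of **segregation distortion loci** (SDL) — loci under
viability selection — from genotype-only data in F2-type crosses.

## The problem

In an F2 population the three genotypes A1A1 : A1A2 : A2A2 segregate
1 : 2 : 1. When a locus affects viability, selection removes carriers of
the unfit genotypes before genotyping, so the surviving sample shows
distorted ratios at that locus and at everything linked to it. `sdlmap`
treats fitness as an unobserved **liability**

    y_j = X_j β + Σ_k Z_jk γ_k + ε_j,   ε_j ~ N(0, 1),

where individual *j* survives iff `y_j > 0`. Each marker *k* (true or
pseudo) carries an additive and a dominance effect `γ_k = (a_k, d_k)` on
the liability, coded `Z` per genotype; non-genetic co-factors with known
pre-selection distributions (e.g. sex 1:1, or a normal covariate) enter
through `β`. Survival probability (penetrance) given the linear predictor
η is `Φ(η)` (probit) or the logistic function.

Because only survivors are observed, the post-selection genotype
distribution at locus *k* is, by Bayes' theorem,

    π_j(g) ∝ φ_g · Φ(H_g γ_k + η_j(−k)),

with `φ` the Mendelian prior and `η_j(−k)` the predictor excluding locus
*k*. The product of these multinomial terms over individuals is the
likelihood for `γ_k`. A hierarchical prior `γ_k ~ N(0, Σ_k)`,
`Σ_k ~ Inv-Wishart(τ, ω)` shrinks negligible effects to zero, so the model
can hold several times more effects than individuals (e.g. 933 effects
from 110 mice). Estimation is posterior-mode **Newton–Raphson coordinate
descent**: one Newton step per co-factor and per locus per sweep, then the
conjugate update `Σ_k = (γ_k γ_kᵀ + V_k + ω) / ((τ+1) + dim + 1)`,
repeated to convergence. Evidence is reported per scalar effect as a
Wald-type LOD, `(estimate/SE)² / (2 ln 10)`.

Missing genotypes and pseudo markers (inserted so no map interval exceeds
5 cM) are handled by exact multipoint conditional probabilities from a
3-state Markov chain under the Haldane map function.

The package also ships the matching **viability-selection simulator**
(F2 meiosis, liability construction, truncation selection) and the
evaluation protocol: empirical null-threshold calibration and a
replicated power / false-positive study.

## Worked example

```python
import numpy as np
from sdlmap import SimConfig, SDLScan, simulate_selected_population
from sdlmap import locus_heritability, expected_genotype_freqs

# simulate 500 survivors of selection on one strong locus plus the
# default co-factors (sex beta=1, continuous N(0, 0.25) beta=1)
cfg = SimConfig(n_chromosomes=1, length_cM=300, spacing_cM=5,
                effects=[(50.0, 1.4135, 0.0)], n_survivors=500, seed=3)
genotypes, cofactors, truth = simulate_selected_population(cfg)

scan = SDLScan().fit(genotypes, cofactors=cofactors)   # sklearn-style
lod = scan.lod_.max(axis=1)
k = lod.argmax()
print(f"peak at {k*5} cM  LOD={lod[k]:.2f}  a_hat={scan.additive_[k]:.3f}")
print(f"sex effect beta={scan.beta_[0]:.3f}  LOD={scan.beta_lod_[0]:.2f}")
```

```
peak at 50 cM  LOD=21.54  a_hat=1.127
sex effect beta=1.142  LOD=28.26
```

The scan peaks at the simulated locus (50 cM) with the estimate
shrunk slightly below the true 1.4135 — the expected behaviour of the
zero-centred shrinkage prior — and recovers the sex effect (true β = 1).

Closed-form liability summaries reproduce the published mouse-locus
arithmetic: with the reported estimates â = 4.6230, d̂ = −1.6656,

```python
vg, vp, h = locus_heritability(4.6230, -1.6656)   # VP = 14.460, H = 0.9308
freqs, pibar = expected_genotype_freqs(4.6230, -1.6656)
# pibar = 0.2743, survivor frequencies (0.0014, 0.0873, 0.9113)
```

i.e. a single locus explaining ~93% of the liability variance, with the
A2A2 homozygote at 91% frequency among survivors.

A command-line interface mirrors the library:

```bash
sdlmap simulate --seed 1 --out-dir sim/        # map/genotype/co-factor CSVs
sdlmap fit --map sim/map.csv --genotypes sim/genotypes.csv \
           --cofactors sim/cofactors.csv --out results.csv
sdlmap calibrate --n-replicates 30 --seed 2    # empirical null LOD threshold
sdlmap power --threshold 2.99 --n-replicates 30 --seed 1
```

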