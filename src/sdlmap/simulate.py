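"""F2 viability-selection simulator.

Generates F2 genotypes along a genetic map (two independent gamete Markov
chains per chromosome, Haldane recombination), draws co-factors from
their pre-selection distributions, builds each individual's liability
y = X beta + sum Z gamma + e with e ~ N(0, 1), and keeps only individuals
with y > 0 (rejection sampling) until the requested number of survivors
is reached.  The surviving genotypes show segregation distortion at and
around the simulated viability loci; that distortion is the signal the
GLMM scan recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_map import GeneticMap, GenotypeData, recomb_fraction, uniform_map
from .liability import CofactorSpec, design_matrix


@dataclass
class SimConfig:
    """Study design for one simulated selected population.

    The default design is a single 2400 cM chromosome covered by 481
    markers at 5 cM spacing, six additive viability loci, a +/-1 sex
    co-factor with effect 1 and a N(0, 0.25) continuous co-factor with
    effect 1, and 500 surviving individuals.  ``effects`` entries are
    (position_cM, additive, dominance) with positions on chromosome 1
    unless given as (chromosome, position, a, d).
    """

    n_chromosomes: int = 1
    length_cM: float = 2400.0
    spacing_cM: float = 5.0
    effects: list[tuple] = field(
        default_factory=lambda: [
            (50.0, 1.4135, 0.0),
            (125.0, -0.9993, 0.0),
            (360.0, 0.9993, 0.0),
            (905.0, -1.2048, 0.0),
            (1750.0, 1.0, 0.0),
            (2115.0, -1.41354, 0.0),
        ]
    )
    cofactors: list[CofactorSpec] = field(
        default_factory=lambda: [
            CofactorSpec("sex", "discrete", beta=1.0),
            CofactorSpec("cofactor2", "continuous", mu=0.0, sigma2=0.25, beta=1.0),
        ]
    )
    n_survivors: int = 500
    link: str = "probit"
    seed: int = 0

    def genetic_map(self) -> GeneticMap:
        return uniform_map(self.n_chromosomes, self.length_cM, self.spacing_cM)

    def effect_table(self, gmap: GeneticMap) -> pd.DataFrame:
        """True effects resolved to marker indices of ``gmap``."""
        names = gmap.marker_names
        positions = gmap.positions
        frame = gmap.to_frame()
        rows = []
        for eff in self.effects:
            if len(eff) == 4:
                chrom, pos, a, d = eff
            else:
                pos, a, d = eff
                chrom = next(iter(gmap.chromosomes))
            block = frame[frame["chromosome"].astype(str) == str(chrom)]
            if block.empty:
                raise ValueError(f"effect references unknown chromosome {chrom!r}")
            i = (block["position_cM"] - float(pos)).abs().idxmin()
            if abs(frame.loc[i, "position_cM"] - float(pos)) > 1e-9:
                raise ValueError(f"no marker at position {pos} cM on chromosome {chrom!r}")
            rows.append((int(i), names[i], str(chrom), positions[i], float(a), float(d)))
        return pd.DataFrame(
            rows, columns=["marker_index", "marker", "chromosome", "position_cM", "additive", "dominance"]
        )


def simulate_f2_genotypes(gmap: GeneticMap, n: int, rng) -> np.ndarray:
    """(n, p) genotype codes {0, 1, 2} = number of A2 alleles.

    Each chromosome is two independent gamete chains: the allele at the
    first marker is fair, and flips between adjacent markers with the
    Haldane recombination fraction of the interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = np.empty((n, gmap.n_markers), dtype=int)
    col = 0
    for markers in gmap.chromosomes.values():
        m = len(markers)
        pos = np.array([mk.position for mk in markers])
        r = recomb_fraction(np.diff(pos))
        gametes = np.empty((2, n, m), dtype=int)
        gametes[:, :, 0] = rng.random((2, n)) < 0.5
        for j in range(1, m):
            flip = rng.random((2, n)) < r[j - 1]
            gametes[:, :, j] = gametes[:, :, j - 1] ^ flip
        out[:, col : col + m] = gametes.sum(axis=0)
        col += m
    return out


def _draw_cofactors(cofactors, n, rng):
    cols = []
    for spec in cofactors:
        if spec.kind == "discrete":
            p1 = spec.class_priors[0]
            cols.append(np.where(rng.random(n) < p1, 1.0, -1.0))
        else:
            cols.append(rng.normal(spec.mu, np.sqrt(spec.sigma2), n))
    return np.column_stack(cols) if cols else np.zeros((n, 0))


def simulate_selected_population(config: SimConfig):
    """Simulate survivors of viability selection.

    Returns ``(genotypes, cofactors, truth)``: a :class:`GenotypeData` of
    the survivors, the co-factor specs with the survivors' values filled
    in, and a truth table (one row per survivor) with the liability
    decomposition y = X beta + sum Z gamma + e.  The truth table's attrs
    record the genetic map, true effects and realised acceptance rate.
    """
    rng = np.random.default_rng(config.seed)
    gmap = config.genetic_map()
    effects = config.effect_table(gmap)
    H = design_matrix("additive_dominance")
    gamma = effects[["additive", "dominance"]].to_numpy()
    idx = effects["marker_index"].to_numpy()
    betas = np.array([spec.beta for spec in config.cofactors])

    kept_geno, kept_x, rows = [], [], []
    kept = 0
    drawn = survived = 0
    batch = max(2 * config.n_survivors, 200)
    while kept < config.n_survivors:
        g = simulate_f2_genotypes(gmap, batch, rng)
        x = _draw_cofactors(config.cofactors, batch, rng)
        eps = rng.normal(size=batch)
        z = H[g[:, idx]] if len(idx) else np.zeros((batch, 0, 2))
        genetic = np.einsum("nkd,kd->n", z, gamma) if len(idx) else np.zeros(batch)
        y = x @ betas + genetic + eps
        alive = y > 0
        drawn += batch
        survived += int(alive.sum())
        for sel in np.flatnonzero(alive):
            if kept >= config.n_survivors:
                break
            kept_geno.append(g[sel])
            kept_x.append(x[sel])
            rows.append((y[sel], eps[sel], genetic[sel], float(x[sel] @ betas)))
            kept += 1
        if drawn >= 1_000_000 and survived / drawn < 1e-6:
            raise RuntimeError("infeasible selection regime: survival probability < 1e-6")
        # size the next batch from the running survival-rate estimate
        need = config.n_survivors - kept
        batch = max(int(1.3 * need / max(survived / drawn, 1e-3)), 64)

    codes = np.vstack(kept_geno)
    xvals = np.vstack(kept_x) if kept_x and kept_x[0].size else np.zeros((kept, 0))
    individuals = [f"ind{i}" for i in range(config.n_survivors)]
    genotypes = GenotypeData(individuals, gmap.marker_names, codes=codes)
    cofactors = []
    for c, spec in enumerate(config.cofactors):
        cofactors.append(
            CofactorSpec(spec.name, spec.kind, values=xvals[:, c],
                         class_priors=spec.class_priors, mu=spec.mu,
                         sigma2=spec.sigma2, beta=spec.beta)
        )
    truth = pd.DataFrame(rows, columns=["liability", "residual", "genetic", "cofactor_part"])
    truth.index = individuals
    truth.attrs["map"] = gmap
    truth.attrs["effects"] = effects
    truth.attrs["acceptance_rate"] = survived / drawn
    truth.attrs["seed"] = config.seed
    return genotypes, cofactors, truth


def simulate_null(gmap: GeneticMap, n: int, seed: int,
                  cofactors: list[CofactorSpec] | None = None):
    """Pure Mendelian sampling: no selection, every individual survives.

    Co-factor values (if any) are drawn from their pre-selection
    distributions with zero effect on the liability.
    """
    rng = np.random.default_rng(seed)
    codes = simulate_f2_genotypes(gmap, n, rng)
    genotypes = GenotypeData([f"ind{i}" for i in range(n)], gmap.marker_names, codes=codes)
    specs = []
    if cofactors:
        x = _draw_cofactors(cofactors, n, rng)
        for c, spec in enumerate(cofactors):
            specs.append(
                CofactorSpec(spec.name, spec.kind, values=x[:, c],
                             class_priors=spec.class_priors, mu=spec.mu,
                             sigma2=spec.sigma2, beta=0.0)
            )
    return genotypes, specs
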