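"""Genetic maps, pseudo markers and multipoint genotype probabilities.

An F2 genome is represented as ordered markers per chromosome with
positions in centiMorgans.  Genotypes along a chromosome form a 3-state
Markov chain (A1A1, A1A2, A2A2) under the Haldane map function (no
crossover interference), which lets missing and pseudo markers be imputed
exactly by the forward-backward algorithm conditioned on every observed
marker of the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Mendelian genotype prior in an F2: A1A1 : A1A2 : A2A2 = 1 : 2 : 1.
F2_PRIOR = np.array([0.25, 0.5, 0.25])

#: Integer codes used for genotype classes throughout the package.
A1A1, A1A2, A2A2, MISSING = 0, 1, 2, -1


def recomb_fraction(distance_cM):
    """Haldane recombination fraction for a map distance in cM.

    r = (1 - exp(-2 d / 100)) / 2, in [0, 0.5).
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-0.02 * d))


def f2_transition_matrix(r):
    """F2 genotype transition matrix between adjacent loci.

    The two gametes recombine independently, each with probability ``r``,
    so e.g. P(A1A1 -> A1A1) = (1-r)^2 and the heterozygote row mixes the
    two phases: P(A1A2 -> A1A2) = (1-r)^2 + r^2.
    """
    r = float(r)
    s = 1.0 - r
    return np.array(
        [
            [s * s, 2 * r * s, r * r],
            [r * s, s * s + r * r, r * s],
            [r * r, 2 * r * s, s * s],
        ]
    )


@dataclass(frozen=True)
class Marker:
    name: str
    position: float  # cM, within chromosome
    is_pseudo: bool = False


@dataclass
class GeneticMap:
    """Ordered markers per chromosome with cM positions.

    ``chromosomes`` maps chromosome name -> list of :class:`Marker` with
    strictly increasing positions.  Marker names are unique genome-wide.
    """

    chromosomes: dict[str, list[Marker]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self):
        seen = set()
        for chrom, markers in self.chromosomes.items():
            if not markers:
                raise ValueError(f"chromosome {chrom!r} has no markers")
            pos = [m.position for m in markers]
            if any(p < 0 for p in pos):
                raise ValueError(f"negative position on chromosome {chrom!r}")
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom!r}"
                )
            for m in markers:
                if m.name in seen:
                    raise ValueError(f"duplicate marker name {m.name!r}")
                seen.add(m.name)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneticMap":
        """Build a map from a frame with columns marker, chromosome, position_cM."""
        required = {"marker", "chromosome", "position_cM"}
        if not required.issubset(frame.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        chroms: dict[str, list[Marker]] = {}
        for chrom, block in frame.groupby("chromosome", sort=False):
            block = block.sort_values("position_cM")
            chroms[str(chrom)] = [
                Marker(str(r.marker), float(r.position_cM),
                       bool(getattr(r, "is_pseudo", False)))
                for r in block.itertuples()
            ]
        return cls(chroms)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m.name, chrom, m.position, m.is_pseudo)
            for chrom, markers in self.chromosomes.items()
            for m in markers
        ]
        return pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM", "is_pseudo"])

    @property
    def marker_names(self) -> list[str]:
        return [m.name for ms in self.chromosomes.values() for m in ms]

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position for ms in self.chromosomes.values() for m in ms])

    @property
    def n_markers(self) -> int:
        return sum(len(ms) for ms in self.chromosomes.values())

    def chromosome_slices(self) -> dict[str, slice]:
        """Column slices of each chromosome in genome-wide marker order."""
        out, start = {}, 0
        for chrom, markers in self.chromosomes.items():
            out[chrom] = slice(start, start + len(markers))
            start += len(markers)
        return out


def uniform_map(n_chromosomes: int, length_cM: float, spacing_cM: float) -> GeneticMap:
    """Evenly spaced markers from 0 to ``length_cM`` on each chromosome."""
    n_per = int(round(length_cM / spacing_cM)) + 1
    chroms = {}
    for c in range(1, n_chromosomes + 1):
        chroms[str(c)] = [
            Marker(f"M{c}_{i}", i * spacing_cM) for i in range(n_per)
        ]
    return GeneticMap(chroms)


def insert_pseudo_markers(gmap: GeneticMap, max_spacing: float = 5.0) -> GeneticMap:
    """Subdivide every interval longer than ``max_spacing`` cM.

    An interval of length L > max_spacing is split into ceil(L/max_spacing)
    equal sub-intervals; the new positions are flagged as pseudo markers
    and named ``<chrom>_<position with 2 decimals>`` so the densified map
    is deterministic.  Original markers are untouched.
    """
    if max_spacing <= 0:
        raise ValueError("max_spacing must be positive")
    chroms: dict[str, list[Marker]] = {}
    for chrom, markers in gmap.chromosomes.items():
        dense: list[Marker] = [markers[0]]
        for left, right in zip(markers, markers[1:]):
            length = right.position - left.position
            if length > max_spacing:
                n_sub = int(np.ceil(length / max_spacing))
                step = length / n_sub
                for i in range(1, n_sub):
                    pos = left.position + i * step
                    dense.append(Marker(f"{chrom}_{pos:.2f}", pos, is_pseudo=True))
            dense.append(right)
        chroms[chrom] = dense
    return GeneticMap(chroms)


@dataclass
class GenotypeData:
    """Genotypes of surviving individuals, hard calls or probability triplets.

    ``codes`` is (n_individuals, n_markers) with entries in {0, 1, 2, -1}
    (A1A1, A1A2, A2A2, missing); ``probs`` is (n, p, 3) with each triplet
    summing to 1.  Either may be None; :func:`codes_to_probs` converts a
    hard call to its indicator triplet and a missing call to the prior.
    """

    individuals: list[str]
    marker_names: list[str]
    codes: np.ndarray | None = None
    probs: np.ndarray | None = None

    def __post_init__(self):
        n, p = len(self.individuals), len(self.marker_names)
        if self.codes is not None:
            self.codes = np.asarray(self.codes, dtype=int)
            if self.codes.shape != (n, p):
                raise ValueError("codes shape mismatch")
            bad = ~np.isin(self.codes, (A1A1, A1A2, A2A2, MISSING))
            if bad.any():
                raise ValueError("genotype codes must be in {0,1,2,-1}")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)
            if self.probs.shape != (n, p, 3):
                raise ValueError("probs shape mismatch")
            if np.any(self.probs < 0):
                raise ValueError("genotype probabilities must be non-negative")
            if not np.allclose(self.probs.sum(axis=2), 1.0, atol=1e-9):
                raise ValueError("genotype probability triplets must sum to 1")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


def codes_to_probs(codes: np.ndarray, prior: np.ndarray = F2_PRIOR) -> np.ndarray:
    """Indicator triplets for observed calls, the prior for missing calls."""
    codes = np.asarray(codes, dtype=int)
    probs = np.empty(codes.shape + (3,), dtype=float)
    probs[...] = np.asarray(prior, dtype=float)
    for g in (A1A1, A1A2, A2A2):
        mask = codes == g
        probs[mask] = 0.0
        probs[mask, g] = 1.0
    return probs


def _chain_matrices(positions: np.ndarray) -> list[np.ndarray]:
    return [
        f2_transition_matrix(recomb_fraction(b - a))
        for a, b in zip(positions, positions[1:])
    ]


def multipoint_genotype_probs(
    gmap: GeneticMap,
    genotypes: GenotypeData,
    prior: np.ndarray = F2_PRIOR,
) -> GenotypeData:
    """Conditional genotype probabilities at every marker of the map.

    For each individual and chromosome, runs the forward-backward
    algorithm on the 3-state F2 genotype chain started at the Mendelian
    prior, conditioning on all observed markers of that chromosome.
    Observed markers keep their indicator triplet; missing and pseudo
    markers receive the full multipoint conditional distribution.

    ``genotypes`` holds the observed markers only; its columns must be a
    subset of the map's markers (pseudo markers are never observed).
    """
    prior = np.asarray(prior, dtype=float)
    obs_index = {name: j for j, name in enumerate(genotypes.marker_names)}
    if genotypes.codes is not None:
        obs = codes_to_probs(genotypes.codes, prior)
        # missing calls carry no evidence: emission weight 1 for all states
        obs[genotypes.codes == MISSING] = 1.0
    elif genotypes.probs is not None:
        obs = genotypes.probs
    else:
        raise ValueError("genotype data has neither codes nor probs")

    n = genotypes.n_individuals
    out = np.empty((n, gmap.n_markers, 3), dtype=float)
    col = 0
    for chrom, markers in gmap.chromosomes.items():
        m = len(markers)
        positions = np.array([mk.position for mk in markers])
        trans = _chain_matrices(positions)
        # per-position emission weights (n, m, 3); 1 = uninformative
        emit = np.ones((n, m, 3))
        for j, mk in enumerate(markers):
            if mk.name in obs_index:
                emit[:, j, :] = obs[:, obs_index[mk.name], :]
        fwd = np.empty((n, m, 3))
        bwd = np.empty((n, m, 3))
        fwd[:, 0] = prior * emit[:, 0]
        for j in range(1, m):
            fwd[:, j] = (fwd[:, j - 1] @ trans[j - 1]) * emit[:, j]
            # guard underflow on long chromosomes
            norm = fwd[:, j].sum(axis=1, keepdims=True)
            if np.any(norm <= 0):
                raise ValueError(
                    f"impossible genotype configuration on chromosome {chrom!r}"
                )
            fwd[:, j] /= norm
        bwd[:, m - 1] = 1.0
        for j in range(m - 2, -1, -1):
            bwd[:, j] = (bwd[:, j + 1] * emit[:, j + 1]) @ trans[j].T
            bwd[:, j] /= bwd[:, j].sum(axis=1, keepdims=True)
        post = fwd * bwd
        post /= post.sum(axis=2, keepdims=True)
        out[:, col : col + m] = post
        col += m
    return GenotypeData(
        individuals=list(genotypes.individuals),
        marker_names=gmap.marker_names,
        probs=out,
    )
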