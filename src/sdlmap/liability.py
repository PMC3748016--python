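"""Liability-scale probability machinery.

The liability of individual j is y_j = X_j beta + sum_k Z_jk gamma_k + e_j
with e_j ~ N(0, 1); only individuals with y_j > 0 survive and are
genotyped.  Survival probability (penetrance) given the linear predictor
eta is Phi(eta) under the probit link or the logistic function under the
logit link.  Bayes' theorem then gives the post-selection genotype and
co-factor distributions, whose products over individuals are the
conditional likelihoods optimised by the fitting engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr

from .genome_map import F2_PRIOR

#: Probability clip applied before taking logs; a strong locus drives
#: penetrances numerically to 0 and logs must stay finite.
PROB_FLOOR = 1e-12

#: Genotype design codes: rows of H are (additive, dominance) codes for
#: A1A1, A1A2, A2A2.  The additive code is the centred count of A2
#: alleles (-1, 0, +1), so a positive additive effect favours the A2A2
#: homozygote; the dominance code is -1, +1, -1.  Var(additive code) =
#: 1/2 and Var(dominance code) = 1 under the 1:2:1 F2 ratio.
H_ADD_DOM = np.array([[-1.0, -1.0], [0.0, 1.0], [1.0, -1.0]])
H_ADD = H_ADD_DOM[:, :1]


def design_matrix(effect_model: str) -> np.ndarray:
    """Class-by-effect code matrix for the chosen genetic model."""
    if effect_model == "additive":
        return H_ADD
    if effect_model == "additive_dominance":
        return H_ADD_DOM
    raise ValueError(f"unknown effect model {effect_model!r}")


def design_codes(genotype_class: int, effect_model: str = "additive_dominance") -> np.ndarray:
    """Code vector Z for one genotype class (0=A1A1, 1=A1A2, 2=A2A2)."""
    H = design_matrix(effect_model)
    if genotype_class not in (0, 1, 2):
        raise ValueError(f"unknown genotype class {genotype_class!r}")
    return H[genotype_class].copy()


def penetrance(eta, link: str = "probit"):
    """Survival probability given the liability expectation ``eta``.

    Clipped to [1e-12, 1 - 1e-12] so downstream logs are finite.
    """
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("linear predictor must be finite")
    if link == "probit":
        p = ndtr(eta)
    elif link == "logistic":
        p = expit(eta)
    else:
        raise ValueError(f"unknown link {link!r}")
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


def penetrance_derivatives(eta, link: str = "probit"):
    """(F, f, f') of the penetrance function at ``eta``.

    F is the clipped penetrance, f its density and f' the density's
    derivative; these feed the analytic gradients and Hessians.
    """
    eta = np.asarray(eta, dtype=float)
    F = penetrance(eta, link)
    if link == "probit":
        f = np.exp(-0.5 * eta**2) / np.sqrt(2.0 * np.pi)
        fp = -eta * f
    else:
        s = expit(eta)
        f = s * (1.0 - s)
        fp = f * (1.0 - 2.0 * s)
    return F, f, fp


def genotype_posterior(
    gamma: np.ndarray,
    eta_minus_k,
    prior: np.ndarray = F2_PRIOR,
    link: str = "probit",
    effect_model: str = "additive_dominance",
) -> np.ndarray:
    """Post-selection genotype distribution pi_j at one locus.

    pi_j(g) = prior_g * Phi(H_g gamma + eta_j(-k)) / pibar_j where
    pibar_j, the prior-weighted mean of the three penetrances, is the
    survival probability marginalised over the genotype at this locus.
    With gamma = 0 the posterior is the Mendelian prior for every
    individual.  Supports scalar or vector ``eta_minus_k`` (one row per
    individual).
    """
    H = design_matrix(effect_model)
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if gamma.shape != (H.shape[1],):
        raise ValueError(f"gamma must have dimension {H.shape[1]}")
    eta = np.asarray(eta_minus_k, dtype=float)
    u = eta[..., None] + H @ gamma
    F = penetrance(u, link)
    num = np.asarray(prior, dtype=float) * F
    pibar = num.sum(axis=-1, keepdims=True)
    if np.any(pibar <= 3 * PROB_FLOOR * np.max(prior)):
        raise ValueError("degenerate predictor: all penetrances at the clip floor")
    return num / pibar


def discrete_cofactor_posterior(
    beta: float,
    eta_minus_beta,
    priors=(0.5, 0.5),
    link: str = "probit",
) -> np.ndarray:
    """Post-selection class probabilities (xi1, xi2) of a +/-1 co-factor.

    xi_j(1) = phi1 * Phi(eta_j(-beta) + beta) / xibar_j and symmetrically
    for class 2; with beta = 0 the posterior equals the class priors.
    """
    phi = np.asarray(priors, dtype=float)
    if phi.shape != (2,) or np.any(phi < 0) or not np.isclose(phi.sum(), 1.0):
        raise ValueError("class priors must be two non-negative values summing to 1")
    eta = np.asarray(eta_minus_beta, dtype=float)
    u = np.stack([eta + beta, eta - beta], axis=-1)
    num = phi * penetrance(u, link)
    xibar = num.sum(axis=-1, keepdims=True)
    if np.any(xibar <= 2 * PROB_FLOOR):
        raise ValueError("degenerate predictor: all penetrances at the clip floor")
    return num / xibar


def continuous_cofactor_normalizer(
    beta: float,
    eta_minus_beta,
    mu: float,
    sigma2: float,
    link: str = "probit",
    n_quad: int = 64,
):
    """Survival probability marginalised over a normal co-factor.

    xibar_j = E_X[Phi(X beta + eta_j(-beta))] for X ~ N(mu, sigma2).  For
    the probit link this has the closed form
    Phi((mu beta + eta) / sqrt(sigma2 beta^2 + 1)); the identity is
    specific to the normal CDF, so the logistic link falls back to
    Gauss-Hermite quadrature.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    eta = np.asarray(eta_minus_beta, dtype=float)
    if link == "probit":
        return ndtr((mu * beta + eta) / np.sqrt(sigma2 * beta**2 + 1.0))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    x = mu + np.sqrt(sigma2) * nodes  # Gauss-Hermite nodes for N(mu, sigma2)
    vals = expit(x * beta + eta[..., None])
    return (vals * weights).sum(axis=-1) / weights.sum()


def locus_loglik(w: np.ndarray, pi: np.ndarray) -> float:
    """Multinomial log-likelihood sum_j sum_g w_j(g) ln pi_j(g).

    ``w`` holds indicator triplets for observed genotypes or multipoint
    probability triplets for missing/pseudo markers, in which case the
    value is the expected complete-data log-likelihood under the
    multipoint distribution.
    """
    w = np.asarray(w, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if w.shape != pi.shape:
        raise ValueError("w and pi must be aligned")
    if np.any((pi <= 0) & (w > 0)):
        raise ValueError("zero posterior probability with positive weight")
    out = np.zeros_like(w)
    mask = w > 0
    out[mask] = w[mask] * np.log(pi[mask])
    return float(out.sum())


@dataclass
class CofactorSpec:
    """A non-genetic predictor with its known pre-selection distribution.

    For a discrete co-factor (e.g. sex) values are coded +1/-1 and
    ``class_priors`` gives the pre-selection class frequencies; for a
    continuous one (e.g. age) the pre-selection population is
    N(``mu``, ``sigma2``).  ``beta`` is the true effect when the spec is
    used by the simulator; the fitting engine estimates it from data.
    """

    name: str
    kind: str  # "discrete" | "continuous"
    values: np.ndarray | None = None
    class_priors: tuple[float, float] = (0.5, 0.5)
    mu: float = 0.0
    sigma2: float = 1.0
    beta: float = 0.0

    def __post_init__(self):
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"unknown co-factor kind {self.kind!r}")
        if self.kind == "discrete":
            phi = np.asarray(self.class_priors, dtype=float)
            if not np.isclose(phi.sum(), 1.0) or np.any(phi < 0):
                raise ValueError("class priors must sum to 1")
        elif self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if self.kind == "discrete" and not np.all(np.isin(self.values, (-1.0, 1.0))):
                raise ValueError("discrete co-factor values must be coded +1/-1")

    @property
    def prior_variance(self) -> float:
        """Pre-selection variance of the co-factor value."""
        if self.kind == "continuous":
            return float(self.sigma2)
        p1, p2 = self.class_priors
        mean = p1 - p2
        return float(p1 * (1 - mean) ** 2 + p2 * (-1 - mean) ** 2)


def cofactor_loglik(spec: CofactorSpec, beta: float, eta_minus_beta,
                    link: str = "probit") -> float:
    """Conditional log-likelihood of a co-factor effect.

    Discrete: sum_j [ (X_j+1)/2 ln xi_j(1) + (1-X_j)/2 ln xi_j(2) ].
    Continuous: sum_j [ ln Phi(X_j beta + eta_j(-beta)) - ln xibar_j ].
    """
    if spec.values is None:
        raise ValueError("co-factor has no observed values")
    eta = np.asarray(eta_minus_beta, dtype=float)
    x = spec.values
    if spec.kind == "discrete":
        xi = discrete_cofactor_posterior(beta, eta, spec.class_priors, link)
        return float(
            np.sum(0.5 * (x + 1) * np.log(xi[..., 0]) + 0.5 * (1 - x) * np.log(xi[..., 1]))
        )
    num = penetrance(x * beta + eta, link)
    xibar = np.clip(
        continuous_cofactor_normalizer(beta, eta, spec.mu, spec.sigma2, link),
        PROB_FLOOR,
        1.0,
    )
    return float(np.sum(np.log(num) - np.log(xibar)))
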