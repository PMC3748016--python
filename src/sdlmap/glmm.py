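"""Posterior-mode GLMM for genome-wide viability-locus scans.

Every marker (true or pseudo) enters the model simultaneously: the
liability is y_j = X_j beta + sum_k Z_jk gamma_k + e_j, each locus effect
gamma_k carries a zero-mean normal prior N(0, Sigma_k), and each Sigma_k
an inverse-Wishart hyper-prior.  Estimation is coordinate descent: one
Newton-Raphson step per co-factor and per locus per sweep, then the
conjugate update of every Sigma_k, repeated to convergence.  The
data-driven Sigma_k shrink negligible effects to zero, which is what lets
the model hold several times more effects than individuals.

Evidence per scalar effect is reported as a Wald-type LOD score,
(estimate / SE)^2 / (2 ln 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import liability as lia
from .genome_map import F2_PRIOR, GeneticMap, GenotypeData, codes_to_probs, multipoint_genotype_probs

LN10_2 = 2.0 * np.log(10.0)

# --------------------------------------------------------------------------
# class-weighted multinomial objective: shared by loci and discrete
# co-factors (a +/-1 co-factor is a 2-class "locus" with codes +1/-1)
# --------------------------------------------------------------------------


def _class_loglik(w, phi, F, logF):
    """sum_j sum_g w_jg ln[phi_g F_jg / pibar_j] given precomputed F."""
    pibar = F @ phi
    return float(np.sum(w * (np.log(phi) + logF)) - np.log(pibar).sum())


def class_objective(gamma, w, phi, H, eta_minus, link="probit", sigma_inv=None):
    """Log-posterior of one class-coded effect block (prior optional)."""
    u = eta_minus[:, None] + H @ gamma
    F = lia.penetrance(u, link)
    val = _class_loglik(w, phi, F, np.log(F))
    if sigma_inv is not None:
        dim = len(gamma)
        sign, logdet = np.linalg.slogdet(sigma_inv)
        val += 0.5 * (logdet - dim * np.log(2 * np.pi)) - 0.5 * gamma @ sigma_inv @ gamma
    return val


def class_grad_hess(gamma, w, phi, H, eta_minus, link="probit", sigma_inv=None):
    """Analytic gradient and Hessian of :func:`class_objective`.

    With u_jg = H_g gamma + eta_j(-k), F = penetrance, f = F', the score
    splits into a data term weighted by w and a normalisation term
    weighted by the prior-penetrance mix phi_g f_jg / pibar_j.
    """
    u = eta_minus[:, None] + H @ gamma
    F, f, fp = lia.penetrance_derivatives(u, link)
    pibar = F @ phi
    ratio = f / F
    c = w * ratio - (phi * f) / pibar[:, None]
    grad = c.sum(axis=0) @ H
    a = w * (fp / F - ratio**2) - (phi * fp) / pibar[:, None]
    hess = (H.T * a.sum(axis=0)) @ H
    b = (phi * f) @ H / pibar[:, None]
    hess += b.T @ b
    if sigma_inv is not None:
        grad = grad - sigma_inv @ gamma
        hess = hess - sigma_inv
    return grad, hess


def _neg_def_inverse(hess, ridge0=1e-6, max_doublings=60):
    """Invert -hess, adding a doubling ridge until positive definite."""
    A = -hess
    lam = 0.0
    for _ in range(max_doublings):
        try:
            L = np.linalg.cholesky(A + lam * np.eye(A.shape[0]))
            Linv = np.linalg.inv(L)
            return Linv.T @ Linv
        except np.linalg.LinAlgError:
            lam = ridge0 if lam == 0.0 else 2.0 * lam
    raise np.linalg.LinAlgError("Hessian could not be regularised to negative definite")


def newton_update_locus(
    gamma,
    w,
    phi,
    H,
    eta_minus,
    sigma,
    link="probit",
    max_halvings=10,
):
    """One safeguarded Newton-Raphson step on a locus log-posterior.

    Returns (gamma_new, V) where V = [-d2 LogPost/dgamma dgamma^T]^{-1}
    evaluated at the incoming gamma.  If the proposed step decreases the
    log-posterior it is halved (up to ``max_halvings`` times).
    """
    sigma_inv = np.linalg.inv(sigma) if sigma is not None else None
    grad, hess = class_grad_hess(gamma, w, phi, H, eta_minus, link, sigma_inv)
    if not (np.all(np.isfinite(grad)) and np.all(np.isfinite(hess))):
        raise FloatingPointError("non-finite derivatives in locus update")
    V = _neg_def_inverse(hess)
    step = V @ grad
    if float(np.abs(step).max()) < 1e-12:
        return gamma.copy(), V
    obj0 = class_objective(gamma, w, phi, H, eta_minus, link, sigma_inv)
    for _ in range(max_halvings + 1):
        cand = gamma + step
        if class_objective(cand, w, phi, H, eta_minus, link, sigma_inv) >= obj0 - 1e-10:
            return cand, V
        step = 0.5 * step
    return gamma.copy(), V


def update_sigma(gamma, V, tau=0.0, omega=0.0):
    """Conjugate posterior-mode update of a locus prior variance matrix.

    Sigma = (gamma gamma^T + V + omega) / ((tau+1) + dim + 1), the mode of
    the inverse-Wishart posterior with E(gamma gamma^T) taken from the
    current normal approximation.  Diagonal floored at 1e-10 so a fully
    shrunk locus keeps a proper (point-mass-like) prior.
    """
    gamma = np.atleast_1d(gamma)
    dim = gamma.shape[0]
    V = np.atleast_2d(V)
    omega = np.asarray(omega, dtype=float)
    if omega.ndim == 0:
        omega = float(omega) * np.eye(dim)
    sigma = (np.outer(gamma, gamma) + V + omega) / ((tau + 1.0) + dim + 1.0)
    sigma = 0.5 * (sigma + sigma.T)
    # keep the prior proper: floor the spectrum, not just the diagonal
    vals, vecs = np.linalg.eigh(sigma)
    return (vecs * np.maximum(vals, 1e-10)) @ vecs.T


# --------------------------------------------------------------------------
# co-factor updates
# --------------------------------------------------------------------------

_H_DISCRETE = np.array([[1.0], [-1.0]])


def update_beta(spec: lia.CofactorSpec, beta, eta_minus, link="probit"):
    """One Newton step on a co-factor likelihood (uniform prior on beta).

    Returns (beta_new, var_beta) with var(beta) = -[d2 L/dbeta^2]^{-1}
    at the incoming beta.
    """
    if spec.kind == "discrete":
        x = spec.values
        w = np.stack([0.5 * (x + 1), 0.5 * (1 - x)], axis=1)
        phi = np.asarray(spec.class_priors, dtype=float)
        g = np.array([beta])
        g_new, V = newton_update_locus(g, w, phi, _H_DISCRETE, eta_minus, None, link)
        return float(g_new[0]), float(V[0, 0])
    if link == "probit":
        grad, hess = _continuous_beta_derivs(spec, beta, eta_minus)
    else:
        grad, hess = _fd_beta_derivs(spec, beta, eta_minus, link)
    if not (np.isfinite(grad) and np.isfinite(hess)):
        raise FloatingPointError("non-finite derivatives in co-factor update")
    obj0 = lia.cofactor_loglik(spec, beta, eta_minus, link)
    var = 1.0 / max(-hess, 1e-12)
    step = var * grad
    for _ in range(11):
        cand = beta + step
        if lia.cofactor_loglik(spec, cand, eta_minus, link) >= obj0 - 1e-10:
            return float(cand), float(var)
        step = 0.5 * step
    return float(beta), float(var)


def _continuous_beta_derivs(spec, beta, eta_minus):
    """Analytic d L/d beta and d2 L/d beta2 for a normal co-factor, probit link.

    L = sum_j ln Phi(x_j beta + eta_j) - ln Phi(s_j),
    s_j = (mu beta + eta_j) / sqrt(sigma2 beta^2 + 1).
    """
    x, mu, s2 = spec.values, spec.mu, spec.sigma2
    u = x * beta + eta_minus
    F, f, fp = lia.penetrance_derivatives(u)
    r = f / F
    rp = fp / F - r**2
    q = s2 * beta**2 + 1.0
    s = (mu * beta + eta_minus) / np.sqrt(q)
    Fs, fs, fps = lia.penetrance_derivatives(s)
    rs = fs / Fs
    rsp = fps / Fs - rs**2
    sp = (mu - eta_minus * s2 * beta) * q**-1.5
    spp = -eta_minus * s2 * q**-1.5 - 3.0 * s2 * beta * (mu - eta_minus * s2 * beta) * q**-2.5
    grad = np.sum(x * r - rs * sp)
    hess = np.sum(x**2 * rp - (rsp * sp**2 + rs * spp))
    return float(grad), float(hess)


def _fd_beta_derivs(spec, beta, eta_minus, link, h=1e-5):
    lp = lia.cofactor_loglik(spec, beta + h, eta_minus, link)
    lm = lia.cofactor_loglik(spec, beta - h, eta_minus, link)
    l0 = lia.cofactor_loglik(spec, beta, eta_minus, link)
    return (lp - lm) / (2 * h), (lp - 2 * l0 + lm) / h**2


def lod_scores(estimates, variances):
    """Wald-based LOD per scalar effect: (estimate/SE)^2 / (2 ln 10)."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if np.any(var <= 0):
        raise ValueError("variances must be positive")
    return est**2 / var / LN10_2


# --------------------------------------------------------------------------
# the coordinate-descent engine
# --------------------------------------------------------------------------


@dataclass
class FitResult:
    """Converged genome-scan estimates.

    ``gamma`` is (p, dim) with columns (additive[, dominance]); ``se`` and
    ``lod`` match its shape.  Co-factor estimates are parallel lists.
    """

    marker_names: list[str]
    gamma: np.ndarray
    se: np.ndarray
    lod: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    cofactor_names: list[str]
    beta: np.ndarray
    beta_se: np.ndarray
    beta_lod: np.ndarray
    eta: np.ndarray
    n_sweeps: int
    converged: bool
    max_change: float
    trace: list[float] = field(default_factory=list)
    chromosome: list[str] | None = None
    position_cM: np.ndarray | None = None

    @property
    def effect_names(self):
        return ["additive", "dominance"][: self.gamma.shape[1]]

    def to_frame(self) -> pd.DataFrame:
        """Per-marker results table, co-factors appended as extra rows."""
        cols = {}
        cols["marker"] = list(self.marker_names)
        cols["chromosome"] = list(self.chromosome) if self.chromosome else [""] * len(self.marker_names)
        cols["position_cM"] = (
            self.position_cM if self.position_cM is not None else np.full(len(self.marker_names), np.nan)
        )
        cols["additive"] = self.gamma[:, 0]
        cols["add_se"] = self.se[:, 0]
        cols["add_lod"] = self.lod[:, 0]
        if self.gamma.shape[1] > 1:
            cols["dominance"] = self.gamma[:, 1]
            cols["dom_se"] = self.se[:, 1]
            cols["dom_lod"] = self.lod[:, 1]
        frame = pd.DataFrame(cols)
        if self.cofactor_names:
            rows = pd.DataFrame(
                {
                    "marker": [f"cofactor:{n}" for n in self.cofactor_names],
                    "chromosome": "",
                    "position_cM": np.nan,
                    "additive": self.beta,
                    "add_se": self.beta_se,
                    "add_lod": self.beta_lod,
                }
            )
            frame = pd.concat([frame, rows], ignore_index=True)
        return frame


def fit_engine(
    w: np.ndarray,
    cofactors: list[lia.CofactorSpec] | None = None,
    *,
    effect_model: str = "additive_dominance",
    link: str = "probit",
    prior: np.ndarray = F2_PRIOR,
    tau: float = 0.0,
    omega: float = 0.0,
    tol: float = 1e-6,
    max_sweeps: int = 200,
    shrink_tol: float = 1e-8,
    marker_names: list[str] | None = None,
) -> FitResult:
    """Coordinate-descent posterior-mode fit over all loci and co-factors.

    ``w`` is the (n, p, 3) genotype weight array: indicator triplets for
    observed genotypes, multipoint conditional probabilities for missing
    and pseudo markers.  One sweep updates every co-factor (Newton step on
    its likelihood), every locus effect in map order (Newton step on its
    log-posterior, Gauss-Seidel: the linear predictor always reflects the
    latest values), then every Sigma_k; sweeps repeat until the largest
    parameter change drops below ``tol``.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 3 or w.shape[2] != 3:
        raise ValueError("w must be (n_individuals, n_markers, 3)")
    n, p, _ = w.shape
    if p < 1 or n < 2:
        raise ValueError("need at least 1 marker and 2 individuals")
    cofactors = list(cofactors or [])
    for spec in cofactors:
        if spec.values is None or len(spec.values) != n:
            raise ValueError(f"co-factor {spec.name!r} values missing or misaligned")
    phi = np.asarray(prior, dtype=float)
    H = lia.design_matrix(effect_model)
    dim = H.shape[1]
    zbar = w @ H  # expected design codes, used to maintain eta

    beta = np.zeros(len(cofactors))
    var_beta = np.ones(len(cofactors))
    gamma = np.zeros((p, dim))
    sigma = np.tile(np.eye(dim), (p, 1, 1))
    V = np.tile(np.eye(dim), (p, 1, 1))
    eta = np.zeros(n)

    trace: list[float] = []
    converged = False
    sweep = 0
    for sweep in range(1, max_sweeps + 1):
        delta = 0.0
        # step 1: non-genetic effects
        for c, spec in enumerate(cofactors):
            eta_minus = eta - spec.values * beta[c]
            b_new, var_c = update_beta(spec, beta[c], eta_minus, link)
            delta = max(delta, abs(b_new - beta[c]))
            beta[c] = b_new
            var_beta[c] = var_c
            eta = eta_minus + spec.values * b_new
        # step 2: locus effects, Gauss-Seidel in map order
        for k in range(p):
            eta_minus = eta - zbar[:, k] @ gamma[k]
            if np.all(np.diag(sigma[k]) < shrink_tol):
                # shrunk out this sweep: effect pinned at 0, variance from
                # the prior-dominated Hessian so Sigma keeps updating
                g_new = np.zeros(dim)
                _, hess = class_grad_hess(
                    g_new, w[:, k], phi, H, eta_minus, link, np.linalg.inv(sigma[k])
                )
                V[k] = _neg_def_inverse(hess)
            else:
                g_new, V[k] = newton_update_locus(
                    gamma[k], w[:, k], phi, H, eta_minus, sigma[k], link
                )
            delta = max(delta, float(np.abs(g_new - gamma[k]).max()))
            gamma[k] = g_new
            eta = eta_minus + zbar[:, k] @ g_new
        # step 3: prior variance matrices
        for k in range(p):
            s_new = update_sigma(gamma[k], V[k], tau, omega)
            delta = max(delta, float(np.abs(s_new - sigma[k]).max()))
            sigma[k] = s_new
        trace.append(delta)
        if delta < tol:
            converged = True
            break

    se = np.sqrt(np.maximum(np.stack([np.diag(V[k]) for k in range(p)]), 1e-300))
    lod = lod_scores(gamma, se**2)
    beta_se = np.sqrt(np.maximum(var_beta, 1e-300))
    beta_lod = lod_scores(beta, var_beta) if len(cofactors) else np.zeros(0)
    return FitResult(
        marker_names=list(marker_names) if marker_names is not None else [f"m{k}" for k in range(p)],
        gamma=gamma,
        se=se,
        lod=lod,
        sigma=sigma,
        V=V,
        cofactor_names=[s.name for s in cofactors],
        beta=beta,
        beta_se=beta_se,
        beta_lod=beta_lod,
        eta=eta,
        n_sweeps=sweep,
        converged=converged,
        max_change=trace[-1] if trace else np.nan,
        trace=trace,
    )


# --------------------------------------------------------------------------
# sklearn-style estimator
# --------------------------------------------------------------------------


class SDLScan(BaseEstimator):
    """Genome-wide segregation-distortion locus scan.

    Fits the hierarchical liability GLMM to the genotypes of surviving
    individuals of an F2-type cross and exposes per-marker additive (and
    optionally dominance) effects, standard errors and LOD scores.

    Parameters
    ----------
    effect_model : {"additive_dominance", "additive"}
        Whether each locus carries (a_k, d_k) or only a_k.
    link : {"probit", "logistic"}
        Penetrance function on the liability scale.
    tau, omega : float
        Inverse-Wishart hyper-prior degrees of freedom and scale; the
        default (0, 0) is the Jeffreys prior for the variance components.
    mendelian_prior : tuple of 3 floats
        Pre-selection genotype frequencies (F2 default 1:2:1).
    tol, max_sweeps : float, int
        Coordinate-descent stopping rule: largest absolute parameter
        change below ``tol`` or ``max_sweeps`` reached.

    Attributes
    ----------
    additive_, dominance_ : (p,) arrays of effect estimates
    se_, lod_ : (p, dim) arrays aligned with ``gamma_``
    beta_, beta_se_, beta_lod_ : co-factor estimates
    results_ : tidy per-marker DataFrame
    """

    def __init__(
        self,
        effect_model="additive_dominance",
        link="probit",
        tau=0.0,
        omega=0.0,
        mendelian_prior=(0.25, 0.5, 0.25),
        tol=1e-6,
        max_sweeps=200,
        shrink_tol=1e-8,
    ):
        self.effect_model = effect_model
        self.link = link
        self.tau = tau
        self.omega = omega
        self.mendelian_prior = mendelian_prior
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.shrink_tol = shrink_tol

    def fit(self, X, y=None, *, genetic_map: GeneticMap | None = None,
            cofactors: list[lia.CofactorSpec] | None = None,
            marker_names: list[str] | None = None):
        """Fit the scan.

        ``X`` may be an (n, p) integer genotype matrix with codes
        {0, 1, 2, -1=missing}, an (n, p, 3) probability array, or a
        :class:`GenotypeData`.  When ``genetic_map`` is given, missing and
        pseudo-marker genotypes are first replaced by their multipoint
        conditional probabilities.
        """
        prior = np.asarray(self.mendelian_prior, dtype=float)
        chrom = positions = None
        if isinstance(X, GenotypeData):
            gdata = X
        else:
            X = np.asarray(X)
            if X.ndim == 2:
                names = list(marker_names) if marker_names is not None else [
                    f"m{k}" for k in range(X.shape[1])
                ]
                gdata = GenotypeData([str(i) for i in range(X.shape[0])], names, codes=X.astype(int))
            elif X.ndim == 3:
                names = list(marker_names) if marker_names is not None else [
                    f"m{k}" for k in range(X.shape[1])
                ]
                gdata = GenotypeData([str(i) for i in range(X.shape[0])], names, probs=X)
            else:
                raise ValueError("X must be 2-D codes or 3-D probabilities")
        if genetic_map is not None:
            gdata = multipoint_genotype_probs(genetic_map, gdata, prior)
            frame = genetic_map.to_frame()
            chrom = frame["chromosome"].astype(str).tolist()
            positions = frame["position_cM"].to_numpy()
        w = gdata.probs if gdata.probs is not None else codes_to_probs(gdata.codes, prior)
        result = fit_engine(
            w,
            cofactors,
            effect_model=self.effect_model,
            link=self.link,
            prior=prior,
            tau=self.tau,
            omega=self.omega,
            tol=self.tol,
            max_sweeps=self.max_sweeps,
            shrink_tol=self.shrink_tol,
            marker_names=gdata.marker_names,
        )
        result.chromosome = chrom
        result.position_cM = positions
        self.result_ = result
        self.marker_names_ = result.marker_names
        self.gamma_ = result.gamma
        self.additive_ = result.gamma[:, 0]
        self.dominance_ = result.gamma[:, 1] if result.gamma.shape[1] > 1 else None
        self.se_ = result.se
        self.lod_ = result.lod
        self.sigma_ = result.sigma
        self.beta_ = result.beta
        self.beta_se_ = result.beta_se
        self.beta_lod_ = result.beta_lod
        self.n_sweeps_ = result.n_sweeps
        self.converged_ = result.converged
        self.results_ = result.to_frame()
        return self


def fit_scan(X, genetic_map=None, cofactors=None, **params) -> FitResult:
    """Functional wrapper over :class:`SDLScan`; returns the FitResult."""
    return SDLScan(**params).fit(X, genetic_map=genetic_map, cofactors=cofactors).result_
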