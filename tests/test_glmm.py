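import numpy as np
import pytest

from sdlmap import SDLScan, fit_scan, lod_scores
from sdlmap.genome_map import F2_PRIOR, uniform_map
from sdlmap.glmm import (
    class_grad_hess,
    class_objective,
    newton_update_locus,
    update_beta,
    update_sigma,
)
from sdlmap.liability import H_ADD_DOM, CofactorSpec, cofactor_loglik
from sdlmap.simulate import simulate_null


def finite_diff(fun, x, h=1e-5):
    """Central-difference gradient and Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    d = len(x)
    grad = np.empty(d)
    hess = np.empty((d, d))
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        grad[i] = (fun(x + e) - fun(x - e)) / (2 * h)
        hess[i, i] = (fun(x + e) - 2 * fun(x) + fun(x - e)) / h**2
        for j in range(i):
            ej = np.zeros(d)
            ej[j] = h
            hess[i, j] = hess[j, i] = (
                fun(x + e + ej) - fun(x + e - ej) - fun(x - e + ej) + fun(x - e - ej)
            ) / (4 * h**2)
    return grad, hess


def random_instance(rng, n=40, link="probit", with_prior=True):
    w = rng.dirichlet(np.ones(3), size=n)
    eta = rng.normal(scale=0.8, size=n)
    gamma = rng.normal(scale=0.7, size=2)
    sigma_inv = None
    if with_prior:
        A = rng.normal(size=(2, 2))
        sigma_inv = A @ A.T + 0.5 * np.eye(2)
    return gamma, w, F2_PRIOR, H_ADD_DOM, eta, link, sigma_inv


class TestDerivatives:
    @pytest.mark.parametrize("link", ["probit", "logistic"])
    @pytest.mark.parametrize("with_prior", [True, False])
    def test_locus_grad_hess_match_finite_differences(self, link, with_prior):
        rng = np.random.default_rng(42)
        for _ in range(5):
            gamma, w, phi, H, eta, link_, si = random_instance(rng, link=link, with_prior=with_prior)
            grad, hess = class_grad_hess(gamma, w, phi, H, eta, link_, si)
            fd_g, fd_h = finite_diff(
                lambda g: class_objective(g, w, phi, H, eta, link_, si), gamma
            )
            assert np.allclose(grad, fd_g, rtol=1e-4, atol=1e-6)
            assert np.allclose(hess, fd_h, rtol=1e-4, atol=1e-4)

    def test_continuous_cofactor_derivs_match_finite_differences(self):
        from sdlmap.glmm import _continuous_beta_derivs

        rng = np.random.default_rng(7)
        for _ in range(5):
            spec = CofactorSpec(
                "age", "continuous", values=rng.normal(0.3, 0.9, 30), mu=0.3, sigma2=0.81
            )
            eta = rng.normal(scale=0.6, size=30)
            beta = rng.normal(scale=0.8)
            grad, hess = _continuous_beta_derivs(spec, beta, eta)
            h = 1e-5
            f = lambda b: cofactor_loglik(spec, b, eta)
            fd_g = (f(beta + h) - f(beta - h)) / (2 * h)
            fd_h = (f(beta + h) - 2 * f(beta) + f(beta - h)) / h**2
            assert grad == pytest.approx(fd_g, rel=1e-4)
            assert hess == pytest.approx(fd_h, rel=1e-3)


class TestNewtonUpdate:
    def test_fixed_point_at_interior_maximum(self):
        rng = np.random.default_rng(3)
        gamma, w, phi, H, eta, link, si = random_instance(rng)
        # walk to the maximum first
        for _ in range(50):
            gamma, _ = newton_update_locus(gamma, w, phi, H, eta, np.linalg.inv(si), link)
        g2, _ = newton_update_locus(gamma, w, phi, H, eta, np.linalg.inv(si), link)
        assert np.allclose(g2, gamma, atol=1e-8)
        grad, _ = class_grad_hess(gamma, w, phi, H, eta, link, si)
        assert np.abs(grad).max() < 1e-6

    def test_objective_never_decreases_along_accepted_steps(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            gamma, w, phi, H, eta, link, si = random_instance(rng)
            sigma = np.linalg.inv(si)
            obj0 = class_objective(gamma, w, phi, H, eta, link, si)
            g1, _ = newton_update_locus(gamma, w, phi, H, eta, sigma, link)
            obj1 = class_objective(g1, w, phi, H, eta, link, si)
            assert obj1 >= obj0 - 1e-9

    def test_conjugate_normal_mode_recovered(self):
        # with an uninformative data term (w = prior-shaped posterior at
        # gamma=0), the posterior mode under a tight prior stays at 0
        n = 30
        w = np.tile(F2_PRIOR, (n, 1))
        sigma = 1e-4 * np.eye(2)
        g1, V = newton_update_locus(np.array([0.3, -0.2]), w, F2_PRIOR, H_ADD_DOM,
                                    np.zeros(n), sigma)
        assert np.abs(g1).max() < 0.02
        assert np.all(np.diag(V) <= 1e-4 + 1e-6)


class TestSigmaUpdate:
    def test_printed_denominator_dim2(self):
        gamma = np.array([1.0, -0.5])
        V = np.array([[0.2, 0.05], [0.05, 0.1]])
        s = update_sigma(gamma, V)
        assert np.allclose(s, (np.outer(gamma, gamma) + V) / 4.0)

    def test_same_formula_dim1(self):
        s = update_sigma(np.array([2.0]), np.array([[0.5]]))
        assert s[0, 0] == pytest.approx((4.0 + 0.5) / 3.0)

    def test_degenerate_floors_to_point_mass(self):
        s = update_sigma(np.zeros(2), np.zeros((2, 2)))
        assert np.allclose(np.diag(s), 1e-10)
        assert np.all(np.linalg.eigvalsh(s) >= 1e-10 - 1e-16)

    def test_prior_scale_and_dof(self):
        s = update_sigma(np.zeros(1), np.array([[0.3]]), tau=2.0, omega=0.6)
        assert s[0, 0] == pytest.approx((0.3 + 0.6) / (3.0 + 1.0 + 1.0))


class TestBetaUpdate:
    def test_balanced_discrete_null_goes_to_zero(self):
        x = np.array([1.0, -1.0] * 25)
        spec = CofactorSpec("sex", "discrete", values=x)
        beta = 0.8
        for _ in range(30):
            beta, var = update_beta(spec, beta, np.zeros(50))
        assert abs(beta) < 1e-6
        assert var > 0

    def test_sex_effect_recovered_within_3se(self, small_selected):
        genotypes, cofactors, truth = small_selected
        res = fit_scan(genotypes, cofactors=cofactors)
        assert res.beta[0] == pytest.approx(1.0, abs=3 * res.beta_se[0])


class TestLod:
    def test_zero_estimate(self):
        assert lod_scores([0.0], [1.0])[0] == 0.0

    def test_mouse_printed_values(self):
        # the printed estimate/SE are rounded to 4 d.p., hence 0.5% slack
        add = lod_scores([4.6230], [0.4248**2])[0]
        assert add == pytest.approx(25.69, rel=5e-3)
        dom = lod_scores([-1.6656], [0.1833**2])[0]
        assert dom == pytest.approx(17.92, rel=5e-3)
        sex = lod_scores([0.1969], [0.3002**2])[0]
        assert round(sex, 4) == 0.0934

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            lod_scores([1.0], [0.0])


class TestFit:
    def test_single_locus_recovery(self, small_selected):
        genotypes, cofactors, truth = small_selected
        res = fit_scan(genotypes, cofactors=cofactors)
        assert res.converged
        lod = res.lod.max(axis=1)
        k_true = truth.attrs["effects"].marker_index.iloc[0]
        k_peak = int(lod.argmax())
        assert abs(k_peak - k_true) <= 1  # at or adjacent to the true marker
        a_hat = res.gamma[k_peak, 0]
        assert np.sign(a_hat) == np.sign(truth.attrs["effects"].additive.iloc[0])
        # shrunken estimate: below the truth but well away from zero
        assert 0.3 < a_hat <= 1.4135 + 3 * res.se[k_peak, 0]

    def test_null_data_shrinks_everything(self):
        gmap = uniform_map(1, 200.0, 5.0)
        genotypes, _ = simulate_null(gmap, 200, seed=5)
        res = fit_scan(genotypes)
        assert np.abs(res.gamma).max() < 0.2
        assert res.lod.max() < 3.0

    def test_individual_permutation_invariance(self, small_selected):
        genotypes, cofactors, truth = small_selected
        res = fit_scan(genotypes, cofactors=cofactors)
        rng = np.random.default_rng(0)
        perm = rng.permutation(genotypes.n_individuals)
        from sdlmap.genome_map import GenotypeData

        gperm = GenotypeData(
            [genotypes.individuals[i] for i in perm],
            genotypes.marker_names,
            codes=genotypes.codes[perm],
        )
        cperm = [
            CofactorSpec(c.name, c.kind, values=c.values[perm],
                         class_priors=c.class_priors, mu=c.mu, sigma2=c.sigma2)
            for c in cofactors
        ]
        res2 = fit_scan(gperm, cofactors=cperm)
        assert np.allclose(res2.gamma, res.gamma, atol=1e-8)
        assert np.allclose(res2.beta, res.beta, atol=1e-8)

    def test_determinism(self, small_selected):
        genotypes, cofactors, _ = small_selected
        r1 = fit_scan(genotypes, cofactors=cofactors)
        r2 = fit_scan(genotypes, cofactors=cofactors)
        assert np.array_equal(r1.gamma, r2.gamma)
        assert np.array_equal(r1.lod, r2.lod)
        assert r1.n_sweeps == r2.n_sweeps

    def test_stationarity_of_active_loci(self, small_selected):
        genotypes, cofactors, _ = small_selected
        res = fit_scan(genotypes, cofactors=cofactors)
        from sdlmap.genome_map import codes_to_probs

        w = codes_to_probs(genotypes.codes)
        zbar = w @ H_ADD_DOM
        eta = res.eta
        for k in range(res.gamma.shape[0]):
            if np.all(np.diag(res.sigma[k]) < 1e-8):
                continue
            eta_minus = eta - zbar[:, k] @ res.gamma[k]
            grad, hess = class_grad_hess(
                res.gamma[k], w[:, k], F2_PRIOR, H_ADD_DOM, eta_minus,
                "probit", np.linalg.inv(res.sigma[k]),
            )
            # Newton displacement is the curvature-scaled stationarity measure;
            # the raw gradient is only meaningful when the prior is not tight
            step = np.linalg.solve(-hess, grad)
            assert np.abs(step).max() < 1e-5
            if np.linalg.eigvalsh(res.sigma[k]).min() > 1e-4:
                assert np.abs(grad).max() < 1e-4

    def test_grid_search_oracle_at_convergence(self, small_selected):
        # the converged estimate maximises its own single-locus posterior
        genotypes, cofactors, _ = small_selected
        res = fit_scan(genotypes, cofactors=cofactors)
        from sdlmap.genome_map import codes_to_probs

        w = codes_to_probs(genotypes.codes)
        zbar = w @ H_ADD_DOM
        k = int(res.lod.max(axis=1).argmax())
        eta_minus = res.eta - zbar[:, k] @ res.gamma[k]
        si = np.linalg.inv(res.sigma[k])
        grid = np.linspace(-0.2, 0.2, 41)
        best = max(
            ((da, dd) for da in grid for dd in grid),
            key=lambda s: class_objective(
                res.gamma[k] + np.array(s), w[:, k], F2_PRIOR, H_ADD_DOM,
                eta_minus, "probit", si,
            ),
        )
        assert np.abs(np.array(best)).max() <= 0.011  # within grid resolution

    def test_additive_only_model(self, small_selected):
        genotypes, cofactors, truth = small_selected
        res = fit_scan(genotypes, cofactors=cofactors, effect_model="additive")
        assert res.gamma.shape[1] == 1
        k_true = truth.attrs["effects"].marker_index.iloc[0]
        assert abs(int(res.lod[:, 0].argmax()) - k_true) <= 1

    def test_estimator_sklearn_interface(self, small_selected):
        genotypes, cofactors, _ = small_selected
        scan = SDLScan(tol=1e-4, max_sweeps=50)
        params = scan.get_params()
        assert params["tol"] == 1e-4
        scan.set_params(max_sweeps=60).fit(genotypes, cofactors=cofactors)
        assert scan.results_.shape[0] == len(genotypes.marker_names) + len(cofactors)
        assert (scan.se_ > 0).all()
        assert (scan.lod_ >= 0).all()

    def test_non_convergence_flagged_not_raised(self, small_selected):
        genotypes, cofactors, _ = small_selected
        res = fit_scan(genotypes, cofactors=cofactors, max_sweeps=2)
        assert res.converged is False
        assert res.n_sweeps == 2
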