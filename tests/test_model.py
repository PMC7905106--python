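import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from manowave.cross import PhaseGrid
from manowave.design import build_design_matrices
from manowave.kernels import add_jitter, logse_gram, periodic_gram
from manowave.model import (GPFunctionalMixedModel, ModelSpec,
                            _LogPosterior, fit_hmc, kron_inv,
                            log_likelihood, log_likelihood_2d,
                            structured_covariance)
from manowave.simulate import TrueEffects, simulate_responses
from manowave.wavelet import FrequencyGrid

rng = np.random.default_rng(7)


def dense_logpdf(Y, Eta, Omega, C):
    return sum(
        multivariate_normal.logpdf(
            Y[i], Eta[i], np.diag(Omega[i]) @ C @ np.diag(Omega[i]))
        for i in range(Y.shape[0]))


class TestStructuredLikelihood:
    def test_diagonal_limit_reduces_to_independent_gaussians(self):
        K, N = 5, 4
        Y = rng.normal(size=(N, K))
        Eta = rng.normal(size=(N, K))
        Om = np.ones((N, K))
        se = 2.0
        C = 1e-30 * np.eye(K) + se ** 2 * np.eye(K)
        ll = log_likelihood(Y, Eta, Om, C)
        iid = np.sum(-0.5 * ((Y - Eta) / se) ** 2
                     - 0.5 * np.log(2 * np.pi * se ** 2))
        assert np.isclose(ll, iid)

    def test_matches_dense_oracle_1d(self):
        K, N = 6, 3
        freqs = np.geomspace(0.001, 0.25, K)
        C = structured_covariance(freqs, 0.7, 0.4, 0.3)
        Y = rng.normal(size=(N, K))
        Eta = rng.normal(size=(N, K))
        Om = np.exp(0.3 * rng.normal(size=(N, K)))
        assert abs(log_likelihood(Y, Eta, Om, C)
                   - dense_logpdf(Y, Eta, Om, C)) < 1e-8

    def test_matches_dense_oracle_2d(self):
        kf, kh, N = 4, 3, 3
        f = np.geomspace(0.002, 0.2, kf)
        phi = np.linspace(-np.pi, np.pi, kh, endpoint=False)
        KF = add_jitter(logse_gram(f, 0.8, 0.5), 0.8)
        KH = periodic_gram(phi, 0.9)
        se = 0.25
        Y = rng.normal(size=(N, kf * kh))
        Eta = rng.normal(size=(N, kf * kh))
        Om = np.exp(0.2 * rng.normal(size=(N, kf * kh)))
        Cd = np.kron(KF, KH) + se ** 2 * np.eye(kf * kh)
        eig = log_likelihood_2d(Y, Eta, Om, KF, KH, se)
        assert abs(eig - dense_logpdf(Y, Eta, Om, Cd)) < 1e-8
        # eigen path equals the Cholesky path on the assembled matrix
        assert abs(eig - log_likelihood(Y, Eta, Om, Cd)) < 1e-8

    def test_non_pd_covariance_reports_eigenvalue(self):
        C = -np.eye(3)
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            log_likelihood(np.zeros((1, 3)), np.zeros((1, 3)),
                           np.ones((1, 3)), C)

    def test_kronecker_inverse_identity(self):
        A = add_jitter(logse_gram(np.geomspace(0.001, 0.2, 8), 1.1, 0.6),
                       1.1)
        B = periodic_gram(np.linspace(-np.pi, np.pi, 8, endpoint=False),
                          0.7) + 1e-8 * np.eye(8)
        direct = np.linalg.inv(np.kron(A, B))
        assert np.allclose(kron_inv(A, B), direct, atol=1e-10)


class TestLogPosterior:
    def make_post(self, small_dm, is_2d=False):
        if is_2d:
            spec = ModelSpec(fgrid=FrequencyGrid.from_band(n=4),
                             pgrid=PhaseGrid(5))
            Y = rng.normal(size=(20, 20))
        else:
            spec = ModelSpec(fgrid=FrequencyGrid.from_band(n=7))
            Y = rng.normal(size=(20, 7))
        return _LogPosterior(spec, small_dm, Y, 0.0)

    @pytest.mark.parametrize("is_2d", [False, True])
    def test_gradient_matches_finite_differences(self, small_dm, is_2d):
        post = self.make_post(small_dm, is_2d)
        th = np.random.default_rng(3).normal(size=post.layout.size) * 0.3
        lp, g = post.logp_grad(th)
        assert np.isfinite(lp)
        eps = 1e-6
        idx = np.random.default_rng(4).choice(post.layout.size, 30,
                                              replace=False)
        for i in idx:
            tp, tm = th.copy(), th.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (post.logp_grad(tp)[0] - post.logp_grad(tm)[0]) / (2 * eps)
            assert abs(fd - g[i]) / (1 + abs(fd)) < 1e-5

    def test_lambda_sigma_constraint_in_decode(self, small_dm):
        post = self.make_post(small_dm)
        for seed in range(20):
            th = np.random.default_rng(seed).normal(
                size=post.layout.size) * 1.5
            _, _, _, hy = post.decode(th)
            pool = np.concatenate([hy["lam_beta"].ravel(),
                                   hy["lam_gamma"].ravel(),
                                   hy["lam_b"].ravel()])
            assert hy["lam_sigma"].max() < pool.min()

    def test_nonfinite_point_returns_neg_inf(self, small_dm):
        post = self.make_post(small_dm)
        th = np.full(post.layout.size, 60.0)  # exp overflow territory
        lp, g = post.logp_grad(th)
        assert lp == -np.inf
        assert np.all(g == 0.0)

    def test_exchangeability_of_observations(self, small_obs):
        # permuting observation rows leaves the log posterior unchanged
        perm = np.random.default_rng(5).permutation(len(small_obs))
        dm1 = build_design_matrices(small_obs, "group*meal + (1|subject)",
                                    "1")
        obs2 = small_obs.iloc[perm].reset_index(drop=True)
        dm2 = build_design_matrices(obs2, "group*meal + (1|subject)", "1")
        fg = FrequencyGrid.from_band(n=5)
        Y = rng.normal(size=(20, 5))
        spec = ModelSpec(fgrid=fg, offset="zero")
        p1 = _LogPosterior(spec, dm1, Y, 0.0)
        p2 = _LogPosterior(spec, dm2, Y[perm], 0.0)
        th = np.random.default_rng(6).normal(size=p1.layout.size) * 0.3
        # subject blocks keep first-appearance order; rebuild matching
        # permutation of the subject latents
        subj_perm = [dm1.groups.index(s) for s in dm2.groups]
        th2 = th.copy()
        sl = p1.layout.slices["b_til"]
        npts = p1.n_points
        b = th[sl].reshape(len(dm1.groups), -1)
        th2[sl] = b[subj_perm].ravel()
        assert np.isclose(p1.logp_grad(th)[0], p2.logp_grad(th2)[0])


class TestSimulateResponses:
    def test_noiseless_limit_returns_eta(self, small_dm, grid9):
        K = 9
        truth = TrueEffects(beta=rng.normal(size=(4, K)),
                            gamma=np.zeros((1, K)),
                            sigma_b=np.zeros((1, 1)),
                            tau_sigma=1e-9, lambda_sigma=0.3,
                            sigma_eps=1e-12)
        Y, lat = simulate_responses(small_dm.X, small_dm.Z, small_dm.W,
                                    grid9.centers, truth, seed=0,
                                    return_latent=True)
        assert np.allclose(Y, lat["eta"], atol=1e-4)

    def test_seeded_reproducibility(self, small_dm, grid9):
        truth = TrueEffects(beta=rng.normal(size=(4, 9)),
                            gamma=np.zeros((1, 9)),
                            sigma_b=np.array([[0.04]]))
        Y1 = simulate_responses(small_dm.X, small_dm.Z, small_dm.W,
                                grid9.centers, truth, seed=5)
        Y2 = simulate_responses(small_dm.X, small_dm.Z, small_dm.W,
                                grid9.centers, truth, seed=5)
        assert np.array_equal(Y1, Y2)

    def test_gamma_column_scales_residual_sd(self, grid9):
        # doubling a gamma column shifts the log residual sd linearly in
        # the predictor
        obs = pd.DataFrame([
            {"subject": f"s{i}", "group": "healthy", "meal": "preprandial",
             "nchan": 24} for i in range(4)])
        dm = build_design_matrices(obs, "1", "1")
        K = 9
        beta = np.zeros((1, K))
        reps = 3000
        sds = []
        for gval in (0.0, 0.7):
            truth = TrueEffects(beta=beta, gamma=np.full((1, K), gval),
                                sigma_b=np.zeros((1, 1)), tau_sigma=0.3,
                                lambda_sigma=0.3, sigma_eps=0.2)
            Ys = np.stack([
                simulate_responses(dm.X, dm.Z, dm.W, grid9.centers, truth,
                                   seed=s)
                for s in range(reps // 4)])
            sds.append(np.log(Ys.std()))
        assert abs((sds[1] - sds[0]) - 0.7) < 0.05

    def test_standardized_residual_covariance_matches_model(self, grid9):
        obs = pd.DataFrame([
            {"subject": f"s{i}", "group": "healthy", "meal": "preprandial",
             "nchan": 24} for i in range(4)])
        dm = build_design_matrices(obs, "1", "1")
        K = grid9.n_bins
        truth = TrueEffects(beta=np.zeros((1, K)),
                            gamma=np.full((1, K), 0.3),
                            sigma_b=np.zeros((1, 1)), tau_sigma=0.4,
                            lambda_sigma=0.35, sigma_eps=0.15)
        n_rep = 500  # 4 obs x 500 reps = 2000 curves
        resid = []
        C = None
        for s in range(n_rep):
            Y, lat = simulate_responses(dm.X, dm.Z, dm.W, grid9.centers,
                                        truth, seed=1000 + s,
                                        return_latent=True)
            resid.append((Y - lat["eta"]) / lat["omega"])
            C = lat["C"]
        R = np.concatenate(resid, axis=0)
        emp = R.T @ R / R.shape[0]
        n = R.shape[0]
        mc_se = np.sqrt((np.outer(np.diag(C), np.diag(C)) + C ** 2) / n)
        assert np.all(np.abs(emp - C) <= 3.0 * mc_se)


class Test2DFitSmoke:
    def test_small_2d_fit_runs_and_respects_constraints(self):
        rng2 = np.random.default_rng(8)
        obs = pd.DataFrame([
            {"subject": f"s{i}", "group": "healthy" if i < 3 else
             "patient", "meal": "preprandial", "nchan": 24}
            for i in range(6)])
        dm = build_design_matrices(obs, "group", "0")
        spec = ModelSpec(fgrid=FrequencyGrid.from_band(n=3),
                         pgrid=PhaseGrid(4))
        Y = rng2.normal(size=(6, 12)) * 0.5
        post = fit_hmc(spec, dm, Y, chains=1, warmup=80, iters=80, seed=4,
                       max_treedepth=5)
        assert post.n_draws == 80
        assert post.beta.shape == (80, 2, 12)
        # 2D hyperparameters present and constraints hold per draw
        assert "rho" in post.hyper
        assert np.all((post.hyper["rho"] > 0) & (post.hyper["rho"] < 1))
        lam_sigma = post.hyper["lam_sigma"]       # (draws, 2)
        lam_beta = post.hyper["lam_beta"]         # (draws, P, 2)
        for d in range(0, 80, 16):
            assert lam_sigma[d, 0] < lam_beta[d, :, 0].min()
            assert lam_sigma[d, 1] < lam_beta[d, :, 1].min()


class TestPriorPredictive:
    def test_prior_only_beta_marginal_sd(self):
        # prior-only sampling: marginal sd of beta_p(x) is the tau prior's
        # root second moment, sqrt(E tau^2) = sqrt(6) for Gamma(2,1)
        obs = pd.DataFrame([{"subject": "s0", "group": "healthy",
                             "meal": "preprandial", "nchan": 24},
                            {"subject": "s1", "group": "healthy",
                             "meal": "preprandial", "nchan": 24}])
        dm = build_design_matrices(obs, "1", "0")
        fg = FrequencyGrid.from_band(n=5)
        post = fit_hmc(ModelSpec(fgrid=fg), dm, np.zeros((2, 5)),
                       chains=2, warmup=200, iters=400, seed=3,
                       max_treedepth=6, prior_only=True)
        sd = post.beta[:, 0, :].std()
        assert abs(sd - np.sqrt(6.0)) / np.sqrt(6.0) < 0.2


class TestEstimatorInterface:
    def test_get_set_params(self):
        est = GPFunctionalMixedModel(chains=2)
        p = est.get_params()
        assert p["chains"] == 2 and p["adapt_delta"] == 0.9
        est.set_params(warmup=10)
        assert est.warmup == 10
        with pytest.raises(ValueError):
            est.set_params(nope=3)

    def test_response_shape_validation(self, small_dm):
        spec = ModelSpec(fgrid=FrequencyGrid.from_band(n=5))
        with pytest.raises(ValueError, match="points"):
            fit_hmc(spec, small_dm, np.zeros((20, 7)), chains=1, warmup=5,
                    iters=5)
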