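import numpy as np
import pandas as pd
import pytest

from manowave.design import build_design_matrices, fixed_row
from manowave.kernels import (KernelSpec, add_jitter, gram_2d, kernel_2d,
                              kernel_logse, kernel_periodic, logse_gram,
                              periodic_gram)
from manowave.simulate import make_obs_table


class TestLogSEKernel:
    def test_equal_frequencies_give_tau_squared(self):
        assert np.isclose(kernel_logse(0.05, 0.05, tau=1.7), 1.7 ** 2)

    def test_long_distance_limit_zero(self):
        assert kernel_logse(1e-6, 1e6, tau=1.0, lam=0.3) < 1e-30

    def test_e_fold_distance(self):
        f = 0.04
        assert np.isclose(kernel_logse(f, np.e * f, tau=1.0, lam=1.0),
                          np.exp(-0.5))

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            kernel_logse(-0.1, 0.1)
        with pytest.raises(ValueError):
            kernel_logse(0.1, 0.0)

    def test_symmetry_and_psd(self):
        f = np.geomspace(1e-3, 0.3, 40)
        K = add_jitter(logse_gram(f, 1.3, 0.7), 1.3)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K)[0] > 0


class TestPeriodicKernel:
    def test_two_pi_periodicity(self):
        phi = 0.7
        for mult in (1, 2, -3):
            assert np.isclose(kernel_periodic(phi, phi + 2 * np.pi * mult,
                                              0.8),
                              kernel_periodic(phi, phi, 0.8))

    def test_psd_on_phase_grid(self):
        phi = np.linspace(-np.pi, np.pi, 36, endpoint=False)
        K = periodic_gram(phi, 0.6) + 1e-10 * np.eye(36)
        assert np.linalg.eigvalsh(K)[0] > 0


class Test2DKernel:
    def test_separability(self):
        f, f2, p, p2 = 0.02, 0.07, 0.3, -1.2
        k = kernel_2d(f, p, f2, p2, tau=1.4, lam_f=0.5, lam_phi=0.9)
        assert np.isclose(
            k, kernel_logse(f, f2, 1.4, 0.5)
            * kernel_periodic(p, p2, 0.9))

    def test_kronecker_equals_dense_evaluation(self):
        f = np.geomspace(0.002, 0.2, 8)
        phi = np.linspace(-np.pi, np.pi, 6, endpoint=False)
        Kk = gram_2d(f, phi, tau=1.2, lam_f=0.6, lam_phi=0.8)
        ff, pp = np.meshgrid(f, phi, indexing="ij")
        x1 = np.stack([ff.ravel(), pp.ravel()])
        dense = np.empty((48, 48))
        for i in range(48):
            for j in range(48):
                dense[i, j] = kernel_2d(x1[0, i], x1[1, i], x1[0, j],
                                        x1[1, j], 1.2, 0.6, 0.8)
        assert np.allclose(Kk, dense, atol=1e-12)

    def test_kernel_spec_validation(self):
        with pytest.raises(ValueError):
            KernelSpec(kind="matern")
        with pytest.raises(ValueError):
            KernelSpec(kind="logse_periodic")  # missing lambda_phi
        ks = KernelSpec(kind="logse", tau=2.0, correlation_only=True)
        assert ks.tau == 1.0  # correlation kernels pin tau


class TestDesignMatrices:
    def test_full_factorial_shapes(self):
        obs = make_obs_table(11, 12, seed=0)
        dm = build_design_matrices(obs)
        assert dm.X.shape == (92, 8)
        assert dm.Z.shape == (92, 92)     # 4 effects x 23 subjects
        assert dm.W.shape == (92, 9)
        assert dm.U.shape == (92, 0)
        assert dm.effects_per_group == 4

    def test_single_row_intercept(self):
        obs = pd.DataFrame([{"subject": "a", "group": "healthy",
                             "region": "descending", "meal": "preprandial",
                             "nchan": 30}])
        dm = build_design_matrices(obs, "1", "1")
        assert dm.X.shape == (1, 1)
        assert dm.X[0, 0] == 1.0

    def test_meal_rows_differ_only_in_meal_columns(self):
        obs = make_obs_table(2, 2, seed=0)
        dm = build_design_matrices(obs)
        a = obs.index[(obs.subject == "h00") & (obs.region == "descending")
                      & (obs.meal == "preprandial")][0]
        b = obs.index[(obs.subject == "h00") & (obs.region == "descending")
                      & (obs.meal == "postprandial")][0]
        diff = dm.X[a] != dm.X[b]
        meal_cols = [i for i, lab in enumerate(dm.x_labels)
                     if "meal" in lab]
        assert set(np.flatnonzero(diff)) <= set(meal_cols)
        assert diff.any()

    def test_reference_levels(self):
        obs = make_obs_table(2, 2, seed=0)
        dm = build_design_matrices(obs)
        ref = fixed_row(dm, group="healthy", region="descending",
                        meal="preprandial")
        assert ref[0] == 1.0 and np.all(ref[1:] == 0.0)

    def test_nchan_standardized(self):
        obs = make_obs_table(3, 3, seed=1)
        dm = build_design_matrices(obs)
        col = dm.w_labels.index("nchan")
        assert abs(dm.W[:, col].mean()) < 1e-12
        assert np.isclose(dm.W[:, col].std(), 1.0)

    def test_z_block_structure(self):
        obs = make_obs_table(2, 2, seed=0)
        dm = build_design_matrices(obs)
        E = dm.effects_per_group
        for i, subj in enumerate(obs["subject"].astype(str)):
            j = dm.groups.index(subj)
            row = dm.Z[i]
            outside = np.delete(row, np.s_[j * E:(j + 1) * E])
            assert np.all(outside == 0.0)
            assert row[j * E] == 1.0  # within-subject intercept

    def test_missing_column_named_in_error(self):
        obs = make_obs_table(2, 2, seed=0).drop(columns=["nchan"])
        with pytest.raises(ValueError, match="nchan"):
            build_design_matrices(obs)

    def test_unknown_level_rejected_in_cell_row(self):
        obs = make_obs_table(2, 2, seed=0)
        dm = build_design_matrices(obs)
        with pytest.raises(ValueError, match="sideways"):
            fixed_row(dm, group="healthy", region="sideways",
                      meal="preprandial")
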