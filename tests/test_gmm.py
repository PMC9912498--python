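"""Robust shared-component mixture fitting."""

import numpy as np
import pandas as pd
import pytest

from sampleqc.core import CellQCTable
from sampleqc.gmm import (
    FitConfig,
    GroupFit,
    initialize_fit,
    compute_responsibilities,
    update_sample_shifts,
    fit_sampleqc,
    trim_consistency_factor,
)
from conftest import make_table


def _two_sample_table(rng, shift=(1.0, 0.0, 0.0), n=400):
    a = rng.standard_normal((n, 3)) * 0.3
    b = rng.standard_normal((n, 3)) * 0.3 + np.asarray(shift)
    return make_table(np.vstack([a, b]), sample_ids=["a"] * n + ["b"] * n)


class TestInitialization:
    def test_k1_respects_centering_constraints(self):
        rng = np.random.default_rng(0)
        tab = _two_sample_table(rng)
        fit = initialize_fit(tab, FitConfig(K=1, seed=0))
        np.testing.assert_allclose(fit.beta_k, 0.0, atol=1e-12)
        # n_j-weighted mean of alpha_j is zero
        np.testing.assert_allclose(fit.alpha_j.mean(axis=0), 0.0, atol=1e-10)
        # samples shifted by (1,0,0): alpha_j ~ +/- (0.5, 0, 0)
        assert fit.alpha_j[1, 0] - fit.alpha_j[0, 0] == pytest.approx(1.0, abs=0.1)

    def test_separated_blobs_found(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.standard_normal((500, 2)) * 0.2,
             rng.standard_normal((500, 2)) * 0.2 + 3.0]
        )
        fit = initialize_fit(make_table(X), FitConfig(K=2, seed=0))
        centers = np.sort(fit.alpha_0 + fit.beta_k, axis=0)
        assert np.abs(centers[0] - 0.0).max() < 0.1
        assert np.abs(centers[1] - 3.0).max() < 0.1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        tab = _two_sample_table(rng)
        f1 = initialize_fit(tab, FitConfig(K=2, seed=5))
        f2 = initialize_fit(tab, FitConfig(K=2, seed=5))
        np.testing.assert_array_equal(f1.beta_k, f2.beta_k)
        np.testing.assert_array_equal(f1.Sigma_k, f2.Sigma_k)

    def test_too_few_cells_raises(self):
        tab = make_table(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="too few cells"):
            initialize_fit(tab, FitConfig(K=3))


class TestResponsibilities:
    def _fit(self, p):
        return GroupFit(
            metric_names=["x", "y"], sample_ids=["s0"],
            alpha_0=np.zeros(2), alpha_j=np.zeros((1, 2)),
            beta_k=np.array([[-1.0, 0.0], [1.0, 0.0]]),
            Sigma_k=np.stack([np.eye(2)] * 2),
            p_jk=np.array([p]),
        )

    def test_equidistant_point_splits_evenly(self):
        tab = make_table(np.array([[0.0, 0.0]]))
        gamma = compute_responsibilities(tab, self._fit([0.5, 0.5]))
        np.testing.assert_allclose(gamma, [[0.5, 0.5]], atol=1e-12)

    def test_degenerate_proportions_dominate(self):
        tab = make_table(np.array([[5.0, 2.0]]))
        gamma = compute_responsibilities(tab, self._fit([1.0, 0.0]))
        np.testing.assert_allclose(gamma, [[1.0, 0.0]], atol=1e-300)

    def test_single_component_all_ones(self):
        fit = GroupFit(
            metric_names=["x"], sample_ids=["s0"],
            alpha_0=np.zeros(1), alpha_j=np.zeros((1, 1)),
            beta_k=np.zeros((1, 1)), Sigma_k=np.ones((1, 1, 1)),
            p_jk=np.ones((1, 1)),
        )
        tab = make_table(np.array([[0.3], [9.9]]))
        np.testing.assert_array_equal(compute_responsibilities(tab, fit), [[1.0], [1.0]])

    def test_rows_sum_to_one(self, small_experiment):
        obs, _ = small_experiment
        fit = initialize_fit(obs, FitConfig(K=3, seed=0))
        gamma = compute_responsibilities(obs, fit)
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


class TestRobustEstimation:
    def test_contamination_resistance(self):
        # 10% gross outliers at distance 100: robust center stays near 0 and
        # the covariance near identity, while the plain MLE center is dragged
        rng = np.random.default_rng(11)
        direction = rng.standard_normal(2)
        direction /= np.linalg.norm(direction)
        X = np.vstack(
            [rng.standard_normal((4500, 2)), 100 * direction + rng.standard_normal((500, 2))]
        )
        tab = make_table(X)
        robust = fit_sampleqc(tab, FitConfig(K=1, seed=1))
        center = robust.alpha_0 + robust.beta_k[0]
        assert np.abs(center).max() < 0.1
        assert np.abs(robust.Sigma_k[0] - np.eye(2)).max() < 0.15
        mle = fit_sampleqc(tab, FitConfig(K=1, robust=False, seed=1))
        assert np.linalg.norm(mle.alpha_0 + mle.beta_k[0]) > 5.0

    def test_clean_data_covariance_consistent(self):
        rng = np.random.default_rng(5)
        tab = make_table(rng.standard_normal((10_000, 2)))
        fit = fit_sampleqc(tab, FitConfig(K=1, seed=2))
        assert np.abs(fit.Sigma_k[0] - np.eye(2)).max() < 0.05

    def test_consistency_factor_exceeds_one(self):
        assert trim_consistency_factor(0.1, 3) > 1.0
        assert trim_consistency_factor(0.0, 3) == 1.0

    def test_identical_points_do_not_crash(self):
        tab = make_table(np.zeros((200, 2)))
        fit = fit_sampleqc(tab, FitConfig(K=1, seed=0, max_iter=5))
        assert np.all(np.isfinite(fit.Sigma_k))
        assert np.linalg.eigvalsh(fit.Sigma_k[0]).min() > 0


class TestSampleShifts:
    def test_two_shifted_samples_hand_case(self):
        rng = np.random.default_rng(3)
        tab = _two_sample_table(rng, shift=(1.0, 0.0, 0.0), n=2000)
        fit = fit_sampleqc(tab, FitConfig(K=1, seed=0))
        assert fit.alpha_j[0, 0] == pytest.approx(-0.5, abs=0.05)
        assert fit.alpha_j[1, 0] == pytest.approx(+0.5, abs=0.05)

    def test_identical_samples_zero_shifts(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((1200, 2)) * 0.3
        tab = make_table(X, sample_ids=np.repeat(["a", "b", "c"], 400))
        fit = fit_sampleqc(tab, FitConfig(K=1, seed=0))
        assert np.abs(fit.alpha_j).max() < 0.05

    def test_weighted_mean_constraint_enforced(self, small_experiment):
        obs, _ = small_experiment
        fit = fit_sampleqc(obs, FitConfig(K=3, seed=0))
        n_j = obs.data.groupby("sample_id", sort=False).size().to_numpy()
        scale = np.abs(fit.alpha_j).max() + 1.0
        np.testing.assert_allclose(
            (n_j[:, None] * fit.alpha_j).sum(axis=0) / n_j.sum(), 0.0,
            atol=1e-8 * scale,
        )


class TestFitSampleQC:
    def test_mle_objective_monotone(self):
        rng = np.random.default_rng(6)
        X = np.vstack(
            [rng.standard_normal((600, 2)) * 0.5,
             rng.standard_normal((600, 2)) * 0.5 + 2.5]
        )
        ids = np.tile(np.repeat(["a", "b"], 300), 2)
        tab = make_table(X, sample_ids=ids)
        fit = fit_sampleqc(tab, FitConfig(K=2, robust=False, seed=0))
        trace = np.array(fit.objective_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_reparameterization_leaves_responsibilities_unchanged(self, small_experiment):
        obs, _ = small_experiment
        fit = fit_sampleqc(obs, FitConfig(K=2, seed=0, max_iter=30))
        gamma = compute_responsibilities(obs, fit)
        v = np.array([0.7, -0.3, 1.1])
        fit.alpha_0 = fit.alpha_0 + v
        fit.beta_k = fit.beta_k - v
        np.testing.assert_allclose(
            compute_responsibilities(obs, fit), gamma, atol=1e-9
        )

    def test_global_shift_equivariance(self):
        rng = np.random.default_rng(7)
        X = np.vstack(
            [rng.standard_normal((500, 2)) * 0.4,
             rng.standard_normal((500, 2)) * 0.4 + 2.0]
        )
        ids = np.tile(np.repeat(["a", "b"], 250), 2)
        tab1 = make_table(X, sample_ids=ids)
        v = np.array([10.0, -4.0])
        tab2 = make_table(X + v, sample_ids=ids)
        f1 = fit_sampleqc(tab1, FitConfig(K=2, seed=3))
        f2 = fit_sampleqc(tab2, FitConfig(K=2, seed=3))
        np.testing.assert_allclose(f2.alpha_0 - f1.alpha_0, v, atol=1e-6)
        np.testing.assert_allclose(f2.beta_k, f1.beta_k, atol=1e-6)
        np.testing.assert_allclose(f2.alpha_j, f1.alpha_j, atol=1e-6)
        np.testing.assert_allclose(f2.Sigma_k, f1.Sigma_k, atol=1e-6)
        np.testing.assert_allclose(f2.p_jk, f1.p_jk, atol=1e-6)

    def test_overspecified_k_warns(self):
        rng = np.random.default_rng(8)
        tab = make_table(rng.standard_normal((3000, 2)) * 0.3)
        with pytest.warns(UserWarning):
            fit = fit_sampleqc(tab, FitConfig(K=4, seed=0, max_iter=50))
        w = fit.responsibilities.mean(axis=0)
        assert (not fit.converged) or w.min() < 0.01

    def test_components_sorted_and_rows_stochastic(self, small_experiment):
        obs, _ = small_experiment
        fit = fit_sampleqc(obs, FitConfig(K=3, seed=1))
        assert np.all(np.diff(fit.beta_k[:, 0]) >= 0)
        np.testing.assert_allclose(fit.p_jk.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-9)

    def test_json_roundtrip(self, small_experiment, tmp_path):
        obs, _ = small_experiment
        fit = fit_sampleqc(obs, FitConfig(K=2, seed=0, max_iter=20))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = GroupFit.from_json(path)
        np.testing.assert_allclose(back.beta_k, fit.beta_k)
        np.testing.assert_allclose(back.Sigma_k, fit.Sigma_k)
        assert back.sample_ids == fit.sample_ids


class TestParameterRecovery:
    def test_recovery_matches_simulation_truth(self, small_experiment):
        from scipy.optimize import linear_sum_assignment
        from scipy.spatial.distance import cdist

        obs, truth = small_experiment
        fit = fit_sampleqc(obs, FitConfig(K=3, seed=42))
        n_j = truth.cells.groupby("sample_id", sort=False).size().to_numpy().astype(float)
        w_true = np.bincount(truth.cells.component, minlength=3).astype(float)

        def recenter(a0, aj, b, n_j, w):
            wj = n_j / n_j.sum()
            ab = wj @ aj
            wk = w / w.sum()
            bb = wk @ b
            return a0 + ab + bb, aj - ab, b - bb

        a_true = np.vstack([s.alpha_j + s.p_jk @ s.delta_jk for s in truth.samples])
        _, ajt, bt = recenter(truth.expt.mu_g[0].copy(), a_true,
                              truth.expt.beta_k.copy(), n_j, w_true)
        row, col = linear_sum_assignment(cdist(fit.beta_k, bt))
        _, ajf, bf = recenter(fit.alpha_0.copy(), fit.alpha_j.copy(),
                              fit.beta_k.copy(), n_j, w_true[col])
        p_t = np.vstack([s.p_jk for s in truth.samples])
        assert np.abs(bf[row] - bt[col]).max() < 0.1
        assert np.abs(ajf - ajt).max() < 0.1  # 800 cells/sample: looser than at 2000
        assert np.abs(fit.p_jk[:, row] - p_t[:, col]).max() < 0.1
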