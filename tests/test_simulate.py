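"""Hierarchical QC-metric simulator."""

import numpy as np
import pytest

from sampleqc.core import logit_smoothed
from sampleqc.simulate import (
    SimConfig,
    draw_expt_level,
    draw_group_level,
    draw_sample_level,
    draw_cell_qcs,
    perturb_outlier,
    simulate_qcs,
)


class TestExptLevel:
    def test_single_component_centered_at_zero(self):
        expt = draw_expt_level(1000, 1, 1, seed=0)
        np.testing.assert_array_equal(expt.beta_k, 0.0)

    def test_covariances_are_spd(self):
        expt = draw_expt_level(1000, 2, 4, seed=1)
        for S in expt.Sigma_k:
            assert np.linalg.eigvalsh(S).min() > 0

    def test_offsets_separated_within_band(self):
        from scipy.spatial.distance import pdist

        for seed in range(3):
            expt = draw_expt_level(1000, 1, 3, seed=seed)
            d = pdist(expt.beta_k)
            assert d.min() >= 1.0 - 1e-9 and d.max() <= 3.0 + 1e-9

    def test_same_seed_reproduces(self):
        a = draw_expt_level(1000, 2, 3, seed=7)
        b = draw_expt_level(1000, 2, 3, seed=7)
        np.testing.assert_array_equal(a.beta_k, b.beta_k)
        np.testing.assert_array_equal(a.Sigma_k, b.Sigma_k)
        np.testing.assert_array_equal(a.mu_g, b.mu_g)


class TestGroupLevel:
    def test_two_groups_two_components_admissible_subsets(self):
        expt = draw_expt_level(1000, 2, 2, seed=0)
        admissible = {(0,), (1,), (0, 1)}
        for seed in range(10):
            groups = draw_group_level(expt, seed=seed)
            subs = [g.components for g in groups]
            assert len(set(subs)) == 2
            assert all(s in admissible for s in subs)

    def test_cell_counts_sum_exactly(self):
        expt = draw_expt_level(12_345, 3, 3, seed=1)
        groups = draw_group_level(expt, seed=1)
        assert sum(g.n_cells for g in groups) == 12_345

    def test_pigeonhole_error(self):
        expt = draw_expt_level(1000, 4, 2, seed=0)
        with pytest.raises(ValueError, match="distinct"):
            draw_group_level(expt, seed=0)

    def test_explicit_subsets_respected(self):
        cfg = SimConfig(n_groups=2, K=3, component_subsets=[(0,), (1, 2)])
        expt = draw_expt_level(1000, 2, 3, seed=0, config=cfg)
        groups = draw_group_level(expt, seed=0, config=cfg)
        assert [g.components for g in groups] == [(0,), (1, 2)]


class TestSampleLevel:
    def test_outlier_proportion_unbiased(self):
        # law of large numbers on p_out_j ~ Beta(p0*theta, (1-p0)*theta)
        expt = draw_expt_level(1000, 1, 2, seed=0)
        cfg = SimConfig(samples_per_group=2000)
        groups = draw_group_level(expt, seed=0, config=cfg)
        g = groups[0]
        samples = draw_sample_level(g, expt, seed=0, config=cfg)
        p = np.array([s.p_out_j for s in samples])
        se = np.sqrt(g.p_out_0 * (1 - g.p_out_0) / (g.theta_0 + 1) / len(p))
        assert abs(p.mean() - g.p_out_0) < 3 * se

    def test_high_concentration_pins_proportions(self):
        expt = draw_expt_level(1000, 1, 2, seed=1)
        cfg = SimConfig(samples_per_group=50, theta_0_range=(1e6, 1e6))
        g = draw_group_level(expt, seed=1, config=cfg)[0]
        samples = draw_sample_level(g, expt, seed=1, config=cfg)
        assert all(abs(s.p_out_j - g.p_out_0) < 0.01 for s in samples)

    def test_mixing_proportions_normalized_on_subset(self):
        cfg = SimConfig(n_groups=2, K=3, samples_per_group=20,
                        component_subsets=[(0, 2), (1,)])
        expt = draw_expt_level(1000, 2, 3, seed=2, config=cfg)
        groups = draw_group_level(expt, seed=2, config=cfg)
        for g in groups:
            for s in draw_sample_level(g, expt, seed=2, config=cfg):
                assert s.p_jk.sum() == pytest.approx(1.0, abs=1e-12)
                off = [k for k in range(3) if k not in g.components]
                assert np.all(s.p_jk[off] == 0)


class TestCellLevel:
    def _setup(self, seed=0, **kw):
        cfg = SimConfig(samples_per_group=5, **kw)
        expt = draw_expt_level(50_000, 1, 2, seed=seed, config=cfg)
        group = draw_group_level(expt, seed=seed, config=cfg)[0]
        sample = draw_sample_level(group, expt, seed=seed, config=cfg)[0]
        return cfg, expt, group, sample

    def test_degenerate_covariance_limit(self):
        cfg, expt, group, sample = self._setup(sigma_scale=1e-12)
        X, k = draw_cell_qcs(sample, group, expt, 200, seed=0, config=cfg)
        mean = expt.mu_g[0] + sample.alpha_j + expt.beta_k[k] + sample.delta_jk[k]
        assert np.abs(X - mean).max() < 1e-5

    def test_component_frequencies_match_multinomial(self):
        cfg, expt, group, sample = self._setup(seed=3)
        _, k = draw_cell_qcs(sample, group, expt, 10_000, seed=3, config=cfg)
        for kk in group.components:
            p = sample.p_jk[kk]
            se = np.sqrt(p * (1 - p) / 10_000)
            assert abs((k == kk).mean() - p) < 3 * se + 1e-9

    def test_component_means_match_theory(self):
        cfg, expt, group, sample = self._setup(seed=4)
        X, k = draw_cell_qcs(sample, group, expt, 10_000, seed=4, config=cfg)
        for kk in np.unique(k):
            pts = X[k == kk]
            mean = expt.mu_g[0] + sample.alpha_j + expt.beta_k[kk] + sample.delta_jk[kk]
            se = np.sqrt(np.diag(expt.Sigma_k[kk]) / len(pts))
            assert np.all(np.abs(pts.mean(axis=0) - mean) < 3 * se + 1e-9)

    def test_t_variant_heavier_tails(self):
        cfg_g, expt, group, sample = self._setup(seed=5)
        cfg_t = SimConfig(samples_per_group=5, t_df=3.0)
        Xg, _ = draw_cell_qcs(sample, group, expt, 20_000, seed=5, config=cfg_g)
        Xt, _ = draw_cell_qcs(sample, group, expt, 20_000, seed=5, config=cfg_t)
        assert np.abs(Xt).max() > np.abs(Xg).max()


class TestPerturbOutlier:
    def test_worked_example_in_expectation(self):
        # n=1000, m=100, feats=500, 50% loss of the 900 non-mito reads:
        # expected total 100 + 450 = 550, mito fraction ~ 100/550 = 0.1818,
        # features ~ 250
        n_cells = 20_000
        pre = np.column_stack([
            np.full(n_cells, 3.0),
            np.full(n_cells, np.log10(500)),
            np.full(n_cells, logit_smoothed(100, 1000)),
        ])
        obs = perturb_outlier(pre, np.full(n_cells, 0.5), seed=1)
        total = 10 ** obs[:, 0]
        feats = 10 ** obs[:, 1]
        se_total = np.sqrt(900 * 0.25 / n_cells)
        se_feats = np.sqrt(500 * 0.25 / n_cells)
        assert abs(total.mean() - 550) < 3 * se_total
        assert abs(feats.mean() - 250) < 3 * se_feats
        mito_frac = 100 / total.mean()
        assert mito_frac == pytest.approx(0.1818, abs=0.01)
        assert mito_frac > 0.1

    def test_zero_loss_limit_identity(self):
        pre = np.array([[3.0, 2.5, -2.0]])
        obs = perturb_outlier(pre, np.array([0.0]), seed=0)
        np.testing.assert_array_equal(obs, pre)

    def test_thinning_monotonicity_invariants(self):
        rng = np.random.default_rng(2)
        n_cells = 10_000
        n = rng.integers(200, 5000, n_cells)
        m = (n * rng.uniform(0, 0.3, n_cells)).astype(int)
        f = rng.integers(50, 2000, n_cells)
        pre = np.column_stack([np.log10(n), np.log10(f), logit_smoothed(m, n)])
        loss = rng.uniform(0.1, 0.9, n_cells)
        obs = perturb_outlier(pre, loss, seed=3)
        assert np.all(obs[:, 0] <= pre[:, 0] + 1e-12)   # counts never increase
        assert np.all(obs[:, 1] <= pre[:, 1] + 1e-12)   # features never increase
        assert np.all(obs[:, 2] >= pre[:, 2] - 1e-12)   # mito fraction never drops

    def test_out_of_range_loss_rejected(self):
        with pytest.raises(ValueError, match="p_loss"):
            perturb_outlier(np.array([3.0, 2.0, -3.0]), 1.5)


class TestSimulateQCs:
    def test_requested_cells_delivered_exactly(self):
        cfg = SimConfig(n_cells=5000, n_groups=2, K=2, samples_per_group=3, seed=0)
        obs, truth = simulate_qcs(cfg)
        assert obs.n_cells == 5000 and len(truth.cells) == 5000

    def test_no_outliers_means_observed_equals_pre(self):
        cfg = SimConfig(n_cells=2000, K=2, samples_per_group=3,
                        p_out_0_range=(0.0, 0.0), seed=1)
        obs, truth = simulate_qcs(cfg)
        np.testing.assert_array_equal(
            obs.values(),
            truth.cells[["pre_log_counts", "pre_log_feats", "pre_logit_mito"]].to_numpy(),
        )
        assert not truth.cells["outlier"].any()

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_cells=3000, n_groups=2, K=3, samples_per_group=4, seed=9)
        a_obs, a_truth = simulate_qcs(cfg)
        b_obs, b_truth = simulate_qcs(cfg)
        np.testing.assert_array_equal(a_obs.values(), b_obs.values())
        assert a_truth.cells.equals(b_truth.cells)

    def test_every_cell_labeled_once(self, small_experiment):
        obs, truth = small_experiment
        assert len(truth.cells) == obs.n_cells
        assert truth.cells.index.is_unique
        assert truth.cells[["group", "sample_id", "component"]].notna().all().all()

    def test_outlier_fraction_matches_expectation(self, small_experiment):
        _, truth = small_experiment
        n_j = truth.cells.groupby("sample_id", sort=False).size()
        expected = sum(s.p_out_j * n_j[s.sample_id] for s in truth.samples)
        var = sum(s.p_out_j * (1 - s.p_out_j) * n_j[s.sample_id] for s in truth.samples)
        observed = truth.cells["outlier"].sum()
        assert abs(observed - expected) < 3 * np.sqrt(var)

    def test_multimodal_marginals_when_separated(self):
        from scipy.stats import gaussian_kde

        cfg = SimConfig(n_cells=8000, K=2, samples_per_group=4,
                        beta_sep_range=(2.0, 3.0), p_out_0_range=(0.0, 0.0), seed=3)
        obs, truth = simulate_qcs(cfg)
        # project onto the axis separating the two components
        direction = truth.expt.beta_k[1] - truth.expt.beta_k[0]
        direction /= np.linalg.norm(direction)
        proj = obs.values() @ direction
        kde = gaussian_kde(proj)
        m0, m1 = truth.expt.mu_g[0] @ direction + np.array(
            [truth.expt.beta_k[0] @ direction, truth.expt.beta_k[1] @ direction]
        )
        xs = np.linspace(m0, m1, 100)
        dens = kde(xs)
        valley = dens[25:75].min()
        assert valley < 0.8 * min(dens[0], dens[-1])

    def test_params_json_replayable(self, small_experiment):
        import json

        _, truth = small_experiment
        obj = json.loads(truth.params_json())
        assert len(obj["samples"]) == 6
        np.testing.assert_allclose(
            np.array(obj["expt"]["beta_k"]), truth.expt.beta_k
        )
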