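"""Validation experiments: the package's end-to-end self-checks.

Each function runs one simulated study and measures how well the pipeline
does the thing it claims to do: chi-square calibration of the outlier
statistic, recovery of the generative mixture parameters, good-cell
precision/recall, cell-type bias relative to MAD and mixture-of-regressions
baselines, sample-group recovery, agreement of the MMD estimator with a
brute-force oracle, robustness of the trimmed estimator, and the
arithmetic of the degradation model.  These back both the test suite and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import chi2, kstest
from sklearn.metrics import adjusted_rand_score

from .core import CellQCTable, logit_smoothed
from .gmm import FitConfig, fit_sampleqc
from .grouping import pairwise_mmd_matrix, cluster_samples, mmd_squared
from .outliers import call_cell_outliers, chi2_cutoff
from .benchmark import (
    mad_filter,
    mixture_regression_filter,
    evaluate_good_cell_recovery,
    cell_type_bias,
)
from .simulate import SimConfig, simulate_qcs, perturb_outlier
from .workflow import run_sampleqc_pipeline

__all__ = [
    "chi2_calibration",
    "parameter_recovery",
    "bias_benchmark",
    "unimodal_recall_gap",
    "grouping_recovery",
    "mmd_oracle_check",
    "robustness_check",
    "degradation_check",
]

D = 3


def _derived_seeds(seed: int, n: int, salt: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), salt])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _recenter(alpha_0, alpha_j, beta_k, n_j, w_k):
    wj = n_j / n_j.sum()
    a_bar = wj @ alpha_j
    wk = w_k / w_k.sum()
    b_bar = wk @ beta_k
    return alpha_0 + a_bar + b_bar, alpha_j - a_bar, beta_k - b_bar


def chi2_calibration(seed: int, n_seeds: int = 5, n_cells: int = 50_000) -> dict:
    """Fit outlier-free 3-component data and check the chi-square null.

    Kept cells are those below the alpha cutoff, so their distances follow
    chi-square truncated at that cutoff; that truncated law is the KS null.
    """
    fracs, ks_pass = [], 0
    for s in _derived_seeds(seed, n_seeds, salt=1):
        cfg = SimConfig(n_cells=n_cells, n_groups=1, K=3, samples_per_group=10,
                        p_out_0_range=(0.0, 0.0), seed=s)
        obs, _ = simulate_qcs(cfg, seed=s)
        fit = fit_sampleqc(obs, FitConfig(K=3, seed=s))
        calls = call_cell_outliers(obs, fit, alpha=0.01)
        fracs.append(float(calls["outlier"].mean()))
        d2 = calls.loc[~calls["outlier"], "mahalanobis_sq"].to_numpy()
        cut = chi2_cutoff(D, 0.01)
        ks = kstest(d2, lambda x: chi2.cdf(np.minimum(x, cut), D) / chi2.cdf(cut, D))
        ks_pass += ks.pvalue > 0.01
    return {
        "flagged_fraction_mean": float(np.mean(fracs)),
        "flagged_fraction_max": float(np.max(fracs)),
        "flagged_fraction_min": float(np.min(fracs)),
        "ks_pass_count": int(ks_pass),
        "n_seeds": n_seeds,
        "n_cells": n_cells,
    }


def parameter_recovery(seed: int, n_seeds: int = 5, cells_per_sample: int = 2000) -> dict:
    """Recover (beta_k, alpha_j, p_jk) from 10 samples with 5% outliers.

    Fitted and true parameters are compared in a common identifiability
    convention; the fitted sample shift is compared against
    alpha_j + sum_k p_jk delta_jk, the shift actually identifiable when the
    generator adds per-sample component wobble the model does not carry.
    """
    db, da, dp, precs, recs = [], [], [], [], []
    for s in _derived_seeds(seed, n_seeds, salt=2):
        cfg = SimConfig(n_cells=10 * cells_per_sample, n_groups=1, K=3,
                        samples_per_group=10, cells_per_sample=cells_per_sample,
                        p_out_0_range=(0.05, 0.05), seed=s)
        obs, truth = simulate_qcs(cfg, seed=s)
        fit = fit_sampleqc(obs, FitConfig(K=3, seed=s))
        tc = truth.cells
        n_j = tc.groupby("sample_id", sort=False).size().to_numpy().astype(float)
        w_true = np.bincount(tc["component"], minlength=3).astype(float)
        a_true = np.vstack([sp.alpha_j + sp.p_jk @ sp.delta_jk for sp in truth.samples])
        _, ajt, bt = _recenter(truth.expt.mu_g[0].copy(), a_true,
                               truth.expt.beta_k.copy(), n_j, w_true)
        row, col = linear_sum_assignment(cdist(fit.beta_k, bt))
        _, ajf, bf = _recenter(fit.alpha_0.copy(), fit.alpha_j.copy(),
                               fit.beta_k.copy(), n_j, w_true[col])
        p_t = np.vstack([sp.p_jk for sp in truth.samples])
        db.append(float(np.abs(bf[row] - bt[col]).max()))
        da.append(float(np.abs(ajf - ajt).max()))
        dp.append(float(np.abs(fit.p_jk[:, row] - p_t[:, col]).max()))
        calls = call_cell_outliers(obs, fit, alpha=0.01)
        res = evaluate_good_cell_recovery(calls["outlier"].to_numpy(), tc.reset_index())
        precs.append(res.precision)
        recs.append(res.recall)
    return {
        "beta_max_abs_error": float(np.max(db)),
        "alpha_max_abs_error": float(np.max(da)),
        "p_jk_max_abs_error": float(np.max(dp)),
        "precision_min": float(np.min(precs)),
        "recall_min": float(np.min(recs)),
        "n_seeds": n_seeds,
        "n_cells": 10 * cells_per_sample,
    }


def bias_benchmark(seed: int, n_seeds: int = 3, n_cells: int = 20_000) -> dict:
    """Cell-type bias of the pipeline vs MAD and mixture-regression filters.

    Samples carry a low-abundance QC cell type at low counts (Dirichlet
    concentration (1.5, 10)); defaults: alpha 0.01, 2.5 MADs, 0.75 posterior.
    """
    rows = []
    for s in _derived_seeds(seed, n_seeds, salt=3):
        cfg = SimConfig(n_cells=n_cells, n_groups=1, K=2, samples_per_group=10,
                        dirichlet_conc=(1.5, 10.0), seed=s)
        obs, truth = simulate_qcs(cfg, seed=s)
        tc = truth.cells.reset_index()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, calls = run_sampleqc_pipeline(obs, k_per_group=2, alpha=0.01, seed=s)
            flags = {
                "sampleqc": calls["outlier"].to_numpy(),
                "mad": mad_filter(obs, nmads=2.5),
                "mixture_regression": mixture_regression_filter(obs, 0.75),
            }
        rows.append({m: cell_type_bias(f, tc).attrs["bias_index"]
                     for m, f in flags.items()})
    wins = sum(r["sampleqc"] < r["mad"] and r["sampleqc"] < r["mixture_regression"]
               for r in rows)
    return {
        "bias_index_sampleqc_max": float(max(r["sampleqc"] for r in rows)),
        "bias_index_mad_min": float(min(r["mad"] for r in rows)),
        "bias_index_mixreg_min": float(min(r["mixture_regression"] for r in rows)),
        "sampleqc_lowest_bias_count": int(wins),
        "n_seeds": n_seeds,
        "n_cells": n_cells,
    }


def unimodal_recall_gap(seed: int, n_seeds: int = 3, n_cells: int = 20_000) -> dict:
    """On unimodal samples the pipeline and the MAD filter should agree."""
    gaps = []
    for s in _derived_seeds(seed, n_seeds, salt=4):
        cfg = SimConfig(n_cells=n_cells, n_groups=1, K=1, samples_per_group=10, seed=s)
        obs, truth = simulate_qcs(cfg, seed=s)
        tc = truth.cells.reset_index()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, calls = run_sampleqc_pipeline(obs, k_per_group=1, alpha=0.01, seed=s)
            r_s = evaluate_good_cell_recovery(calls["outlier"].to_numpy(), tc)
            r_m = evaluate_good_cell_recovery(mad_filter(obs), tc)
        gaps.append(abs(r_s.recall - r_m.recall))
    return {"recall_gap_max": float(np.max(gaps)), "n_seeds": n_seeds,
            "n_cells": n_cells}


def grouping_recovery(seed: int, n_seeds: int = 5, n_cells: int = 24_000) -> dict:
    """Louvain on the MMD kNN graph vs the generative sample groups.

    Three groups of 8 samples with pairwise-disjoint component subsets
    (outlier-free): the setting in which the group labels are identifiable.
    """
    aris = []
    for s in _derived_seeds(seed, n_seeds, salt=5):
        cfg = SimConfig(n_cells=n_cells, n_groups=3, K=6, samples_per_group=8,
                        component_subsets=[(0, 1), (2, 3), (4, 5)],
                        p_out_0_range=(0.0, 0.0), seed=s)
        obs, truth = simulate_qcs(cfg, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = cluster_samples(pairwise_mmd_matrix(obs, subsample=500, seed=s),
                                    seed=s)
        tg = {sp.sample_id: sp.group for sp in truth.samples}
        aris.append(adjusted_rand_score([tg[x] for x in graph.sample_ids],
                                        graph.group_labels))
    return {
        "ari_min": float(np.min(aris)),
        "ari_pass_count": int(sum(a > 0.9 for a in aris)),
        "n_seeds": n_seeds,
        "n_samples": 24,
    }


def mmd_oracle_check(seed: int, n_instances: int = 50) -> dict:
    """Vectorized MMD estimator vs the naive double-loop U-statistic."""

    def naive(A, B, h):
        m, n = len(A), len(B)
        k = lambda x, y: np.exp(-np.sum((x - y) ** 2) / (2 * h * h))
        t1 = sum(k(A[i], A[j]) for i in range(m) for j in range(m) if i != j)
        t2 = sum(k(B[i], B[j]) for i in range(n) for j in range(n) if i != j)
        t3 = sum(k(a, b) for a in A for b in B)
        return t1 / (m * (m - 1)) + t2 / (n * (n - 1)) - 2 * t3 / (m * n)

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        m, n = rng.integers(2, 201, 2)
        d = int(rng.integers(1, 5))
        A = rng.standard_normal((int(m), d))
        B = rng.standard_normal((int(n), d)) + rng.normal(0, 1, d)
        h = float(rng.uniform(0.5, 3.0))
        worst = max(worst, abs(mmd_squared(A, B, h) - max(naive(A, B, h), 0.0)))
    return {"max_abs_difference": float(worst), "n_instances": n_instances}


def robustness_check(seed: int, n: int = 5000) -> dict:
    """Trimmed estimator under 10% gross contamination; EM monotonicity."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(2)
    direction /= np.linalg.norm(direction)
    n_bad = n // 10
    X = np.vstack([rng.standard_normal((n - n_bad, 2)),
                   100.0 * direction + rng.standard_normal((n_bad, 2))])
    df = pd.DataFrame(X, columns=["m0", "m1"])
    df["sample_id"] = "s0"
    tab = CellQCTable(df, ["m0", "m1"])
    robust = fit_sampleqc(tab, FitConfig(K=1, seed=seed))
    center = robust.alpha_0 + robust.beta_k[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mle = fit_sampleqc(tab, FitConfig(K=1, robust=False, seed=seed))
    # monotonicity on clean data in MLE mode
    clean = pd.DataFrame(rng.standard_normal((4000, 2)) , columns=["m0", "m1"])
    clean["sample_id"] = "s0"
    fit_c = fit_sampleqc(CellQCTable(clean, ["m0", "m1"]),
                         FitConfig(K=2, robust=False, seed=seed, n_restarts=2))
    trace = np.array(fit_c.objective_trace)
    monotone = bool(np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1])))
    return {
        "robust_mean_error": float(np.abs(center).max()),
        "robust_cov_max_error": float(np.abs(robust.Sigma_k[0] - np.eye(2)).max()),
        "mle_mean_displacement": float(np.linalg.norm(mle.alpha_0 + mle.beta_k[0])),
        "mle_objective_monotone": monotone,
        "n_cells": n,
    }


def degradation_check(seed: int, n_cells: int = 10_000) -> dict:
    """Binomial-thinning degradation: worked case + monotonicity invariants."""
    rng = np.random.default_rng(seed)
    pre = np.column_stack([
        np.full(n_cells, 3.0),                       # 1000 counts
        np.full(n_cells, np.log10(500.0)),           # 500 features
        np.full(n_cells, logit_smoothed(100, 1000)),  # 100 mito counts
    ])
    obs = perturb_outlier(pre, np.full(n_cells, 0.5), seed=rng)
    total = 10 ** obs[:, 0]
    feats = 10 ** obs[:, 1]
    # invariants on heterogeneous cells
    n = rng.integers(200, 5000, n_cells)
    m = (n * rng.uniform(0, 0.3, n_cells)).astype(int)
    f = rng.integers(50, 2000, n_cells)
    pre2 = np.column_stack([np.log10(n), np.log10(f), logit_smoothed(m, n)])
    obs2 = perturb_outlier(pre2, rng.uniform(0.1, 0.9, n_cells), seed=rng)
    return {
        "mean_total_counts": float(total.mean()),
        "mean_features": float(feats.mean()),
        "mean_mito_fraction": float((100.0 / total).mean()),
        "counts_never_increase": bool(np.all(obs2[:, 0] <= pre2[:, 0] + 1e-12)),
        "features_never_increase": bool(np.all(obs2[:, 1] <= pre2[:, 1] + 1e-12)),
        "mito_never_decreases": bool(np.all(obs2[:, 2] >= pre2[:, 2] - 1e-12)),
        "n_cells": n_cells,
    }
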