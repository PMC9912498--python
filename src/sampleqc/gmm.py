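"""Robust shared-component Gaussian mixture with per-sample mean shifts.

Within one sample group, the QC metric vector of cell ``i`` from sample
``j`` in mixture component ("QC cell type") ``k`` is modelled as

    X_i ~ N(alpha_0 + alpha_j + beta_k, Sigma_k),
    P(Z_i = k | s_i = j) = p_jk,

i.e. every sample shares the component offsets ``beta_k`` and covariances
``Sigma_k`` but carries its own uniform shift ``alpha_j`` and mixing
proportions ``p_jk``.  The decomposition is identifiable only up to a
constant, so we impose sum_j n_j alpha_j = 0 and sum_k w_k beta_k = 0
(w_k = overall component weights), making ``alpha_0`` the grand center.

Fitting is EM-like.  Because outliers are expected to be present (finding
them is the point), the default M-step is *robust*: cells are
hard-assigned to their max-responsibility component, each component keeps
only the (1 - eps) fraction of its cells nearest the current center in
Mahalanobis distance, and the trimmed covariance is rescaled by the
chi-square consistency factor

    c(eps) = (1 - eps) / F_{chi2_{D+2}}( F^{-1}_{chi2_D}(1 - eps) )

so that on clean Gaussian data the estimate is consistent for Sigma.
Sample shifts are updated with coordinate-wise medians.  With
``robust=False`` the fit degenerates to a classical (generalized) EM with
exact weighted-MLE updates, whose objective is monotone non-decreasing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

from .core import CellQCTable

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "GroupFit",
    "trim_consistency_factor",
    "initialize_fit",
    "compute_responsibilities",
    "update_components_robust",
    "update_sample_shifts",
    "fit_sampleqc",
    "fit_sample_groups",
]

PROP_FLOOR = 1e-6
_REWEIGHT_LEVEL = 0.975  # chi-square gate of the reweighting step


@dataclass
class FitConfig:
    """Configuration for one group-level mixture fit."""

    K: int = 1
    trim_eps: float = 0.1     # trimming fraction per component
    tol: float = 1e-6         # relative objective tolerance
    max_iter: int = 200
    n_restarts: int = 5
    seed: int = 0
    robust: bool = True       # False = plain weighted-MLE EM (testing / clean data)
    ridge: float = 1e-6       # covariance regularization, scaled by trace(Sigma)/D

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0.0 <= self.trim_eps < 0.5):
            raise ValueError("trim_eps must be in [0, 0.5)")
        if self.tol <= 0 or self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("tol, max_iter, n_restarts must be positive")


@dataclass
class GroupFit:
    """Fitted model for one sample group."""

    metric_names: list[str]
    sample_ids: list[str]
    alpha_0: np.ndarray               # (D,)
    alpha_j: np.ndarray               # (J, D)
    beta_k: np.ndarray                # (K, D)
    Sigma_k: np.ndarray               # (K, D, D)
    p_jk: np.ndarray                  # (J, K)
    responsibilities: np.ndarray | None = None   # (N, K)
    objective_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    config: FitConfig | None = None
    warnings_: list = field(default_factory=list)

    @property
    def D(self) -> int:
        return len(self.metric_names)

    @property
    def K(self) -> int:
        return self.beta_k.shape[0]

    def component_means(self) -> np.ndarray:
        """Group-level component centers alpha_0 + beta_k, shape (K, D)."""
        return self.alpha_0[None, :] + self.beta_k

    def sample_lookup(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        obj = {
            "metric_names": self.metric_names,
            "sample_ids": self.sample_ids,
            "alpha_0": self.alpha_0.tolist(),
            "alpha_j": self.alpha_j.tolist(),
            "beta_k": self.beta_k.tolist(),
            "Sigma_k": self.Sigma_k.tolist(),
            "p_jk": self.p_jk.tolist(),
            "objective_trace": [float(v) for v in self.objective_trace],
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "config": asdict(self.config) if self.config else None,
            "warnings": list(self.warnings_),
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "GroupFit":
        with open(path) as fh:
            obj = json.load(fh)
        cfg = FitConfig(**obj["config"]) if obj.get("config") else None
        return cls(
            metric_names=obj["metric_names"],
            sample_ids=obj["sample_ids"],
            alpha_0=np.array(obj["alpha_0"]),
            alpha_j=np.array(obj["alpha_j"]),
            beta_k=np.array(obj["beta_k"]),
            Sigma_k=np.array(obj["Sigma_k"]),
            p_jk=np.array(obj["p_jk"]),
            objective_trace=obj.get("objective_trace", []),
            converged=obj.get("converged", False),
            n_iter=obj.get("n_iter", 0),
            config=cfg,
            warnings_=obj.get("warnings", []),
        )


# -- helpers ---------------------------------------------------------------

def trim_consistency_factor(eps: float, D: int) -> float:
    """Rescaling that makes the eps-trimmed Gaussian covariance consistent."""
    if eps <= 0:
        return 1.0
    q = chi2.ppf(1.0 - eps, D)
    return (1.0 - eps) / chi2.cdf(q, D + 2)


def _ridge_mat(S: np.ndarray, ridge: float) -> np.ndarray:
    D = S.shape[0]
    scale = max(np.trace(S) / D, 1.0e-12)
    return S + ridge * scale * np.eye(D)


def _log_gauss(resid: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """log N(resid | 0, Sigma) for rows of resid."""
    D = Sigma.shape[0]
    L = np.linalg.cholesky(Sigma)
    z = np.linalg.solve(L, resid.T)  # (D, N)
    maha = np.sum(z**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (maha + D * np.log(2.0 * np.pi) + logdet)


def _unpack(cells: CellQCTable):
    X = cells.values()
    sidx = cells.sample_index()
    return X, sidx, cells.sample_ids


def _weighted_median(x: np.ndarray) -> np.ndarray:
    return np.median(x, axis=0)


def _recenter(alpha_0, alpha_j, beta_k, n_j, w_k):
    """Impose sum_j n_j alpha_j = 0 and sum_k w_k beta_k = 0."""
    wj = n_j / n_j.sum()
    a_bar = wj @ alpha_j
    alpha_j = alpha_j - a_bar
    alpha_0 = alpha_0 + a_bar
    wk = w_k / w_k.sum()
    b_bar = wk @ beta_k
    beta_k = beta_k - b_bar
    alpha_0 = alpha_0 + b_bar
    return alpha_0, alpha_j, beta_k


# -- operations ------------------------------------------------------------

def initialize_fit(cells: CellQCTable, config: FitConfig, seed: int | None = None) -> GroupFit:
    """Seeded initialization: per-sample medians for shifts, k-means++ for components."""
    from sklearn.cluster import KMeans

    X, sidx, sample_ids = _unpack(cells)
    N, D = X.shape
    J, K = len(sample_ids), config.K
    if N < K * D * 5:
        raise ValueError(
            f"too few cells to fit: {N} cells for K={K}, D={D} (need >= {K * D * 5})"
        )
    if seed is None:
        seed = config.seed
    n_j = np.bincount(sidx, minlength=J).astype(float)

    # components first (alpha_j = 0), then shifts from component-aware
    # residuals: a per-sample raw median would conflate a true shift with a
    # mere difference in component composition
    alpha_0 = np.median(X, axis=0)
    Y = X - alpha_0
    if K == 1:
        z = np.zeros(N, dtype=int)
        beta = np.zeros((1, D))
    else:
        km = KMeans(n_clusters=K, init="k-means++", n_init=1,
                    random_state=seed % (2**31)).fit(Y)
        z = km.labels_
        beta = km.cluster_centers_.copy()
    resid = Y - beta[z]
    alpha_j = np.vstack([np.median(resid[sidx == j], axis=0) for j in range(J)])
    full_resid = resid - alpha_j[sidx]
    counts_k = np.bincount(z, minlength=K).astype(float)
    w_k = counts_k / counts_k.sum()
    alpha_0, alpha_j, beta = _recenter(alpha_0, alpha_j, beta, n_j, w_k)
    Sigma = np.empty((K, D, D))
    for k in range(K):
        pts = full_resid[z == k]
        S = np.cov(pts.T, ddof=0) if len(pts) > D else np.eye(D)
        Sigma[k] = _ridge_mat(np.atleast_2d(S), config.ridge)

    p_jk = np.full((J, K), PROP_FLOOR)
    for j in range(J):
        cnt = np.bincount(z[sidx == j], minlength=K).astype(float)
        p = cnt / max(cnt.sum(), 1.0)
        p_jk[j] = np.maximum(p, PROP_FLOOR)
    p_jk /= p_jk.sum(axis=1, keepdims=True)

    return GroupFit(
        metric_names=list(cells.metric_names), sample_ids=list(sample_ids),
        alpha_0=alpha_0, alpha_j=alpha_j, beta_k=beta, Sigma_k=Sigma,
        p_jk=p_jk, config=config,
    )


def _log_component_densities(X, sidx, fit: GroupFit) -> np.ndarray:
    """(N, K) matrix of log N(x_i | alpha_0 + alpha_j(i) + beta_k, Sigma_k)."""
    N = X.shape[0]
    K = fit.K
    centered = X - fit.alpha_0 - fit.alpha_j[sidx]
    out = np.empty((N, K))
    for k in range(K):
        out[:, k] = _log_gauss(centered - fit.beta_k[k], fit.Sigma_k[k])
    return out


def compute_responsibilities(cells: CellQCTable, fit: GroupFit) -> np.ndarray:
    """E-step: gamma_ik ∝ p_{j(i)k} N(x_i | ...), log-sum-exp stabilized."""
    X, sidx, _ = _unpack(cells)
    return _responsibilities_arrays(X, sidx, fit)[0]


def _responsibilities_arrays(X, sidx, fit):
    logd = _log_component_densities(X, sidx, fit)
    with np.errstate(divide="ignore"):  # p_jk of exactly 0 is admissible
        logp = np.log(fit.p_jk[sidx])
    lw = logd + logp
    norm = logsumexp(lw, axis=1)
    gamma = np.exp(lw - norm[:, None])
    return gamma, norm


def update_components_robust(
    cells: CellQCTable, responsibilities: np.ndarray, fit: GroupFit,
    config: FitConfig | None = None,
):
    """M-step for (beta_k, Sigma_k): trimmed hard-assignment estimates.

    Returns ``(beta_k, Sigma_k, kept_mask, warnings)`` where ``kept_mask``
    marks cells that survived trimming (all cells in MLE mode).
    """
    if config is None:
        config = fit.config or FitConfig(K=fit.K)
    X, sidx, _ = _unpack(cells)
    N, D = X.shape
    K = fit.K
    Y = X - fit.alpha_0 - fit.alpha_j[sidx]
    eps = config.trim_eps if config.robust else 0.0
    cfac = trim_consistency_factor(eps, D)

    beta = fit.beta_k.copy()
    Sigma = fit.Sigma_k.copy()
    kept = np.ones(N, dtype=bool)
    warns: list[str] = []

    if not config.robust:
        # exact weighted MLE: jointly optimal for (beta_k, Sigma_k) given gamma
        for k in range(K):
            g = responsibilities[:, k]
            gs = g.sum()
            if gs < 1e-9:
                warns.append(f"component {k} has vanishing weight")
                continue
            beta[k] = (g[:, None] * Y).sum(axis=0) / gs
            R = Y - beta[k]
            Sigma[k] = _ridge_mat((g[:, None] * R).T @ R / gs, config.ridge)
        return beta, Sigma, kept, warns

    z = np.argmax(responsibilities, axis=1)  # ties -> lowest index
    for k in range(K):
        idx = np.where(z == k)[0]
        if len(idx) == 0:
            warns.append(f"component {k} received no cells; parameters frozen")
            continue
        pts = Y[idx]
        R = pts - beta[k]
        L = np.linalg.cholesky(Sigma[k])
        d2 = np.sum(np.linalg.solve(L, R.T) ** 2, axis=0)
        n_keep = max(int(np.ceil((1.0 - eps) * len(idx))), 1)
        keep_local = np.argsort(d2, kind="stable")[:n_keep]
        kept_idx = idx[keep_local]
        kept[np.setdiff1d(idx, kept_idx, assume_unique=True)] = False
        sub = Y[kept_idx]
        if len(sub) < D + 2:
            warns.append(
                f"component {k} degenerate: {len(sub)} retained cells (< D+2); ridge inflated"
            )
            beta[k] = sub.mean(axis=0)
            Sigma[k] = _ridge_mat(np.zeros((D, D)), 1.0)
            continue
        m_trim = sub.mean(axis=0)
        Rk = sub - m_trim
        S_trim = (Rk.T @ Rk) / len(sub) * cfac
        S_trim = _ridge_mat(S_trim, config.ridge)
        # one-step reweighting (reweighted-MCD style): the raw trimmed
        # estimate over-corrects when contamination occupies the trim budget
        # (the kept set is then the full clean population, not its core);
        # re-estimating from all cells inside the chi-square gate is
        # consistent in both the clean and the contaminated case.
        Lt = np.linalg.cholesky(S_trim)
        d2w = np.sum(np.linalg.solve(Lt, (pts - m_trim).T) ** 2, axis=0)
        gate = chi2.ppf(_REWEIGHT_LEVEL, D)
        w_idx = idx[d2w <= gate]
        trimmed_far = d2w > gate
        kept[idx] = True
        kept[idx[trimmed_far]] = False
        sub = Y[w_idx]
        if len(sub) < D + 2:
            warns.append(
                f"component {k} degenerate after reweighting: {len(sub)} cells; ridge inflated"
            )
            beta[k] = m_trim
            Sigma[k] = _ridge_mat(np.zeros((D, D)), 1.0)
            continue
        beta[k] = sub.mean(axis=0)
        Rk = sub - beta[k]
        c_gate = _REWEIGHT_LEVEL / chi2.cdf(gate, D + 2)
        S = (Rk.T @ Rk) / len(sub) * c_gate
        Sigma[k] = _ridge_mat(S, config.ridge)
    return beta, Sigma, kept, warns


def update_sample_shifts(
    cells: CellQCTable, responsibilities: np.ndarray, fit: GroupFit,
    robust: bool | None = None,
):
    """M-step for (alpha_0, alpha_j).

    Robust mode: coordinate-wise median of per-cell residuals
    x_i - (alpha_0 + beta_{k(i)}) per sample, then re-centered so that the
    n_j-weighted mean of alpha_j is zero (absorbed into alpha_0).
    MLE mode: exact per-sample GLS given responsibilities (keeps EM monotone).
    """
    if robust is None:
        robust = fit.config.robust if fit.config else True
    X, sidx, sample_ids = _unpack(cells)
    J = len(sample_ids)
    D = X.shape[1]
    n_j = np.bincount(sidx, minlength=J).astype(float)
    if np.any(n_j == 0):
        raise ValueError("sample with zero cells in group")
    alpha_j = np.zeros((J, D))
    if robust:
        z = np.argmax(responsibilities, axis=1)
        resid = X - fit.alpha_0 - fit.beta_k[z]
        # gate out cells far from their component (chi-square radius): at
        # ~10% gross contamination even the median acquires a visible bias
        d2 = np.empty(len(X))
        centered = X - fit.alpha_0 - fit.alpha_j[sidx]
        for k in range(fit.K):
            m = z == k
            if not m.any():
                continue
            L = np.linalg.cholesky(fit.Sigma_k[k])
            d2[m] = np.sum(np.linalg.solve(L, (centered[m] - fit.beta_k[k]).T) ** 2, axis=0)
        gate = d2 <= chi2.ppf(_REWEIGHT_LEVEL, D)
        for j in range(J):
            m = (sidx == j) & gate
            if not m.any():
                m = sidx == j
            alpha_j[j] = _weighted_median(resid[m])
    else:
        Sinv = np.stack([np.linalg.inv(S) for S in fit.Sigma_k])
        for j in range(J):
            rows = np.where(sidx == j)[0]
            A = np.zeros((D, D))
            b = np.zeros(D)
            for k in range(fit.K):
                g = responsibilities[rows, k]
                A += g.sum() * Sinv[k]
                r = X[rows] - fit.alpha_0 - fit.beta_k[k]
                b += Sinv[k] @ (g[:, None] * r).sum(axis=0)
            alpha_j[j] = np.linalg.solve(A, b)
    wj = n_j / n_j.sum()
    a_bar = wj @ alpha_j
    alpha_0 = fit.alpha_0 + a_bar
    alpha_j = alpha_j - a_bar
    return alpha_0, alpha_j


def _order_components(fit: GroupFit) -> GroupFit:
    """Canonical component labels: ascending first coordinate of beta_k."""
    order = np.argsort(fit.beta_k[:, 0], kind="stable")
    fit.beta_k = fit.beta_k[order]
    fit.Sigma_k = fit.Sigma_k[order]
    fit.p_jk = fit.p_jk[:, order]
    if fit.responsibilities is not None:
        fit.responsibilities = fit.responsibilities[:, order]
    return fit


def _em_run(cells: CellQCTable, config: FitConfig, seed: int) -> GroupFit:
    X, sidx, sample_ids = _unpack(cells)
    N = X.shape[0]
    J = len(sample_ids)
    n_j = np.bincount(sidx, minlength=J).astype(float)
    fit = initialize_fit(cells, config, seed=seed)
    trace: list[float] = []
    kept = np.ones(N, dtype=bool)
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        gamma, _ = _responsibilities_arrays(X, sidx, fit)
        beta, Sigma, kept, warns = update_components_robust(cells, gamma, fit, config)
        fit.beta_k, fit.Sigma_k = beta, Sigma
        fit.warnings_.extend(w for w in warns if w not in fit.warnings_)
        fit.alpha_0, fit.alpha_j = update_sample_shifts(
            cells, gamma, fit, robust=config.robust
        )
        # p_jk: per-sample responsibility means, floored and renormalized.
        # Robust mode gates on the chi-square radius at (1 - eps): that
        # removes the same eps fraction of genuine cells from every
        # component (leaving proportions unbiased) but excludes arbitrarily
        # much contamination, unlike the fixed-fraction trim above.
        if config.robust:
            centered = X - fit.alpha_0 - fit.alpha_j[sidx]
            d2min = np.full(N, np.inf)
            for k in range(fit.K):
                L = np.linalg.cholesky(fit.Sigma_k[k])
                R = centered - fit.beta_k[k]
                d2min = np.minimum(d2min, np.sum(np.linalg.solve(L, R.T) ** 2, axis=0))
            use = d2min <= chi2.ppf(1.0 - config.trim_eps, X.shape[1])
        else:
            use = np.ones(N, dtype=bool)
        p_jk = np.empty((J, fit.K))
        for j in range(J):
            m = (sidx == j) & use
            if not m.any():
                m = sidx == j
            p_jk[j] = gamma[m].mean(axis=0)
        p_jk = np.maximum(p_jk, PROP_FLOOR)
        p_jk /= p_jk.sum(axis=1, keepdims=True)
        fit.p_jk = p_jk
        # re-center to the identifiability convention (likelihood-invariant)
        w_k = gamma.mean(axis=0)
        fit.alpha_0, fit.alpha_j, fit.beta_k = _recenter(
            fit.alpha_0, fit.alpha_j, fit.beta_k, n_j, np.maximum(w_k, PROP_FLOOR)
        )
        # objective: observed-data log-likelihood over non-trimmed cells
        _, norm = _responsibilities_arrays(X, sidx, fit)
        obj = float(norm[kept].sum()) if config.robust else float(norm.sum())
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"non-finite objective at iteration {it}: {obj!r}; "
                f"alpha_0={fit.alpha_0!r}"
            )
        trace.append(obj)
        params = np.concatenate(
            [fit.alpha_0, fit.alpha_j.ravel(), fit.beta_k.ravel(),
             fit.Sigma_k.ravel(), fit.p_jk.ravel()]
        )
        if len(trace) >= 2:
            prev = trace[-2]
            rel = abs(obj - prev) / max(abs(prev), 1.0)
            # robust-mode iterations can leave the objective oscillating at
            # the last digit while the parameters sit at a fixed point of the
            # trimmed update; either condition counts as converged
            dpar = np.max(np.abs(params - prev_params)) / max(
                np.max(np.abs(prev_params)), 1.0
            )
            if rel < config.tol or dpar < 1e-9:
                converged = True
                break
        prev_params = params
    gamma, norm = _responsibilities_arrays(X, sidx, fit)
    fit.responsibilities = gamma
    fit.objective_trace = trace
    fit.converged = converged
    fit.n_iter = it
    # flag near-empty components (often a sign K is too large)
    w_k = gamma.mean(axis=0)
    for k, w in enumerate(w_k):
        if w < 0.01:
            msg = f"component {k} has overall weight {w:.2e} (< 1%); K may be too large"
            if msg not in fit.warnings_:
                fit.warnings_.append(msg)
    return _order_components(fit)


def fit_sampleqc(cells: CellQCTable, config: FitConfig) -> GroupFit:
    """Fit the shared-component mixture to one sample group.

    Runs ``config.n_restarts`` independent seeded EM runs and returns the
    one with the best final objective.  If no run converges, the best fit is
    returned with ``converged=False`` and a warning.
    """
    ss = np.random.SeedSequence([config.seed, config.K])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_restarts)]
    best: GroupFit | None = None
    for s in seeds:
        run = _em_run(cells, config, seed=s)
        if best is None or run.objective_trace[-1] > best.objective_trace[-1]:
            best = run
    assert best is not None
    if not best.converged:
        warnings.warn(
            f"no EM restart converged within {config.max_iter} iterations "
            f"(K={config.K}); returning best fit"
        )
    for w in best.warnings_:
        warnings.warn(w)
    return best


def fit_sample_groups(
    table: CellQCTable, group_labels: dict[str, int], k_per_group: list[int],
    config: FitConfig | None = None,
) -> dict[int, GroupFit]:
    """Fit every sample group of an experiment.

    ``group_labels`` maps sample_id -> group index; ``k_per_group[g]`` gives
    the number of mixture components for group ``g``.
    """
    if config is None:
        config = FitConfig()
    groups = sorted(set(group_labels.values()))
    if len(k_per_group) != len(groups):
        raise ValueError(
            f"K vector length mismatch: expected {len(groups)} "
            f"(one per sample group), given {len(k_per_group)}"
        )
    fits: dict[int, GroupFit] = {}
    for g in groups:
        samples = {s for s, gg in group_labels.items() if gg == g}
        mask = table.data["sample_id"].astype(str).isin(samples).to_numpy()
        sub = table.subset(mask)
        cfg = FitConfig(**{**asdict(config), "K": k_per_group[g]})
        logger.info("fitting group %d: %d samples, %d cells, K=%d",
                    g, len(samples), sub.n_cells, cfg.K)
        fits[g] = fit_sampleqc(sub, cfg)
    return fits
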