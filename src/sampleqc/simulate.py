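"""Hierarchical simulator of single-cell QC metrics with degraded outliers.

The generator mirrors the structure of real multi-sample experiments:

* experiment level — component offsets ``beta_k`` and covariances
  ``Sigma_k`` for the K "QC cell types", and a mean ``mu_g`` per sample
  group (three metrics: log10 library size, log10 features, logit
  mitochondrial proportion);
* group level — a multinomial split of cells, a non-empty component
  subset per group (all subsets pairwise distinct), and the group's
  outlier regime (mean outlier proportion ``p_out_0`` with beta
  concentration ``theta_0``; mean read-loss ``p_loss_0`` with logit-normal
  spread ``sigma_loss``);
* sample level — a Gaussian sample shift ``alpha_j``, Dirichlet mixing
  proportions ``p_jk`` over the group's subset, a beta-drawn outlier
  proportion ``p_out_j``, a logit-normal read-loss ``p_loss_j``, and a
  small per-sample component wobble ``delta_jk``;
* cell level — component draw, multivariate normal (or t) metric draw,
  Bernoulli outlier flag, and, for outliers, binomial thinning of the
  reconstructed non-mitochondrial reads and features.

Degradation acts on reconstructed counts, so outliers lose reads and
features while their mitochondrial fraction can only rise — the signature
of dying or lysed cells.  The full parameter draw is kept for replay and
as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    CellQCTable,
    inverse_logit_fraction,
    log10_transform,
    logit_smoothed,
)

__all__ = [
    "SimConfig",
    "ExptParams",
    "GroupParams",
    "SampleParams",
    "SimTruth",
    "draw_expt_level",
    "draw_group_level",
    "draw_sample_level",
    "draw_cell_qcs",
    "perturb_outlier",
    "simulate_qcs",
]

METRIC_NAMES = ["log_counts", "log_feats", "logit_mito"]
D = 3


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults emulate a droplet experiment with ~2000 counts and ~1000
    features per cell and low mitochondrial content; component separations
    of 1-3 transformed units produce visibly multimodal metrics.
    """

    n_cells: int = 20_000
    n_groups: int = 1
    K: int = 3
    samples_per_group: int | tuple[int, int] = (4, 12)
    cells_per_sample: int | None = None  # exact per-sample size; overrides n_cells
    base_mu: tuple = (3.3, 3.0, -3.0)
    mu_g_sd: float = 0.2
    beta_sep_range: tuple = (1.0, 3.0)
    sigma_scale: float = 0.05            # E[Sigma_k] = sigma_scale * I
    wishart_df: int = D + 4
    dirichlet_conc: float | tuple = 5.0  # scalar or per-component vector
    alpha_sd: float = 0.15
    delta_sd: float = 0.05
    p_out_0_range: tuple = (0.02, 0.15)
    theta_0_range: tuple = (20.0, 100.0)
    p_loss_0_range: tuple = (0.4, 0.8)
    sigma_loss_range: tuple = (0.3, 0.7)
    loss_conc: float = 50.0              # per-cell beta concentration around p_loss_j
    t_df: float | None = None            # multivariate-t variant when set
    component_subsets: list | None = None  # explicit per-group component sets
    smoothing_c: float = 0.5
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass
class ExptParams:
    n_cells: int
    G: int
    K: int
    beta_k: np.ndarray           # (K, D)
    Sigma_k: np.ndarray          # (K, D, D)
    mu_g: np.ndarray             # (G, D)
    seed: int = 0


@dataclass
class GroupParams:
    group: int
    n_cells: int
    n_samples: int
    components: tuple            # global component indices present in this group
    p_out_0: float
    theta_0: float
    p_loss_0: float
    sigma_loss: float


@dataclass
class SampleParams:
    sample_id: str
    group: int
    alpha_j: np.ndarray          # (D,)
    p_jk: np.ndarray             # (K,) zero outside the group's subset
    p_out_j: float
    p_loss_j: float
    delta_jk: np.ndarray         # (K, D)


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment."""

    cells: pd.DataFrame          # per-cell: group, sample_id, component, outlier, loss, pre_*
    expt: ExptParams
    groups: list = field(default_factory=list)
    samples: list = field(default_factory=list)

    def params_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        obj = {
            "expt": asdict(self.expt),
            "groups": [asdict(g) for g in self.groups],
            "samples": [asdict(s) for s in self.samples],
        }
        return json.dumps(obj, indent=1, default=default)


# -- experiment level ------------------------------------------------------

def _draw_separated_offsets(K: int, sep_range, rng) -> np.ndarray:
    """K offsets whose pairwise distances fall in sep_range, mean-centered."""
    if K == 1:
        return np.zeros((1, D))
    lo, hi = sep_range
    scale = 0.5 * (lo + hi) / np.sqrt(2 * D)
    for _ in range(2_000):
        b = rng.normal(0.0, scale, size=(K, D))
        dists = [np.linalg.norm(b[a] - b[c]) for a in range(K) for c in range(a + 1, K)]
        if min(dists) >= lo and max(dists) <= hi:
            return b - b.mean(axis=0)
    # fallback for K too large for rejection to succeed: center + octahedron
    # lattice (pairwise distances in {s, s*sqrt(2), 2s}), jittered and randomly
    # rotated, scaled so every pairwise separation stays inside [lo, hi]
    lattice = [np.zeros(D)]
    for d in range(D):
        for sign in (1.0, -1.0):
            e = np.zeros(D)
            e[d] = sign
            lattice.append(e)
    if K > len(lattice):
        raise ValueError(f"cannot place {K} separated components in {D} dimensions")
    s = lo * 1.2
    if 2 * s > hi:
        s = 0.5 * (lo + hi / 2)
    b = s * np.vstack(lattice[:K])
    b += rng.normal(0.0, 0.03 * s, size=b.shape)
    Q, _ = np.linalg.qr(rng.standard_normal((D, D)))
    b = b @ Q
    return b - b.mean(axis=0)


def draw_expt_level(n_cells: int, G: int, K: int, seed=0, config: SimConfig | None = None) -> ExptParams:
    """Draw experiment-level parameters: component offsets/covariances, group means."""
    if n_cells < 1 or G < 1 or K < 1:
        raise ValueError("n_cells, G, K must be positive")
    cfg = config or SimConfig(n_cells=n_cells, n_groups=G, K=K)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = _draw_separated_offsets(K, cfg.beta_sep_range, rng)
    beta = beta[np.argsort(beta[:, 0], kind="stable")]  # label components low->high counts
    # Wishart draw scaled so E[Sigma] = sigma_scale * I (SPD by construction)
    df = cfg.wishart_df
    V = np.eye(D) * (cfg.sigma_scale / df)
    L = np.linalg.cholesky(V)
    Sigma = np.empty((K, D, D))
    for k in range(K):
        Z = rng.standard_normal((df, D)) @ L.T
        Sigma[k] = Z.T @ Z
    mu_g = np.asarray(cfg.base_mu) + rng.normal(0.0, cfg.mu_g_sd, size=(G, D))
    return ExptParams(n_cells=n_cells, G=G, K=K, beta_k=beta, Sigma_k=Sigma, mu_g=mu_g,
                      seed=seed if isinstance(seed, int) else -1)


# -- group level -----------------------------------------------------------

def _draw_distinct_subsets(G: int, K: int, rng) -> list[tuple]:
    if G > 2**K - 1:
        raise ValueError(
            f"cannot assign {G} pairwise-distinct non-empty subsets of {K} components"
        )
    if G == 1:
        # the experiment has K QC cell types in total; a lone group holds all
        return [tuple(range(K))]
    for _ in range(10_000):
        subsets: list[tuple] = []
        while len(subsets) < G:
            mask = rng.random(K) < 0.6
            if not mask.any():
                continue
            sub = tuple(np.where(mask)[0].tolist())
            if sub not in subsets:
                subsets.append(sub)
        # every component should occur somewhere in the experiment
        if set().union(*map(set, subsets)) == set(range(K)):
            return subsets
    return subsets


def draw_group_level(expt: ExptParams, seed=0, config: SimConfig | None = None) -> list[GroupParams]:
    """Split cells over groups and draw each group's outlier regime."""
    cfg = config or SimConfig(n_cells=expt.n_cells, n_groups=expt.G, K=expt.K)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cfg.component_subsets is not None:
        subsets = [tuple(s) for s in cfg.component_subsets]
        if len(subsets) != expt.G or len(set(subsets)) != expt.G or any(
            len(s) == 0 for s in subsets
        ):
            raise ValueError("component_subsets must give G distinct non-empty subsets")
    else:
        subsets = _draw_distinct_subsets(expt.G, expt.K, rng)

    if isinstance(cfg.samples_per_group, int):
        n_samples = [cfg.samples_per_group] * expt.G
    else:
        lo, hi = cfg.samples_per_group
        n_samples = [int(rng.integers(lo, hi + 1)) for _ in range(expt.G)]

    if cfg.cells_per_sample is not None:
        n_group_cells = [cfg.cells_per_sample * ns for ns in n_samples]
    else:
        n_group_cells = rng.multinomial(expt.n_cells, np.full(expt.G, 1.0 / expt.G)).tolist()

    out = []
    for g in range(expt.G):
        out.append(
            GroupParams(
                group=g,
                n_cells=int(n_group_cells[g]),
                n_samples=n_samples[g],
                components=subsets[g],
                p_out_0=float(rng.uniform(*cfg.p_out_0_range)),
                theta_0=float(rng.uniform(*cfg.theta_0_range)),
                p_loss_0=float(rng.uniform(*cfg.p_loss_0_range)),
                sigma_loss=float(rng.uniform(*cfg.sigma_loss_range)),
            )
        )
    return out


# -- sample level ----------------------------------------------------------

def _beta_mean_conc(rng, mean: float, conc: float, size=None):
    if mean <= 0.0:
        return np.zeros(size) if size else 0.0
    if mean >= 1.0:
        return np.ones(size) if size else 1.0
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=size)


def draw_sample_level(group: GroupParams, expt: ExptParams, seed=0,
                      config: SimConfig | None = None) -> list[SampleParams]:
    """Draw per-sample shifts, mixing proportions, outlier and loss rates."""
    cfg = config or SimConfig(n_cells=expt.n_cells, n_groups=expt.G, K=expt.K)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = list(group.components)
    conc = cfg.dirichlet_conc
    conc_vec = (np.full(len(sub), float(conc)) if np.isscalar(conc)
                else np.asarray(conc, dtype=float)[sub])
    out = []
    for j in range(group.n_samples):
        p = np.zeros(expt.K)
        p[sub] = rng.dirichlet(conc_vec)
        p_loss_j = float(inverse_logit_fraction(
            rng.normal(np.log(group.p_loss_0 / (1 - group.p_loss_0)), group.sigma_loss)
        ))
        out.append(
            SampleParams(
                sample_id=f"g{group.group}_s{j:02d}",
                group=group.group,
                alpha_j=rng.normal(0.0, cfg.alpha_sd, size=D),
                p_jk=p,
                p_out_j=float(_beta_mean_conc(rng, group.p_out_0, group.theta_0)),
                p_loss_j=p_loss_j,
                delta_jk=rng.normal(0.0, cfg.delta_sd, size=(expt.K, D)),
            )
        )
    return out


# -- cell level ------------------------------------------------------------

def draw_cell_qcs(sample: SampleParams, group: GroupParams, expt: ExptParams,
                  n_j: int, seed=0, config: SimConfig | None = None):
    """Pre-degradation metric draws and component labels for one sample."""
    if n_j < 1:
        raise ValueError("n_j must be >= 1")
    cfg = config or SimConfig(n_cells=expt.n_cells, n_groups=expt.G, K=expt.K)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = rng.choice(expt.K, size=n_j, p=sample.p_jk)
    mu_g = expt.mu_g[group.group]
    X = np.empty((n_j, D))
    for kk in np.unique(k):
        idx = np.where(k == kk)[0]
        mean = mu_g + sample.alpha_j + expt.beta_k[kk] + sample.delta_jk[kk]
        L = np.linalg.cholesky(expt.Sigma_k[kk])
        Z = rng.standard_normal((len(idx), D)) @ L.T
        if cfg.t_df is not None:
            w = rng.chisquare(cfg.t_df, size=len(idx)) / cfg.t_df
            Z /= np.sqrt(w)[:, None]
        X[idx] = mean + Z
    return X, k


def perturb_outlier(pre_metrics: np.ndarray, p_loss_cell, seed=0, c: float = 0.5):
    """Degrade cells by binomially thinning non-mitochondrial reads and features.

    Counts are reconstructed from the transformed metrics, the non-mito
    reads and the feature count are each thinned with keep probability
    (1 - p_loss), and the standard transforms are recomputed.  Accepts a
    single D-vector or an (n, D) matrix with matching per-cell losses.
    """
    X = np.atleast_2d(np.asarray(pre_metrics, dtype=float))
    p_loss = np.broadcast_to(np.asarray(p_loss_cell, dtype=float), (X.shape[0],))
    if np.any((p_loss < 0) | (p_loss >= 1)):
        raise ValueError("p_loss must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.all(p_loss == 0):  # zero-loss limit: no thinning, metrics unchanged
        out = X.copy()
        return out[0] if np.asarray(pre_metrics).ndim == 1 else out

    n = np.maximum(np.round(10.0 ** X[:, 0]), 1).astype(np.int64)
    f = np.maximum(np.round(10.0 ** X[:, 1]), 1).astype(np.int64)
    p_sm = inverse_logit_fraction(X[:, 2])            # smoothed fraction (m+c)/(n+2c)
    m = np.clip(np.round(p_sm * (n + 2 * c) - c), 0, n).astype(np.int64)
    r = n - m

    keep = 1.0 - p_loss
    r_new = rng.binomial(r, keep)
    n_new = m + r_new
    floored = n_new < 1
    n_new = np.maximum(n_new, 1)
    if floored.any():
        import warnings

        warnings.warn(f"{int(floored.sum())} degraded cell(s) floored to 1 count")
    f_new = np.maximum(rng.binomial(f, keep), 1)

    out = np.column_stack([
        log10_transform(n_new),
        log10_transform(f_new),
        logit_smoothed(m, n_new, c),
    ])
    return out[0] if np.asarray(pre_metrics).ndim == 1 else out


# -- full hierarchy --------------------------------------------------------

def simulate_qcs(config: SimConfig | None = None, seed: int | None = None):
    """Run the full hierarchical simulation.

    Returns ``(observed, truth)``: a :class:`CellQCTable` of observed
    (possibly degraded) metrics and a :class:`SimTruth` with per-cell
    labels, pre-degradation metrics and all drawn parameters.
    """
    cfg = config or SimConfig()
    if seed is None:
        seed = cfg.seed
    ss = np.random.SeedSequence([seed, cfg.n_cells, cfg.K])
    r_expt, r_group, r_sample, r_cell, r_out = (np.random.default_rng(s) for s in ss.spawn(5))

    expt = draw_expt_level(cfg.n_cells, cfg.n_groups, cfg.K, seed=r_expt, config=cfg)
    groups = draw_group_level(expt, seed=r_group, config=cfg)
    all_samples: list[SampleParams] = []
    frames = []
    for gp in groups:
        samples = draw_sample_level(gp, expt, seed=r_sample, config=cfg)
        all_samples.extend(samples)
        if cfg.cells_per_sample is not None:
            n_per = np.full(gp.n_samples, cfg.cells_per_sample)
        else:
            n_per = r_cell.multinomial(gp.n_cells, np.full(gp.n_samples, 1.0 / gp.n_samples))
        for sp, n_j in zip(samples, n_per):
            n_j = int(n_j)
            if n_j == 0:
                continue
            X_pre, k = draw_cell_qcs(sp, gp, expt, n_j, seed=r_cell, config=cfg)
            is_out = r_out.random(n_j) < sp.p_out_j
            loss = np.zeros(n_j)
            X_obs = X_pre.copy()
            if is_out.any():
                loss[is_out] = _beta_mean_conc(r_out, sp.p_loss_j, cfg.loss_conc,
                                               size=int(is_out.sum()))
                loss[is_out] = np.clip(loss[is_out], 1e-6, 1 - 1e-6)
                X_obs[is_out] = perturb_outlier(X_pre[is_out], loss[is_out],
                                                seed=r_out, c=cfg.smoothing_c)
            frames.append(pd.DataFrame({
                "sample_id": sp.sample_id,
                "group": gp.group,
                "component": k,
                "outlier": is_out,
                "loss": loss,
                "pre_log_counts": X_pre[:, 0],
                "pre_log_feats": X_pre[:, 1],
                "pre_logit_mito": X_pre[:, 2],
                "log_counts": X_obs[:, 0],
                "log_feats": X_obs[:, 1],
                "logit_mito": X_obs[:, 2],
            }))
    df = pd.concat(frames, ignore_index=True)
    df.index = pd.Index([f"cell_{i:06d}" for i in range(len(df))], name="cell_id")

    observed = CellQCTable(df[["sample_id"] + METRIC_NAMES].copy(), METRIC_NAMES)
    truth = SimTruth(
        cells=df[["sample_id", "group", "component", "outlier", "loss",
                  "pre_log_counts", "pre_log_feats", "pre_logit_mito"]].copy(),
        expt=expt, groups=groups, samples=all_samples,
    )
    return observed, truth
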