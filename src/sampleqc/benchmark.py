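"""Baseline QC filters and benchmarking metrics.

Two conventional filters serve as comparison points:

* a per-sample MAD filter (scater-style): flag cells beyond a number of
  scaled median absolute deviations from the per-sample median of each
  metric, one-sided by default (low counts, low features, high mito);
* a per-sample two-component mixture of linear regressions of
  mitochondrial signal on detected features (miQC-style): the component
  with the larger intercept is "compromised", and cells with posterior
  probability of membership above a cutoff (default 0.75) are flagged.

Benchmark metrics treat "good" (non-outlier) as the positive class:
precision/recall of good-cell identification, overall and per sample, and
a per-cell-type bias index measuring whether a filter preferentially
throws away good cells of particular QC cell types.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CellQCTable

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkResult",
    "mad_filter",
    "mixture_regression_filter",
    "evaluate_good_cell_recovery",
    "cell_type_bias",
]

MAD_SCALE = 1.4826
DEFAULT_DIRECTIONS = {
    "log_counts": "lower",
    "log_feats": "lower",
    "logit_mito": "upper",
}


@dataclass
class BenchmarkResult:
    """Precision/recall of good-cell identification for one method."""

    method: str
    precision: float
    recall: float
    f1: float
    per_sample: pd.DataFrame            # sample_id, precision, recall, bias
    flags: np.ndarray = field(repr=False, default=None)


def mad_filter(
    cells: CellQCTable,
    nmads: float = 2.5,
    directions: dict[str, str] | None = None,
) -> np.ndarray:
    """Per-sample MAD-based outlier flags (any-metric union).

    A cell is flagged if, within its sample, any metric lies beyond
    median +/- nmads * 1.4826 * MAD in the configured direction
    (``lower``, ``upper`` or ``both``).
    """
    if directions is None:
        directions = {m: DEFAULT_DIRECTIONS.get(m, "both") for m in cells.metric_names}
    X = cells.values()
    sidx = cells.sample_index()
    flags = np.zeros(len(X), dtype=bool)
    for j in range(len(cells.sample_ids)):
        rows = np.where(sidx == j)[0]
        for d, m in enumerate(cells.metric_names):
            if m not in directions:
                continue
            x = X[rows, d]
            med = np.median(x)
            mad = MAD_SCALE * np.median(np.abs(x - med))
            if mad == 0:
                warnings.warn(
                    f"constant metric '{m}' in sample {cells.sample_ids[j]}: no MAD flags"
                )
                continue
            direction = directions[m]
            out = np.zeros(len(rows), dtype=bool)
            if direction in ("lower", "both"):
                out |= x < med - nmads * mad
            if direction in ("upper", "both"):
                out |= x > med + nmads * mad
            flags[rows[out]] = True
    return flags


def _fit_two_line_mixture(x, y, max_iter=500, tol=1e-9):
    """EM for a 2-component mixture of simple linear regressions of y on x.

    Returns (coef (2,2) rows [intercept, slope], sigma2 (2,), weights (2,),
    posterior (n,2)) or None when EM degenerates.
    """
    n = len(x)
    Xd = np.column_stack([np.ones(n), x])
    b0, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ b0
    # split on residual sign to break symmetry
    hi = resid > np.median(resid)
    coef = np.empty((2, 2))
    sigma2 = np.empty(2)
    w = np.empty(2)
    post = np.column_stack([~hi, hi]).astype(float)
    ll_old = -np.inf
    for _ in range(max_iter):
        for c in range(2):
            g = post[:, c]
            gs = g.sum()
            if gs < 2:
                return None
            W = g[:, None] * Xd
            A = Xd.T @ W
            try:
                coef[c] = np.linalg.solve(A, W.T @ y)
            except np.linalg.LinAlgError:
                return None
            r = y - Xd @ coef[c]
            sigma2[c] = max((g * r**2).sum() / gs, 1e-12)
            w[c] = gs / n
        if w.min() < 0.01:
            return None
        logd = np.empty((n, 2))
        for c in range(2):
            r = y - Xd @ coef[c]
            logd[:, c] = (np.log(w[c]) - 0.5 * np.log(2 * np.pi * sigma2[c])
                          - 0.5 * r**2 / sigma2[c])
        mx = logd.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logd - mx).sum(axis=1))
        post = np.exp(logd - lse[:, None])
        ll = lse.sum()
        if abs(ll - ll_old) < tol * max(abs(ll_old), 1.0):
            break
        ll_old = ll
    # one population split in half masquerades as two lines but barely
    # reduces the residual variance relative to the single-line fit
    resid1 = y - Xd @ b0
    if sigma2.min() > 0.5 * np.mean(resid1**2):
        return None
    return coef, sigma2, w, post


def mixture_regression_filter(
    cells: CellQCTable,
    posterior_cutoff: float = 0.75,
    x_col: str = "log_feats",
    y_col: str = "logit_mito",
    return_posterior: bool = False,
):
    """Per-sample two-line mixture-of-regressions filter (miQC-style).

    "Compromised" is the component with the larger intercept (higher
    mitochondrial signal at the origin of the feature axis); cells with
    posterior(compromised) > cutoff are flagged.  Samples with fewer than
    50 cells, or where EM degenerates (component weight < 1%), contribute
    no flags and a warning.
    """
    for c in (x_col, y_col):
        if c not in cells.metric_names:
            raise ValueError(f"metric '{c}' not in table")
    X = cells.values()
    dx = cells.metric_names.index(x_col)
    dy = cells.metric_names.index(y_col)
    sidx = cells.sample_index()
    flags = np.zeros(len(X), dtype=bool)
    posterior = np.zeros(len(X))
    for j, sid in enumerate(cells.sample_ids):
        rows = np.where(sidx == j)[0]
        if len(rows) < 50:
            warnings.warn(f"sample {sid}: fewer than 50 cells, skipping mixture fit")
            continue
        res = _fit_two_line_mixture(X[rows, dx], X[rows, dy])
        if res is None:
            warnings.warn(f"sample {sid}: degenerate mixture-regression fit, no flags")
            continue
        coef, _, _, post = res
        compromised = int(np.argmax(coef[:, 0]))  # larger intercept
        posterior[rows] = post[:, compromised]
        flags[rows] = post[:, compromised] > posterior_cutoff
    if return_posterior:
        return flags, posterior
    return flags


def evaluate_good_cell_recovery(
    flags: np.ndarray, truth: pd.DataFrame, method: str = "method"
) -> BenchmarkResult:
    """Precision/recall of good-cell identification.

    ``flags`` are predicted outlier calls aligned to ``truth`` (a frame
    with boolean ``outlier`` and ``sample_id``).  Good = true non-outlier,
    kept = not flagged; precision = |good & kept| / |kept|,
    recall = |good & kept| / |good|.
    """
    if "outlier" not in truth.columns:
        raise ValueError("truth frame lacks an 'outlier' column")
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(truth):
        raise ValueError("flags not aligned to truth")
    good = ~truth["outlier"].to_numpy(dtype=bool)
    kept = ~flags

    def _pr(g, k):
        tp = np.sum(g & k)
        prec = tp / k.sum() if k.sum() else np.nan
        rec = tp / g.sum() if g.sum() else np.nan
        return prec, rec

    precision, recall = _pr(good, kept)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    rows = []
    for sid, grp in truth.groupby("sample_id", sort=False):
        idx = truth.index.get_indexer(grp.index)
        p, r = _pr(good[idx], kept[idx])
        n_good = int(good[idx].sum())
        bias = (kept[idx] & good[idx]).sum() / n_good - 1.0 if n_good else np.nan
        rows.append({"sample_id": sid, "precision": p, "recall": r,
                     "retained_good_bias": bias})
    return BenchmarkResult(
        method=method, precision=float(precision), recall=float(recall),
        f1=float(f1), per_sample=pd.DataFrame(rows), flags=flags,
    )


def cell_type_bias(flags: np.ndarray, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-QC-cell-type exclusion bias of a filter.

    For each true component: the fraction of its good cells mistakenly
    excluded, and the component's share of all mistakenly excluded good
    cells.  The scalar ``bias_index`` (attached in ``.attrs``) is the
    spread (max - min) of the exclusion fractions over components with any
    good cells; an unbiased filter excludes uniformly, giving ~0.
    """
    flags = np.asarray(flags, dtype=bool)
    good = ~truth["outlier"].to_numpy(dtype=bool)
    comp = truth["component"].to_numpy()
    mistaken = flags & good
    n_mistaken = int(mistaken.sum())
    rows = []
    fracs = []
    for k in np.unique(comp):
        mask = comp == k
        n_good = int((mask & good).sum())
        n_exc = int((mask & mistaken).sum())
        frac = n_exc / n_good if n_good else np.nan
        if n_good:
            fracs.append(frac)
        rows.append({
            "component": int(k),
            "n_good": n_good,
            "n_good_excluded": n_exc,
            "excluded_fraction": frac,
            "share_of_mistakes": n_exc / n_mistaken if n_mistaken else 0.0,
        })
    out = pd.DataFrame(rows)
    out.attrs["bias_index"] = float(max(fracs) - min(fracs)) if fracs else 0.0
    return out
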