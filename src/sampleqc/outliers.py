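"""Outlier calling from a fitted group model.

For each cell the squared Mahalanobis distance to the nearest mixture
component (under that cell's sample shift) is computed; for a cell that
truly belongs to a component this statistic follows a chi-square
distribution with D degrees of freedom, so cells in the upper tail
(default alpha = 0.01) are flagged as distance outliers.  In addition,
whole components whose group-level mean meets a user rule (e.g. a mean
splice ratio above 3) can be excluded, flagging every cell nearest them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core import CellQCTable
from .gmm import GroupFit

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentRule",
    "min_mahalanobis",
    "chi2_cutoff",
    "call_cell_outliers",
    "sample_statistics",
]

_COMPARATORS = {
    "<": np.less,
    ">": np.greater,
    "<=": np.less_equal,
    ">=": np.greater_equal,
}


@dataclass(frozen=True)
class ComponentRule:
    """Exclude any component whose group-level mean satisfies the comparison."""

    metric: str
    comparator: str
    threshold: float

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator '{self.comparator}'")

    @classmethod
    def parse(cls, text: str) -> "ComponentRule":
        """Parse e.g. ``"splice_ratio > 3"``."""
        m = re.fullmatch(r"\s*(\w+)\s*(<=|>=|<|>)\s*(-?[\d.eE+]+)\s*", text)
        if not m:
            raise ValueError(f"cannot parse component rule: {text!r}")
        return cls(m.group(1), m.group(2), float(m.group(3)))

    def applies(self, mean: np.ndarray, metric_names: list[str]) -> bool:
        if self.metric not in metric_names:
            raise ValueError(f"rule references unknown metric '{self.metric}'")
        v = mean[metric_names.index(self.metric)]
        return bool(_COMPARATORS[self.comparator](v, self.threshold))


def min_mahalanobis(cells: CellQCTable, fit: GroupFit):
    """Per-cell nearest component and squared Mahalanobis distance.

    d2_k = (x - alpha_0 - alpha_j - beta_k)' Sigma_k^{-1} (...); returns
    ``(nearest_component, mahalanobis_sq)`` with ties going to the lowest k.
    """
    X = cells.values()
    lookup = fit.sample_lookup()
    try:
        sidx = cells.data["sample_id"].astype(str).map(lookup).to_numpy(dtype=int)
    except (ValueError, TypeError) as e:
        raise ValueError("cells contain samples unknown to the fit") from e
    centered = X - fit.alpha_0 - fit.alpha_j[sidx]
    N = X.shape[0]
    d2 = np.empty((N, fit.K))
    for k in range(fit.K):
        L = np.linalg.cholesky(fit.Sigma_k[k])
        R = centered - fit.beta_k[k]
        d2[:, k] = np.sum(np.linalg.solve(L, R.T) ** 2, axis=0)
    nearest = np.argmin(d2, axis=1)  # ties -> lowest index
    return nearest, d2[np.arange(N), nearest]


def chi2_cutoff(D: int, alpha: float) -> float:
    """(1 - alpha) quantile of chi-square with D degrees of freedom."""
    if D < 1:
        raise ValueError("D must be >= 1")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    return float(chi2.ppf(1.0 - alpha, D))


def call_cell_outliers(
    cells: CellQCTable,
    fit: GroupFit,
    alpha: float = 0.01,
    rules: tuple[ComponentRule, ...] = (),
) -> pd.DataFrame:
    """Per-cell outlier calls for one fitted sample group.

    Returns a DataFrame with columns: cell_id, sample_id, nearest_component,
    mahalanobis_sq, p_value, outlier, reason.  A cell is an outlier when its
    nearest component is excluded by a rule (reason ``excluded_component``,
    independent of alpha) or its distance p-value falls below alpha (reason
    ``distance``).
    """
    nearest, d2 = min_mahalanobis(cells, fit)
    D = fit.D
    pval = np.maximum(chi2.sf(d2, D), np.finfo(float).tiny)  # keep p in (0, 1]
    cutoff = chi2_cutoff(D, alpha)

    excluded = np.zeros(fit.K, dtype=bool)
    means = fit.component_means()
    for rule in rules:
        for k in range(fit.K):
            if rule.applies(means[k], fit.metric_names):
                excluded[k] = True
    comp_out = excluded[nearest]
    dist_out = d2 > cutoff if alpha < 1.0 else np.ones_like(d2, dtype=bool)

    reason = np.where(comp_out, "excluded_component",
                      np.where(dist_out, "distance", "none"))
    calls = pd.DataFrame(
        {
            "cell_id": cells.data.index.astype(str),
            "sample_id": cells.data["sample_id"].astype(str).to_numpy(),
            "nearest_component": nearest,
            "mahalanobis_sq": d2,
            "p_value": pval,
            "outlier": comp_out | dist_out,
            "reason": reason,
        }
    )
    per_sample = calls.groupby("sample_id", sort=False)["outlier"].agg(["sum", "count"])
    for sid, row in per_sample.iterrows():
        logger.info("sample %s: %d / %d cells flagged", sid, int(row["sum"]), int(row["count"]))
    return calls


def sample_statistics(fit: GroupFit, calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample QC summary with robust z-scores of the sample shifts.

    Each coordinate of alpha_j is z-scored against the across-sample
    median/scaled-MAD; samples with any |z| > 3 are flagged for review.
    """
    rows = []
    med = np.median(fit.alpha_j, axis=0)
    mad = 1.4826 * np.median(np.abs(fit.alpha_j - med), axis=0)
    dev = fit.alpha_j - med
    sign = np.where(dev == 0, 1.0, np.sign(dev))
    z = np.where(dev == 0, 0.0,
                 np.where(mad > 0, dev / np.where(mad > 0, mad, 1.0), sign * np.inf))
    agg = calls.groupby("sample_id", sort=False)["outlier"].agg(["mean", "count"])
    for j, sid in enumerate(fit.sample_ids):
        row = {"sample_id": sid}
        for d, m in enumerate(fit.metric_names):
            row[f"alpha_{m}"] = fit.alpha_j[j, d]
            row[f"z_{m}"] = z[j, d]
        for k in range(fit.K):
            row[f"p_comp{k}"] = fit.p_jk[j, k]
        row["n_cells"] = int(agg.loc[sid, "count"]) if sid in agg.index else 0
        row["outlier_frac"] = float(agg.loc[sid, "mean"]) if sid in agg.index else np.nan
        row["flagged"] = bool(np.any(np.abs(z[j]) > 3))
        rows.append(row)
    return pd.DataFrame(rows)
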