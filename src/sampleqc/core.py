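"""Per-cell QC metric tables, metric computation from counts, and Gaussianizing transforms.

Cell quality in droplet-based single-cell experiments is summarized by a
small vector of per-cell metrics — library size, number of detected
features, mitochondrial read fraction and (for single-nuclei data) the
spliced:unspliced read ratio.  Downstream modelling assumes each metric is
approximately Gaussian within a cell population, which holds only after a
suitable transform: log10 for counts and features, a smoothed logit for
proportions, log2 for ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CellQCTable",
    "MetricTransform",
    "TransformSpec",
    "compute_qc_metrics",
    "transform_metrics",
    "load_qc_table",
    "read_mtx_counts",
    "log10_transform",
    "logit_smoothed",
    "log2_ratio",
]

#: raw (untransformed) column names produced by :func:`compute_qc_metrics`
RAW_COLUMNS = ("counts", "feats", "mito_counts", "spliced", "unspliced")


@dataclass
class CellQCTable:
    """A per-cell table of QC metrics.

    Parameters
    ----------
    data
        DataFrame with one row per cell, containing at least ``sample_id``
        plus the metric columns.  The index holds cell ids.
    metric_names
        Ordered metric columns; every cell must have a finite value in each.
    """

    data: pd.DataFrame
    metric_names: list[str]

    def __post_init__(self) -> None:
        self.metric_names = list(self.metric_names)
        if "sample_id" not in self.data.columns:
            raise ValueError("CellQCTable requires a 'sample_id' column")
        if len(set(self.metric_names)) != len(self.metric_names):
            raise ValueError("metric names must be unique")
        missing = [m for m in self.metric_names if m not in self.data.columns]
        if missing:
            raise ValueError(f"metric column(s) not found: {missing}")
        vals = self.data[self.metric_names].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = np.where(~np.isfinite(vals).all(axis=1))[0]
            raise ValueError(
                f"non-finite metric values at row(s) {bad[:10].tolist()}"
                + ("..." if len(bad) > 10 else "")
            )
        sid = self.data["sample_id"]
        if sid.isna().any() or (sid.astype(str) == "").any():
            raise ValueError("every cell needs a non-empty sample_id")

    # -- accessors ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.data)

    @property
    def n_metrics(self) -> int:
        return len(self.metric_names)

    @property
    def sample_ids(self) -> list[str]:
        """Unique sample ids in first-appearance order."""
        return list(dict.fromkeys(self.data["sample_id"].astype(str)))

    def values(self) -> np.ndarray:
        """N x D metric matrix (float64)."""
        return self.data[self.metric_names].to_numpy(dtype=float)

    def sample_index(self) -> np.ndarray:
        """Per-cell integer index into :attr:`sample_ids`."""
        order = {s: i for i, s in enumerate(self.sample_ids)}
        return self.data["sample_id"].astype(str).map(order).to_numpy()

    def subset(self, mask: np.ndarray) -> "CellQCTable":
        return CellQCTable(self.data.loc[np.asarray(mask)].copy(), self.metric_names)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="cell_id")


@dataclass(frozen=True)
class MetricTransform:
    """One Gaussianizing transform: raw column(s) -> one transformed metric.

    kind is one of ``log10`` (cols: (x,)), ``logit`` (cols: (numer, denom),
    smoothed as (m+c)/(n+2c)), ``log2_ratio`` (cols: (numer, denom), each
    smoothed by +c) or ``identity``.
    """

    name: str
    kind: str
    cols: tuple[str, ...]
    c: float = 0.5

    def __post_init__(self):
        if self.kind not in ("log10", "logit", "log2_ratio", "identity"):
            raise ValueError(f"unknown transform kind '{self.kind}'")


@dataclass
class TransformSpec:
    """Ordered collection of :class:`MetricTransform`."""

    transforms: list[MetricTransform] = field(default_factory=list)

    @classmethod
    def default(cls, with_splice_ratio: bool = False) -> "TransformSpec":
        ts = [
            MetricTransform("log_counts", "log10", ("counts",)),
            MetricTransform("log_feats", "log10", ("feats",)),
            MetricTransform("logit_mito", "logit", ("mito_counts", "counts")),
        ]
        if with_splice_ratio:
            ts.append(MetricTransform("splice_ratio", "log2_ratio", ("spliced", "unspliced")))
        return cls(ts)

    @property
    def metric_names(self) -> list[str]:
        return [t.name for t in self.transforms]


# -- transform primitives (shared with the simulator) ----------------------

def log10_transform(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("log10 transform: negative raw values")
    return np.log10(x)


def logit_smoothed(m: np.ndarray, n: np.ndarray, c: float = 0.5) -> np.ndarray:
    """logit((m+c)/(n+2c)); finite for any m in [0, n], n >= 1 when c > 0."""
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(m < 0) or np.any(n < 0):
        raise ValueError("logit transform: negative raw values")
    return np.log(m + c) - np.log(n - m + c)


def inverse_logit_fraction(t: np.ndarray) -> np.ndarray:
    """Inverse of the (smoothed) logit: the smoothed proportion p' in (0,1)."""
    t = np.asarray(t, dtype=float)
    return 1.0 / (1.0 + np.exp(-t))


def log2_ratio(s: np.ndarray, u: np.ndarray, c: float = 0.5) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(s < 0) or np.any(u < 0):
        raise ValueError("log2 ratio transform: negative raw values")
    return np.log2(s + c) - np.log2(u + c)


# -- operations ------------------------------------------------------------

def compute_qc_metrics(
    counts: sp.spmatrix,
    mito_flags: np.ndarray,
    spliced: sp.spmatrix | None = None,
    unspliced: sp.spmatrix | None = None,
    sample_ids=None,
    cell_ids=None,
) -> CellQCTable:
    """Raw QC metrics from a gene x cell count matrix.

    Per cell: total counts, detected features (genes with count > 0),
    mitochondrial counts, and optional spliced/unspliced totals.  Cells with
    zero total counts (empty barcodes) are dropped with a logged warning.
    """
    counts = sp.csc_matrix(counts)
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("count matrix must be nonnegative")
    mito_flags = np.asarray(mito_flags, dtype=bool)
    n_genes, n_cells = counts.shape
    if mito_flags.shape != (n_genes,):
        raise ValueError(
            f"mito_flags length {mito_flags.shape[0]} != number of genes {n_genes}"
        )
    total = np.asarray(counts.sum(axis=0)).ravel()
    if not np.any(total > 0):
        raise ValueError("no usable cells: all-zero count matrix")
    feats = np.asarray((counts > 0).sum(axis=0)).ravel()
    mito = np.asarray(counts[mito_flags, :].sum(axis=0)).ravel() if mito_flags.any() else np.zeros(n_cells)

    cols = {"counts": total, "feats": feats, "mito_counts": mito}
    for name, mat in (("spliced", spliced), ("unspliced", unspliced)):
        if mat is not None:
            mat = sp.csc_matrix(mat)
            if mat.shape[1] != n_cells:
                raise ValueError(f"{name} matrix cell axis mismatch")
            cols[name] = np.asarray(mat.sum(axis=0)).ravel()

    if cell_ids is None:
        cell_ids = [f"cell_{i:06d}" for i in range(n_cells)]
    if sample_ids is None:
        sample_ids = ["sample_0"] * n_cells
    df = pd.DataFrame(cols, index=pd.Index(cell_ids, name="cell_id"))
    df.insert(0, "sample_id", np.asarray(sample_ids, dtype=object))

    keep = total > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d cell(s) with zero total counts", n_drop)
        warnings.warn(f"dropped {n_drop} cell(s) with zero total counts")
        df = df.loc[keep]
    metric_names = [c for c in df.columns if c != "sample_id"]
    return CellQCTable(df, metric_names)


def transform_metrics(raw: CellQCTable, spec: TransformSpec | None = None) -> CellQCTable:
    """Apply Gaussianizing transforms to a raw-metric table."""
    if spec is None:
        spec = TransformSpec.default(with_splice_ratio="spliced" in raw.data.columns)
    out = raw.data[["sample_id"]].copy()
    for t in spec.transforms:
        for col in t.cols:
            if col not in raw.data.columns:
                raise ValueError(f"transform '{t.name}' needs raw column '{col}'")
        arrs = [raw.data[c].to_numpy(dtype=float) for c in t.cols]
        if t.kind == "log10":
            out[t.name] = log10_transform(arrs[0])
        elif t.kind == "logit":
            out[t.name] = logit_smoothed(arrs[0], arrs[1], t.c)
        elif t.kind == "log2_ratio":
            out[t.name] = log2_ratio(arrs[0], arrs[1], t.c)
        else:  # identity
            out[t.name] = arrs[0]
    return CellQCTable(out, spec.metric_names)


def load_qc_table(path, sample_col: str = "sample_id", metric_cols=None) -> CellQCTable:
    """Load a per-cell QC table from delimited text (CSV/TSV, header required)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"empty file: {path}")
    if sample_col not in df.columns:
        raise ValueError(f"column '{sample_col}' not found in {path}")
    if "cell_id" in df.columns:
        df = df.set_index("cell_id")
    if metric_cols is None:
        metric_cols = [
            c for c in df.columns
            if c != sample_col and pd.api.types.is_numeric_dtype(df[c])
        ]
    else:
        missing = [c for c in metric_cols if c not in df.columns]
        if missing:
            raise ValueError(f"column '{missing[0]}' not found in {path}")
    vals = df[list(metric_cols)].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(vals).all(axis=1))[0]
    if len(bad):
        raise ValueError(f"non-finite metric values at row(s) {bad[:10].tolist()}")
    if sample_col != "sample_id":
        df = df.rename(columns={sample_col: "sample_id"})
    return CellQCTable(df, list(metric_cols))


def read_mtx_counts(mtx_path, features_path, barcodes_path, mito_regex: str = "(?i)^MT-"):
    """Read a 10x-style MatrixMarket triplet.

    Returns ``(counts, mito_flags, gene_names, barcodes)`` with genes on the
    rows.  Mitochondrial genes are identified by regex on the gene name
    (case-insensitive ``MT-`` prefix by default).
    """
    import re

    from scipy.io import mmread

    counts = sp.csc_matrix(mmread(str(mtx_path)))
    feats = pd.read_csv(features_path, sep="\t", header=None)
    # 10x features.tsv: id, name[, type]; fall back to single column
    gene_names = feats.iloc[:, 1] if feats.shape[1] > 1 else feats.iloc[:, 0]
    gene_names = gene_names.astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    if len(gene_names) != counts.shape[0]:
        raise ValueError("features list does not match matrix row count")
    if len(barcodes) != counts.shape[1]:
        raise ValueError("barcodes list does not match matrix column count")
    pat = re.compile(mito_regex)
    mito_flags = np.array([bool(pat.search(g)) for g in gene_names])
    return counts, mito_flags, gene_names, barcodes
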