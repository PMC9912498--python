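"""Diagnostic report generation.

The report shows, per run: the 2-D sample embedding colored by group (and
by any sample annotation), per-group biaxial metric densities overlaid
with 2-SD component ellipses, the histogram of min-Mahalanobis distances
with the chi-square density, the per-sample statistics table, and outlier
counts by reason.  Figure data are also written as CSV so results can be
checked numerically; the figures themselves are embedded as base64 PNGs
in a single self-contained HTML file (markdown fallback available).
"""

from __future__ import annotations

import base64
import io
import json
from pathlib import Path
from string import Template

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.stats import chi2

from .workflow import load_fits

__all__ = ["make_report", "ellipse_points"]

_PAGE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>sampleqc report</title>
<style>body{font-family:sans-serif;margin:2em;max-width:1100px}
table{border-collapse:collapse}td,th{border:1px solid #999;padding:3px 8px;font-size:90%}
img{max-width:100%}h2{border-bottom:1px solid #ccc}</style></head>
<body>
<h1>SampleQC run report</h1>
<p>$n_cells cells, $n_samples samples, $n_groups sample group(s).
Outliers: $n_outliers ($outlier_pct%). By reason: $by_reason.</p>
<h2>Sample embedding</h2>$embedding_figs
<h2>Fitted components (biaxial panels, 2-SD ellipses)</h2>$biaxial_figs
<h2>Mahalanobis distances vs chi-square</h2>$maha_figs
<h2>Per-sample statistics</h2>$sample_table
</body></html>
"""
)


def ellipse_points(mean2, cov2, n_sd=2.0, n=100):
    """Boundary of the n_sd ellipse of a 2-D Gaussian (n x 2 array)."""
    w, v = np.linalg.eigh(np.asarray(cov2, dtype=float))
    t = np.linspace(0, 2 * np.pi, n)
    circ = np.column_stack([np.cos(t), np.sin(t)])
    return np.asarray(mean2) + n_sd * circ * np.sqrt(np.clip(w, 0, None)) @ v.T


def _b64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, bbox_inches="tight")
    plt.close(fig)
    return '<img src="data:image/png;base64,%s"/>' % base64.b64encode(
        buf.getvalue()
    ).decode()


def make_report(run_dir, cells_path=None, fmt: str = "html") -> Path:
    """Render the diagnostic report for a completed run directory."""
    run = Path(run_dir)
    needed = ["groups.csv", "outliers.csv", "sample_stats.csv"]
    missing = [n for n in needed if not (run / n).exists()]
    if missing:
        raise FileNotFoundError(f"missing artifact(s) in {run}: {missing}")
    groups = pd.read_csv(run / "groups.csv")
    calls = pd.read_csv(run / "outliers.csv")
    stats = pd.read_csv(run / "sample_stats.csv")
    fits = load_fits(run)
    cells = None
    if cells_path is None and (run / "cells.csv").exists():
        cells_path = run / "cells.csv"
    if cells_path is not None:
        cells = pd.read_csv(cells_path)

    figdata_dir = run / "figure_data"
    figdata_dir.mkdir(exist_ok=True)

    # -- embedding ---------------------------------------------------------
    emb_figs = []
    for method in ("mds", "umap"):
        c1, c2 = f"{method}_1", f"{method}_2"
        if c1 not in groups.columns:
            continue
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for g, sub in groups.groupby("group"):
            ax.scatter(sub[c1], sub[c2], label=f"group {g}", s=35)
        ax.set_xlabel(c1)
        ax.set_ylabel(c2)
        ax.set_title(f"Sample embedding ({method.upper()})")
        ax.legend(fontsize=8)
        emb_figs.append(_b64(fig))
    groups.to_csv(figdata_dir / "embedding.csv", index=False)

    # -- biaxial panels with component ellipses ----------------------------
    biaxial_figs = []
    ell_rows = []
    for g, fit in fits.items():
        names = fit.metric_names
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.5),
                                 squeeze=False)
        for ax, (ma, mb) in zip(axes[0], pairs):
            ia, ib = names.index(ma), names.index(mb)
            if cells is not None:
                sub = cells[cells["sample_id"].isin(fit.sample_ids)]
                ax.hexbin(sub[ma], sub[mb], gridsize=60, cmap="Greys", mincnt=1)
            for k in range(fit.K):
                mean2 = fit.component_means()[k][[ia, ib]]
                cov2 = fit.Sigma_k[k][np.ix_([ia, ib], [ia, ib])]
                pts = ellipse_points(mean2, cov2)
                ax.plot(pts[:, 0], pts[:, 1], lw=1.5, label=f"comp {k}")
                ell_rows.append({
                    "group": g, "component": k, "x_metric": ma, "y_metric": mb,
                    "mean_x": mean2[0], "mean_y": mean2[1],
                    "cov_xx": cov2[0, 0], "cov_xy": cov2[0, 1], "cov_yy": cov2[1, 1],
                })
            ax.set_xlabel(ma)
            ax.set_ylabel(mb)
        axes[0][0].set_title(f"group {g} (K={fit.K})")
        biaxial_figs.append(_b64(fig))
    pd.DataFrame(ell_rows).to_csv(figdata_dir / "ellipses.csv", index=False)

    # -- Mahalanobis histogram vs chi2 -------------------------------------
    maha_figs = []
    hist_rows = []
    for g, fit in fits.items():
        d2 = calls.loc[calls["group"] == g, "mahalanobis_sq"].to_numpy()
        Df = fit.D
        hi = max(chi2.ppf(0.999, Df), np.percentile(d2, 99))
        bins = np.linspace(0, hi, 60)
        counts, edges = np.histogram(d2[d2 <= hi], bins=bins, density=True)
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.stairs(counts, edges, fill=True, alpha=0.5, label="observed")
        xs = np.linspace(0.01, hi, 200)
        ax.plot(xs, chi2.pdf(xs, Df), "r-", label=f"chi2({Df})")
        ax.set_xlabel("min Mahalanobis distance^2")
        ax.set_title(f"group {g}")
        ax.legend(fontsize=8)
        maha_figs.append(_b64(fig))
        mid = 0.5 * (edges[:-1] + edges[1:])
        for m, c in zip(mid, counts):
            hist_rows.append({"group": g, "bin_mid": m, "density": c,
                              "chi2_density": chi2.pdf(m, Df)})
    pd.DataFrame(hist_rows).to_csv(figdata_dir / "mahalanobis_hist.csv", index=False)

    by_reason = calls.loc[calls["outlier"], "reason"].value_counts().to_dict()
    n_out = int(calls["outlier"].sum())
    html = _PAGE.substitute(
        n_cells=len(calls),
        n_samples=groups.shape[0],
        n_groups=groups["group"].nunique(),
        n_outliers=n_out,
        outlier_pct=f"{100 * n_out / max(len(calls), 1):.2f}",
        by_reason=json.dumps(by_reason),
        embedding_figs="\n".join(emb_figs),
        biaxial_figs="\n".join(biaxial_figs),
        maha_figs="\n".join(maha_figs),
        sample_table=stats.round(4).to_html(index=False),
    )
    if fmt == "html":
        out = run / "report.html"
        out.write_text(html)
    else:
        out = run / "report.md"
        lines = [
            "# SampleQC run report", "",
            f"- cells: {len(calls)}",
            f"- samples: {groups.shape[0]}",
            f"- sample groups: {groups['group'].nunique()}",
            f"- outliers: {n_out} ({100 * n_out / max(len(calls), 1):.2f}%)",
            f"- by reason: {json.dumps(by_reason)}", "",
            "Figure data written under figure_data/.", "",
            stats.round(4).to_markdown(index=False),
        ]
        out.write_text("\n".join(lines))
    return out
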