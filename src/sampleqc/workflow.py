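"""End-to-end pipeline drivers shared by the CLI and the library surface.

The canonical three-step workflow is: pairwise MMDs and sample grouping;
a robust mixture fit per sample group; outlier calling and a report.  Each
stage reads and writes plain-text artifacts (CSV/JSON) in a run directory
so the pipeline is resumable, and :func:`run_sampleqc_pipeline` runs the
whole chain in memory for programmatic use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CellQCTable, load_qc_table
from .grouping import SampleGraph, pairwise_mmd_matrix, cluster_samples, embed_samples
from .gmm import FitConfig, GroupFit, fit_sample_groups
from .outliers import ComponentRule, call_cell_outliers, sample_statistics
from .benchmark import (
    mad_filter,
    mixture_regression_filter,
    evaluate_good_cell_recovery,
    cell_type_bias,
)

logger = logging.getLogger(__name__)

__all__ = [
    "run_sampleqc_pipeline",
    "stage_group",
    "stage_fit",
    "stage_call",
    "stage_benchmark",
]


# -- in-memory driver ------------------------------------------------------

def run_sampleqc_pipeline(
    table: CellQCTable,
    k_per_group: list[int] | int = 1,
    alpha: float = 0.01,
    rules: tuple[ComponentRule, ...] = (),
    seed: int = 0,
    subsample: int = 500,
    fit_config: FitConfig | None = None,
    graph: SampleGraph | None = None,
):
    """Group samples, fit each group, call outliers.

    Returns ``(graph, fits, calls)`` where ``calls`` is a per-cell frame in
    the input row order with a definite boolean call for every cell.
    """
    if graph is None:
        graph = pairwise_mmd_matrix(table, subsample=subsample, seed=seed)
        graph = cluster_samples(graph, seed=seed)
    labels = {s: int(g) for s, g in zip(graph.sample_ids, graph.group_labels)}
    n_groups = len(set(labels.values()))
    if isinstance(k_per_group, int):
        k_per_group = [k_per_group] * n_groups
    cfg = fit_config or FitConfig(seed=seed)
    fits = fit_sample_groups(table, labels, list(k_per_group), cfg)

    pieces = []
    for g, fit in fits.items():
        samples = {s for s, gg in labels.items() if gg == g}
        mask = table.data["sample_id"].astype(str).isin(samples).to_numpy()
        sub = table.subset(mask)
        calls = call_cell_outliers(sub, fit, alpha=alpha, rules=rules)
        calls.insert(1, "group", g)
        pieces.append(calls)
    calls = pd.concat(pieces, ignore_index=True)
    order = {c: i for i, c in enumerate(table.data.index.astype(str))}
    calls = calls.sort_values("cell_id", key=lambda s: s.map(order), ignore_index=True)
    return graph, fits, calls


# -- disk stages -----------------------------------------------------------

def stage_group(cells_path, out_dir, sample_col="sample_id", metric_cols=None,
                subsample=500, k=None, resolution=1.0, seed=0, umap_embedding=False):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = load_qc_table(cells_path, sample_col=sample_col, metric_cols=metric_cols)
    graph = pairwise_mmd_matrix(table, subsample=subsample, seed=seed)
    graph = cluster_samples(graph, k=k, resolution=resolution, seed=seed)
    graph = embed_samples(graph, "mds", seed=seed)
    if umap_embedding:
        graph = embed_samples(graph, "umap", seed=seed)

    pd.DataFrame(graph.mmd, index=graph.sample_ids, columns=graph.sample_ids).to_csv(
        out / "mmd.csv", index_label="sample_id"
    )
    rows = {"sample_id": graph.sample_ids, "group": graph.group_labels,
            "mds_1": graph.embeddings["mds"][:, 0], "mds_2": graph.embeddings["mds"][:, 1]}
    if "umap" in graph.embeddings:
        rows["umap_1"] = graph.embeddings["umap"][:, 0]
        rows["umap_2"] = graph.embeddings["umap"][:, 1]
    pd.DataFrame(rows).to_csv(out / "groups.csv", index=False)
    with open(out / "group_params.json", "w") as fh:
        json.dump({**graph.params, "excluded": graph.excluded}, fh, indent=1)
    logger.info("grouping: %d samples -> %d groups",
                graph.n_samples, len(set(graph.group_labels)))
    return graph


def _load_groups(out_dir) -> dict[str, int]:
    path = Path(out_dir) / "groups.csv"
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: run the 'group' stage before 'fit'"
        )
    df = pd.read_csv(path)
    return {str(r.sample_id): int(r.group) for r in df.itertuples()}


def stage_fit(cells_path, out_dir, k_per_group, sample_col="sample_id",
              metric_cols=None, fit_config: FitConfig | None = None):
    out = Path(out_dir)
    table = load_qc_table(cells_path, sample_col=sample_col, metric_cols=metric_cols)
    labels = _load_groups(out)
    fits = fit_sample_groups(table, labels, list(k_per_group), fit_config or FitConfig())
    fit_dir = out / "fits"
    fit_dir.mkdir(exist_ok=True)
    for g, fit in fits.items():
        fit.to_json(fit_dir / f"fit_g{g}.json")
    return fits


def load_fits(out_dir) -> dict[int, GroupFit]:
    fit_dir = Path(out_dir) / "fits"
    if not fit_dir.exists():
        raise FileNotFoundError(
            f"{fit_dir} not found: run the 'fit' stage before this one"
        )
    fits = {}
    for p in sorted(fit_dir.glob("fit_g*.json")):
        g = int(p.stem.split("fit_g")[1])
        fits[g] = GroupFit.from_json(p)
    return fits


def stage_call(cells_path, out_dir, alpha=0.01, rules=(), sample_col="sample_id",
               metric_cols=None):
    out = Path(out_dir)
    table = load_qc_table(cells_path, sample_col=sample_col, metric_cols=metric_cols)
    labels = _load_groups(out)
    fits = load_fits(out)
    rules = tuple(ComponentRule.parse(r) if isinstance(r, str) else r for r in rules)
    pieces, stats = [], []
    for g, fit in fits.items():
        samples = {s for s, gg in labels.items() if gg == g}
        sub = table.subset(table.data["sample_id"].astype(str).isin(samples).to_numpy())
        calls = call_cell_outliers(sub, fit, alpha=alpha, rules=rules)
        calls.insert(1, "group", g)
        pieces.append(calls)
        st = sample_statistics(fit, calls)
        st.insert(1, "group", g)
        stats.append(st)
    calls = pd.concat(pieces, ignore_index=True)
    order = {c: i for i, c in enumerate(table.data.index.astype(str))}
    calls = calls.sort_values("cell_id", key=lambda s: s.map(order), ignore_index=True)
    calls.to_csv(out / "outliers.csv", index=False)
    pd.concat(stats, ignore_index=True).to_csv(out / "sample_stats.csv", index=False)
    with open(out / "call_params.json", "w") as fh:
        json.dump({"alpha": alpha,
                   "rules": [f"{r.metric} {r.comparator} {r.threshold}" for r in rules]},
                  fh, indent=1)
    return calls


def stage_benchmark(cells_path, truth_path, out_dir, k_per_group=None, alpha=0.01,
                    nmads=2.5, posterior_cutoff=0.75, seed=0,
                    fit_config: FitConfig | None = None):
    """Run all three filters against simulated ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = load_qc_table(cells_path)
    truth = pd.read_csv(truth_path, index_col="cell_id")
    k = k_per_group if k_per_group is not None else 1
    _, _, calls = run_sampleqc_pipeline(table, k_per_group=k, alpha=alpha, seed=seed,
                                        fit_config=fit_config)
    flags = {
        "sampleqc": calls["outlier"].to_numpy(dtype=bool),
        "mad": mad_filter(table, nmads=nmads),
        "mixture_regression": mixture_regression_filter(table, posterior_cutoff),
    }
    summary = {}
    for name, f in flags.items():
        res = evaluate_good_cell_recovery(f, truth, method=name)
        bias = cell_type_bias(f, truth)
        bias.to_csv(out / f"bias_{name}.csv", index=False)
        res.per_sample.to_csv(out / f"per_sample_{name}.csv", index=False)
        summary[name] = {
            "precision": res.precision, "recall": res.recall, "f1": res.f1,
            "bias_index": bias.attrs["bias_index"],
        }
    with open(out / "benchmark_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
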