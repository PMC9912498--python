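import warnings

import numpy as np
import pandas as pd
import pytest

from sampleqc.core import CellQCTable
from sampleqc.simulate import SimConfig, simulate_qcs


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_experiment():
    """One sample group, 3 components, 6 samples x 800 cells, 5% outliers."""
    cfg = SimConfig(
        n_cells=4800, n_groups=1, K=3, samples_per_group=6, cells_per_sample=800,
        p_out_0_range=(0.05, 0.05), seed=42,
    )
    return simulate_qcs(cfg, seed=42)


@pytest.fixture(scope="session")
def grouped_experiment():
    """Three sample groups with disjoint component pairs, outlier-free."""
    cfg = SimConfig(
        n_cells=10800, n_groups=3, K=6, samples_per_group=6,
        component_subsets=[(0, 1), (2, 3), (4, 5)],
        p_out_0_range=(0.0, 0.0), seed=7,
    )
    return simulate_qcs(cfg, seed=7)


def make_table(X, sample_ids=None, metric_names=None):
    """Build a CellQCTable from a raw matrix (helper used across test files)."""
    X = np.atleast_2d(X)
    if metric_names is None:
        metric_names = [f"m{d}" for d in range(X.shape[1])]
    df = pd.DataFrame(X, columns=metric_names)
    df["sample_id"] = sample_ids if sample_ids is not None else "s0"
    return CellQCTable(df, metric_names)
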