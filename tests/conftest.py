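import numpy as np
import pandas as pd
import pytest

from genofabric.config import AnalysisConfig
from genofabric.datamodel import ExpressionDataset, make_sample_sheet


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """3 genes x 6 conditions x K=4, deterministic positive values."""
    rng = np.random.default_rng(42)
    sheet = make_sample_sheet()
    values = pd.DataFrame(
        np.exp(rng.normal(0.0, 0.5, size=(3, len(sheet)))),
        index=["Ga", "Gb", "Gc"],
        columns=sheet.index,
    )
    return ExpressionDataset(values, sheet, "raw")


@pytest.fixture
def two_condition_dataset() -> ExpressionDataset:
    """25 genes x 2 conditions x K=4, median-normalized."""
    rng = np.random.default_rng(7)
    sheet = make_sample_sheet(["MSN", "MBN"], 4)
    raw = pd.DataFrame(
        np.exp(rng.normal(0.0, 1.0, size=(25, len(sheet)))),
        index=[f"g{i:03d}" for i in range(25)],
        columns=sheet.index,
    )
    values = raw / raw.median(axis=0)
    return ExpressionDataset(values, sheet, "normalized")


def vectors_with_correlation(r: float, k: int = 4, seed: int = 0):
    """Two k-vectors whose sample Pearson correlation is exactly r.

    Construction: take any x, build e orthogonal to (x - mean) with zero
    mean, standardize both, and return y = r * x_std + sqrt(1-r^2) * e_std.
    Used as an independent geometric oracle for correlation boundaries.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(k)
    e = rng.standard_normal(k)
    xc = x - x.mean()
    ec = e - e.mean()
    ec = ec - (ec @ xc) / (xc @ xc) * xc  # orthogonal to xc, still zero-mean
    xs = xc / np.sqrt(xc @ xc)
    es = ec / np.sqrt(ec @ ec)
    y = r * xs + np.sqrt(1.0 - r**2) * es
    return x, y
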