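"""Spot-level preprocessing: quality filtering, background subtraction,
median normalization and redundant-probe averaging.

Pipeline order is fixed: filter -> subtract -> completeness drop ->
normalize -> collapse.  A spot survives filtering only if it is not flagged
corrupted, maps to a gene, and its foreground is at least twice its
background (the boundary case foreground == 2 x background passes, reading
"less than twice" literally).  Any probe missing from at least one sample
after filtering is dropped from all samples, so the final gene matrix is
complete.  Each sample column is divided by its own median net signal
before probes are averaged into genes; the per-column median is checked,
but not re-applied, after collapsing.
"""

from __future__ import annotations

import dataclasses
import warnings as _warnings
from typing import Iterable

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, MEDIAN_TOL

SPOT_COLUMNS = ["probe_id", "gene_symbol", "sample_id", "foreground", "background", "corrupted"]


@dataclasses.dataclass(frozen=True)
class SpotMeasurement:
    """One array spot: raw foreground/background fluorescence for a sample."""

    probe_id: str
    gene_symbol: str
    sample_id: str
    foreground: float
    background: float
    corrupted: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.foreground) and self.foreground >= 0):
            raise ValueError(f"foreground must be finite and >= 0: {self.foreground}")
        if not (np.isfinite(self.background) and self.background >= 0):
            raise ValueError(f"background must be finite and >= 0: {self.background}")


def _as_frame(spots: Iterable[SpotMeasurement] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(spots, pd.DataFrame):
        missing = set(SPOT_COLUMNS) - set(spots.columns)
        if missing:
            raise ValueError(f"spot table missing columns {sorted(missing)}")
        return spots.loc[:, SPOT_COLUMNS].reset_index(drop=True)
    return pd.DataFrame([dataclasses.asdict(s) for s in spots], columns=SPOT_COLUMNS)


def filter_spots(
    spots: Iterable[SpotMeasurement] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop corrupted, unmapped and low-signal spots.

    Returns (retained spots, drop log).  The drop log has one row per
    dropped spot with columns probe_id, sample_id, reason in
    {corrupted, unmapped, low_signal}.
    """
    frame = _as_frame(spots)
    fg = frame["foreground"].to_numpy(dtype=float)
    bg = frame["background"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(fg)) and np.all(np.isfinite(bg))):
        raise ValueError("foreground/background must be finite")
    if np.any(fg < 0) or np.any(bg < 0):
        raise ValueError("foreground/background must be >= 0")

    corrupted = frame["corrupted"].astype(bool).to_numpy()
    unmapped = frame["gene_symbol"].fillna("").eq("").to_numpy()
    low = fg < 2.0 * bg  # foreground exactly 2x background is retained

    reason = np.full(len(frame), "", dtype=object)
    reason[low] = "low_signal"
    reason[unmapped] = "unmapped"
    reason[corrupted] = "corrupted"  # highest precedence
    dropped = reason != ""

    drop_log = frame.loc[dropped, ["probe_id", "sample_id"]].copy()
    drop_log["reason"] = reason[dropped]
    return frame.loc[~dropped].reset_index(drop=True), drop_log.reset_index(drop=True)


def background_subtract(
    retained: pd.DataFrame, samples: Iterable[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Net signal table (probe x sample) with the completeness rule applied.

    ``net = foreground - background``.  Spots with non-positive net signal
    are dropped (reason "nonpositive_net"); a probe absent from any sample
    of the universe (default: all sample ids seen in ``retained``) is then
    removed from every sample (reason "incomplete").  Returns
    (net table, drop log).
    """
    frame = retained.copy()
    frame["net"] = frame["foreground"] - frame["background"]
    bad = frame["net"] <= 0
    log_rows = frame.loc[bad, ["probe_id", "sample_id"]].copy()
    log_rows["reason"] = "nonpositive_net"
    frame = frame.loc[~bad]

    universe = list(samples) if samples is not None else sorted(frame["sample_id"].unique())
    net = frame.pivot_table(
        index="probe_id", columns="sample_id", values="net", aggfunc="mean"
    ).reindex(columns=universe)
    incomplete = net.isna().any(axis=1)
    inc_rows = pd.DataFrame(
        {"probe_id": net.index[incomplete], "sample_id": "*", "reason": "incomplete"}
    )
    net = net.loc[~incomplete]
    drop_log = pd.concat([log_rows, inc_rows], ignore_index=True)
    return net, drop_log


def normalize_to_median(net: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each sample column by its own median net signal.

    Returns (normalized table, per-sample normalization factors).  The
    factors are the median net signals; after division every column's
    median equals 1 (exactly, for odd probe counts).
    """
    factors = net.median(axis=0)
    if (factors <= 0).any() or not np.all(np.isfinite(factors.to_numpy())):
        bad = factors.index[(factors <= 0) | ~np.isfinite(factors)].tolist()
        raise ValueError(f"non-positive median net signal in samples {bad}")
    return net / factors, factors


def collapse_probes(
    normalized: pd.DataFrame,
    probe_to_gene: pd.Series | dict,
    sample_sheet: pd.DataFrame,
    median_warn_tol: float = 0.05,
) -> ExpressionDataset:
    """Average redundant probes of the same gene into one row per gene.

    ``probe_to_gene`` maps probe_id -> gene symbol; probes without a mapping
    are ignored.  The per-column median of the collapsed matrix is checked
    against 1 and a warning is emitted if it drifted by more than
    ``median_warn_tol`` — the matrix is reported as-is, never renormalized,
    because normalization is a single step taken at probe level.
    """
    mapping = pd.Series(probe_to_gene)
    genes = mapping.reindex(normalized.index)
    keep = genes.notna() & (genes != "")
    collapsed = normalized.loc[keep].groupby(genes[keep]).mean()
    if collapsed.empty:
        raise ValueError("no probes map to any gene")

    med = collapsed.median(axis=0)
    drift = float((med - 1.0).abs().max())
    state = "normalized" if drift <= MEDIAN_TOL else "collapsed"
    if drift > median_warn_tol:
        _warnings.warn(
            f"per-sample median drifted from 1 by up to {drift:.3g} after "
            "probe collapsing; matrix left unrenormalized",
            stacklevel=2,
        )
    collapsed.index.name = "gene"
    return ExpressionDataset(collapsed, sample_sheet.loc[collapsed.columns], state)


def normalize_dataset(dataset: ExpressionDataset) -> ExpressionDataset:
    """Median-normalize a gene-level dataset (each sample to its median gene)."""
    normalized, _ = normalize_to_median(dataset.values)
    return dataset.with_values(normalized, "normalized")


def preprocess_pipeline(
    spots: Iterable[SpotMeasurement] | pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> tuple[ExpressionDataset, pd.DataFrame, pd.Series]:
    """Full spot-to-gene pipeline.

    Returns (gene-level dataset, drop log, normalization factors).  The
    sample universe for the completeness rule is the sample sheet, so a
    probe must survive filtering in every declared sample to be kept.
    """
    retained, log1 = filter_spots(spots)
    net, log2 = background_subtract(retained, samples=list(sample_sheet.index))
    normalized, factors = normalize_to_median(net)
    probe_to_gene = (
        retained.drop_duplicates("probe_id").set_index("probe_id")["gene_symbol"]
    )
    dataset = collapse_probes(normalized, probe_to_gene, sample_sheet)
    drop_log = pd.concat([log1, log2], ignore_index=True)
    return dataset, drop_log, factors
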