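"""Gene Commanding Height and Gene Master Regulator identification.

The commanding height of a gene in a condition combines its expression
control with the median of its expression coordination with every other
quantified gene (not just pathway partners):

    GCH = exp( REC + 2 * median_j( r_ij^2 ) )        (default form)

A gene that is exactly median-controlled (REC = 0) and uncorrelated with
everything has GCH = 1.  Tight control (large positive REC) and strong
coordination both raise GCH monotonically.  The top-ranked gene of a
condition is its Gene Master Regulator — the presumptive most influential
gene, whose manipulation is expected to propagate most widely through the
transcriptome.  An alternative form using the median absolute correlation
is available for comparison.

Genes with degenerate control (zero replicate variance, RCS = infinity)
are excluded from the ranking and reported, to avoid sentinel propagation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .metrics import DEGENERATE_CONTROL

#: Minimum correlation partners for a trustworthy coordination median.
LOW_SUPPORT = 10


def _cor_summary(partner_r: np.ndarray, form: str) -> float:
    r = np.asarray(partner_r, dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        return 0.0
    if form == "exp_rec_plus_2_median_sq_cor":
        return float(np.median(r**2))
    if form == "exp_rec_plus_2_median_abs_cor":
        return float(np.median(np.abs(r)))
    raise ValueError(f"unknown GCH form {form!r}")


def compute_gch(
    rec: float,
    partner_correlations: np.ndarray,
    form: str = "exp_rec_plus_2_median_sq_cor",
) -> tuple[float, float, bool]:
    """(GCH, cor_summary, low_support) for one gene.

    ``partner_correlations`` are the gene's correlations with all other
    quantified genes; nan entries (undefined partners) are ignored.  Fewer
    than 10 usable partners set the low-support flag.
    """
    summary = _cor_summary(partner_correlations, form)
    usable = int(np.sum(~np.isnan(np.asarray(partner_correlations, dtype=float))))
    gch = float(np.exp(rec + 2.0 * summary))
    return gch, summary, usable < LOW_SUPPORT


@dataclasses.dataclass
class GmrCall:
    """The Gene Master Regulator of one condition (all tied genes listed)."""

    condition: str
    genes: list[str]
    gch: float
    margin: float  # GCH gap between rank 1 and rank 2 (0 on ties)


def rank_gch(
    dataset,
    profiles: pd.DataFrame,
    condition: str,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, GmrCall]:
    """Rank every quantified gene of a condition by commanding height.

    ``profiles`` is the long-format fabric table covering the condition.
    Correlations run over the full transcriptome of the dataset.  Returns
    (records, gmr): records indexed by gene with REC, cor_summary, GCH,
    rank, low_support; ties broken lexicographically for rank order, but a
    tie at the top lists all tied genes in the GMR call with margin 0.
    """
    config = config or AnalysisConfig()
    prof = profiles[profiles["condition"] == condition].set_index("gene")
    keep = prof.index[prof["flag"] != DEGENERATE_CONTROL]
    excluded = sorted(prof.index.difference(keep))

    sub = dataset.condition_values(condition).loc[keep]
    logv = np.log2(sub.to_numpy(dtype=float))
    sd = logv.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmat = np.corrcoef(logv)
    rmat[sd == 0.0, :] = np.nan
    rmat[:, sd == 0.0] = np.nan
    np.fill_diagonal(rmat, np.nan)

    if config.gch_form == "exp_rec_plus_2_median_sq_cor":
        summary = np.nanmedian(rmat**2, axis=1)
    else:
        summary = np.nanmedian(np.abs(rmat), axis=1)
    usable = np.sum(~np.isnan(rmat), axis=1)

    rec = prof.loc[keep, "REC"].to_numpy(dtype=float)
    gch = np.exp(rec + 2.0 * summary)

    records = pd.DataFrame(
        {
            "gene": keep,
            "condition": condition,
            "REC": rec,
            "cor_summary": summary,
            "GCH": gch,
            "low_support": usable < LOW_SUPPORT,
        }
    ).set_index("gene")
    order = records.sort_values(["GCH", "gene"], ascending=[False, True]).index
    records["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    records.attrs["excluded_degenerate"] = excluded

    top = records["GCH"].max()
    tied = sorted(records.index[records["GCH"] == top])
    runners = records.loc[~records.index.isin(tied), "GCH"]
    margin = 0.0 if len(tied) > 1 else float(top - (runners.max() if len(runners) else top))
    gmr = GmrCall(condition=condition, genes=tied, gch=float(top), margin=margin)
    return records.sort_values("rank"), gmr


def top_gch_by_pathway(
    records: pd.DataFrame, catalog, k: int = 5
) -> pd.DataFrame:
    """Top-k commanding-height genes restricted to each pathway."""
    rows = []
    for code, members in sorted(catalog.quantified.items()):
        sub = records.loc[records.index.intersection(members)]
        sub = sub.sort_values(["GCH", "gene"], ascending=[False, True]).head(k)
        for gene, row in sub.iterrows():
            rows.append(
                {
                    "pathway": code,
                    "name": catalog.catalog.names[code],
                    "gene": gene,
                    "GCH": row["GCH"],
                    "rank_overall": int(row["rank"]),
                }
            )
    return pd.DataFrame(rows, columns=["pathway", "name", "gene", "GCH", "rank_overall"])
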