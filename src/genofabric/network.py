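"""Pairwise expression coordination and its between-group dichotomy.

The coordination of two genes within a condition is the Pearson correlation
of their log2 normalized expression levels across that condition's K
replicates (conditions are never pooled).  Significance comes from the
exact t-transform with K - 2 degrees of freedom, two-tailed.  Pairs are
classified three ways:

* **synergistic** — significantly positive correlation (either gene's
  expression stimulates the other's),
* **antagonistic** — significantly negative,
* **independent** — |r| at most a small band (default 0.05), operationalizing
  "total decoupling": with K = 4 an independence call cannot be made from
  the p-value, so a near-zero band is required for a three-way partition.

Pairs in neither band are **indeterminate** and never counted as switches.
At K = 4 the null distribution of the sample correlation is exactly uniform
on [-1, 1], so the two-tailed 5% significance boundary is |r| = 0.95
exactly, and the independence band |r| <= 0.05 holds 5% of null pairs.

The dichotomy comparison behind the sex-difference matrices lists pairs
that are significantly correlated with opposite signs in two groups, pairs
independent in one group but significant in the other ("gained"), and the
reverse ("lost").
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

CLASSES = ("synergistic", "antagonistic", "independent", "indeterminate")


def correlation_p(r: np.ndarray | float, k: int) -> np.ndarray | float:
    """Two-tailed p for a Pearson correlation from K observations.

    Uses the exact t-transform t = r * sqrt((K-2)/(1-r^2)) with K - 2
    degrees of freedom; |r| = 1 gives p = 0.  Requires K >= 3.
    """
    if k < 3:
        raise ValueError("need K >= 3 replicates for a defined p-value")
    r = np.asarray(r, dtype=float)
    r2 = np.clip(r**2, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt((k - 2) / (1.0 - r2))
    p = np.where(r2 >= 1.0, 0.0, 2.0 * stats.t.sf(t, k - 2))
    p = np.where(np.isnan(r), np.nan, p)
    return float(p) if p.ndim == 0 else p


def critical_r(k: int, alpha: float = 0.05) -> float:
    """Two-tailed significance boundary on |r| at K observations."""
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, k - 2)
    return float(t_crit / np.sqrt(t_crit**2 + (k - 2)))


def compute_cor(dataset, gene_a: str, gene_b: str, condition: str) -> tuple[float, float]:
    """(r, p) for one unordered gene pair in one condition.

    r is the Pearson correlation of log2 normalized replicate values; a
    zero-variance gene leaves r (and p) undefined (nan).
    """
    if gene_a == gene_b:
        raise ValueError("correlation of a gene with itself is excluded")
    sub = dataset.condition_values(condition)
    a = np.log2(sub.loc[gene_a].to_numpy(dtype=float))
    b = np.log2(sub.loc[gene_b].to_numpy(dtype=float))
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, float(correlation_p(r, a.size))


def classify_pair(r: float, p: float, config: AnalysisConfig | None = None) -> str:
    """Three-way class with significance taking precedence over the
    independence band; undefined correlations are indeterminate."""
    config = config or AnalysisConfig()
    if np.isnan(r) or np.isnan(p):
        return "indeterminate"
    if p < config.alpha_cor:
        return "synergistic" if r > 0 else "antagonistic"
    if abs(r) <= config.independence_threshold:
        return "independent"
    return "indeterminate"


def pathway_cor_matrix(
    dataset,
    condition: str,
    genes: list[str] | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """All unordered pairs of the given genes in one condition (long format).

    Columns: gene_a, gene_b, condition, r, p, class; gene_a < gene_b
    lexicographically so each pair appears once.  Fewer than 2 genes yield
    an empty frame.  ``attrs["square"]`` holds the symmetric r matrix.
    """
    config = config or AnalysisConfig()
    genes = sorted(genes) if genes is not None else sorted(dataset.genes)
    cols = ["gene_a", "gene_b", "condition", "r", "p", "class"]
    if len(genes) < 2:
        out = pd.DataFrame(columns=cols)
        out.attrs["square"] = pd.DataFrame(index=genes, columns=genes, dtype=float)
        return out

    sub = dataset.condition_values(condition).loc[genes]
    logv = np.log2(sub.to_numpy(dtype=float))
    sd = logv.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rmat = np.corrcoef(logv)
    rmat[sd == 0.0, :] = np.nan
    rmat[:, sd == 0.0] = np.nan

    iu, ju = np.triu_indices(len(genes), k=1)
    r = rmat[iu, ju]
    p = correlation_p(r, sub.shape[1])
    # vectorized classify_pair (same precedence: significance, then band)
    classes = np.select(
        [
            np.isnan(r) | np.isnan(p),
            (p < config.alpha_cor) & (r > 0),
            (p < config.alpha_cor) & (r < 0),
            np.abs(r) <= config.independence_threshold,
        ],
        ["indeterminate", "synergistic", "antagonistic", "independent"],
        default="indeterminate",
    )
    out = pd.DataFrame(
        {
            "gene_a": np.asarray(genes)[iu],
            "gene_b": np.asarray(genes)[ju],
            "condition": condition,
            "r": r,
            "p": p,
            "class": classes,
        }
    )
    out.attrs["square"] = pd.DataFrame(rmat, index=genes, columns=genes)
    return out


@dataclasses.dataclass
class DichotomyReport:
    """Coordination switches between two groups over the same gene set."""

    label_a: str
    label_b: str
    opposite_pairs: list[tuple[str, str]]
    gained_pairs: list[tuple[str, str]]   # independent in A, significant in B
    lost_pairs: list[tuple[str, str]]     # significant in A, independent in B

    @property
    def counts(self) -> dict[str, int]:
        return {
            "opposite": len(self.opposite_pairs),
            "gained": len(self.gained_pairs),
            "lost": len(self.lost_pairs),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "switch": kind}
            for kind, pairs in (
                ("opposite", self.opposite_pairs),
                ("gained", self.gained_pairs),
                ("lost", self.lost_pairs),
            )
            for a, b in pairs
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "switch"])


def dichotomy_compare(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    label_a: str | None = None,
    label_b: str | None = None,
) -> DichotomyReport:
    """Classify coordination switches between two correlation matrices.

    Both inputs are long-format frames from :func:`pathway_cor_matrix` over
    the same gene set.  Indeterminate pairs contribute to no list.
    """
    pa = matrix_a.set_index(["gene_a", "gene_b"])["class"]
    pb = matrix_b.set_index(["gene_a", "gene_b"])["class"]
    if set(pa.index) != set(pb.index):
        diff = sorted(set(pa.index) ^ set(pb.index))
        raise ValueError(f"matrices cover different gene pairs: {diff[:10]}")

    sig = ("synergistic", "antagonistic")
    opposite, gained, lost = [], [], []
    for pair in pa.index:
        ca, cb = pa[pair], pb[pair]
        if ca in sig and cb in sig and ca != cb:
            opposite.append(pair)
        elif ca == "independent" and cb in sig:
            gained.append(pair)
        elif ca in sig and cb == "independent":
            lost.append(pair)
    la = label_a or (matrix_a["condition"].iloc[0] if len(matrix_a) else "A")
    lb = label_b or (matrix_b["condition"].iloc[0] if len(matrix_b) else "B")
    return DichotomyReport(la, lb, opposite, gained, lost)
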