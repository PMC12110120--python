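"""Composite differential-expression criterion with gene-specific cutoffs.

A gene is called significantly regulated between two condition groups when
it passes both clauses of a composite criterion:

* the absolute signed expression ratio ``|x|`` exceeds a gene-specific
  cutoff ``CUT = 1 + coeff * sqrt(REV_c^2 + REV_r^2)`` built from the two
  groups' relative expression variabilities (default coefficient
  sqrt(2)/100, so two 10%-noise groups give CUT = 1.2), and
* a two-tailed heteroscedastic (Welch) t-test of the replicate means gives
  p below alpha.

Because CUT >= 1 always, a gene with identical means (|x| = 1) can never be
called regulated no matter how small p is; the cutoff clause only removes
calls, so the composite criterion's type-I rate is bounded by alpha.  No
multiple-testing correction is applied by default, mirroring raw p < 0.05
usage; a Benjamini-Hochberg mode is available but off by default.
"""

from __future__ import annotations

import warnings as _warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datamodel import BoundCatalog

VERDICTS = ("up", "down", "not_significant")


def expression_ratio(
    ave_compared: float | np.ndarray, ave_reference: float | np.ndarray
) -> float | np.ndarray:
    """Signed expression ratio, |x| >= 1, negative for lower expression in
    the compared group; equality yields -1."""
    c = np.asarray(ave_compared, dtype=float)
    r = np.asarray(ave_reference, dtype=float)
    if np.any(c <= 0) or np.any(r <= 0):
        raise ValueError("AVE values must be positive")
    out = np.where(c > r, c / r, -r / c)
    return float(out) if out.ndim == 0 else out


def welch_p(
    values_compared: np.ndarray, values_reference: np.ndarray
) -> tuple[float, float, float]:
    """Welch's unequal-variance two-tailed t-test.

    Returns (t, Welch-Satterthwaite df, p).  Both groups need >= 2 values.
    If both variances are zero: equal means give p = 1; different means are
    degenerate and treated as p = 0 with a warning.
    """
    a = np.asarray(values_compared, dtype=float)
    b = np.asarray(values_reference, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        _warnings.warn(
            "zero variance in both groups with unequal means; p treated as 0",
            stacklevel=2,
        )
        return np.inf if a.mean() > b.mean() else -np.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def compute_cut(
    rev_compared: float | np.ndarray,
    rev_reference: float | np.ndarray,
    cut_coefficient: float = AnalysisConfig().cut_coefficient,
) -> float | np.ndarray:
    """Gene-specific fold-change cutoff; 1 in the noise-free limit."""
    c = np.asarray(rev_compared, dtype=float)
    r = np.asarray(rev_reference, dtype=float)
    if np.any(c < 0) or np.any(r < 0):
        raise ValueError("REV values must be >= 0")
    out = 1.0 + cut_coefficient * np.sqrt(c**2 + r**2)
    return float(out) if out.ndim == 0 else out


def classify_regulation(
    x: float, p: float, cut: float, config: AnalysisConfig | None = None
) -> str:
    """Verdict of the composite criterion for one gene."""
    config = config or AnalysisConfig()
    if abs(x) > cut and p < config.alpha_de:
        return "up" if x > 0 else "down"
    return "not_significant"


def regulome(
    dataset,
    profiles: pd.DataFrame,
    compared: str,
    reference: str,
    catalog: BoundCatalog | None = None,
    config: AnalysisConfig | None = None,
    fdr: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regulation records for every quantified gene in one comparison.

    Parameters
    ----------
    profiles:
        Long-format fabric table from :func:`genofabric.metrics.fabric_profiles`
        covering both conditions.
    catalog:
        Optional bound pathway catalog; when given, a per-pathway summary of
        up/down counts restricted to catalog membership is returned.
    fdr:
        Apply Benjamini-Hochberg adjustment to the p-values before the
        significance clause (off by default).

    Returns
    -------
    (records, summaries):
        records has one row per gene with x, p, CUT and verdict; summaries
        has one row per pathway (a single "all genes" row when no catalog).
    """
    if compared == reference:
        raise ValueError("cannot compare a condition with itself")
    config = config or AnalysisConfig()

    a = dataset.condition_values(compared).to_numpy(dtype=float)
    b = dataset.condition_values(reference).to_numpy(dtype=float)
    genes = dataset.genes

    pc = profiles[profiles["condition"] == compared].set_index("gene").loc[genes]
    pr = profiles[profiles["condition"] == reference].set_index("gene").loc[genes]

    x = expression_ratio(pc["AVE"].to_numpy(), pr["AVE"].to_numpy())
    cut = compute_cut(
        pc["REV"].to_numpy(), pr["REV"].to_numpy(), config.cut_coefficient
    )
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate rows (zero variance in both groups) yield nan from the test
    both_const = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    if both_const.any():
        equal = a.mean(axis=1) == b.mean(axis=1)
        p = np.where(both_const, np.where(equal, 1.0, 0.0), p)

    p_eff = _bh_adjust(p) if fdr else p
    significant = (np.abs(x) > cut) & (p_eff < config.alpha_de)
    verdict = np.where(significant, np.where(x > 0, "up", "down"), "not_significant")

    records = pd.DataFrame(
        {
            "gene": genes,
            "compared": compared,
            "reference": reference,
            "x": x,
            "p": p,
            "CUT": cut,
            "verdict": verdict,
        }
    )

    summaries = _summarize(records, catalog, f"{compared}_vs_{reference}")
    return records, summaries


def _summarize(
    records: pd.DataFrame, catalog: BoundCatalog | None, label: str
) -> pd.DataFrame:
    rows = []
    if catalog is None:
        groups = {(-1, "all"): records["gene"].tolist()}
    else:
        groups = {
            (code, catalog.catalog.names[code]): members
            for code, members in catalog.quantified.items()
        }
    indexed = records.set_index("gene")
    for (code, name), members in sorted(groups.items()):
        sub = indexed.loc[indexed.index.intersection(members)]
        up = sorted(sub.index[sub["verdict"] == "up"])
        down = sorted(sub.index[sub["verdict"] == "down"])
        rows.append(
            {
                "pathway": code,
                "name": name,
                "comparison": label,
                "n_quantified": len(sub),
                "n_up": len(up),
                "n_down": len(down),
                "up_genes": ",".join(up),
                "down_genes": ",".join(down),
            }
        )
    return pd.DataFrame(rows)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out


def standard_comparisons(conditions: list[str] | None = None) -> list[tuple[str, str]]:
    """The study's comparison plan: within sex BN vs SN and BY vs BN, and
    male vs female (female reference) within each condition."""
    conditions = conditions or ["MSN", "FSN", "MBN", "FBN", "MBY", "FBY"]
    present = set(conditions)
    out: list[tuple[str, str]] = []
    for sex in ("M", "F"):
        for comp, ref in ((f"{sex}BN", f"{sex}SN"), (f"{sex}BY", f"{sex}BN")):
            if {comp, ref} <= present:
                out.append((comp, ref))
    for arm in ("SN", "BN", "BY"):
        if {f"M{arm}", f"F{arm}"} <= present:
            out.append((f"M{arm}", f"F{arm}"))
    return out
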