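"""Per-gene, per-condition transcriptome-topology metrics.

Three independent measures characterize each quantified gene in each
condition:

* **AVE** — average expression level across the K biological replicates, in
  units of the median gene (the dataset is median-normalized per sample).
* **REV** — relative expression variability: the coefficient of variation
  sd/AVE corrected by the midinterval of the two-sided chi-square
  confidence bounds on the CV, reported in percent.  With r = K - 1 degrees
  of freedom and tail probability beta, the correction factor is

      1/2 * [ sqrt(r / chi2(1-beta; r)) + sqrt(r / chi2(beta; r)) ]

  which tends to 1 as r grows (the CV estimator is consistent).
* **REC / RCS** — relative expression control.  RCS = median(REV) / REV
  measures how many times more tightly the gene is controlled than the
  median gene of the condition; REC = log2(RCS) is its log form, so the
  median-REV gene has REC = 0 and positive REC means stricter control.

Control strengths of a gene in two groups are compared through a signed
fold-change whose magnitude is always >= 1, negative when control is weaker
in the compared group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig

#: Sentinel flag for genes with zero replicate variance (REV = 0, RCS = inf).
DEGENERATE_CONTROL = "degenerate_control"


def chi2_midinterval_factor(
    df: int | np.ndarray, beta: float, form: str = "midpoint"
) -> float | np.ndarray:
    """Chi-square interval correction of the CV estimator.

    ``midpoint`` (default) returns the midinterval of the two-sided
    confidence bounds sqrt(df/chi2(1-beta)) and sqrt(df/chi2(beta));
    ``halfwidth`` returns half their difference (the alternative reading of
    the corrupted source formula, kept for comparison).
    """
    df = np.asarray(df, dtype=float)
    if np.any(df < 1):
        raise ValueError("degrees of freedom must be >= 1")
    if not (0.0 < beta < 0.5):
        raise ValueError("beta must be in (0, 0.5)")
    lo = np.sqrt(df / stats.chi2.ppf(1.0 - beta, df))
    hi = np.sqrt(df / stats.chi2.ppf(beta, df))
    if form == "midpoint":
        out = 0.5 * (lo + hi)
    elif form == "halfwidth":
        out = 0.5 * (hi - lo)
    else:
        raise ValueError(f"unknown factor form {form!r}")
    return out.item() if out.ndim == 0 else out


def compute_ave(values: np.ndarray | pd.Series) -> tuple[float, float]:
    """(mean, sample sd) of one gene's replicate values in one condition."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicates")
    return float(arr.mean()), float(arr.std(ddof=1))


def compute_rev(
    ave: float | np.ndarray,
    sd: float | np.ndarray,
    df: int | np.ndarray,
    beta: float,
    form: str = "midpoint",
) -> float | np.ndarray:
    """REV in percent: chi-square-corrected CV x 100.  Requires AVE > 0."""
    ave = np.asarray(ave, dtype=float)
    if np.any(ave <= 0):
        raise ValueError("AVE must be positive")
    out = chi2_midinterval_factor(df, beta, form) * (np.asarray(sd) / ave) * 100.0
    return float(out) if np.ndim(out) == 0 else out


def condition_profile(
    dataset, condition: str, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Fabric profile of every gene in one condition.

    Returns a DataFrame indexed by gene with columns AVE, sd, df, REV, RCS,
    REC, flag.  Genes with zero replicate variance have REV = 0, RCS = inf,
    REC = inf and are flagged ``degenerate_control``; they are excluded
    from the condition's median REV.
    """
    config = config or AnalysisConfig()
    sub = dataset.condition_values(condition)
    arr = sub.to_numpy(dtype=float)
    k = arr.shape[1]
    ave = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    df = k - 1
    rev = compute_rev(ave, sd, df, config.beta_chi2, config.rev_factor_form)

    degenerate = rev == 0.0
    if degenerate.all():
        raise ValueError(f"all genes have zero variance in condition {condition}")
    median_rev = float(np.median(rev[~degenerate]))

    with np.errstate(divide="ignore"):
        rcs = median_rev / rev
        rec = np.log2(rcs)

    out = pd.DataFrame(
        {
            "gene": sub.index,
            "condition": condition,
            "AVE": ave,
            "sd": sd,
            "df": df,
            "REV": rev,
            "RCS": rcs,
            "REC": rec,
            "flag": np.where(degenerate, DEGENERATE_CONTROL, ""),
        }
    ).set_index("gene")
    out.attrs["median_REV"] = median_rev
    return out


def fabric_profiles(
    dataset, config: AnalysisConfig | None = None, conditions: list[str] | None = None
) -> pd.DataFrame:
    """Tidy fabric table over several conditions (long format).

    One row per (gene, condition); ``attrs["condition_summary"]`` carries
    the per-condition median REV and gene count.
    """
    config = config or AnalysisConfig()
    conditions = conditions or dataset.conditions
    pieces, summary = [], []
    for cond in conditions:
        prof = condition_profile(dataset, cond, config)
        pieces.append(prof.reset_index())
        summary.append(
            {
                "condition": cond,
                "median_REV": prof.attrs["median_REV"],
                "gene_count": int((prof["flag"] == "").sum()),
            }
        )
    out = pd.concat(pieces, ignore_index=True)
    out.attrs["condition_summary"] = pd.DataFrame(summary)
    return out


def rcs_fold_change(
    rcs_compared: float | np.ndarray, rcs_reference: float | np.ndarray
) -> float | np.ndarray:
    """Signed fold-change of control strength between two groups.

    FC = RCS_c / RCS_r when the compared group is more tightly controlled,
    else -RCS_r / RCS_c; magnitude always >= 1, equality yields -1 (no
    change, never reported as regulation).
    """
    c = np.asarray(rcs_compared, dtype=float)
    r = np.asarray(rcs_reference, dtype=float)
    if np.any(c <= 0) or np.any(r <= 0):
        raise ValueError("RCS values must be positive")
    out = np.where(c > r, c / r, -r / c)
    return float(out) if out.ndim == 0 else out


def control_comparison(
    profiles: pd.DataFrame, compared: str, reference: str
) -> pd.DataFrame:
    """Per-gene RCS fold-change table between two profiled conditions."""
    pc = profiles[profiles["condition"] == compared].set_index("gene")
    pr = profiles[profiles["condition"] == reference].set_index("gene")
    common = pc.index.intersection(pr.index)
    ok = (pc.loc[common, "flag"] == "") & (pr.loc[common, "flag"] == "")
    genes = common[ok]
    return pd.DataFrame(
        {
            "gene": genes,
            "compared": compared,
            "reference": reference,
            "RCS_compared": pc.loc[genes, "RCS"].to_numpy(),
            "RCS_reference": pr.loc[genes, "RCS"].to_numpy(),
            "FC": rcs_fold_change(
                pc.loc[genes, "RCS"].to_numpy(), pr.loc[genes, "RCS"].to_numpy()
            ),
        }
    )
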