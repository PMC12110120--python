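"""Analysis configuration: significance levels and cutoff coefficients.

All thresholds used by the fabric metrics, the regulome criterion, the
coordination classifier and the GCH ranking live in a single record so a
run is fully described by (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from pathlib import Path

import yaml

#: Functional forms accepted for the Gene Commanding Height score.
GCH_FORMS = ("exp_rec_plus_2_median_sq_cor", "exp_rec_plus_2_median_abs_cor")

#: Parses accepted for the chi-square interval correction of the CV.
REV_FACTOR_FORMS = ("midpoint", "halfwidth")


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and pluggable functional forms for a full analysis run.

    Parameters
    ----------
    alpha_de:
        Two-tailed significance level of the heteroscedastic t-test in the
        composite differential-expression criterion.
    alpha_cor:
        Two-tailed significance level for pairwise expression correlation.
    beta_chi2:
        Tail probability of the chi-square interval used to correct the
        coefficient of variation (0.025 gives the central 95% interval).
    independence_threshold:
        Largest absolute correlation still counted as "independent"
        expression of a gene pair.
    cut_coefficient:
        Multiplier of the combined-noise term in the gene-specific
        fold-change cutoff, default sqrt(2)/100.
    gch_form:
        Name of the Gene Commanding Height functional form.
    rev_factor_form:
        Parse of the chi-square CV correction: "midpoint" (default) uses the
        midinterval of the two-sided confidence bounds, "halfwidth" their
        half-difference.
    seed:
        Default seed for any randomized step.
    """

    alpha_de: float = 0.05
    alpha_cor: float = 0.05
    beta_chi2: float = 0.025
    independence_threshold: float = 0.05
    cut_coefficient: float = math.sqrt(2.0) / 100.0
    gch_form: str = "exp_rec_plus_2_median_sq_cor"
    rev_factor_form: str = "midpoint"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_de < 1.0):
            raise ValueError(f"alpha_de must be in (0, 1), got {self.alpha_de}")
        if not (0.0 < self.alpha_cor < 1.0):
            raise ValueError(f"alpha_cor must be in (0, 1), got {self.alpha_cor}")
        if not (0.0 < self.beta_chi2 < 0.5):
            raise ValueError(f"beta_chi2 must be in (0, 0.5), got {self.beta_chi2}")
        if self.independence_threshold < 0.0:
            raise ValueError("independence_threshold must be >= 0")
        if self.gch_form not in GCH_FORMS:
            raise ValueError(f"gch_form must be one of {GCH_FORMS}")
        if self.rev_factor_form not in REV_FACTOR_FORMS:
            raise ValueError(f"rev_factor_form must be one of {REV_FACTOR_FORMS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d or {})

    def digest(self) -> str:
        """Short stable hash of the configuration, for output provenance."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
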