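"""Core domain types: condition codes, gene annotations, expression datasets
and pathway catalogs.

The experimental design has six condition groups labeled by three letters:
sex (M/F), prenatal priming (S = saline, B = betamethasone) and presence of
NMDA-triggered spasms (Y/N).  Only the SN, BN and BY arms exist — saline
priming is never followed by spasms.  Each condition carries the same number
K of biological replicates (K = 4 in the original design).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The six study condition codes, in canonical order.
STUDY_CONDITIONS = ("MSN", "FSN", "MBN", "FBN", "MBY", "FBY")

#: Pathway code -> short name for the six neurotransmission gene sets.
PATHWAY_NAMES = {0: "SVC", 1: "GLU", 2: "GABA", 3: "ACh", 4: "DA", 5: "5HT"}
PATHWAY_CODES = {v: k for k, v in PATHWAY_NAMES.items()}

#: Median tolerance for a dataset that claims to be median-normalized.
MEDIAN_TOL = 1e-9


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclasses.dataclass(frozen=True)
class SampleCondition:
    """One of the six sex x priming x spasms groups."""

    sex: str        # "M" or "F"
    priming: str    # "S" (saline) or "B" (betamethasone)
    spasms: str     # "Y" or "N"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.priming not in ("S", "B"):
            raise ValueError(f"priming must be S or B, got {self.priming!r}")
        if self.spasms not in ("Y", "N"):
            raise ValueError(f"spasms must be Y or N, got {self.spasms!r}")
        if self.priming == "S" and self.spasms == "Y":
            raise ValueError("saline-primed groups cannot have spasms (no SY arm)")

    @property
    def code(self) -> str:
        return self.sex + self.priming + self.spasms

    @classmethod
    def from_code(cls, code: str) -> "SampleCondition":
        if len(code) != 3:
            raise ValueError(f"condition code must have 3 letters, got {code!r}")
        return cls(sex=code[0], priming=code[1], spasms=code[2])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


@dataclasses.dataclass(frozen=True)
class GeneAnnotation:
    """A gene symbol with free-text description and pathway memberships."""

    symbol: str
    description: str = ""
    pathways: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be nonempty")
        bad = set(self.pathways) - set(PATHWAY_NAMES)
        if bad:
            raise ValueError(f"unknown pathway codes {sorted(bad)}")
        object.__setattr__(self, "pathways", frozenset(self.pathways))


class ExpressionDataset:
    """Complete genes x samples matrix of positive expression values.

    Rows are genes (unique symbols); columns are samples, each assigned to a
    condition code and a replicate index.  A dataset is only constructible if
    every gene is quantified in every sample (no missing cells) and every
    condition carries the same replicate count K >= 2.  When
    ``normalization_state == "normalized"`` the per-sample median over genes
    must equal 1 within 1e-9, i.e. values are expressed in units of the
    median gene.  The state ``"collapsed"`` marks a matrix normalized at
    probe level whose per-sample medians drifted during redundant-probe
    averaging; it is in median-gene units but deliberately not renormalized
    (normalization is a single, probe-level step).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: pd.DataFrame,
        normalization_state: str = "raw",
        annotations: Mapping[str, GeneAnnotation] | None = None,
    ) -> None:
        if normalization_state not in ("raw", "normalized", "collapsed"):
            raise ValueError(
                "normalization_state must be 'raw', 'normalized' or 'collapsed'"
            )
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dups}")
        if set(values.columns) != set(samples.index):
            missing = set(values.columns) ^ set(samples.index)
            raise FormatError(
                f"expression columns and sample sheet disagree on: {sorted(missing)}"
            )
        if not {"condition", "replicate"} <= set(samples.columns):
            raise FormatError("sample sheet needs 'condition' and 'replicate' columns")

        arr = values.to_numpy(dtype=float)
        if arr.size == 0:
            raise ValueError("empty dataset")
        if not np.all(np.isfinite(arr)):
            raise ValueError("dataset contains missing or non-finite values")
        if not np.all(arr > 0):
            raise ValueError("dataset contains non-positive values")

        # validate condition codes and replicate structure
        counts: dict[str, int] = {}
        for sid in samples.index:
            code = samples.loc[sid, "condition"]
            SampleCondition.from_code(code)
            counts[code] = counts.get(code, 0) + 1
        ks = set(counts.values())
        if len(ks) != 1:
            raise ValueError(f"unequal replicate counts per condition: {counts}")
        k = ks.pop()
        if k < 2:
            raise ValueError(f"need K >= 2 replicates per condition, got {k}")

        # order columns by condition (first appearance) then replicate
        order = sorted(
            samples.index,
            key=lambda s: (
                list(dict.fromkeys(samples["condition"])).index(samples.loc[s, "condition"]),
                int(samples.loc[s, "replicate"]),
            ),
        )
        self.values = values.loc[:, order].astype(float)
        self.samples = samples.loc[order].copy()
        self.samples["replicate"] = self.samples["replicate"].astype(int)
        self.samples.index.name = "sample_id"
        self.values.index.name = "gene"
        self.normalization_state = normalization_state
        self.annotations = dict(annotations or {})

        if normalization_state == "normalized":
            med = np.median(self.values.to_numpy(), axis=0)
            if np.any(np.abs(med - 1.0) > MEDIAN_TOL):
                worst = float(np.max(np.abs(med - 1.0)))
                raise ValueError(
                    "normalized dataset must have per-sample median 1 "
                    f"(max deviation {worst:.3g})"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    @property
    def replicates(self) -> int:
        """Replicate count K, identical for every condition."""
        return int((self.samples["condition"] == self.conditions[0]).sum())

    def condition_values(self, code: str) -> pd.DataFrame:
        """Genes x K sub-matrix for one condition, replicate-ordered."""
        cols = self.samples.index[self.samples["condition"] == code]
        if len(cols) == 0:
            raise KeyError(f"condition {code!r} not present")
        return self.values.loc[:, cols]

    def with_values(self, values: pd.DataFrame, state: str) -> "ExpressionDataset":
        return ExpressionDataset(values, self.samples, state, self.annotations)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionDataset({self.n_genes} genes, "
            f"{len(self.conditions)} conditions x K={self.replicates}, "
            f"{self.normalization_state})"
        )


@dataclasses.dataclass
class PathwayCatalog:
    """Named, possibly overlapping gene sets keyed by pathway code 0-5."""

    sets: dict[int, set[str]]
    names: dict[int, str] = dataclasses.field(
        default_factory=lambda: dict(PATHWAY_NAMES)
    )

    def __post_init__(self) -> None:
        bad = set(self.sets) - set(self.names)
        if bad:
            raise ValueError(f"pathway codes without names: {sorted(bad)}")

    def pathways_of(self, symbol: str) -> frozenset:
        return frozenset(c for c, genes in self.sets.items() if symbol in genes)

    def bind(self, dataset: ExpressionDataset) -> "BoundCatalog":
        """Resolve the catalog against a dataset's quantified genes."""
        present = set(dataset.genes)
        quantified = {c: sorted(g & present) for c, g in self.sets.items()}
        unresolved = {c: sorted(g - present) for c, g in self.sets.items()}
        return BoundCatalog(self, quantified, unresolved)

    def annotate(self, dataset: ExpressionDataset) -> dict[str, GeneAnnotation]:
        """Gene annotations carrying this catalog's memberships."""
        out = {}
        for sym in dataset.genes:
            out[sym] = GeneAnnotation(symbol=sym, pathways=self.pathways_of(sym))
        return out


@dataclasses.dataclass
class BoundCatalog:
    """A catalog resolved against one dataset."""

    catalog: PathwayCatalog
    quantified: dict[int, list[str]]
    unresolved: dict[int, list[str]]

    def quantified_counts(self) -> dict[int, int]:
        return {c: len(g) for c, g in self.quantified.items()}

    def unresolved_report(self) -> pd.DataFrame:
        rows = [
            {"pathway": c, "name": self.catalog.names[c], "symbol": s}
            for c, syms in sorted(self.unresolved.items())
            for s in syms
        ]
        return pd.DataFrame(rows, columns=["pathway", "name", "symbol"])


def make_sample_sheet(
    conditions: Sequence[str] = STUDY_CONDITIONS, replicates: int = 4
) -> pd.DataFrame:
    """Canonical sample sheet: sample ids '<code>_<k>' grouped by condition."""
    rows = []
    for code in conditions:
        SampleCondition.from_code(code)
        for k in range(1, replicates + 1):
            rows.append({"sample_id": f"{code}_{k}", "condition": code, "replicate": k})
    return pd.DataFrame(rows).set_index("sample_id")
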