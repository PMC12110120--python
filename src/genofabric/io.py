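"""Readers and writers for the package's plain-text formats.

Expression tables are TSV with genes in rows (first column ``gene``) and one
column per sample; the sample -> condition assignment lives in a separate
sample-sheet TSV (``sample_id``, ``condition_code``, ``replicate``) so that
expression files stay standard and exportable.  Gene sets are GMT.  All
report outputs are TSV with ``#``-prefixed header comments recording the
configuration digest and seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .config import AnalysisConfig
from .datamodel import (
    ExpressionDataset,
    FormatError,
    PATHWAY_CODES,
    PathwayCatalog,
)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition_code": str})
    required = {"sample_id", "condition_code", "replicate"}
    if not required <= set(sheet.columns):
        raise FormatError(
            f"sample sheet {path} must have columns {sorted(required)}, "
            f"found {list(sheet.columns)}"
        )
    if sheet["sample_id"].duplicated().any():
        raise FormatError(f"duplicate sample ids in sheet {path}")
    out = sheet.rename(columns={"condition_code": "condition"}).set_index("sample_id")
    out["replicate"] = out["replicate"].astype(int)
    return out[["condition", "replicate"]]


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.rename(columns={"condition": "condition_code"}).reset_index()
    out = out.rename(columns={"index": "sample_id"})
    out.to_csv(path, sep="\t", index=False)


def read_expression_table(
    path: str | Path, sample_sheet: str | Path | pd.DataFrame
) -> ExpressionDataset:
    """Read a gene-level expression TSV together with its sample sheet.

    The returned dataset has ``normalization_state = "raw"``; call
    :func:`genofabric.preprocess.normalize_dataset` if the table is not yet
    in median-gene units.  Non-numeric or non-positive cells and columns
    missing from the sheet are rejected with the offending row/column named.
    """
    sheet = (
        sample_sheet
        if isinstance(sample_sheet, pd.DataFrame)
        else read_sample_sheet(sample_sheet)
    )
    table = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if table.columns[0] != "gene":
        raise FormatError(f"{path}: first column must be 'gene', got {table.columns[0]!r}")
    if table["gene"].duplicated().any():
        dups = table.loc[table["gene"].duplicated(), "gene"].unique().tolist()
        raise FormatError(f"{path}: duplicate gene symbols {dups}")
    table = table.set_index("gene")

    missing = [c for c in table.columns if c not in sheet.index]
    if missing:
        raise FormatError(f"{path}: columns absent from sample sheet: {missing}")

    for col in table.columns:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() | (numeric <= 0)
        if bad.any():
            row = table.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-numeric or non-positive value at gene {row!r}, "
                f"sample {col!r}"
            )
        table[col] = numeric

    return ExpressionDataset(table, sheet.loc[table.columns], "raw")


def write_expression_table(dataset: ExpressionDataset, path: str | Path) -> None:
    out = dataset.values.copy()
    out.index.name = "gene"
    # %.17g round-trips IEEE doubles exactly
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_sets(path: str | Path, name_to_code: Mapping[str, int] | None = None):
    """Read a GMT file into a :class:`PathwayCatalog`.

    Each line is ``name<TAB>description<TAB>symbol...``.  Set names map to
    pathway codes 0-5 through ``name_to_code`` (default: the standard
    SVC/GLU/GABA/ACh/DA/5HT names).  Duplicate set names are a format
    error; empty sets are retained with a warning in the returned report.

    Returns
    -------
    (catalog, warnings) : tuple[PathwayCatalog, list[str]]
    """
    name_to_code = dict(name_to_code or PATHWAY_CODES)
    sets: dict[int, set[str]] = {}
    names: dict[int, str] = {}
    warnings: list[str] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: GMT line needs name and description")
        name, _desc, *symbols = parts
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        seen.add(name)
        if name not in name_to_code:
            raise FormatError(
                f"{path}:{lineno}: set name {name!r} has no pathway code mapping"
            )
        code = name_to_code[name]
        members = {s for s in symbols if s}
        if not members:
            warnings.append(f"gene set {name!r} is empty")
        sets[code] = members
        names[code] = name
    return PathwayCatalog(sets=sets, names=names), warnings


def write_gene_sets(catalog: PathwayCatalog, path: str | Path) -> None:
    lines = []
    for code in sorted(catalog.sets):
        name = catalog.names[code]
        lines.append("\t".join([name, f"pathway {code}", *sorted(catalog.sets[code])]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_report_table(
    records: pd.DataFrame,
    path: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    extra: Mapping[str, str] | None = None,
) -> None:
    """Write a result table as TSV with '#' provenance header comments.

    An empty table still produces a header-only file with column names.
    """
    path = Path(path)
    header = []
    if config is not None:
        header.append(f"# config_digest: {config.digest()}")
    if seed is not None:
        header.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        header.append(f"# {k}: {v}")
    body = records.to_csv(sep="\t", index=False, float_format="%.6g")
    path.write_text(("\n".join(header) + "\n" if header else "") + body)


def read_report_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_spot_table(path: str | Path) -> pd.DataFrame:
    """Read spot-level measurements (probe_id, gene_symbol, sample_id,
    foreground, background, corrupted 0/1)."""
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"probe_id": str, "gene_symbol": str, "sample_id": str},
        keep_default_na=False,
        na_values=[],
    )
    required = {"probe_id", "gene_symbol", "sample_id", "foreground", "background", "corrupted"}
    if not required <= set(table.columns):
        raise FormatError(f"{path}: spot table must have columns {sorted(required)}")
    table["foreground"] = pd.to_numeric(table["foreground"])
    table["background"] = pd.to_numeric(table["background"])
    table["corrupted"] = table["corrupted"].astype(int).astype(bool)
    return table


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    out = spots.copy()
    out["corrupted"] = out["corrupted"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")
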