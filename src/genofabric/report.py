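"""Pipeline orchestration and paper-style report bundles.

``run_pipeline`` drives preprocess (for spot-level input) -> fabric metrics
-> regulome -> coordination -> commanding-height ranking and writes a
bundle of TSV tables plus a manifest from which the run is reproducible:
top-expressed and most/least-controlled tables, per-pathway regulome
summaries, coordination dichotomy reports, and GCH/GMR tables.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig
from .datamodel import BoundCatalog, ExpressionDataset
from .gch import rank_gch, top_gch_by_pathway
from .io import (
    read_expression_table,
    read_gene_sets,
    read_sample_sheet,
    read_spot_table,
    write_report_table,
)
from .metrics import fabric_profiles
from .network import dichotomy_compare, pathway_cor_matrix
from .preprocess import normalize_dataset, preprocess_pipeline
from .regulome import regulome, standard_comparisons

TOP_KEYS = ("AVE", "REC_high", "REC_low", "GCH")


def top_k_table(
    records: pd.DataFrame,
    key: str,
    k: int = 5,
    pathway_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Top-k rows per condition under a ranking key.

    ``records`` is a long-format table with 'gene' and 'condition' columns
    (fabric profiles for AVE/REC keys, GCH records for the GCH key).
    ``REC_low`` reverses ``REC_high`` exactly.  Ties break lexicographically
    by symbol.  ``k`` larger than the gene count returns the full table.
    """
    if key not in TOP_KEYS:
        raise ValueError(f"key must be one of {TOP_KEYS}")
    column = {"AVE": "AVE", "REC_high": "REC", "REC_low": "REC", "GCH": "GCH"}[key]
    ascending = key == "REC_low"
    table = records.reset_index() if "gene" not in records.columns else records.copy()
    table.attrs = {}  # frame-level attrs (summaries) confuse concat below
    if pathway_genes is not None:
        table = table[table["gene"].isin(set(pathway_genes))]
    pieces = []
    for cond, sub in table.groupby("condition", sort=False):
        sub = sub.sort_values([column, "gene"], ascending=[ascending, True]).head(k)
        pieces.append(sub)
    if not pieces:
        return table.head(0)
    return pd.concat(pieces, ignore_index=True)


def _file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def run_pipeline(
    out_dir: str | Path,
    config: AnalysisConfig,
    expression: str | Path | None = None,
    spots: str | Path | None = None,
    sample_sheet: str | Path = None,
    gene_sets: str | Path | None = None,
    dataset: ExpressionDataset | None = None,
    catalog: BoundCatalog | None = None,
    top_k: int = 5,
) -> Path:
    """Run the full analysis and write a report bundle under ``out_dir``.

    Input is either a gene-level expression table (+ sample sheet), a
    spot-level table (+ sample sheet), or an in-memory dataset.  Gene-level
    input skips the spot preprocessing stage (noted in the manifest).
    Returns the bundle directory.  Reruns with the same inputs, config and
    seed are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": f"genofabric {__version__}",
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {},
    }

    stage = "input"
    try:
        if dataset is None:
            sheet = read_sample_sheet(sample_sheet)
            manifest["inputs"]["sample_sheet"] = _file_digest(sample_sheet)
            if spots is not None:
                stage = "preprocess"
                spot_table = read_spot_table(spots)
                manifest["inputs"]["spots"] = _file_digest(spots)
                dataset, drop_log, _ = preprocess_pipeline(spot_table, sheet)
                write_report_table(drop_log, out / "drop_log.tsv", config, config.seed)
                manifest["preprocess"] = {
                    "dropped_spots": int(len(drop_log)),
                    "genes_retained": dataset.n_genes,
                }
            elif expression is not None:
                dataset = read_expression_table(expression, sheet)
                manifest["inputs"]["expression"] = _file_digest(expression)
                manifest["preprocess"] = "skipped (gene-level input)"
            else:
                raise ValueError("need expression, spots, or an in-memory dataset")
        else:
            manifest["preprocess"] = "skipped (in-memory dataset)"
        if dataset.normalization_state == "raw":
            dataset = normalize_dataset(dataset)

        if catalog is None and gene_sets is not None:
            full_catalog, warnings = read_gene_sets(gene_sets)
            manifest["inputs"]["gene_sets"] = _file_digest(gene_sets)
            catalog = full_catalog.bind(dataset)
            if warnings:
                manifest["gene_set_warnings"] = warnings

        stage = "fabric_metrics"
        profiles = fabric_profiles(dataset, config)
        write_report_table(profiles, out / "fabric.tsv", config, config.seed)
        write_report_table(
            profiles.attrs["condition_summary"],
            out / "condition_summary.tsv",
            config,
            config.seed,
        )
        for key in ("AVE", "REC_high", "REC_low"):
            table = top_k_table(
                profiles,
                key,
                top_k,
                pathway_genes=_all_pathway_genes(catalog) if catalog else None,
            )
            write_report_table(table, out / f"top_{key}.tsv", config, config.seed)

        stage = "regulome"
        all_summaries = []
        for compared, reference in standard_comparisons(dataset.conditions):
            records, summaries = regulome(
                dataset, profiles, compared, reference, catalog, config
            )
            write_report_table(
                records, out / f"regulome_{compared}_vs_{reference}.tsv", config, config.seed
            )
            all_summaries.append(summaries)
        if all_summaries:
            write_report_table(
                pd.concat(all_summaries, ignore_index=True),
                out / "regulome_summary.tsv",
                config,
                config.seed,
            )

        stage = "coordination"
        if catalog is not None:
            dich_rows = []
            for code, members in sorted(catalog.quantified.items()):
                for cond in dataset.conditions:
                    matrix = pathway_cor_matrix(dataset, cond, members, config)
                    name = catalog.catalog.names[code]
                    write_report_table(
                        matrix, out / f"network_{name}_{cond}.tsv", config, config.seed
                    )
                conds = dataset.conditions
                sexes = {c[0] for c in conds}
                if {"M", "F"} <= sexes:
                    for arm in sorted({c[1:] for c in conds}):
                        ma, fa = f"M{arm}", f"F{arm}"
                        if ma in conds and fa in conds:
                            rep = dichotomy_compare(
                                pathway_cor_matrix(dataset, ma, members, config),
                                pathway_cor_matrix(dataset, fa, members, config),
                            )
                            frame = rep.to_frame()
                            frame.insert(0, "pathway", code)
                            frame.insert(1, "groups", f"{ma}_vs_{fa}")
                            dich_rows.append(frame)
            if dich_rows:
                write_report_table(
                    pd.concat(dich_rows, ignore_index=True),
                    out / "dichotomy.tsv",
                    config,
                    config.seed,
                )

        stage = "gch"
        gch_tables, gmr_rows = [], []
        for cond in dataset.conditions:
            records, gmr = rank_gch(dataset, profiles, cond, config)
            gch_tables.append(records.reset_index())
            gmr_rows.append(
                {
                    "condition": cond,
                    "gmr": ",".join(gmr.genes),
                    "GCH": gmr.gch,
                    "margin": gmr.margin,
                }
            )
            if catalog is not None:
                write_report_table(
                    top_gch_by_pathway(records, catalog, top_k),
                    out / f"gch_pathways_{cond}.tsv",
                    config,
                    config.seed,
                )
        write_report_table(
            pd.concat(gch_tables, ignore_index=True), out / "gch.tsv", config, config.seed
        )
        write_report_table(
            pd.DataFrame(gmr_rows), out / "gmr.tsv", config, config.seed
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest["tables"] = sorted(p.name for p in out.glob("*.tsv"))
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out


def _all_pathway_genes(catalog: BoundCatalog | None) -> list[str] | None:
    if catalog is None:
        return None
    genes: set[str] = set()
    for members in catalog.quantified.values():
        genes |= set(members)
    return sorted(genes)
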