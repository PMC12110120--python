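"""Simulation-based validation measurements for the analysis pipeline.

Each function here runs the package end to end on generated data and
measures an operating characteristic of the method: type-I error of the
composite regulation criterion, the significant-correlation rate under the
null, recovery of planted fold-changes, recovery of a planted master
regulator, and recovery of planted coordination blocks.  They are used by
the test suite and by ``scripts/acceptance.py``; all randomness flows from
the supplied seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import AnalysisConfig
from .datamodel import make_sample_sheet
from .gch import rank_gch
from .metrics import fabric_profiles
from .network import pathway_cor_matrix
from .preprocess import preprocess_pipeline
from .regulome import regulome
from .simulate import (
    SimulationParams,
    generate_gene_level,
    generate_spot_level,
    scenario_library,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def null_error_rates(
    seed: int,
    n_sims: int = 200,
    n_genes: int = 500,
    config: AnalysisConfig | None = None,
) -> dict[str, float]:
    """Type-I characteristics on all-null data.

    Returns the false-call rate of the composite regulation criterion
    (fraction of null genes called up or down between the two conditions)
    and the significant-correlation rate over disjoint gene pairs, pooled
    over ``n_sims`` simulated experiments of ``n_genes`` genes at K = 4.
    """
    config = config or AnalysisConfig()
    base = dataclasses.replace(scenario_library()["null"], n_genes=n_genes)
    false_calls = gene_total = 0
    sig_pairs = pair_total = 0
    for s in _child_seeds(seed, n_sims):
        ds, _ = generate_gene_level(base, seed=s)
        prof = fabric_profiles(ds, config)
        records, _ = regulome(ds, prof, "MBN", "MSN", config=config)
        false_calls += int((records["verdict"] != "not_significant").sum())
        gene_total += len(records)
        # disjoint pairs (2i, 2i+1) are independent under the null
        genes = list(ds.genes)
        pairs = pathway_cor_matrix(ds, "MSN", genes, config)
        idx = pairs.set_index(["gene_a", "gene_b"])
        wanted = [(genes[2 * i], genes[2 * i + 1]) for i in range(len(genes) // 2)]
        sub = idx.loc[idx.index.intersection(wanted)]
        sig_pairs += int((sub["p"] < config.alpha_cor).sum())
        pair_total += len(sub)
    return {
        "false_call_rate": false_calls / gene_total,
        "n_gene_tests": gene_total,
        "significant_cor_rate": sig_pairs / pair_total,
        "n_pair_tests": pair_total,
    }


def de_recovery(
    seed: int, n_sims: int = 100, config: AnalysisConfig | None = None
) -> dict[str, float]:
    """Sensitivity for planted ratio-3 regulations (CV 10%, K = 4) and the
    null false-call rate in the same experiments."""
    config = config or AnalysisConfig()
    params = scenario_library()["de_power"]
    planted_hits = planted_total = 0
    null_calls = null_total = 0
    for s in _child_seeds(seed, n_sims):
        ds, truth = generate_gene_level(params, seed=s)
        prof = fabric_profiles(ds, config)
        records, _ = regulome(ds, prof, "MBY", "MBN", config=config)
        verdicts = records.set_index("gene")["verdict"]
        planted = list(truth.regulated["gene"])
        planted_hits += int((verdicts.loc[planted] == "up").sum())
        planted_total += len(planted)
        nulls = verdicts.drop(planted)
        null_calls += int((nulls != "not_significant").sum())
        null_total += len(nulls)
    return {
        "sensitivity": planted_hits / planted_total,
        "null_false_call_rate": null_calls / null_total,
    }


def gmr_recovery(
    seed: int, n_sims: int = 100, config: AnalysisConfig | None = None
) -> dict[str, float]:
    """Fraction of seeds in which the planted master regulator ranks 1,
    and in which it lands in the top five, under the positive-control
    preset."""
    config = config or AnalysisConfig()
    params = scenario_library()["gmr_planted"]
    rank1 = top5 = 0
    for s in _child_seeds(seed, n_sims):
        ds, truth = generate_gene_level(params, seed=s)
        prof = fabric_profiles(ds, config)
        records, gmr = rank_gch(ds, prof, "MSN", config)
        rank1 += gmr.genes == [truth.gmr]
        top5 += int(records.loc[truth.gmr, "rank"]) <= 5
    return {"rank1_rate": rank1 / n_sims, "top5_rate": top5 / n_sims}


def block_synergy_recovery(
    seed: int,
    n_sims: int = 100,
    loading: float = 0.95,
    config: AnalysisConfig | None = None,
) -> dict[str, float]:
    """Fraction of planted correlation-block pairs classified synergistic.

    Uses the dichotomy preset's block (10 genes) at the given loading in
    one condition; pair correlation on the log scale is loading^2.
    """
    config = config or AnalysisConfig()
    base = scenario_library()["network_dichotomy"]
    block = dataclasses.replace(base.correlation_blocks[0], loading=loading)
    params = dataclasses.replace(base, correlation_blocks=(block,))
    hits = total = 0
    for s in _child_seeds(seed, n_sims):
        ds, truth = generate_gene_level(params, seed=s)
        genes = list(truth.blocks[0].genes)
        out = pathway_cor_matrix(ds, "FSN", genes, config)
        hits += int((out["class"] == "synergistic").sum())
        total += len(out)
    return {"sensitivity": hits / total, "n_pairs": total}


def preprocess_fidelity(seed: int) -> dict[str, float]:
    """Recovery of the gene-level truth through the spot-level pipeline.

    Runs the full spot preprocessing (2x-background filter, completeness
    drop, median normalization, redundant-probe averaging) on the
    spot-level expansion of a two-condition experiment and compares the
    result with the directly generated gene-level dataset over the
    surviving genes, in common median-gene units (the probe-level and
    gene-level medians define slightly different units at desk-scale N).
    Also reports the exact-recovery error of the lossless configuration.
    """
    seeds = _child_seeds(seed, 2)
    lossless = SimulationParams(
        n_genes=101,
        conditions=("MSN", "MBN"),
        probe_redundancy=(1, 1),
        probe_noise_cv=0.0,
        corruption_rate=0.0,
        low_signal_rate=0.0,
        unmapped_rate=0.0,
        background_mean=1e-6,
        seed=seeds[0],
    )
    sheet = make_sample_sheet(lossless.conditions, lossless.replicates)
    spots, _ = generate_spot_level(lossless)
    gene_ds, _ = generate_gene_level(lossless)
    spot_ds, _, _ = preprocess_pipeline(spots, sheet)
    lossless_err = float(
        np.abs(spot_ds.values / gene_ds.values.loc[spot_ds.values.index] - 1.0)
        .max()
        .max()
    )

    noisy = dataclasses.replace(
        lossless,
        n_genes=301,
        probe_redundancy=(1, 3),
        probe_noise_cv=0.02,
        seed=seeds[1],
    )
    spots, _ = generate_spot_level(noisy)
    gene_ds, _ = generate_gene_level(noisy)
    spot_ds, _, _ = preprocess_pipeline(spots, sheet)
    a = spot_ds.values / spot_ds.values.median(axis=0)
    b = gene_ds.values.loc[a.index] / gene_ds.values.loc[a.index].median(axis=0)
    rel = np.abs(a / b - 1.0).to_numpy()
    med_err = float(np.median(rel))
    q99_err = float(np.quantile(rel, 0.99))
    return {
        "lossless_max_rel_err": lossless_err,
        "noisy_median_rel_err": med_err,
        "noisy_q99_rel_err": q99_err,
        "n_genes_recovered": int(spot_ds.n_genes),
    }
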