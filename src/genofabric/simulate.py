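"""Synthetic replicate-data generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes for a
median-normalized microarray experiment: six sex x treatment condition
groups with K = 4 biological replicates each, log-normally distributed
baseline expression spanning roughly 0.01-200x the median gene, per-gene
coefficients of variation drawn uniformly from 5-50%, redundant probes per
gene, a fraction of corrupted and low-signal spots, and optional planted
effects — fold-changes between conditions, control-strength (CV) shifts,
latent-factor correlation blocks, and a designated master-regulator gene
with minimal expression variability.

Replicate values within a condition are generated on the log scale as

    x_gk = mu_g + sigma_g * ( L_g * F_k + sqrt(1 - L_g^2) * Z_gk )

with a per-replicate latent factor F_k shared by every gene of a
correlation block (loading L_g, 0 outside blocks; a negative loading makes
a gene anti-correlated with its block, so mixed signs plant antagonistic
pairs).  sigma_g = sqrt(ln(1 + CV^2)) and mu_g = ln(mean) - sigma_g^2 / 2
make the arithmetic replicate mean equal the planted mean and the planted
CV exact.  Two genes sharing a factor with loadings L_a, L_b have
log-scale correlation L_a * L_b.  Columns are median-normalized after
generation.  Everything is reproducible bit-for-bit from the seed (numpy
Generator / PCG64 seeded through SeedSequence).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, STUDY_CONDITIONS, make_sample_sheet
from .preprocess import SPOT_COLUMNS


@dataclasses.dataclass(frozen=True)
class PlantedRegulation:
    """A gene whose true mean in ``compared`` is ``ratio`` x its mean in
    ``reference`` (ratio > 1 plants up-regulation in compared)."""

    gene: str
    compared: str
    reference: str
    ratio: float

    @property
    def signed_ratio(self) -> float:
        return self.ratio if self.ratio >= 1.0 else -1.0 / self.ratio


@dataclasses.dataclass(frozen=True)
class ControlShift:
    """A gene whose CV in one condition is multiplied by ``cv_multiplier``
    (values < 1 plant tighter control, i.e. higher RCS)."""

    gene: str
    condition: str
    cv_multiplier: float


@dataclasses.dataclass(frozen=True)
class CorrelationBlock:
    """A gene set sharing a per-replicate latent factor in some conditions.

    ``anti_genes`` load with -loading and so correlate negatively with the
    rest of the block (planting antagonistic pairs).
    """

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    loading: float
    anti_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.loading <= 1.0):
            raise ValueError("loading must be in [0, 1]")
        if not set(self.anti_genes) <= set(self.genes):
            raise ValueError("anti_genes must be a subset of the block's genes")


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Complete description of one synthetic experiment."""

    n_genes: int = 2000
    conditions: tuple[str, ...] = STUDY_CONDITIONS
    replicates: int = 4
    log_mean_sigma: float = 1.8      # ln-scale sd of baseline means (span ~0.01-200x)
    cv_low: float = 0.05
    cv_high: float = 0.50
    planted_regulation: tuple[PlantedRegulation, ...] = ()
    planted_control_shifts: tuple[ControlShift, ...] = ()
    correlation_blocks: tuple[CorrelationBlock, ...] = ()
    planted_gmr: str | None = None
    gmr_cv: float = 0.002            # "minimal REV": well below the CV floor
    probe_redundancy: tuple[int, int] = (1, 3)
    probe_noise_cv: float = 0.02
    corruption_rate: float = 0.02
    low_signal_rate: float = 0.05
    unmapped_rate: float = 0.01
    background_mean: float = 50.0
    signal_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("corruption_rate", "low_signal_rate", "unmapped_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if not (0.0 < self.cv_low <= self.cv_high):
            raise ValueError("need 0 < cv_low <= cv_high")
        for reg in self.planted_regulation:
            if reg.ratio <= 0:
                raise ValueError("planted ratios must be > 0")

    def gene_names(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a generated dataset."""

    true_mean: pd.DataFrame          # gene x condition, pre-normalization units
    true_cv: pd.DataFrame            # gene x condition
    regulated: pd.DataFrame          # gene, compared, reference, ratio, signed_ratio
    blocks: tuple[CorrelationBlock, ...]
    gmr: str | None
    params: SimulationParams

    def block_pairs(self, condition: str) -> list[tuple[str, str, int]]:
        """All planted pairs active in a condition with their correlation
        sign (+1 synergistic, -1 antagonistic)."""
        out = []
        for block in self.blocks:
            if condition not in block.conditions:
                continue
            genes = sorted(block.genes)
            anti = set(block.anti_genes)
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    sign = -1 if (a in anti) != (b in anti) else 1
                    out.append((a, b, sign))
        return out


def _validate(params: SimulationParams) -> None:
    names = set(params.gene_names())
    conds = set(params.conditions)
    for reg in params.planted_regulation:
        if reg.gene not in names:
            raise ValueError(f"planted regulation gene {reg.gene!r} not in gene list")
        if not {reg.compared, reg.reference} <= conds:
            raise ValueError(f"planted regulation conditions unknown: {reg}")
    for shift in params.planted_control_shifts:
        if shift.gene not in names:
            raise ValueError(f"control-shift gene {shift.gene!r} not in gene list")
        if shift.condition not in conds:
            raise ValueError(f"control-shift condition unknown: {shift}")
    for block in params.correlation_blocks:
        missing = set(block.genes) - names
        if missing:
            raise ValueError(f"block genes not in gene list: {sorted(missing)}")
        if not set(block.conditions) <= conds:
            raise ValueError(f"block conditions unknown: {block.conditions}")
    if params.planted_gmr is not None and params.planted_gmr not in names:
        raise ValueError(f"planted GMR {params.planted_gmr!r} not in gene list")


def _truth_tables(params: SimulationParams, rng: np.random.Generator):
    genes = params.gene_names()
    n, conds = params.n_genes, list(params.conditions)
    base_mean = np.exp(params.log_mean_sigma * rng.standard_normal(n))
    base_cv = rng.uniform(params.cv_low, params.cv_high, n)

    mean = pd.DataFrame({c: base_mean.copy() for c in conds}, index=genes)
    cv = pd.DataFrame({c: base_cv.copy() for c in conds}, index=genes)

    for reg in params.planted_regulation:
        mean.loc[reg.gene, reg.compared] *= reg.ratio
    for shift in params.planted_control_shifts:
        cv.loc[shift.gene, shift.condition] *= shift.cv_multiplier
    if params.planted_gmr is not None:
        cv.loc[params.planted_gmr, :] = params.gmr_cv
    return mean, cv


def _loadings(params: SimulationParams, condition: str) -> tuple[np.ndarray, np.ndarray]:
    """(loading, block index) arrays over genes for one condition."""
    genes = params.gene_names()
    idx = {g: i for i, g in enumerate(genes)}
    load = np.zeros(params.n_genes)
    block_of = np.full(params.n_genes, -1, dtype=int)
    for b, block in enumerate(params.correlation_blocks):
        if condition not in block.conditions:
            continue
        for g in block.genes:
            i = idx[g]
            if block_of[i] != -1:
                raise ValueError(
                    f"gene {g!r} belongs to two blocks active in {condition}"
                )
            block_of[i] = b
            load[i] = -block.loading if g in block.anti_genes else block.loading
    return load, block_of


def _raw_matrix(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Gene x sample matrix of raw (pre-normalization) positive values."""
    mean, cv = _truth_tables(params, rng)
    genes, k = params.gene_names(), params.replicates
    cols, chunks = [], []
    for cond in params.conditions:
        load, block_of = _loadings(params, cond)
        factors = rng.standard_normal((max(len(params.correlation_blocks), 1), k))
        noise = rng.standard_normal((params.n_genes, k))
        f_per_gene = np.where(
            block_of[:, None] >= 0, factors[np.maximum(block_of, 0), :], 0.0
        )
        sigma = np.sqrt(np.log1p(cv[cond].to_numpy() ** 2))
        mu = np.log(mean[cond].to_numpy()) - sigma**2 / 2.0
        z = load[:, None] * f_per_gene + np.sqrt(1.0 - load**2)[:, None] * noise
        chunks.append(np.exp(mu[:, None] + sigma[:, None] * z))
        cols.extend(f"{cond}_{i}" for i in range(1, k + 1))
    raw = pd.DataFrame(np.hstack(chunks), index=genes, columns=cols)
    raw.index.name = "gene"

    regulated = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "compared": r.compared,
                "reference": r.reference,
                "ratio": r.ratio,
                "signed_ratio": r.signed_ratio,
            }
            for r in params.planted_regulation
        ],
        columns=["gene", "compared", "reference", "ratio", "signed_ratio"],
    )
    truth = SyntheticTruth(
        true_mean=mean,
        true_cv=cv,
        regulated=regulated,
        blocks=params.correlation_blocks,
        gmr=params.planted_gmr,
        params=params,
    )
    return raw, truth


def generate_gene_level(
    params: SimulationParams, seed: int | None = None
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate a median-normalized gene-level dataset plus its truth."""
    _validate(params)
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    gene_ss, _ = ss.spawn(2)
    raw, truth = _raw_matrix(params, np.random.default_rng(gene_ss))
    normalized = raw / raw.median(axis=0)
    sheet = make_sample_sheet(params.conditions, params.replicates)
    return ExpressionDataset(normalized, sheet, "normalized"), truth


def generate_spot_level(
    params: SimulationParams, seed: int | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Expand the gene-level truth to spot-level measurements.

    Each gene gets 1-3 redundant probes (uniform); each spot's net signal is
    the gene's raw value times ``signal_scale`` with multiplicative probe
    noise, on top of a positive background channel.  Corrupted spots are
    flagged; low-signal spots have their foreground forced below twice the
    background; a further fraction of spots probe unmapped sequences (empty
    gene symbol).  Running the preprocessing pipeline on the output recovers
    the gene-level dataset (exactly, when redundancy is 1 and all noise and
    corruption rates are 0).
    """
    _validate(params)
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    gene_ss, spot_ss = ss.spawn(2)
    raw, truth = _raw_matrix(params, np.random.default_rng(gene_ss))
    rng = np.random.default_rng(spot_ss)

    lo, hi = params.probe_redundancy
    n_probes = rng.integers(lo, hi + 1, size=params.n_genes)
    probe_gene = np.repeat(raw.index.to_numpy(), n_probes)
    probe_ids = np.concatenate(
        [[f"{g}_p{j}" for j in range(n_probes[i])] for i, g in enumerate(raw.index)]
    )
    n_unmapped = int(round(params.unmapped_rate * probe_ids.size))
    if n_unmapped:
        probe_ids = np.concatenate(
            [probe_ids, [f"unmapped_p{j}" for j in range(n_unmapped)]]
        )
        probe_gene = np.concatenate([probe_gene, [""] * n_unmapped])

    samples = raw.columns.to_numpy()
    n_spots = probe_ids.size * samples.size
    sigma_probe = np.sqrt(np.log1p(params.probe_noise_cv**2))

    value = np.empty((probe_ids.size, samples.size))
    mapped = probe_gene != ""
    row_of = raw.index.get_indexer(probe_gene[mapped])
    value[mapped] = raw.to_numpy()[row_of, :]
    value[~mapped] = np.exp(
        params.log_mean_sigma * rng.standard_normal(((~mapped).sum(), 1))
    )
    gain = np.exp(
        sigma_probe * rng.standard_normal(value.shape) - sigma_probe**2 / 2.0
    ) if sigma_probe > 0 else np.ones_like(value)
    net = value * gain * params.signal_scale
    background = params.background_mean * np.exp(
        0.3 * rng.standard_normal(value.shape)
    )
    foreground = background + net

    corrupted = rng.random(value.shape) < params.corruption_rate
    low = rng.random(value.shape) < params.low_signal_rate
    foreground = np.where(low, background * rng.uniform(1.0, 1.9, value.shape), foreground)

    spots = pd.DataFrame(
        {
            "probe_id": np.repeat(probe_ids, samples.size),
            "gene_symbol": np.repeat(probe_gene, samples.size),
            "sample_id": np.tile(samples, probe_ids.size),
            "foreground": foreground.ravel(),
            "background": background.ravel(),
            "corrupted": corrupted.ravel(),
        },
        columns=SPOT_COLUMNS,
    )
    assert len(spots) == n_spots
    return spots, truth


def scenario_library() -> dict[str, SimulationParams]:
    """Named presets covering the analysis' study conditions.

    * ``study_like`` — six conditions x K = 4, N = 2000 genes (the study's
      16,066 unigenes scaled to desk size), no planted effects.
    * ``null`` — two conditions, 500 i.i.d. genes; for type-I calibration.
    * ``de_power`` — 10 genes planted at ratio 3 (CV 10%) among 500 nulls.
    * ``network_dichotomy`` — a loading-0.95 block active in the female SN
      group only, for coordination-switch recovery.
    * ``gmr_planted`` — a positive control for master-regulator recovery: a
      designated gene with far-below-floor variability (CV 0.2% vs a 20%
      population floor) inside a strong correlation block.  The expression
      spread is narrowed (sigma_ln 0.3) so that median-normalization noise
      (which scales as 1/(f(median) sqrt(N)) per sample and inflates every
      gene's apparent variability) does not mask the plant; under the full
      study-like spread the 3-df variance-estimation noise makes a
      minimal-CV plant indistinguishable from the lower tail of the null
      REV order statistics at any N.
    """
    genes = lambda n: [f"g{i:05d}" for i in range(n)]  # noqa: E731
    de_planted = tuple(
        PlantedRegulation(gene=g, compared="MBY", reference="MBN", ratio=3.0)
        for g in genes(10)
    )
    dichotomy_block = CorrelationBlock(
        genes=tuple(genes(10)), conditions=("FSN",), loading=0.95
    )
    gmr_block = CorrelationBlock(
        genes=tuple(genes(10)), conditions=("MSN",), loading=0.9
    )
    return {
        "study_like": SimulationParams(n_genes=2000),
        "null": SimulationParams(
            n_genes=500, conditions=("MSN", "MBN"), log_mean_sigma=1.0
        ),
        "de_power": SimulationParams(
            n_genes=510,
            conditions=("MBN", "MBY"),
            cv_low=0.10,
            cv_high=0.10,
            planted_regulation=de_planted,
        ),
        "network_dichotomy": SimulationParams(
            n_genes=200,
            conditions=("MSN", "FSN"),
            correlation_blocks=(dichotomy_block,),
        ),
        "gmr_planted": SimulationParams(
            n_genes=2000,
            conditions=("MSN",),
            log_mean_sigma=0.3,
            cv_low=0.20,
            cv_high=0.50,
            planted_gmr="g00000",
            correlation_blocks=(gmr_block,),
        ),
    }
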