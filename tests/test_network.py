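"""Expression coordination: correlation, three-way classes, dichotomy."""

import numpy as np
import pandas as pd
import pytest

from genofabric.config import AnalysisConfig
from genofabric.datamodel import ExpressionDataset, make_sample_sheet
from genofabric.network import (
    classify_pair,
    compute_cor,
    correlation_p,
    critical_r,
    dichotomy_compare,
    pathway_cor_matrix,
)
from genofabric.simulate import (
    CorrelationBlock,
    SimulationParams,
    generate_gene_level,
    scenario_library,
)

from conftest import vectors_with_correlation


def dataset_from_rows(rows: dict[str, list[float]], condition="MSN"):
    sheet = make_sample_sheet([condition], len(next(iter(rows.values()))))
    values = pd.DataFrame(rows, index=sheet.index).T
    return ExpressionDataset(values, sheet, "raw")


class TestComputeCor:
    def test_proportional_genes_correlate_perfectly(self):
        ds = dataset_from_rows({"a": [1, 2, 4, 8], "b": [3, 6, 12, 24]})
        r, p = compute_cor(ds, "a", "b", "MSN")
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_inversely_proportional_genes_anticorrelate(self):
        ds = dataset_from_rows({"a": [1, 2, 4, 8], "b": [8, 4, 2, 1]})
        r, _ = compute_cor(ds, "a", "b", "MSN")
        assert r == pytest.approx(-1.0)

    def test_constant_gene_is_undefined(self):
        ds = dataset_from_rows({"a": [1, 2, 4, 8], "b": [2, 2, 2, 2]})
        r, p = compute_cor(ds, "a", "b", "MSN")
        assert np.isnan(r) and np.isnan(p)

    def test_significance_boundary_at_k4(self):
        # geometric oracle: vectors constructed with exact sample r
        for r0, side in [(0.951, "below"), (0.949, "above")]:
            x, y = vectors_with_correlation(r0)
            ds = dataset_from_rows(
                {"a": list(np.exp(x)), "b": list(np.exp(y))}
            )
            # correlation of log2 values is invariant to the exp/log pair
            # up to the log base; feed exp() so stored values are positive
            r, p = compute_cor(ds, "a", "b", "MSN")
            # note: log2(exp(x)) = x / ln 2, an affine map, so r is exact
            assert r == pytest.approx(r0, abs=1e-12)
            assert (p < 0.05) == (side == "below")

    def test_critical_r_matches_uniform_null_law(self):
        # at K = 4 the null sample correlation is uniform on [-1, 1], so
        # the two-tailed 5% boundary is exactly 0.95
        assert critical_r(4, 0.05) == pytest.approx(0.95, abs=1e-12)
        r = np.array([0.951, 0.949])
        p = correlation_p(r, 4)
        assert p[0] < 0.05 < p[1]
        # uniform law: p(|r|) = 1 - |r| at K = 4
        assert correlation_p(0.3, 4) == pytest.approx(0.7, abs=1e-9)


class TestClassifyPair:
    def test_three_way_partition(self, config):
        assert classify_pair(0.99, correlation_p(0.99, 4), config) == "synergistic"
        assert classify_pair(-0.99, correlation_p(-0.99, 4), config) == "antagonistic"
        assert classify_pair(0.02, correlation_p(0.02, 4), config) == "independent"
        assert classify_pair(0.60, correlation_p(0.60, 4), config) == "indeterminate"
        assert classify_pair(float("nan"), float("nan"), config) == "indeterminate"


class TestPathwayMatrix:
    def test_single_gene_gives_empty_matrix(self, two_condition_dataset, config):
        out = pathway_cor_matrix(two_condition_dataset, "MSN", ["g000"], config)
        assert out.empty

    def test_all_pairs_present_and_symmetric(self, two_condition_dataset, config):
        genes = list(two_condition_dataset.genes)[:6]
        out = pathway_cor_matrix(two_condition_dataset, "MSN", genes, config)
        assert len(out) == 15
        square = out.attrs["square"]
        assert np.allclose(square, square.T, equal_nan=True)
        # long-format r agrees with the scalar path for a spot-checked pair
        row = out.iloc[3]
        r, p = compute_cor(two_condition_dataset, row["gene_a"], row["gene_b"], "MSN")
        assert row["r"] == pytest.approx(r) and row["p"] == pytest.approx(p)

    def test_latent_factor_block_pairs_synergize(self, config):
        params = SimulationParams(
            n_genes=12,
            conditions=("MSN",),
            cv_low=0.2,
            cv_high=0.2,
            correlation_blocks=(
                CorrelationBlock(tuple(f"g{i:05d}" for i in range(5)), ("MSN",), 0.999),
            ),
            seed=5,
        )
        ds, truth = generate_gene_level(params)
        out = pathway_cor_matrix(ds, "MSN", [f"g{i:05d}" for i in range(5)], config)
        assert (out["class"] == "synergistic").all()

    def test_null_significant_fraction_near_alpha(self, config):
        # disjoint pairs over many seeds; the null law of r is uniform at
        # K = 4, so the significant fraction estimates alpha = 0.05
        hits = total = 0
        for seed in range(30):
            ds, _ = generate_gene_level(
                SimulationParams(n_genes=100, conditions=("MSN",), seed=seed)
            )
            out = pathway_cor_matrix(ds, "MSN", None, config)
            pairs = out[out["gene_a"].str[-1].astype(int) % 2 == 0]
            sig = out["p"] < config.alpha_cor
            hits += int(sig.sum())
            total += len(out)
        rate = hits / total
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_synergy_recovery_tracks_bivariate_oracle(self, config):
        # a block pair with factor loading L has log-scale correlation L^2;
        # an independent bivariate-normal Monte-Carlo of the K = 4 sample
        # correlation gives the attainable recovery P(r >= 0.95 | rho = L^2);
        # package rates must rise monotonically with L and match the oracle
        # (median-normalization noise dilutes rho slightly at N = 1001)
        rng = np.random.default_rng(99)
        loadings = (0.5, 0.9, 0.99)

        def oracle(rho: float, m: int = 100_000) -> float:
            z = rng.standard_normal((m, 4))
            e = rng.standard_normal((m, 4))
            y = rho * z + np.sqrt(1 - rho**2) * e
            zc = z - z.mean(1, keepdims=True)
            yc = y - y.mean(1, keepdims=True)
            r = (zc * yc).sum(1) / np.sqrt((zc**2).sum(1) * (yc**2).sum(1))
            return float((r >= 0.95).mean())

        rates = []
        for loading in loadings:
            hit = tot = 0
            for seed in range(30):
                params = SimulationParams(
                    n_genes=1001,
                    conditions=("MSN",),
                    cv_low=0.3,
                    cv_high=0.3,
                    correlation_blocks=(
                        CorrelationBlock(
                            tuple(f"g{i:05d}" for i in range(5)), ("MSN",), loading
                        ),
                    ),
                    seed=seed,
                )
                ds, truth = generate_gene_level(params)
                out = pathway_cor_matrix(
                    ds, "MSN", [f"g{i:05d}" for i in range(5)], config
                )
                hit += int((out["class"] == "synergistic").sum())
                tot += len(out)
            rates.append(hit / tot)
        assert rates[0] < rates[1] < rates[2]
        for rate, loading in zip(rates, loadings):
            assert rate == pytest.approx(oracle(loading**2), abs=0.12)


class TestDichotomy:
    def _matrix(self, classes: dict[tuple[str, str], str]) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "condition": "X", "r": 0.0, "p": 1.0, "class": c}
            for (a, b), c in classes.items()
        ]
        return pd.DataFrame(rows)

    def test_identical_matrices_have_no_switches(self):
        m = self._matrix({("g1", "g2"): "synergistic", ("g3", "g4"): "independent"})
        rep = dichotomy_compare(m, m)
        assert rep.counts == {"opposite": 0, "gained": 0, "lost": 0}

    def test_hand_enumerated_toy(self):
        a = self._matrix({("g1", "g2"): "synergistic", ("g3", "g4"): "independent"})
        b = self._matrix({("g1", "g2"): "antagonistic", ("g3", "g4"): "synergistic"})
        rep = dichotomy_compare(a, b)
        assert rep.opposite_pairs == [("g1", "g2")]
        assert rep.gained_pairs == [("g3", "g4")]
        assert rep.lost_pairs == []

    def test_indeterminate_contributes_nothing(self):
        a = self._matrix({("g1", "g2"): "indeterminate", ("g3", "g4"): "synergistic"})
        b = self._matrix({("g1", "g2"): "synergistic", ("g3", "g4"): "indeterminate"})
        rep = dichotomy_compare(a, b)
        assert rep.counts == {"opposite": 0, "gained": 0, "lost": 0}

    def test_mismatched_gene_sets_error(self):
        a = self._matrix({("g1", "g2"): "independent"})
        b = self._matrix({("g1", "g3"): "independent"})
        with pytest.raises(ValueError, match="different gene pairs"):
            dichotomy_compare(a, b)

    def test_sex_dichotomy_recovers_block_only_present_in_one_sex(self, config):
        # blocks exist in FSN only; switches must be overwhelmingly
        # gains (independent/indeterminate in males, significant in
        # females) rather than losses
        params = scenario_library()["network_dichotomy"]
        gained = lost = 0
        for seed in range(20):
            ds, truth = generate_gene_level(params, seed=seed)
            block_genes = list(truth.blocks[0].genes)
            ma = pathway_cor_matrix(ds, "MSN", block_genes, config)
            fa = pathway_cor_matrix(ds, "FSN", block_genes, config)
            rep = dichotomy_compare(ma, fa)
            gained += rep.counts["gained"]
            lost += rep.counts["lost"]
        assert gained > lost
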