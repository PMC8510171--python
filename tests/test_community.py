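"""Rarefaction, diversity indices, aggregation, z-scores and networks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special

from bmpkit.community import (
    CountTable,
    QpcrAbundance,
    activity_ratio,
    aggregate_taxa,
    alpha_diversity,
    bray_curtis,
    cooccurrence_network,
    correlation_edges,
    dna_rna_divergence,
    pearson_with_p,
    rarefy,
    zscore_rows,
)
from bmpkit.datasets import reference_levels
from bmpkit.simulate import planted_block_profiles, simulate_counts


def tiny_table(counts: dict, taxonomy: dict | None = None, meta: dict | None = None):
    counts_df = pd.DataFrame(counts).T  # dict of sample -> feature counts
    features = counts_df.columns
    taxonomy = taxonomy or {
        f: {"phylum": "P", "class": "C", "order": "O", "family": f"Fam_{f}", "genus": f"Gen_{f}"}
        for f in features
    }
    meta = meta or {
        s: {"fraction": "DNA", "ammonium": 1.7, "modality": "independent", "replicate": 1}
        for s in counts_df.index
    }
    return CountTable(
        counts=counts_df.astype(np.int64),
        taxonomy=pd.DataFrame(taxonomy).T,
        sample_meta=pd.DataFrame(meta).T,
    )


class TestRarefy:
    def test_own_total_is_identity_and_single_feature(self):
        table = tiny_table({"s1": {"a": 7, "b": 3}, "s2": {"a": 10, "b": 0}})
        same = rarefy(table, 10, seed=0)
        assert same.counts.loc["s1"].sum() == 10
        assert (same.counts.loc["s1"] == [7, 3]).all()
        assert same.counts.loc["s2", "a"] == 10  # only nonzero feature takes all draws

    def test_totals_and_no_inflation(self):
        table, _ = simulate_counts(reference_levels("independent")[:3], depth=5000, seed=1)
        rar = rarefy(table, 2000, seed=2)
        assert (rar.counts.sum(axis=1) == 2000).all()
        assert (rar.counts.to_numpy() <= table.counts[rar.counts.columns].to_numpy()).all()

    def test_expected_counts_match_hypergeometric_mean(self):
        table = tiny_table({"s1": {"a": 60, "b": 30, "c": 10}})
        depth = 40
        draws = np.array(
            [rarefy(table, depth, seed=s).counts.reindex(columns=["a", "b", "c"], fill_value=0).loc["s1"].to_numpy() for s in range(500)]
        )
        expected = depth * np.array([60, 30, 10]) / 100
        sem = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 4 * sem + 1e-9)

    def test_depth_above_total_names_sample(self):
        table = tiny_table({"shallow": {"a": 5, "b": 2}, "deep": {"a": 50, "b": 50}})
        with pytest.raises(ValueError, match="shallow"):
            rarefy(table, 20, seed=0)


class TestAlphaDiversity:
    def test_uniform_and_singleton(self):
        assert alpha_diversity([5, 5, 5, 5]) == (4, pytest.approx(np.log(4)))
        assert alpha_diversity([0, 9, 0]) == (1, pytest.approx(0.0))
        with pytest.raises(ValueError):
            alpha_diversity([0, 0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=100), min_size=3, max_size=12))
    def test_merging_never_increases_shannon_and_log_richness_bound(self, counts):
        counts = np.array(counts, dtype=float)
        if counts.sum() == 0:
            counts[0] = 1
        richness, shannon = alpha_diversity(counts)
        assert shannon <= np.log(richness) + 1e-12
        merged = np.concatenate([[counts[0] + counts[1]], counts[2:]])
        if merged.sum() > 0:
            _, shannon_merged = alpha_diversity(merged)
            assert shannon_merged <= shannon + 1e-12


class TestBrayCurtis:
    def test_edge_cases_and_hand_example(self):
        assert bray_curtis([1, 2, 3], [2, 4, 6]) == pytest.approx(0.0)  # same relative profile
        assert bray_curtis([5, 0, 0], [0, 3, 3]) == pytest.approx(1.0)
        # relative profiles (1/6,2/6,3/6) vs (3/6,2/6,1/6): sum|diff| / sum = 1/3
        assert bray_curtis([1, 2, 3], [3, 2, 1]) == pytest.approx(1.0 / 3.0)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.integers(0, 50, size=(2, 6)) + 1
            d1, d2 = bray_curtis(a, b), bray_curtis(b, a)
            assert d1 == pytest.approx(d2)
            assert 0.0 <= d1 <= 1.0

    def test_mismatched_feature_space(self):
        with pytest.raises(ValueError, match="feature space"):
            bray_curtis([1, 2], [1, 2, 3])


class TestDnaRnaDivergence:
    def test_identical_fractions_give_zero(self):
        counts = {"d1": {"a": 10, "b": 5}, "r1": {"a": 10, "b": 5}}
        meta = {
            "d1": {"fraction": "DNA", "ammonium": 1.7, "modality": "independent", "replicate": 1},
            "r1": {"fraction": "RNA", "ammonium": 1.7, "modality": "independent", "replicate": 1},
        }
        table = tiny_table(counts, meta=meta)
        result, _ = dna_rna_divergence(table)
        assert result["divergence"].to_numpy() == pytest.approx([0.0])

    def test_divergence_increases_along_gradient(self):
        table, _ = simulate_counts(reference_levels("independent"), depth=20_000, seed=4)
        result, trend = dna_rna_divergence(table)
        assert trend["slope"] > 0

    def test_trend_matches_ols_oracle(self):
        table, _ = simulate_counts(reference_levels("independent"), depth=20_000, seed=4)
        result, trend = dna_rna_divergence(table)
        x, y = result["ammonium"].to_numpy(), result["divergence"].to_numpy()
        design = np.column_stack([x, np.ones_like(x)])
        coef, residuals, *_ = np.linalg.lstsq(design, y, rcond=None)
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert trend["slope"] == pytest.approx(coef[0], rel=1e-9)
        assert trend["r_squared"] == pytest.approx(1 - residuals[0] / ss_tot, rel=1e-9)

    def test_unpaired_condition_skipped_with_warning(self):
        counts = {"d1": {"a": 10, "b": 5}}
        meta = {"d1": {"fraction": "DNA", "ammonium": 1.7, "modality": "independent", "replicate": 1}}
        with pytest.warns(UserWarning, match="skipped"):
            result, _ = dna_rna_divergence(tiny_table(counts, meta=meta))
        assert result.empty


class TestActivityRatio:
    def test_examples_and_normalisation_invariance(self):
        assert activity_ratio(QpcrAbundance("s", 1e11, 1e11)) == 1.0
        assert activity_ratio(QpcrAbundance("s", 6.0e11, 3.0e12)) == pytest.approx(5.0)
        base = QpcrAbundance("s", 4e11, 9e11)
        scaled = QpcrAbundance("s", 4e11 * 2.5, 9e11 * 2.5)
        assert activity_ratio(base) == pytest.approx(activity_ratio(scaled))
        with pytest.raises(ValueError):
            activity_ratio(QpcrAbundance("s", 0.0, 1e9))


class TestAggregateTaxa:
    def test_single_family_collapses_to_column_sums(self):
        counts = {"s1": {"a": 3, "b": 7}, "s2": {"a": 1, "b": 4}}
        taxonomy = {
            f: {"phylum": "P", "class": "C", "order": "O", "family": "OneFam", "genus": f"G{f}"}
            for f in ("a", "b")
        }
        agg = aggregate_taxa(tiny_table(counts, taxonomy), rank="family", top_k=10)
        assert list(agg.columns) == ["OneFam"]
        assert agg["OneFam"].tolist() == [10, 5]

    def test_unclassified_fallback_label(self):
        counts = {"s1": {"a": 5, "b": 5}}
        taxonomy = {
            "a": {"phylum": "P", "class": "C", "order": "O", "family": "FamA", "genus": "GenA"},
            "b": {"phylum": "Firmicutes", "class": "Limnochordia", "order": None, "family": None, "genus": None},
        }
        agg = aggregate_taxa(tiny_table(counts, taxonomy), rank="genus", top_k=10)
        assert "c_Limnochordia" in agg.columns and "GenA" in agg.columns

    def test_conserves_selected_totals(self):
        table, _ = simulate_counts(reference_levels("independent")[:3], depth=9000, seed=2)
        agg = aggregate_taxa(table, rank="family", top_k=50)
        assert (agg.sum(axis=1) == table.counts.sum(axis=1)).all()

    def test_unknown_rank(self):
        table = tiny_table({"s1": {"a": 1}})
        with pytest.raises(ValueError, match="rank"):
            aggregate_taxa(table, rank="kingdom")


class TestZscore:
    def test_hand_computed_row(self):
        out = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert out.iloc[0].tolist() == pytest.approx([-1.224745, 0.0, 1.224745], abs=1e-6)

    def test_constant_row_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_rows(pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]]))
        assert (out.iloc[0] == 0).all()

    def test_rows_standardised(self):
        rng = np.random.default_rng(1)
        out = zscore_rows(pd.DataFrame(rng.normal(5, 2, size=(4, 9))))
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.std(axis=1, ddof=0), 1, atol=1e-12)


class TestPearson:
    def test_perfect_line_and_zero_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p < 1e-8
        r0, p0 = pearson_with_p(x, np.array([1.0, -1.0, -1.0, 1.0]))  # orthogonal contrast
        assert r0 == pytest.approx(0.0, abs=1e-12) and p0 == pytest.approx(1.0)

    def test_p_matches_t_density_integration(self):
        x = np.array([2.0, 4.0, 5.0, 7.0, 8.0, 11.0])
        y = np.array([1.0, 3.0, 2.0, 6.0, 5.0, 8.0])
        r, p = pearson_with_p(x, y)
        n = len(x)
        t = abs(r) * np.sqrt((n - 2) / (1 - r**2))
        df = n - 2

        def t_pdf(u):
            return (
                special.gamma((df + 1) / 2)
                / (np.sqrt(df * np.pi) * special.gamma(df / 2))
                * (1 + u**2 / df) ** (-(df + 1) / 2)
            )

        tail, _ = integrate.quad(t_pdf, t, np.inf)
        assert p == pytest.approx(2 * tail, rel=1e-6)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="3"):
            pearson_with_p([1, 2], [3, 4])
        with pytest.raises(ValueError, match="variance"):
            pearson_with_p([1, 1, 1], [1, 2, 3])


class TestNetwork:
    def test_two_perfectly_correlated_families(self):
        profiles = pd.DataFrame(
            {"FamA": [0.1, 0.2, 0.3, 0.4, 0.5], "FamB": [0.2, 0.4, 0.6, 0.8, 1.0]}
        )
        edges = correlation_edges(profiles, r_threshold=0.8, alpha=0.05)
        assert len(edges) == 1 and edges[0].sign == "positive"

    def test_planted_two_block_structure_recovered(self):
        profiles, truth = planted_block_profiles(n_samples=7, noise_sd=0.02, seed=5)
        edges = correlation_edges(profiles, r_threshold=0.8, alpha=0.05)
        found = {frozenset((e.family_a, e.family_b)): e.sign for e in edges}
        true_pos = sum(1 for pair, sign in found.items() if truth.get(pair) == sign)
        precision = true_pos / max(len(found), 1)
        recall = true_pos / len(truth)
        assert precision >= 0.9 and recall >= 0.9

    def test_threshold_and_alpha_monotonicity(self):
        profiles, _ = planted_block_profiles(n_samples=7, noise_sd=0.1, seed=9)
        loose = {
            frozenset((e.family_a, e.family_b)) for e in correlation_edges(profiles, 0.5, 0.2)
        }
        tight_r = {
            frozenset((e.family_a, e.family_b)) for e in correlation_edges(profiles, 0.9, 0.2)
        }
        tight_a = {
            frozenset((e.family_a, e.family_b)) for e in correlation_edges(profiles, 0.5, 0.01)
        }
        assert tight_r <= loose and tight_a <= loose

    def test_full_network_reports_degrees_and_components(self):
        table, _ = simulate_counts(reference_levels("independent"), replicates=2, depth=30_000, seed=6)
        rna = table.select_samples(table.sample_meta["fraction"] == "RNA")
        result = cooccurrence_network(rna, rank="family", top_k=50, r_threshold=0.8, alpha=0.05)
        assert set(result.degrees) == set(result.graph.nodes)
        assert sum(len(c) for c in result.components) == result.graph.number_of_nodes()

    def test_stratum_preconditions(self):
        table = tiny_table({"s1": {"a": 1, "b": 2}, "s2": {"a": 2, "b": 1}})
        with pytest.raises(ValueError, match="3 samples"):
            cooccurrence_network(table)
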