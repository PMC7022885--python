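"""Count-table operations: contaminant removal, abundance filtering,
rank aggregation, size factors, normalization and differential abundance."""

import numpy as np
import pandas as pd
import pytest

from rhizomine.synthetic import SyntheticConfig, make_taxonomy, simulate_counts
from rhizomine.tables import (
    CountTable,
    aggregate_at_rank,
    diff_abundance,
    low_abundance_filter,
    normalize,
    remove_contaminant_lineages,
    size_factors,
)


def make_table(counts: dict, samples=None, meta=None) -> CountTable:
    frame = pd.DataFrame(counts).T
    if samples is not None:
        frame.columns = samples
    return CountTable(frame, meta)


@pytest.fixture
def taxid_table(ranked_tree):
    # species 50, 51 (Burkholderiaceae), 52 (Micrococcaceae), plus the
    # family 30 itself and phylum 20
    counts = pd.DataFrame(
        {
            "s1": [4, 2, 7, 1, 3],
            "s2": [5, 1, 2, 0, 9],
            "s3": [6, 0, 1, 2, 2],
        },
        index=[50, 51, 52, 30, 20],
    )
    return CountTable(counts)


class TestContaminantRemoval:
    def test_plant_lineage_feature_removed(self, ranked_tree):
        # graft a plant-like clade under the root
        from rhizomine.taxonomy import TaxonomyNode, TaxonomyTree

        nodes = list(ranked_tree.nodes.values()) + [
            TaxonomyNode(90, 1, "kingdom", "Viridiplantae"),
            TaxonomyNode(91, 90, "species", "S. lycopersicum"),
        ]
        tree = TaxonomyTree(nodes)
        counts = pd.DataFrame(
            {"s1": [1, 2, 3, 4, 5]}, index=[50, 51, 52, 91, 30]
        )
        out = remove_contaminant_lineages(CountTable(counts), tree, {90})
        assert list(out.counts.index) == [50, 51, 52, 30]

    def test_empty_exclusion_is_identity(self, ranked_tree, taxid_table):
        out = remove_contaminant_lineages(taxid_table, ranked_tree, set())
        assert out.counts.equals(taxid_table.counts)

    def test_all_features_excluded_gives_empty_table(self, ranked_tree, taxid_table):
        out = remove_contaminant_lineages(taxid_table, ranked_tree, {1})
        assert out.n_features == 0

    def test_unknown_taxids_dropped_with_warning(self, ranked_tree):
        counts = pd.DataFrame({"s1": [1, 2]}, index=[50, 999_999])
        out = remove_contaminant_lineages(CountTable(counts), ranked_tree, set())
        assert list(out.counts.index) == [50]


class TestLowAbundanceFilter:
    def test_boundary_feature_retained(self):
        table = make_table({"keep": [5, 5, 5, 0], "drop": [4, 4, 4, 4]})
        out = low_abundance_filter(table, min_count=5, min_samples=3)
        assert list(out.counts.index) == ["keep"]

    def test_min_samples_exceeding_library_count_errors(self):
        table = make_table({"f": [5, 5]})
        with pytest.raises(ValueError):
            low_abundance_filter(table, min_samples=3)

    def test_matches_row_scan_oracle(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.integers(0, 12, size=(50, 18)),
            index=[f"f{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(18)],
        )
        out = low_abundance_filter(CountTable(counts), min_count=5, min_samples=3)
        expected = [
            f
            for f in counts.index
            if sum(1 for v in counts.loc[f] if v >= 5) >= 3
        ]
        assert list(out.counts.index) == expected

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(
            rng.integers(0, 10, size=(30, 8)),
            index=[f"f{i}" for i in range(30)],
        )
        table = CountTable(counts)
        base = set(low_abundance_filter(table, 4, 3).counts.index)
        assert set(low_abundance_filter(table, 5, 3).counts.index) <= base
        assert set(low_abundance_filter(table, 4, 4).counts.index) <= base

    def test_commutes_with_sample_reordering(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 9, size=(20, 6)), columns=[f"s{j}" for j in range(6)]
        )
        table = CountTable(counts)
        shuffled = CountTable(counts[["s3", "s0", "s5", "s1", "s4", "s2"]])
        assert set(low_abundance_filter(table).counts.index) == set(
            low_abundance_filter(shuffled).counts.index
        )


class TestAggregateAtRank:
    def test_sibling_species_sum_into_family(self, ranked_tree):
        counts = pd.DataFrame({"s1": [3, 4], "s2": [1, 0]}, index=[50, 51])
        out = aggregate_at_rank(CountTable(counts), ranked_tree, "family")
        assert list(out.counts.index) == [30]
        assert out.counts.loc[30].tolist() == [7, 1]

    def test_family_level_table_is_identity_up_to_order(self, ranked_tree):
        counts = pd.DataFrame({"s1": [3, 4]}, index=[30, 31])
        out = aggregate_at_rank(CountTable(counts), ranked_tree, "family")
        assert sorted(out.counts.index) == [30, 31]
        assert out.counts.loc[30, "s1"] == 3

    def test_rankless_features_bucketed_and_sums_conserved(self, ranked_tree, taxid_table):
        out = aggregate_at_rank(taxid_table, ranked_tree, "family")
        assert "unranked" in out.counts.index  # the phylum-level feature
        assert out.counts.sum(axis=0).equals(taxid_table.counts.sum(axis=0))

    def test_unknown_rank_errors(self, ranked_tree, taxid_table):
        with pytest.raises(ValueError):
            aggregate_at_rank(taxid_table, ranked_tree, "flavor")


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        table = make_table({"a": [10, 10, 10], "b": [3, 3, 3]})
        assert np.allclose(size_factors(table), 1.0)

    def test_doubling_one_sample_doubles_only_its_factor(self):
        base = pd.DataFrame(
            {"s1": [10, 20, 5], "s2": [10, 20, 5], "s3": [20, 40, 10]},
            index=["a", "b", "c"],
        )
        factors = size_factors(CountTable(base))
        assert factors["s3"] == pytest.approx(2 * factors["s1"])
        assert factors["s1"] == pytest.approx(factors["s2"])

    def test_matches_direct_median_of_ratios(self):
        rng = np.random.default_rng(19)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.05, size=(20, 6)) + 1,
            index=[f"f{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        factors = size_factors(CountTable(counts))
        # brute-force oracle, ratio by ratio
        arr = counts.to_numpy(dtype=float)
        geo = np.array([np.prod(row) ** (1 / len(row)) for row in arr])
        for j, sample in enumerate(counts.columns):
            ratios = sorted(arr[i, j] / geo[i] for i in range(20))
            expected = np.median(ratios)
            assert factors[sample] == pytest.approx(expected, rel=1e-9)

    def test_no_all_positive_feature_errors(self):
        table = make_table({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(table)


class TestNormalize:
    def test_unit_factors_are_identity(self, taxid_table):
        factors = pd.Series(1.0, index=taxid_table.samples)
        assert normalize(taxid_table, factors).equals(
            taxid_table.counts.astype(float)
        )

    def test_round_trip_recovers_counts(self):
        rng = np.random.default_rng(7)
        counts = pd.DataFrame(rng.integers(1, 100, size=(10, 4)))
        table = CountTable(counts)
        factors = size_factors(table)
        assert np.allclose(normalize(table, factors) * factors.to_numpy(), counts)

    def test_missing_factor_errors(self, taxid_table):
        with pytest.raises(ValueError):
            normalize(taxid_table, pd.Series({"s1": 1.0}))


class TestDiffAbundance:
    def test_identical_groups_are_null(self):
        meta = pd.DataFrame(
            {"genotype": ["B", "B", "C", "C"]}, index=["s1", "s2", "s3", "s4"]
        )
        counts = pd.DataFrame(
            {"s1": [100, 30], "s2": [100, 30], "s3": [100, 30], "s4": [100, 30]},
            index=["fa", "fb"],
        )
        res = diff_abundance(CountTable(counts, meta), ("genotype", "C", "B"))
        assert np.allclose(res["log2FoldChange"], 0.0)
        assert (res["pvalue"] > 0.9).all()
        assert not res["significant"].any()

    def test_absent_level_errors(self):
        meta = pd.DataFrame({"genotype": ["B", "B", "C", "C"]}, index=list("wxyz"))
        counts = pd.DataFrame({s: [5] for s in "wxyz"}, index=["f"])
        with pytest.raises(ValueError, match="absent"):
            diff_abundance(CountTable(counts, meta), ("genotype", "Z", "B"))

    def test_true_effects_rank_first_and_fdr_is_controlled(self):
        n_true = 10
        fdps = []
        top_hits = []
        for seed in range(20):
            cfg = SyntheticConfig(
                seed=seed,
                n_features=200,
                affected_fraction=n_true / 200,
                effect_size=4.0,
            )
            table, affected = simulate_counts(cfg)
            res = diff_abundance(table, ("genotype", "C", "B"))
            top = set(res.head(n_true)["feature"])
            top_hits.append(len(top & set(affected)) / n_true)
            called = res[res["significant"]]["feature"]
            if len(called):
                fdps.append(len(set(called) - set(affected)) / len(called))
            else:
                fdps.append(0.0)
        assert np.mean(top_hits) > 0.9  # true features dominate the top ranks
        assert np.mean(fdps) <= 0.10  # empirical FDR within 2x nominal

    def test_null_rejection_rate_calibrated(self):
        rates = []
        for seed in range(100):
            cfg = SyntheticConfig(seed=seed, effect_size=1.0, n_features=50)
            table, _ = simulate_counts(cfg, n_replicates=2)  # 6 per genotype
            res = diff_abundance(table, ("genotype", "C", "B"))
            rates.append((res["pvalue"] < 0.05).mean())
        assert 0.02 <= np.mean(rates) <= 0.09

    def test_bh_adjustment_monotone_and_above_p(self):
        cfg = SyntheticConfig(seed=77, n_features=100, effect_size=2.0)
        table, _ = simulate_counts(cfg)
        res = diff_abundance(table, ("genotype", "C", "B"))
        assert (res["fdr"] >= res["pvalue"] - 1e-12).all()
        assert (np.diff(res["fdr"]) >= -1e-12).all()  # sorted by p
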