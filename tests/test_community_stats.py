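"""Bray-Curtis distances, PERMANOVA, NMDS and pathway enrichment."""

import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from rhizomine.community_stats import (
    DistanceMatrix,
    bray_curtis,
    finalize_permanova_table,
    hypergeom_enrichment,
    nmds,
    permanova,
)
from rhizomine.synthetic import SyntheticConfig, simulate_counts
from rhizomine.tables import normalize, size_factors


class TestBrayCurtis:
    def test_identical_samples_have_zero_distance(self):
        values = pd.DataFrame({"s1": [3, 5, 1], "s2": [3, 5, 1]})
        assert bray_curtis(values).data[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_have_unit_distance(self):
        values = pd.DataFrame({"s1": [3, 0, 2, 0], "s2": [0, 4, 0, 1]})
        assert bray_curtis(values).data[0, 1] == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(12)
        values = pd.DataFrame(
            rng.uniform(0, 10, size=(5, 4)), columns=list("abcd")
        )
        dm = bray_curtis(values)
        for j, sj in enumerate(values.columns):
            for k, sk in enumerate(values.columns):
                x, y = values[sj], values[sk]
                expected = np.abs(x - y).sum() / (x + y).sum()
                assert dm.data[j, k] == pytest.approx(expected, rel=1e-12)

    def test_all_zero_sample_errors(self):
        values = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(values)

    def test_negative_values_rejected(self):
        values = pd.DataFrame({"s1": [1, -2], "s2": [1, 1]})
        with pytest.raises(ValueError):
            bray_curtis(values)


def _normalized_profile(seed, effect=3.0):
    cfg = SyntheticConfig(seed=seed, effect_size=effect, n_features=30)
    table, _ = simulate_counts(cfg)
    return normalize(table, size_factors(table)), table.sample_meta


class TestPermanova:
    def test_matches_vegan_adonis2(self, tmp_path):
        """Independent oracle: vegan's adonis2 on the same data must give
        identical Df/SS/R2/F columns (permutation-free quantities)."""
        norm, meta = _normalized_profile(seed=7)
        dm = bray_curtis(norm)
        result = permanova(dm, meta, n_perm=0)
        norm.T.to_csv(tmp_path / "profile.tsv", sep="\t")
        meta.to_csv(tmp_path / "meta.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(vegan))
            args <- commandArgs(trailingOnly=TRUE)
            x <- read.delim(args[1], row.names=1)
            meta <- read.delim(args[2], row.names=1)
            d <- vegdist(x, method="bray")
            fit <- adonis2(d ~ genotype*soil, data=meta, permutations=2, by="terms")
            write.table(data.frame(Df=fit$Df, SS=fit$SumOfSqs, R2=fit$R2, F=fit$F),
                        args[3], sep="\t", quote=FALSE, row.names=FALSE)
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(
            [
                "Rscript",
                str(tmp_path / "oracle.R"),
                str(tmp_path / "profile.tsv"),
                str(tmp_path / "meta.tsv"),
                str(tmp_path / "vegan.tsv"),
            ],
            check=True,
            capture_output=True,
        )
        vegan = pd.read_csv(tmp_path / "vegan.tsv", sep="\t")
        rows = ["genotype", "soil", "genotype:soil", "Residual", "Total"]
        for i, term in enumerate(rows):
            assert result.loc[term, "Df"] == vegan.loc[i, "Df"]
            assert result.loc[term, "SS"] == pytest.approx(vegan.loc[i, "SS"], rel=1e-6)
            assert result.loc[term, "R2"] == pytest.approx(vegan.loc[i, "R2"], rel=1e-6)
            if term not in ("Residual", "Total"):
                assert result.loc[term, "pseudo_F"] == pytest.approx(
                    vegan.loc[i, "F"], rel=1e-6
                )

    def test_partition_identities(self):
        norm, meta = _normalized_profile(seed=3)
        result = permanova(bray_curtis(norm), meta, n_perm=49, seed=0)
        terms = ["genotype", "soil", "genotype:soil", "Residual"]
        assert result.loc[terms, "SS"].sum() == pytest.approx(
            result.loc["Total", "SS"], rel=1e-9
        )
        assert result.loc[terms, "R2"].sum() == pytest.approx(1.0, rel=1e-9)
        assert result.loc[terms, "Df"].sum() == 17

    def test_null_r2_near_df_expectation(self):
        # exchangeable groups: E[R2] for a 1-df term is ~ 1/(n-1)
        r2 = []
        for seed in range(40):
            norm, meta = _normalized_profile(seed=seed, effect=1.0)
            result = permanova(bray_curtis(norm), meta, n_perm=0)
            r2.append(result.loc["genotype", "R2"])
        assert np.mean(r2) == pytest.approx(1 / 17, abs=0.02)

    def test_permutation_p_respects_plus_one_floor(self):
        norm, meta = _normalized_profile(seed=1, effect=5.0)
        result = permanova(bray_curtis(norm), meta, n_perm=99, seed=5)
        p = result.loc[["genotype", "soil", "genotype:soil"], "p"]
        assert (p >= 1 / 100 - 1e-12).all()

    def test_full_enumeration_matches_brute_force_oracle(self):
        """n=6 one-way design: exact p over all 720 relabelings equals a
        brute-force within/between-group computation from raw distances."""
        from itertools import permutations as iter_permutations

        rng = np.random.default_rng(23)
        points = rng.normal(size=(6, 3))
        points[:3] += 1.0
        d = squareform(pdist(points))
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        meta = pd.DataFrame(
            {"genotype": ["B"] * 3 + ["C"] * 3}, index=dm.ids
        )
        all_perms = np.array(list(iter_permutations(range(6))))
        result = permanova(
            dm, meta, terms=("genotype",), permutations=all_perms
        )

        def oracle_f(labels):
            n = len(labels)
            ss_total = (d**2).sum() / (2 * n)
            ss_within = 0.0
            for g in set(labels):
                idx = [i for i, l in enumerate(labels) if l == g]
                sub = d[np.ix_(idx, idx)]
                ss_within += (sub**2).sum() / (2 * len(idx))
            ss_between = ss_total - ss_within
            return (ss_between / 1) / (ss_within / (n - 2))

        labels = meta["genotype"].tolist()
        f_obs = oracle_f(labels)
        assert result.loc["genotype", "pseudo_F"] == pytest.approx(f_obs, rel=1e-9)
        count = sum(
            oracle_f([labels[i] for i in perm]) >= f_obs - 1e-12
            for perm in all_perms
        )
        assert result.loc["genotype", "p"] == pytest.approx(count / 720, abs=1e-12)

    def test_missing_metadata_errors(self):
        norm, meta = _normalized_profile(seed=2)
        with pytest.raises(ValueError, match="metadata"):
            permanova(bray_curtis(norm), meta.iloc[:5], n_perm=0)


class TestFinalize:
    def test_derived_columns(self):
        table = finalize_permanova_table(
            {"Genotype": 1, "Residual": 12},
            {"Genotype": 0.3, "Residual": 1.2},
            ss_total=2.0,
        )
        assert table.loc["Genotype", "MS"] == pytest.approx(0.3)
        assert table.loc["Genotype", "pseudo_F"] == pytest.approx(0.3 / 0.1)
        assert table.loc["Genotype", "R2"] == pytest.approx(0.15)
        assert table.loc["Genotype", "explained_pct"] == pytest.approx(15.0)
        assert table.loc["Total", "R2"] == pytest.approx(1.0)

    def test_residual_required(self):
        with pytest.raises(ValueError, match="Residual"):
            finalize_permanova_table({"A": 1}, {"A": 0.5}, 1.0)


class TestNmds:
    @staticmethod
    def planar_distances(seed=0, n=12):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(n, 2))
        return DistanceMatrix([f"s{i}" for i in range(n)], squareform(pdist(pts)))

    def test_exactly_embeddable_distances_reach_low_stress(self):
        result = nmds(self.planar_distances(), k=2, n_starts=8, seed=0)
        assert result.stress < 0.01

    def test_relabeling_invariance(self):
        dm = self.planar_distances(seed=4)
        perm = [5, 2, 9, 0, 7, 1, 11, 3, 8, 10, 6, 4]
        shuffled = dm.reorder([dm.ids[i] for i in perm])
        a = nmds(dm, n_starts=1)
        b = nmds(shuffled, n_starts=1)
        assert b.stress == pytest.approx(a.stress, abs=1e-8)
        # embedded inter-sample distances agree sample-for-sample
        da = squareform(pdist(a.coordinates.loc[shuffled.ids]))
        db = squareform(pdist(b.coordinates))
        assert np.allclose(da, db, atol=1e-6)

    def test_two_cluster_structure_recovered(self):
        rng = np.random.default_rng(6)
        pts = np.vstack(
            [rng.normal(0, 0.3, size=(9, 4)), rng.normal(3, 0.3, size=(9, 4))]
        )
        dm = DistanceMatrix(
            [f"s{i}" for i in range(18)], squareform(pdist(pts))
        )
        result = nmds(dm, k=2, n_starts=8, seed=1)
        labels = [0] * 9 + [1] * 9
        assert silhouette_score(result.coordinates.to_numpy(), labels) > 0

    def test_excessive_dimension_errors(self):
        with pytest.raises(ValueError):
            nmds(self.planar_distances(n=4), k=3)


class TestHypergeomEnrichment:
    def test_matches_closed_form_tail(self):
        universe = {f"K{i}" for i in range(10)}
        pathway = {"K0", "K1", "K2"}
        selected = pathway
        result = hypergeom_enrichment(selected, universe, {"map1": pathway})
        # P(all 3 of 3 draws in the pathway) = C(3,3)C(7,0)/C(10,3)
        expected = 1 / math.comb(10, 3)
        assert result.loc[0, "p"] == pytest.approx(expected, rel=1e-12)
        assert bool(result.loc[0, "enriched"])

    def test_null_selection_p_is_uniformish(self):
        rng = np.random.default_rng(31)
        universe = [f"K{i}" for i in range(100)]
        pathways = {
            f"map{j}": set(rng.choice(universe, size=20, replace=False))
            for j in range(10)
        }
        ps = []
        for _ in range(50):
            selected = set(rng.choice(universe, size=15, replace=False))
            result = hypergeom_enrichment(selected, universe, pathways)
            ps.extend(result["p"])
        assert 0.35 < np.mean(ps) < 0.75

    def test_empty_selection_gives_no_rows(self):
        result = hypergeom_enrichment(set(), {"K0"}, {"m": {"K0"}})
        assert result.empty

    def test_selection_outside_universe_errors(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeom_enrichment({"K9"}, {"K0"}, {"m": {"K0"}})

    def test_overlap_bounded_by_set_sizes(self):
        universe = {f"K{i}" for i in range(30)}
        selected = {f"K{i}" for i in range(8)}
        pathways = {"m1": {f"K{i}" for i in range(5, 20)}}
        result = hypergeom_enrichment(selected, universe, pathways)
        row = result.iloc[0]
        assert row["overlap"] <= min(row["pathway_size"], row["selected_size"])
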