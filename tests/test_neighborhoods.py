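"""Neighbor profiles, neighborhood clustering, coverage and naming."""

import logging

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import spatialtma as s
from spatialtma.neighborhoods import ProfileSet

from conftest import archetype_config, make_cells


def brute_force_profiles(cells, k, categories):
    """Independent O(N^2) oracle: full distance matrix per core, neighbors
    chosen by (distance, cell_id) order, counts per category."""
    out = {}
    for core_id, grp in cells.groupby("core_id"):
        grp = grp.reset_index(drop=True)
        if len(grp) < k + 1:
            continue
        xy = grp[["x_um", "y_um"]].to_numpy(float)
        ids = grp["cell_id"].to_numpy()
        cats = np.where(grp["compartment"] == "epithelium", "E", "S") \
            + "_" + grp["phenotype"].to_numpy(dtype=object)
        for i in range(len(grp)):
            d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
            order = sorted((float(d[j]), ids[j], j)
                           for j in range(len(grp)) if j != i)
            counts = dict.fromkeys(categories, 0)
            for _, _, j in order[:k]:
                counts[cats[j]] += 1
            out[ids[i]] = counts
    return out


def profiles_from_counts(counts, categories, k):
    """Wrap a raw count matrix as a ProfileSet (constructed archetypes)."""
    n = len(counts)
    df = pd.DataFrame(counts, columns=categories)
    df.insert(0, "compartment", "stroma")
    df.insert(0, "phenotype", "Other")
    df.insert(0, "patient_id", "p0")
    df.insert(0, "core_id", "c0")
    df.insert(0, "cell_id", [f"c0-{i}" for i in range(n)])
    return ProfileSet(df, k=k, categories=list(categories))


class TestNeighborProfiles:
    def test_single_phenotype_collinear_core(self):
        cells = make_cells([(0, 0), (1, 0), (2, 0), (3, 0)], "CD3")
        pset = s.neighbor_profiles(cells, k=3)
        assert (pset.profiles["S_CD3"] == 3).all()
        assert pset.counts.sum(axis=1).tolist() == [3, 3, 3, 3]

    def test_default_k_is_15(self, small_cohort_labeled):
        _, cells = small_cohort_labeled
        pset = s.neighbor_profiles(cells)
        assert pset.k == 15

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        cells = make_cells(rng.random((300, 2)) * 600,
                           rng.choice(["CD3", "CD16a", "Other"], 300),
                           compartment=rng.choice(["epithelium", "stroma"], 300))
        for k in (5, 15):
            pset = s.neighbor_profiles(cells, k=k)
            oracle = brute_force_profiles(cells, k, pset.categories)
            for _, row in pset.profiles.iterrows():
                assert {c: row[c] for c in pset.categories} == oracle[row["cell_id"]]

    def test_tie_break_on_lattice(self):
        """Exact distance ties resolved by cell_id: counts still sum to k and
        match the oracle on a 5x5 integer lattice."""
        xy = [(i, j) for i in range(5) for j in range(5)]
        phen = ["CD3" if (i + j) % 2 else "CD68" for i, j in xy]
        cells = make_cells(xy, phen)
        pset = s.neighbor_profiles(cells, k=4)
        oracle = brute_force_profiles(cells, 4, pset.categories)
        for _, row in pset.profiles.iterrows():
            assert {c: row[c] for c in pset.categories} == oracle[row["cell_id"]]

    def test_small_core_excluded_with_warning(self, caplog):
        big = make_cells(np.random.default_rng(0).random((30, 2)) * 100,
                         "CD3", core_id="big")
        tiny = make_cells([(0, 0), (1, 1)], "CD3", core_id="tiny")
        cells = pd.concat([big, tiny], ignore_index=True)
        with caplog.at_level(logging.WARNING):
            pset = s.neighbor_profiles(cells, k=5)
        assert pset.excluded_cores == ["tiny"]
        assert "excluded" in caplog.text

    def test_duplicate_cell_id_errors(self):
        cells = make_cells([(0, 0), (1, 1), (2, 2)], "CD3")
        cells.loc[1, "cell_id"] = cells.loc[0, "cell_id"]
        with pytest.raises(ValueError, match="duplicate cell_id"):
            s.neighbor_profiles(cells, k=1)

    def test_invalid_k_errors(self):
        cells = make_cells([(0, 0), (1, 1)], "CD3")
        with pytest.raises(ValueError, match="k must be"):
            s.neighbor_profiles(cells, k=0)

    def test_isometry_invariance(self, small_cohort_labeled):
        """Translating and rotating a core changes no profile."""
        _, cells = small_cohort_labeled
        pset = s.neighbor_profiles(cells, k=10)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = cells.copy()
        xy = moved[["x_um", "y_um"]].to_numpy(float) @ rot.T + [123.0, -45.0]
        moved[["x_um", "y_um"]] = xy
        pset2 = s.neighbor_profiles(moved, k=10)
        assert np.array_equal(pset.counts, pset2.counts)
        assert (pset.profiles["cell_id"] == pset2.profiles["cell_id"]).all()


class TestColocalization:
    def test_single_phenotype_diagonal(self):
        cells = make_cells([(0, 0), (1, 0), (2, 0), (3, 0)], "CD3")
        coloc = s.colocalization_matrix(s.neighbor_profiles(cells, k=3))
        assert list(coloc.index) == ["S_CD3"]
        assert coloc.loc["S_CD3", "S_CD3"] == pytest.approx(100.0)

    def test_alternating_grid_is_half_half(self):
        """Two phenotypes interleaved in alternating columns on a fine grid:
        with k=4 each interior cell sees two same-column and two
        opposite-column neighbors, so each row is approximately 50/50."""
        xy = [(i * 1.0, j * 0.9) for i in range(40) for j in range(20)]
        phen = ["CD3" if i % 2 else "CD68" for i in range(40) for j in range(20)]
        coloc = s.colocalization_matrix(
            s.neighbor_profiles(make_cells(xy, phen), k=4))
        for row in coloc.index:
            for col in coloc.columns:
                assert abs(coloc.loc[row, col] - 50.0) < 5.0

    def test_rows_sum_to_100(self, small_cohort_labeled):
        _, cells = small_cohort_labeled
        coloc = s.colocalization_matrix(s.neighbor_profiles(cells, k=15))
        assert np.allclose(coloc.sum(axis=1), 100.0, atol=1e-6)

    def test_empty_profiles_error(self):
        empty = profiles_from_counts(np.empty((0, 2)), ["S_CD3", "S_Other"], 5)
        with pytest.raises(ValueError, match="no profiled cells"):
            s.colocalization_matrix(empty)


class TestClusterNeighborhoods:
    def test_n1_degenerate_full_coverage(self):
        rng = np.random.default_rng(0)
        pset = profiles_from_counts(rng.integers(0, 5, (40, 3)),
                                    ["S_A", "S_B", "S_C"], 5)
        model = s.cluster_neighborhoods(pset, n=1, seed=0)
        assert model.degenerate
        cov = s.coverage(model, pset)
        assert (cov.core[0] == 1.0).all()

    def test_two_planted_archetypes_perfect_ari(self):
        rng = np.random.default_rng(1)
        a = np.clip(rng.normal([10, 0, 5], 0.3, (50, 3)), 0, None)
        b = np.clip(rng.normal([0, 10, 5], 0.3, (50, 3)), 0, None)
        pset = profiles_from_counts(np.concatenate([a, b]),
                                    ["S_A", "S_B", "S_C"], 15)
        model = s.cluster_neighborhoods(pset, n=2, seed=0)
        truth = [0] * 50 + [1] * 50
        assert adjusted_rand_score(truth, model.labels.to_numpy()) == 1.0

    def test_n_exceeding_profiles_errors(self):
        pset = profiles_from_counts(np.ones((3, 2)), ["S_A", "S_B"], 2)
        with pytest.raises(ValueError, match="exceeds"):
            s.cluster_neighborhoods(pset, n=4, seed=0)

    def test_best_of_restarts_inertia(self):
        """Best-of-10-restarts inertia is <= any single restart's."""
        rng = np.random.default_rng(2)
        pset = profiles_from_counts(rng.integers(0, 10, (200, 4)),
                                    ["S_A", "S_B", "S_C", "S_D"], 10)
        multi = s.cluster_neighborhoods(pset, n=5, seed=0, n_init=10)
        single = s.cluster_neighborhoods(pset, n=5, seed=0, n_init=1)
        assert multi.inertia <= single.inertia + 1e-9


class TestCompositionAndSimilarity:
    def test_zscore_column_means_are_zero(self, small_cohort_labeled):
        _, cells = small_cohort_labeled
        pset = s.neighbor_profiles(cells, k=15)
        model = s.cluster_neighborhoods(pset, n=5, seed=0)
        comp = s.neighborhood_composition(model, pset)
        assert np.allclose(comp.zscores.mean(axis=0), 0.0, atol=1e-9)

    def test_n1_composition_degenerate(self):
        pset = profiles_from_counts(np.ones((10, 2)), ["S_A", "S_B"], 2)
        model = s.cluster_neighborhoods(pset, n=1, seed=0)
        comp = s.neighborhood_composition(model, pset)
        assert comp.degenerate and comp.zscores is None
        assert np.allclose(comp.mean_counts.to_numpy(), 1.0)

    def test_planted_hotspot_maximizes_cd16a_zscore(self, small_cohort_labeled):
        cohort, cells = small_cohort_labeled
        pset = s.neighbor_profiles(cells, k=15)
        model = s.cluster_neighborhoods(pset, n=6, seed=0)
        comp = s.neighborhood_composition(model, pset)
        # neighborhood holding most hotspot cells
        truth = cohort.truth_cells.set_index("cell_id")["planted_id"]
        lab = model.labels
        hot_nb = lab[truth.reindex(lab.index).to_numpy() >= 0].mode()[0]
        z = comp.zscores
        cd16_cols = [c for c in z.columns if "CD16a" in c]
        assert z.loc[hot_nb].idxmax() in cd16_cols

    def test_similarity_closed_forms(self):
        pset = profiles_from_counts(np.ones((3, 3)), ["S_A", "S_B", "S_C"], 2)
        model = s.cluster_neighborhoods(pset, n=1, seed=0)
        model.centroids = pd.DataFrame([[1, 1, 0], [1, 0, 1], [0, 1, 1]],
                                       columns=["S_A", "S_B", "S_C"])
        model.n = 3
        sim, flagged = s.neighborhood_similarity(model)
        assert sim.loc[0, 1] == pytest.approx(0.5)
        assert sim.loc[0, 0] == pytest.approx(1.0)
        assert flagged == []

    def test_identical_centroids_flagged(self):
        pset = profiles_from_counts(np.ones((2, 2)), ["S_A", "S_B"], 2)
        model = s.cluster_neighborhoods(pset, n=1, seed=0)
        model.centroids = pd.DataFrame([[1.0, 2.0], [2.0, 4.0]],
                                       columns=["S_A", "S_B"])
        model.n = 2
        sim, flagged = s.neighborhood_similarity(model)
        assert sim.loc[0, 1] == pytest.approx(1.0)
        assert flagged == [(0, 1)]

    def test_zero_centroid_similarity_missing(self):
        pset = profiles_from_counts(np.ones((2, 2)), ["S_A", "S_B"], 2)
        model = s.cluster_neighborhoods(pset, n=1, seed=0)
        model.centroids = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]],
                                       columns=["S_A", "S_B"])
        model.n = 2
        sim, flagged = s.neighborhood_similarity(model)
        assert np.isnan(sim.loc[0, 1]) and flagged == []


class TestSelectKN:
    def _archetype_profiles(self, n_arch, per=60, spread=0.3, k=15, seed=0):
        rng = np.random.default_rng(seed)
        cats = [f"S_P{i}" for i in range(n_arch)]
        blocks = [np.clip(rng.normal(np.eye(n_arch)[i] * k, spread, (per, n_arch)),
                          0, None) for i in range(n_arch)]
        return profiles_from_counts(np.concatenate(blocks), cats, k)

    def test_six_archetypes_recommend_six(self):
        pset = self._archetype_profiles(6)
        diag, rec = s.select_k_n(profiles_by_k={15: pset},
                                 n_grid=(5, 6, 7, 8), seed=0)
        assert rec == (15, 6)
        row = diag[(diag.k == 15) & (diag.n == 7)].iloc[0]
        assert row["n_flagged_pairs"] > 0     # splitting creates near-duplicates

    def test_single_archetype_no_recommendation(self):
        pset = self._archetype_profiles(1, per=200)
        diag, rec = s.select_k_n(profiles_by_k={15: pset}, n_grid=(2, 3, 4),
                                 seed=0)
        assert rec is None
        assert (diag["n_flagged_pairs"] > 0).all()

    def test_default_grids(self):
        assert s.neighborhoods.DEFAULT_K_GRID == (5, 10, 15, 20)
        assert s.neighborhoods.DEFAULT_N_GRID == (5, 6, 7, 8, 9, 10)


class TestCoverage:
    def test_hand_counted_fractions(self):
        pset = profiles_from_counts(np.ones((10, 2)), ["S_A", "S_B"], 2)
        model = s.cluster_neighborhoods(pset, n=1, seed=0)
        model.n = 2
        model.labels = pd.Series([0] * 7 + [1] * 3,
                                 index=pset.profiles["cell_id"],
                                 name="neighborhood")
        cov = s.coverage(model, pset)
        assert cov.core.loc["c0", 0] == pytest.approx(0.7)
        assert cov.core.loc["c0", 1] == pytest.approx(0.3)

    def test_patient_mean_over_duplicate_cores(self):
        a = make_cells([(0, 0)] * 10, "CD3", core_id="c1", patient_id="p")
        b = make_cells([(0, 0)] * 10, "CD3", core_id="c2", patient_id="p")
        prof = pd.concat([a, b], ignore_index=True)
        prof["cell_id"] = [f"x{i}" for i in range(20)]
        pset = ProfileSet(
            prof.assign(S_CD3=1), k=1, categories=["S_CD3"])
        model = s.cluster_neighborhoods(pset, n=1, seed=0)
        model.n = 2
        labels = [0] * 6 + [1] * 4 + [0] * 8 + [1] * 2   # 0.6/0.4 and 0.8/0.2
        model.labels = pd.Series(labels, index=pset.profiles["cell_id"],
                                 name="neighborhood")
        cov = s.coverage(model, pset)
        assert cov.patient.loc["p", 0] == pytest.approx(0.7)
        assert cov.patient.loc["p", 1] == pytest.approx(0.3)

    def test_rows_sum_to_one(self, small_cohort_labeled):
        _, cells = small_cohort_labeled
        pset = s.neighbor_profiles(cells, k=15)
        model = s.cluster_neighborhoods(pset, n=6, seed=0)
        cov = s.coverage(model, pset)
        assert np.allclose(cov.core.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(cov.patient.sum(axis=1), 1.0, atol=1e-9)


class TestCoverageRatio:
    def _cov(self, patient_df):
        return s.CoverageTable(core=patient_df, patient=patient_df)

    def test_ratio_arithmetic(self):
        cov = self._cov(pd.DataFrame({0: [0.5], 1: [0.25]}, index=["p"]))
        assert s.coverage_ratio(cov, 0, 1).loc["p"] == pytest.approx(2.0)

    def test_zero_denominator_missing(self, caplog):
        cov = self._cov(pd.DataFrame({0: [0.5], 1: [0.0]}, index=["p"]))
        with caplog.at_level(logging.WARNING):
            ratio = s.coverage_ratio(cov, 0, 1)
        assert np.isnan(ratio.loc["p"])
        assert "zero denominator" in caplog.text

    def test_zero_numerator_is_zero(self):
        cov = self._cov(pd.DataFrame({0: [0.0], 1: [0.5]}, index=["p"]))
        assert s.coverage_ratio(cov, 0, 1).loc["p"] == 0.0

    def test_unknown_id_errors(self):
        cov = self._cov(pd.DataFrame({0: [0.5]}, index=["p"]))
        with pytest.raises(KeyError):
            s.coverage_ratio(cov, 0, 9)


class TestAnnotate:
    def _comp(self, rows, cats):
        means = pd.DataFrame(rows, columns=cats)
        if len(means) > 1:
            std = means.std(axis=0, ddof=0)
            z = (means - means.mean(axis=0)).div(std.where(std > 0, 1.0), axis=1)
        else:
            z = None
        return s.neighborhoods.CompositionResult(means, z, z is None)

    def test_pure_epithelial_is_cold_epithelium(self):
        comp = self._comp([[14.0, 1.0, 0.0], [1.0, 1.0, 13.0]],
                          ["E_PanCK", "S_Other", "S_CD16a"])
        names = s.annotate_neighborhoods(comp)
        assert names[0] == "cold epithelium"

    def test_cd16a_stromal_enriched(self):
        comp = self._comp([[14.0, 1.0, 0.0], [1.0, 1.0, 13.0]],
                          ["E_PanCK", "S_Other", "S_CD16a"])
        assert s.annotate_neighborhoods(comp)[1] == "CD16a enriched stroma"

    def test_all_other_fallback_name(self):
        comp = self._comp([[0.0, 0.0]], ["S_CD3", "S_CD16a"])
        assert s.annotate_neighborhoods(comp)[0] == "N0"

    def test_override_wins(self):
        comp = self._comp([[14.0, 1.0, 0.0], [1.0, 1.0, 13.0]],
                          ["E_PanCK", "S_Other", "S_CD16a"])
        names = s.annotate_neighborhoods(comp, overrides={0: "tumor nest"})
        assert names[0] == "tumor nest"

    def test_immune_rank_names(self):
        comp = self._comp(
            [[12.0, 2.0, 1.0], [2.0, 12.0, 1.0], [6.0, 8.0, 1.0]],
            ["S_CD3", "S_CD68", "S_Other"])
        names = s.annotate_neighborhoods(comp, immune_threshold=0.1)
        assert "immune-rich" in names.values()
        assert any(v.startswith("immune-moderate") for v in names.values())
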