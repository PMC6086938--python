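import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from codextk import phantoms
from codextk.interactions import NeighborhoodGraph
from codextk.niches import (NicheModel, assign_cell_types, cluster_niches,
                            marker_niche_anova, niche_compartment_distribution,
                            niche_composition, niche_marker_profile)


def star_graph(neighbor_types, center_type="A"):
    """One index cell (id 1) with an explicit ring."""
    n = len(neighbor_types) + 1
    edges = np.array([[0, i] for i in range(1, n)])
    g = NeighborhoodGraph(ids=np.arange(1, n + 1), xy=np.zeros((n, 2)),
                          edges=edges, max_edge_length=1.0)
    return g, np.array([center_type] + list(neighbor_types), dtype=object)


class TestComposition:
    def test_ring_fractions(self):
        g, types = star_graph(["A", "A", "B"])
        comp, _ = niche_composition(g, types)
        assert comp.loc[1, "A"] == pytest.approx(2 / 3)
        assert comp.loc[1, "B"] == pytest.approx(1 / 3)

    def test_index_cell_excluded_from_own_ring(self):
        g, types = star_graph(["B", "B", "B"], center_type="A")
        comp, _ = niche_composition(g, types)
        assert comp.loc[1, "B"] == pytest.approx(1.0)
        assert comp.loc[1, "A"] == pytest.approx(0.0)

    def test_grid_matches_bruteforce_neighbor_tally(self, rng):
        from codextk.interactions import delaunay_graph
        pts = rng.uniform(0, 30, (200, 2))
        g = delaunay_graph(pts)
        types = rng.choice(["A", "B", "C"], 200)
        comp, _ = niche_composition(g, types)
        adj = g.adjacency_lists()
        for node in (0, 57, 123):
            neigh = [types[w] for w in adj[node]]
            if len(neigh) == 0:
                continue
            for t in "ABC":
                assert comp.loc[node, t] == pytest.approx(neigh.count(t) / len(neigh))

    def test_rows_sum_to_one_and_low_degree_excluded(self, rng):
        from codextk.interactions import delaunay_graph
        pts = rng.uniform(0, 30, (150, 2))
        g = delaunay_graph(pts)
        types = rng.choice(["A", "B"], 150)
        comp, excluded = niche_composition(g, types, min_degree=5)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0)
        deg = g.degrees()
        assert set(excluded) == set(np.asarray(g.ids)[deg < 5])


class TestClustering:
    def test_identical_compositions_single_centroid(self):
        comp = pd.DataFrame(np.tile([0.25, 0.75], (20, 1)), columns=["A", "B"])
        model = cluster_niches(comp, k=1, seed=0)
        np.testing.assert_allclose(model.centroids.iloc[0], [0.25, 0.75])

    def test_planted_archetypes_recovered(self):
        arch = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        table, g, labels, index_ids = phantoms.plant_niches(3, arch, 200, seed=1)
        comp, _ = niche_composition(g, table["type"].to_numpy(), min_degree=3)
        model = cluster_niches(comp.loc[index_ids], k=3, seed=1)
        ari = adjusted_rand_score(labels, model.assignment.loc[index_ids])
        assert ari > 0.9

    def test_inertia_non_increasing_in_k(self, rng):
        comp = pd.DataFrame(rng.dirichlet(np.ones(3), 120), columns=list("ABC"))
        inertias = [cluster_niches(comp, k=k, seed=0).inertia for k in (2, 4, 8)]
        assert inertias[0] >= inertias[1] >= inertias[2]

    def test_niche_ids_ordered_by_abundance(self, rng):
        comp = pd.DataFrame(rng.dirichlet(np.ones(3), 150), columns=list("ABC"))
        model = cluster_niches(comp, k=5, seed=0)
        ab = model.abundance().to_numpy()
        assert (np.diff(ab) <= 0).all()

    def test_k_larger_than_n_rejected(self):
        comp = pd.DataFrame(np.eye(3), columns=list("ABC"))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_niches(comp, k=10, seed=0)

    def test_deterministic_for_fixed_seed(self, rng):
        comp = pd.DataFrame(rng.dirichlet(np.ones(4), 200), columns=list("ABCD"))
        a = cluster_niches(comp, k=6, seed=3)
        b = cluster_niches(comp, k=6, seed=3)
        assert a.assignment.equals(b.assignment)


def toy_model(niche_ids, cell_ids=None):
    niche_ids = np.asarray(niche_ids)
    k = int(niche_ids.max()) + 1
    if cell_ids is None:
        cell_ids = np.arange(1, len(niche_ids) + 1)
    return NicheModel(k=k, centroids=pd.DataFrame(np.zeros((k, 1))),
                      assignment=pd.Series(niche_ids, index=cell_ids),
                      seed=0, inertia=0.0)


class TestProfiles:
    def test_single_cell_niche_profile_equals_its_expression(self):
        table = pd.DataFrame({"cell_id": [1, 2], "type": ["A", "A"],
                              "M1": [3.0, 7.0]})
        model = toy_model([0, 1])
        prof = niche_marker_profile(table, model, "A", markers=["M1"])
        assert prof.values.loc[0, "M1"] == 3.0
        assert prof.values.loc[1, "M1"] == 7.0

    def test_masked_niches_are_exactly_those_without_index_type(self):
        table = pd.DataFrame({"cell_id": [1, 2, 3], "type": ["A", "B", "A"],
                              "M1": [1.0, 2.0, 3.0]})
        model = toy_model([0, 1, 0])
        prof = niche_marker_profile(table, model, "A", markers=["M1"])
        assert not prof.empty.loc[0]
        assert prof.empty.loc[1]
        assert np.isnan(prof.values.loc[1, "M1"])

    def test_absent_index_type_rejected(self):
        table = pd.DataFrame({"cell_id": [1], "type": ["A"], "M1": [1.0]})
        with pytest.raises(ValueError, match="absent"):
            niche_marker_profile(table, toy_model([0]), "Z", markers=["M1"])

    def test_planted_niche_effect_separates_profiles(self, rng):
        # marker shifted in niches 0-1; the profile must separate them
        n = 600
        nich = rng.integers(0, 6, n)
        m = rng.normal(0, 1, n) + np.where(nich < 2, 2.0, 0.0)
        table = pd.DataFrame({"cell_id": np.arange(1, n + 1),
                              "type": ["T"] * n, "M1": m})
        prof = niche_marker_profile(table, toy_model(nich), "T", markers=["M1"])
        vals = prof.values["M1"]
        assert vals.loc[[0, 1]].min() > vals.loc[[2, 3, 4, 5]].max()


class TestCompartments:
    def test_single_compartment_all_niches_specific(self):
        model = toy_model([0, 0, 1, 1])
        frac, specific, _ = niche_compartment_distribution(
            model, pd.Series(["PALS"] * 4, index=[1, 2, 3, 4]))
        assert specific == [0, 1]
        np.testing.assert_allclose(frac.sum(axis=1), 1.0)

    def test_mixed_niche_not_flagged(self):
        model = toy_model([0, 0, 0, 0])
        comp = pd.Series(["PALS", "PALS", "MZ", "MZ"], index=[1, 2, 3, 4])
        _, specific, _ = niche_compartment_distribution(model, comp)
        assert specific == []

    def test_per_sample_abundance_sums_to_assignable_cells(self):
        model = toy_model([0, 1, 1, 2])
        comp = pd.Series(["a"] * 4, index=[1, 2, 3, 4])
        samples = pd.Series(["s1", "s1", "s2", "s2"], index=[1, 2, 3, 4])
        _, _, per_sample = niche_compartment_distribution(model, comp, samples)
        assert per_sample.to_numpy().sum() == 4


class TestAnova:
    def test_intercept_baseline_matches_hand_rss_arithmetic(self):
        # single type: the reduced model is intercept-only
        table = pd.DataFrame({"cell_id": [1, 2, 3, 4, 5, 6],
                              "type": ["T"] * 6,
                              "M": [1.0, 2.0, 3.0, 4.0, 5.0, 9.0]})
        model = toy_model([0, 0, 0, 1, 1, 1])
        res = marker_niche_anova(table, model, "M")
        y = table["M"].to_numpy()
        rss_r = ((y - y.mean()) ** 2).sum()
        g1, g2 = y[:3], y[3:]
        rss_f = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        f_hand = ((rss_r - rss_f) / 1) / (rss_f / 4)
        assert res.F == pytest.approx(f_hand)
        assert res.df_num == 1 and res.df_den == 4

    def test_matches_statsmodels_nested_anova(self, rng):
        n = 400
        types = rng.choice(["A", "B", "C"], n)
        nich = rng.integers(0, 8, n)
        y = (types == "A") * 1.0 + (nich < 2) * 0.5 + rng.normal(0, 1, n)
        table = pd.DataFrame({"cell_id": np.arange(1, n + 1), "type": types, "M": y})
        res = marker_niche_anova(table, toy_model(nich), "M")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        df = table.assign(niche=nich.astype(str))
        reduced = smf.ols("M ~ C(type)", df).fit()
        full = smf.ols("M ~ C(type) + C(niche)", df).fit()
        tab = anova_lm(reduced, full)
        assert res.F == pytest.approx(tab["F"].iloc[1], rel=1e-8)
        assert res.p == pytest.approx(tab["Pr(>F)"].iloc[1], rel=1e-6)

    def test_collinear_niche_rejected_with_explanation(self):
        # niche perfectly aliased with type
        table = pd.DataFrame({"cell_id": [1, 2, 3, 4],
                              "type": ["A", "A", "B", "B"],
                              "M": [1.0, 2.0, 3.0, 4.0]})
        model = toy_model([0, 0, 1, 1])
        with pytest.raises(ValueError, match="rank deficient"):
            marker_niche_anova(table, model, "M")

    def test_requires_two_occupied_niches(self):
        table = pd.DataFrame({"cell_id": [1, 2], "type": ["A", "B"],
                              "M": [1.0, 2.0]})
        with pytest.raises(ValueError, match="niches"):
            marker_niche_anova(table, toy_model([0, 0]), "M")


class TestAssignTypes:
    def test_external_labels_round_trip(self):
        table = pd.DataFrame({"cell_id": [1, 2], "M1": [0.1, 5.0]})
        out = assign_cell_types(table, "external_labels", labels=["x", "y"])
        assert out.tolist() == ["x", "y"]

    def test_external_label_count_mismatch_rejected(self):
        table = pd.DataFrame({"cell_id": [1, 2], "M1": [0.1, 5.0]})
        with pytest.raises(ValueError, match="match"):
            assign_cell_types(table, "external_labels", labels=["x"])

    def test_baseline_kmeans_recovers_separated_profiles(self, rng):
        n = 300
        truth = rng.integers(0, 3, n)
        profiles = np.array([[100.0, 5.0, 5.0], [5.0, 100.0, 5.0], [5.0, 5.0, 100.0]])
        X = profiles[truth] * rng.lognormal(0, 0.1, (n, 3))
        table = pd.DataFrame(X, columns=["CD4", "B220", "CD8"])
        table.insert(0, "cell_id", np.arange(1, n + 1))
        out = assign_cell_types(table, "baseline_kmeans", k=3, seed=0)
        assert adjusted_rand_score(truth, out) > 0.95

    def test_k_one_gives_single_label(self, rng):
        table = pd.DataFrame({"cell_id": [1, 2, 3],
                              "M1": rng.random(3), "M2": rng.random(3)})
        out = assign_cell_types(table, "baseline_kmeans", k=1, seed=0)
        assert out.nunique() == 1
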