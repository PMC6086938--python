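import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from codextk import interactions as ia
from codextk.interactions import (NeighborhoodGraph, bh_fdr, binomial_pvalues,
                                  chi_deviation, compare_conditions, delaunay_graph,
                                  interaction_analysis, interaction_change_summary,
                                  interaction_counts, odds_ratio_matrix)


def square_graph():
    """4 nodes, 4 edges: A-B, A-B, A-A, B-B."""
    g = NeighborhoodGraph(ids=np.arange(4), xy=np.zeros((4, 2)),
                          edges=np.array([[0, 1], [2, 3], [0, 2], [1, 3]]),
                          max_edge_length=10.0)
    return g, np.array(["A", "B", "A", "B"], dtype=object)


class TestDelaunayGraph:
    def test_triangle_has_three_edges_degree_two(self):
        g = delaunay_graph(np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 1.0]]))
        assert g.n_edges == 3
        assert g.degrees().tolist() == [2, 2, 2]

    def test_unit_grid_pruned_to_axis_edges(self, rng):
        ys, xs = np.meshgrid(np.arange(10), np.arange(10), indexing="ij")
        pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
        pts += rng.uniform(-1e-6, 1e-6, pts.shape)  # break cocircular degeneracy
        g = delaunay_graph(pts, max_edge_length=1.1)
        assert g.n_edges == 180  # 2 * 10 * 9 axis-aligned edges
        lengths = np.linalg.norm(pts[g.edges[:, 0]] - pts[g.edges[:, 1]], axis=1)
        assert lengths.max() <= 1.1

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            delaunay_graph(np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(5.0), np.arange(5.0)], axis=1)
        with pytest.raises(ValueError):
            delaunay_graph(pts)


class TestCounts:
    def test_square_graph_enumeration(self):
        g, types = square_graph()
        counts = interaction_counts(g, types)
        assert counts.loc["A", "B"] == 2
        assert counts.loc["A", "A"] == 1
        assert counts.loc["B", "B"] == 1

    def test_invariant_under_consistent_renaming(self):
        g, types = square_graph()
        counts = interaction_counts(g, types)
        renamed = interaction_counts(g, np.char.replace(types.astype(str), "A", "Z"))
        assert renamed.loc["Z", "Z"] == counts.loc["A", "A"]
        assert renamed.loc["B", "Z"] == counts.loc["A", "B"]

    def test_matches_bruteforce_edge_scan_on_planted_graph(self):
        from codextk.phantoms import plant_interactions
        table, g = plant_interactions(2000, {"A": 0.5, "B": 0.3, "C": 0.2}, seed=9)
        types = table["type"].to_numpy()
        counts = interaction_counts(g, types)
        brute = {}
        for u, v in g.edges:
            key = tuple(sorted((types[u], types[v])))
            brute[key] = brute.get(key, 0) + 1
        for (a, b), n in brute.items():
            assert counts.loc[a, b] == n

    def test_unlabeled_node_rejected(self):
        g, types = square_graph()
        types = types.copy()
        types[2] = None
        with pytest.raises(ValueError, match="type"):
            interaction_counts(g, types)


class TestOddsRatios:
    def test_square_graph_under_incident_edge_convention(self):
        g, types = square_graph()
        counts = interaction_counts(g, types)
        log_odds, observed, expected = odds_ratio_matrix(counts, incident_mode="edge")
        assert observed.loc["A", "B"] == pytest.approx(0.5)
        assert expected.loc["A", "B"] == pytest.approx(0.75 * 0.75)
        assert log_odds.loc["A", "B"] == pytest.approx(math.log(0.5 / 0.5625))

    def test_single_heterotypic_edge_gives_zero_log_odds(self):
        g = NeighborhoodGraph(ids=np.arange(2), xy=np.zeros((2, 2)),
                              edges=np.empty((0, 2)), max_edge_length=1.0)
        counts = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]],
                              index=["A", "B"], columns=["A", "B"])
        log_odds, observed, expected = odds_ratio_matrix(counts, incident_mode="edge")
        assert observed.loc["A", "B"] == 1.0
        assert expected.loc["A", "B"] == 1.0
        assert log_odds.loc["A", "B"] == 0.0

    def test_zero_count_pair_reports_minus_infinity_sentinel(self):
        counts = pd.DataFrame([[3.0, 0.0], [0.0, 2.0]],
                              index=["A", "B"], columns=["A", "B"])
        log_odds, _, _ = odds_ratio_matrix(counts)
        assert np.isneginf(log_odds.loc["A", "B"])

    def test_default_convention_centred_under_random_labels(self):
        from codextk.phantoms import plant_interactions
        table, g = plant_interactions(3000, {"A": 0.5, "B": 0.5}, seed=11)
        res = interaction_analysis(g, table["type"].to_numpy())
        finite = res.log_odds.to_numpy()[np.isfinite(res.log_odds.to_numpy())]
        assert np.abs(finite).max() < 0.1

    def test_zero_edges_rejected(self):
        counts = pd.DataFrame(np.zeros((2, 2)), index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError, match="zero"):
            odds_ratio_matrix(counts)


class TestBinomial:
    def test_zero_expected_zero_count_gives_p_one(self):
        counts = pd.DataFrame([[10.0, 0.0], [0.0, 0.0]],
                              index=list("AB"), columns=list("AB"))
        expected = pd.DataFrame(np.zeros((2, 2)), index=list("AB"), columns=list("AB"))
        p = binomial_pvalues(counts, expected)
        assert p.loc["A", "B"] == 1.0

    def test_ten_trials_half_probability_zero_successes(self):
        counts = pd.DataFrame([[0.0, 0.0], [0.0, 10.0]],
                              index=list("AB"), columns=list("AB"))
        expected = pd.DataFrame(np.full((2, 2), 0.5), index=list("AB"),
                                columns=list("AB"))
        p = binomial_pvalues(counts, expected)
        assert p.loc["A", "A"] == pytest.approx(2.0**-10, rel=1e-12)

    def test_normal_approximation_close_to_exact_at_boundary(self):
        # at the handover count the continuity-corrected normal tail agrees
        # with the exact sum to ~1e-3 for balanced probabilities (skewed
        # probabilities at this count are still within half a percent)
        E = 10_000
        n_obs = int(E * 0.5 * 0.95)
        exact = float(stats.binom.cdf(n_obs, E, 0.5))
        mu, sd = E * 0.5, math.sqrt(E * 0.25)
        approx = float(stats.norm.cdf((n_obs + 0.5 - mu) / sd))
        assert abs(exact - approx) < 1e-3
        for skewed in (0.01, 0.2):
            n_obs = int(E * skewed * 0.95)
            exact = float(stats.binom.cdf(n_obs, E, skewed))
            mu, sd = E * skewed, math.sqrt(E * skewed * (1 - skewed))
            approx = float(stats.norm.cdf((n_obs + 0.5 - mu) / sd))
            assert abs(exact - approx) < 5e-3


class TestBHFDR:
    def test_all_equal_pvalues_unchanged(self):
        q = bh_fdr(np.full(7, 0.2))
        np.testing.assert_allclose(q, 0.2)

    def test_hand_computed_step_up(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.04, 0.05]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.05, 0.05])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance_and_statsmodels_agreement(self, ps, rnd):
        p = np.array(ps)
        q = bh_fdr(p)
        perm = np.array(rnd.sample(range(len(p)), len(p)))
        assert np.allclose(bh_fdr(p[perm]), q[perm])
        from statsmodels.stats.multitest import multipletests
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)


class TestCompareConditions:
    def make_matrices(self, base, n, jitter, rng):
        out = []
        for _ in range(n):
            m = base + rng.normal(0, jitter, base.shape)
            m = np.maximum((m + m.T) / 2, 0)
            out.append(pd.DataFrame(m, index=list("AB"), columns=list("AB")))
        return out

    def test_identical_conditions_give_zero_t(self, rng):
        base = np.array([[30.0, 20.0], [20.0, 50.0]])
        ms = self.make_matrices(base, 3, 0.0, rng)
        out = compare_conditions(ms, [m.copy() for m in ms])
        assert (out["t"] == 0).all()
        assert (out["p"] == 1.0).all()

    def test_textbook_two_sample_t(self):
        # values {1,2,3} vs {4,5,6} on one pair, via matrices with equal totals
        def mat(v):
            return pd.DataFrame([[v, 10.0], [10.0, 100.0 - v - 20.0]],
                                index=list("AB"), columns=list("AB"))
        a = [mat(1.0), mat(2.0), mat(3.0)]
        b = [mat(4.0), mat(5.0), mat(6.0)]
        out = compare_conditions(b, a).set_index(["type_a", "type_b"])
        t = out.loc[("A", "A"), "t"]
        assert t == pytest.approx(-3.6742346, abs=1e-4)

    def test_planted_shift_has_minimum_q(self, rng):
        base = np.array([[30.0, 20.0], [20.0, 50.0]])
        a = self.make_matrices(base, 3, 1.0, rng)
        shifted = base.copy()
        shifted[0, 1] = shifted[1, 0] = 45.0
        b = self.make_matrices(shifted, 3, 1.0, rng)
        out = compare_conditions(a, b).set_index(["type_a", "type_b"])
        assert out["q"].idxmin() == ("A", "B")

    def test_requires_two_samples_per_condition(self):
        m = pd.DataFrame(np.ones((2, 2)), index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError, match="2 samples"):
            compare_conditions([m], [m, m])


class TestChiDeviation:
    def test_zero_on_reference_equal_matrix(self):
        m = np.arange(9.0).reshape(3, 3)
        res = chi_deviation(m, m, np.ones((3, 3)))
        assert res.chi == 0.0

    def test_single_element_one_sd_off_gives_one(self):
        mu = np.zeros((3, 3))
        x = mu.copy()
        x[1, 2] = 2.0
        res = chi_deviation(x, mu, np.full((3, 3), 2.0))
        assert res.chi == pytest.approx(1.0)

    def test_hand_computed_three_by_three(self):
        x = np.array([[1.0, 2.0, 0.0], [4.0, 2.0, 1.0], [0.0, 1.0, 3.0]])
        mu = np.full((3, 3), 1.0)
        sd = np.full((3, 3), 0.5)
        expected = math.sqrt(sum(((v - 1.0) / 0.5) ** 2 for v in x.ravel()))
        assert chi_deviation(x, mu, sd).chi == pytest.approx(expected)

    def test_matches_bruteforce_loop(self, rng):
        x = rng.normal(2, 1, (4, 4))
        mu = rng.normal(2, 1, (4, 4))
        sd = rng.uniform(0.5, 2, (4, 4))
        brute = math.sqrt(sum(((x[i, j] - mu[i, j]) / sd[i, j]) ** 2
                              for i in range(4) for j in range(4)))
        assert chi_deviation(x, mu, sd).chi == pytest.approx(brute)

    def test_monotone_under_deviation_amplification(self, rng):
        mu = rng.normal(0, 1, (3, 3))
        sd = rng.uniform(0.5, 1.5, (3, 3))
        x = mu + rng.normal(0, 1, (3, 3))
        chis = [chi_deviation(mu + s * (x - mu), mu, sd).chi for s in (1, 2, 5)]
        assert chis[0] < chis[1] < chis[2]

    def test_zero_sd_elements_excluded_and_counted(self):
        sd = np.ones((2, 2))
        sd[0, 0] = 0.0
        res = chi_deviation(np.ones((2, 2)), np.zeros((2, 2)), sd)
        assert res.n_excluded == 1
        assert res.chi == pytest.approx(math.sqrt(3.0))

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            chi_deviation(np.ones((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))


class TestChangeSummary:
    def analysis_of(self, seed, attraction=None):
        from codextk.phantoms import plant_interactions
        table, g = plant_interactions(1500, {"A": 0.25, "B": 0.25, "C": 0.5},
                                      attraction=attraction, seed=seed)
        return interaction_analysis(g, table["type"].to_numpy())

    def test_identical_conditions_give_zero_deltas_and_nan_r2(self):
        res = self.analysis_of(3)
        table, summary = interaction_change_summary(res, res)
        assert np.allclose(table["delta_count"], 0)
        assert np.isnan(summary["r2_odds_vs_count"])

    def test_hand_ols_on_three_pair_table(self):
        x = np.array([0.1, 0.5, 0.9])
        y = np.array([10.0, 30.0, 35.0])
        r = stats.linregress(x, y)
        # same arithmetic as the summary's R^2 (closed-form least squares)
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        r2_hand = sxy**2 / (((x - x.mean())**2).sum() * ((y - y.mean())**2).sum())
        assert r.rvalue**2 == pytest.approx(r2_hand)

    def test_frequency_driven_change_scores_higher_frequency_r2(self, rng):
        # counts scale with type frequencies at fixed mixing: the frequency
        # co-distribution should explain the count changes better than the
        # odds co-distribution
        import warnings
        from codextk.phantoms import plant_interactions
        res_a = self.analysis_of(21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table_b, g_b = plant_interactions(
                1500, {"A": 0.45, "B": 0.1, "C": 0.45}, seed=22)
        res_b = interaction_analysis(g_b, table_b["type"].to_numpy())
        _, summary = interaction_change_summary(res_a, res_b)
        assert summary["r2_freq_vs_count"] > summary["r2_odds_vs_count"]
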