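import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from admetk import netstats as ns


class TestPairwiseCorrelation:
    def test_perfect_linearity(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame([x, 2 * x], index=["a", "b"])
        c, p = ns.pairwise_correlation(df, "pearson")
        assert c.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(c), 1.0)

    def test_monotone_transform_spearman(self):
        x = np.arange(1, 11, dtype=float)
        df = pd.DataFrame([x, x**3], index=["a", "b"])
        c_s, _ = ns.pairwise_correlation(df, "spearman")
        c_p, _ = ns.pairwise_correlation(df, "pearson")
        assert c_s.loc["a", "b"] == pytest.approx(1.0)
        assert c_p.loc["a", "b"] < 1.0

    def test_p_matches_t_transform(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(2, 20)), index=["a", "b"])
        c, p = ns.pairwise_correlation(df, "pearson")
        r = c.loc["a", "b"]
        n = 20
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p_oracle = 2 * stats.t.sf(abs(t), df=n - 2)
        assert p.loc["a", "b"] == pytest.approx(p_oracle, rel=1e-10)

    def test_constant_vector_recorded_missing(self):
        df = pd.DataFrame([[1.0] * 5, [1, 2, 3, 4, 5]], index=["a", "b"])
        c, p = ns.pairwise_correlation(df)
        assert np.isnan(c.loc["a", "b"]) and np.isnan(p.loc["a", "b"])

    def test_pairwise_complete_minimum(self):
        df = pd.DataFrame(
            [[1, 2, np.nan, np.nan, np.nan], [1, 2, 3, 4, 5]], index=["a", "b"]
        )
        c, _ = ns.pairwise_correlation(df, min_obs=3)
        assert np.isnan(c.loc["a", "b"])  # only 2 shared observations


class TestHolm:
    def test_hand_computed_step_down(self):
        np.testing.assert_allclose(
            ns.holm_adjust([0.01, 0.02, 0.30]), [0.03, 0.04, 0.30]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ns.holm_adjust([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(ns.holm_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            ns.holm_adjust([0.5, 1.5])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=25)
        np.testing.assert_allclose(
            ns.holm_adjust(p), multipletests(p, method="holm")[1]
        )

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_permutation_equivariant(self, p):
        p = np.array(p)
        adj = ns.holm_adjust(p)
        assert np.all(adj >= p - 1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(ns.holm_adjust(p[perm]), adj[perm])


class TestNetwork:
    def test_perfect_triangle(self):
        t = np.arange(12, dtype=float)
        df = pd.DataFrame([t, 2 * t + 1, 3 * t - 2], index=list("abc"))
        c, p = ns.pairwise_correlation(df)
        net = ns.build_network(c, p, coef_min=0.75, alpha=0.05)
        assert sorted(d for _, d in net.graph.degree) == [2, 2, 2]

    def test_coefficient_threshold_is_hard(self):
        ids = ["a", "b"]
        c = pd.DataFrame([[1.0, 0.74], [0.74, 1.0]], index=ids, columns=ids)
        p = pd.DataFrame([[np.nan, 1e-9], [1e-9, np.nan]], index=ids, columns=ids)
        net = ns.build_network(c, p, coef_min=0.75, alpha=0.05, adjust=False)
        assert net.graph.number_of_edges() == 0

    def test_edge_set_shrinks_as_thresholds_tighten(self):
        rng = np.random.default_rng(3)
        latent = rng.normal(size=30)
        df = pd.DataFrame(
            [latent + rng.normal(0, s, 30) for s in (0.1, 0.2, 0.5, 1.0, 2.0)],
            index=list("abcde"),
        )
        c, p = ns.pairwise_correlation(df)
        loose = ns.build_network(c, p, coef_min=0.5, alpha=0.10)
        tight = ns.build_network(c, p, coef_min=0.9, alpha=0.01)
        assert set(tight.graph.edges) <= set(loose.graph.edges)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(4, 15)), index=list("abcd"))
        c1, p1 = ns.pairwise_correlation(df)
        perm = rng.permutation(df.shape[1])
        c2, p2 = ns.pairwise_correlation(df.iloc[:, perm])
        n1 = ns.build_network(c1, p1, coef_min=0.3, alpha=0.5)
        n2 = ns.build_network(c2, p2, coef_min=0.3, alpha=0.5)
        assert set(n1.graph.edges) == set(n2.graph.edges)

    def test_restriction_to_parent_neighbours(self, sim_default):
        from admetk.endogenous import pqn_normalise

        matrix, truth, _ = sim_default
        norm, _ = pqn_normalise(matrix)
        exp_ids = [s.sample_id for s in matrix.samples if s.cls == "exposed"]
        ids = [truth.parent_feature_id] + sorted(truth.coupled_signs)[:10] + [
            f for f in matrix.feature_ids if f.startswith("ENDO") and
            not f.startswith(("ENDO_DC", "ENDO_CS"))
        ][:10]
        df = norm.to_frame().loc[ids, exp_ids]
        c, p = ns.pairwise_correlation(df, "spearman")
        net = ns.build_network(
            c, p, coef_min=0.9, alpha=0.05, adjust=False,
            restrict_to_neighbors_of=truth.parent_feature_id,
        )
        linked = set(net.graph.nodes) - {truth.parent_feature_id}
        assert linked  # coupled features present
        assert all(net.graph.has_edge(truth.parent_feature_id, n) for n in linked)


def fisher_oracle(N, K, n, k):
    """Brute-force hypergeometric upper-tail sum."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / math.comb(N, n)


class TestOverRepresentation:
    def test_known_table(self):
        # N=20, K=5, n=8, k=4 -> 7280/125970
        universe = {f"l{i}": ("SM" if i < 5 else "PC") for i in range(20)}
        selected = [f"l{i}" for i in range(4)] + [f"l{i}" for i in range(5, 9)]
        res = ns.over_representation(universe, selected).set_index("class")
        assert res.loc["SM", "p_value"] == pytest.approx(
            fisher_oracle(20, 5, 8, 4), abs=1e-12
        )
        assert res.loc["SM", "p_value"] == pytest.approx(0.0578, abs=5e-4)

    def test_zero_hits_p_one(self):
        universe = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        res = ns.over_representation(universe, ["c"]).set_index("class")
        assert res.loc["X", "p_value"] == pytest.approx(1.0)

    def test_selected_equals_universe(self):
        universe = {f"i{i}": ("A" if i % 2 else "B") for i in range(10)}
        res = ns.over_representation(universe, list(universe))
        assert np.allclose(res["p_value"], 1.0)

    def test_matches_bruteforce_on_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            N = int(rng.integers(4, 31))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = {f"i{i}": ("A" if i < K else "B") for i in range(N)}
            selected = [f"i{i}" for i in rng.choice(N, size=n, replace=False)]
            k = sum(1 for s in selected if universe[s] == "A")
            res = ns.over_representation(universe, selected).set_index("class")
            assert res.loc["A", "p_value"] == pytest.approx(
                fisher_oracle(N, K, n, k), abs=1e-12
            )

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            ns.over_representation({}, [])
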