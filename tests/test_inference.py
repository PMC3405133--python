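import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acst import inference
from acst.inference import (
    bonferroni,
    empirical_pvalue,
    fdr_point_estimate,
    permutation_null,
    permute_labels,
    repeatability,
)
from acst.synthetic_fixtures import cascade_pathway, random_pathway, simulate_expression


class TestPermuteLabels:
    def test_group_sizes_preserved(self, rng):
        labels = np.array(["A", "A", "B", "B", "B"], dtype=object)
        for _ in range(20):
            out = permute_labels(labels, rng)
            assert sorted(out) == sorted(labels)

    def test_seeded_sequence_reproducible(self):
        labels = np.array(["A"] * 3 + ["B"] * 3, dtype=object)
        seq1 = [permute_labels(labels, np.random.default_rng(7)).tolist() for _ in range(1)]
        a = np.random.default_rng(7)
        b = np.random.default_rng(7)
        for _ in range(10):
            assert permute_labels(labels, a).tolist() == permute_labels(labels, b).tolist()


class TestPermutationNull:
    @pytest.fixture(scope="class")
    @staticmethod
    def setup():
        catalog = [random_pathway(8, 10, seed=i, pathway_id=f"p{i}") for i in range(3)]
        dataset = simulate_expression(catalog, seed=11)
        return dataset, catalog

    def test_deterministic(self, setup):
        dataset, catalog = setup
        a = permutation_null(dataset, catalog, B=20, seed=5)
        b = permutation_null(dataset, catalog, B=20, seed=5)
        np.testing.assert_array_equal(a.stats, b.stats)
        np.testing.assert_array_equal(a.observed, b.observed)

    def test_observed_shares_code_path_with_null(self, setup):
        # observed statistic equals scoring the true labeling as a "permutation"
        dataset, catalog = setup
        null = permutation_null(dataset, catalog, B=10, seed=5)
        from acst.core_stats import gene_stats, gene_universe
        from acst.consistency_engine import global_statistic

        universe = gene_universe(dataset, catalog)
        stats = gene_stats(dataset, universe)
        t = {s.gene: s.t for s in stats}
        z = {s.gene: s.z for s in stats}
        for i, g in enumerate(catalog):
            assert null.observed[i] == pytest.approx(
                global_statistic(g, t, z).global_stat, rel=1e-9, abs=1e-9
            )

    def test_shapes(self, setup):
        dataset, catalog = setup
        null = permutation_null(dataset, catalog[:1], B=13, seed=0)
        assert null.stats.shape == (1, 13)
        assert null.observed.shape == (1,)

    def test_b_guard(self, setup):
        dataset, catalog = setup
        with pytest.raises(ValueError, match="B must be"):
            permutation_null(dataset, catalog, B=0, seed=0)

    def test_standardization_equalizes_scales(self):
        # under the null, the standardized local statistics of observed and
        # permuted labelings are on one scale: both are mean-0/sd-1 by
        # construction, so permuted global statistics are comparable to the
        # observed one rather than systematically smaller
        catalog = [random_pathway(10, 12, seed=41, pathway_id="q")]
        dataset = simulate_expression(catalog, seed=42)
        null = permutation_null(dataset, catalog, B=200, seed=43)
        obs = null.observed[0]
        lo, hi = np.quantile(null.stats[0], [0.01, 0.99])
        assert lo <= obs <= hi


class TestEmpiricalPvalue:
    def test_observed_beats_all(self):
        assert empirical_pvalue(10.0, np.zeros(1000)) == pytest.approx(1 / 1001)

    def test_observed_is_minimum(self):
        assert empirical_pvalue(0.0, np.ones(1000)) == 1.0

    def test_count_arithmetic(self):
        null = np.concatenate([np.full(49, 5.0), np.full(951, -5.0)])
        assert empirical_pvalue(0.0, null) == pytest.approx(50 / 1001)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, np.array([]))

    @given(
        st.floats(-10, 10),
        st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=200),
    )
    def test_bounds(self, obs, null):
        p = empirical_pvalue(obs, np.array(null))
        assert 1 / (len(null) + 1) <= p <= 1.0


def fdr_oracle(observed, stats):
    """Straight transcription of the estimator: V̂/R capped at 1, then the
    step-up running minimum over thresholds below each statistic."""
    observed = np.asarray(observed, float)
    stats = np.asarray(stats, float)
    raw = []
    for c in observed:
        R = (observed >= c).sum()
        V = (stats >= c).sum() / stats.shape[1]
        raw.append(min(1.0, V / R))
    adj = []
    for k, c in enumerate(observed):
        adj.append(min(r for r, cc in zip(raw, observed) if cc <= c))
    return np.array(adj)


class TestFdrPointEstimate:
    def test_toy_instance_hand_computed(self):
        # observed (5,3,1); null columns (0,0,0) and (4,0,0):
        #   c=5: R=1, V̂=0            → 0
        #   c=3: R=2, V̂=(0+1)/2=0.5  → 1/4
        #   c=1: R=3, V̂=(0+1)/2=0.5  → 1/6
        # step-up pass: (0, 1/6, 1/6)
        observed = np.array([5.0, 3.0, 1.0])
        stats = np.array([[0.0, 4.0], [0.0, 0.0], [0.0, 0.0]])
        adj = fdr_point_estimate(observed, stats)
        np.testing.assert_allclose(adj, [0.0, 1 / 6, 1 / 6])
        np.testing.assert_allclose(adj, fdr_oracle(observed, stats))

    def test_all_null_below_gives_zero(self):
        observed = np.array([3.0, 2.0, 1.0])
        stats = np.full((3, 10), -1.0)
        np.testing.assert_array_equal(fdr_point_estimate(observed, stats), np.zeros(3))

    def test_single_pathway_reduces_to_exceedance_mean(self, rng):
        observed = np.array([0.3])
        stats = rng.normal(size=(1, 50))
        expected = min(1.0, float((stats >= 0.3).mean()))
        assert fdr_point_estimate(observed, stats)[0] == pytest.approx(expected)

    def test_capped_at_one(self, rng):
        observed = np.array([-5.0, -6.0])
        stats = rng.normal(size=(2, 40))
        adj = fdr_point_estimate(observed, stats)
        assert np.all(adj <= 1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_oracle_and_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        m, B = int(rng.integers(1, 8)), int(rng.integers(1, 12))
        observed = rng.normal(size=m)
        stats = rng.normal(size=(m, B))
        adj = fdr_point_estimate(observed, stats)
        np.testing.assert_allclose(adj, fdr_oracle(observed, stats), rtol=1e-12)
        order = np.argsort(observed)
        assert np.all(np.diff(adj[order]) <= 1e-12)  # non-increasing in statistic
        assert np.all((adj >= 0) & (adj <= 1))

    def test_invariant_to_pathway_order(self, rng):
        observed = rng.normal(size=6)
        stats = rng.normal(size=(6, 9))
        perm = rng.permutation(6)
        adj = fdr_point_estimate(observed, stats)
        adj_perm = fdr_point_estimate(observed[perm], stats[perm])
        np.testing.assert_allclose(adj[perm], adj_perm, rtol=1e-12)

    def test_ties_share_value(self):
        observed = np.array([2.0, 2.0, 1.0])
        stats = np.array([[1.5], [0.0], [0.0]])
        adj = fdr_point_estimate(observed, stats)
        assert adj[0] == adj[1]


class TestRepeatability:
    def test_identical_ranking(self):
        rho, F, p = repeatability([0.1, 0.2, 0.3, 0.4], [0.01, 0.02, 0.03, 0.04])
        assert rho == pytest.approx(1.0)
        assert F == float("inf")
        assert p == 0.0

    def test_reversed_ranking(self):
        rho, _, _ = repeatability([0.1, 0.2, 0.3, 0.4], [0.4, 0.3, 0.2, 0.1])
        assert rho == pytest.approx(-1.0)

    def test_f_statistic_formula(self, rng):
        a = rng.random(20)
        b = 0.5 * a + rng.random(20)
        rho, F, p = repeatability(a, b)
        assert F == pytest.approx(rho**2 * 18 / (1 - rho**2))
        assert 0 <= p <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            repeatability([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            repeatability([0.1, 0.2], [0.1, 0.2, 0.3])


def test_bonferroni():
    np.testing.assert_allclose(bonferroni([0.01, 0.4]), [0.02, 0.8])
    np.testing.assert_allclose(bonferroni([0.01, 0.4], k=10), [0.1, 1.0])


class TestAnalyze:
    def test_planted_pathway_detected(self):
        decoys = [random_pathway(8, 10, seed=100 + i, pathway_id=f"d{i}") for i in range(4)]
        planted, plant = cascade_pathway(8, 4, n_extra_edges=5, seed=9, pathway_id="planted")
        catalog = decoys + [planted]
        dataset = simulate_expression(catalog, [plant], n_test=10, n_control=10, seed=21, effect=3.0)
        results = inference.analyze(dataset, catalog, B=200, seed=2)
        by_id = {r.pathway_id: r for r in results}
        assert by_id["planted"].pvalue == min(r.pvalue for r in results)
        assert by_id["planted"].pvalue <= 0.05
        assert set(plant.cascade_nodes) <= set(by_id["planted"].top_subgraph_nodes)

    def test_pvalues_within_bounds(self):
        catalog = [random_pathway(8, 10, seed=i, pathway_id=f"p{i}") for i in range(3)]
        dataset = simulate_expression(catalog, seed=33)
        results = inference.analyze(dataset, catalog, B=50, seed=3)
        for r in results:
            assert 1 / 51 <= r.pvalue <= 1.0
            assert 0.0 <= r.adj_pvalue <= 1.0
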