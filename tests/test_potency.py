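import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse.linalg import eigsh
from scipy.stats import spearmanr

from scpotency import (
    ccat,
    ccat_matrix,
    cm_entropy,
    diffusion_chain,
    entropy_rate,
    gcs,
    gene_count,
    invariant_measure,
    normalize_log,
    score_all,
    sr_approximation,
    stemid_entropy,
    transition_matrix,
)
from scpotency.synthetic import generate_network, simulate_cells

from conftest import complete_net, random_connected_net


class TestTransitionMatrix:
    def test_complete_graph_uniform_rows(self):
        net = complete_net(3)
        P = transition_matrix(np.ones(3), net).toarray()
        off = P[~np.eye(3, dtype=bool)]
        assert off == pytest.approx(1 / 2)

    def test_path_hand_values(self, path_net):
        # a-b-c with x=(1,1,2): flux from b splits 1:2 between a and c
        P = transition_matrix(np.array([1.0, 1.0, 2.0]), path_net).toarray()
        assert P[1, 0] == pytest.approx(1 / 3)
        assert P[1, 2] == pytest.approx(2 / 3)
        assert P[0, 1] == pytest.approx(1.0)
        assert P[2, 1] == pytest.approx(1.0)

    def test_rows_sum_to_one(self, star_net):
        rng = np.random.default_rng(1)
        P = transition_matrix(rng.uniform(0.1, 5, 4), star_net)
        assert np.asarray(P.sum(axis=1)).ravel() == pytest.approx(np.ones(4), abs=1e-12)

    def test_nonpositive_x_rejected(self, path_net):
        with pytest.raises(ValueError, match="pseudocount"):
            transition_matrix(np.array([1.0, 0.0, 1.0]), path_net)


class TestInvariantMeasure:
    def test_path_uniform_hand_value(self, path_net):
        pi = invariant_measure(np.ones(3), path_net)
        assert pi == pytest.approx([1 / 4, 1 / 2, 1 / 4])

    def test_star_uniform_hand_value(self, star_net):
        pi = invariant_measure(np.ones(4), star_net)
        expected = {"c": 1 / 2, "l1": 1 / 6, "l2": 1 / 6, "l3": 1 / 6}
        assert pi == pytest.approx([expected[g] for g in star_net.node_ids])

    def test_regular_graph_uniform(self):
        net = complete_net(5)
        assert invariant_measure(np.ones(5), net) == pytest.approx(np.full(5, 1 / 5))

    def test_stationarity(self, path_net):
        x = np.array([0.3, 1.7, 0.9])
        chain = diffusion_chain(x, path_net)
        assert chain.pi @ chain.P.toarray() == pytest.approx(chain.pi, abs=1e-12)


class TestEntropyRate:
    @pytest.mark.parametrize("n", range(3, 8))
    def test_complete_graph_closed_form(self, n):
        assert entropy_rate(np.ones(n), complete_net(n)) == pytest.approx(
            np.log(n - 1), abs=1e-10
        )

    def test_path_hand_value(self, path_net):
        assert entropy_rate(np.ones(3), path_net) == pytest.approx(0.5 * np.log(2), abs=1e-10)

    def test_star_hand_value(self, star_net):
        assert entropy_rate(np.ones(4), star_net) == pytest.approx(0.5 * np.log(3), abs=1e-10)

    def test_scale_invariance(self, star_net):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.2, 4, 4)
        for c in (1e-3, 0.5, 7.0, 1e4):
            assert entropy_rate(c * x, star_net) == pytest.approx(
                entropy_rate(x, star_net), abs=1e-10
            )

    def test_parry_upper_bound(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            net = random_connected_net(rng)
            x = rng.uniform(0.1, 10, net.n_nodes)
            lam_max = eigsh(net.adjacency.astype(float), k=1, which="LA",
                            return_eigenvectors=False)[0]
            assert 0 <= entropy_rate(x, net) <= np.log(lam_max) + 1e-10

    def test_parry_bound_attained_on_regular_graph(self):
        # on K_n the uniform x is the Parry measure: SR = log(lambda_max) = log(n-1)
        net = complete_net(6)
        lam_max = eigsh(net.adjacency.astype(float), k=1, which="LA",
                        return_eigenvectors=False)[0]
        assert entropy_rate(np.ones(6), net) == pytest.approx(np.log(lam_max), abs=1e-10)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_markov_chain_contract_on_random_graphs(seed):
    """Row-stochasticity, stationarity and detailed balance on random graphs."""
    rng = np.random.default_rng(seed)
    net = random_connected_net(rng)
    x = rng.uniform(0.05, 10, net.n_nodes)
    chain = diffusion_chain(x, net)
    P = chain.P.toarray()
    assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
    assert (P[net.adjacency.toarray() == 0] == 0).all()
    assert chain.pi.sum() == pytest.approx(1, abs=1e-12)
    assert np.abs(chain.pi @ P - chain.pi).max() < 1e-8
    flux = chain.pi[:, None] * P
    assert np.abs(flux - flux.T).max() < 1e-10
    assert (chain.S >= 0).all()


class TestSrApproximation:
    def test_path_hand_value(self, path_net):
        # S = (0, log 2, 0), x = k-weights 1 -> 1*2*log2
        assert sr_approximation(np.ones(3), path_net) == pytest.approx(2 * np.log(2))

    def test_rank_correlates_with_entropy_rate(self):
        net = generate_network(60, 3, seed=4)
        ds = simulate_cells(net=net, n_cells=100, seed=4)
        ln = normalize_log(ds.expr)
        sr = [entropy_rate(ln.values[:, j], net) for j in range(100)]
        approx = [sr_approximation(ln.values[:, j], net) for j in range(100)]
        assert spearmanr(sr, approx).statistic > 0.5


class TestCcat:
    def test_identity_and_anticorrelation(self):
        k = np.array([3.0, 2.0, 1.0])
        assert ccat(k, k) == pytest.approx(1.0)
        assert ccat(np.array([1.0, 2.0, 3.0]), k) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert ccat(np.array([1, 2, 3, 4.0]), np.array([1, 3, 2, 4.0])) == pytest.approx(0.8)

    def test_constant_profile_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(ccat(np.ones(4), np.array([1, 2, 3, 4.0])))

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.1, 5, 50)
        k = rng.integers(1, 30, 50).astype(float)
        base = ccat(x, k)
        for a, b in ((2.0, 0.0), (0.01, 3.0), (1e3, -1.0)):
            assert ccat(a * x + b, k) == pytest.approx(base, abs=1e-10)

    def test_vectorized_matches_per_cell(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0.1, 5, size=(40, 15))
        k = rng.integers(1, 20, 40).astype(float)
        vec = ccat_matrix(X, k)
        loop = [ccat(X[:, j], k) for j in range(15)]
        assert vec == pytest.approx(loop, abs=1e-12)

    def test_positively_tracks_entropy_rate_on_scale_free_net(self):
        net = generate_network(100, 3, seed=7)
        ds = simulate_cells(net=net, n_cells=100, seed=7)
        ln = normalize_log(ds.expr)
        sr = [entropy_rate(ln.values[:, j], net) for j in range(100)]
        cc = ccat_matrix(ln.values, net.degrees)
        assert spearmanr(sr, cc).statistic > 0.5


class TestCountBasedMeasures:
    def test_gene_count(self):
        assert gene_count([0, 5, 0, 2]) == 2
        assert gene_count(np.zeros(3)) == 0
        assert gene_count(np.arange(1, 8)) == 7

    def test_stemid_entropy_extremes_and_hand_value(self):
        assert stemid_entropy(np.ones(5)) == pytest.approx(np.log(5))
        assert stemid_entropy([0, 7, 0]) == pytest.approx(0.0)
        # counts (3,1): H = -(3/4)ln(3/4) - (1/4)ln(1/4) = 0.562335...
        q = np.array([0.75, 0.25])
        assert stemid_entropy([3, 1]) == pytest.approx(-(q * np.log(q)).sum(), abs=1e-12)

    def test_stemid_empty_cell_sentinel(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert np.isnan(stemid_entropy(np.zeros(4)))

    def test_cm_entropy_restriction(self):
        counts = np.array([5, 4, 3, 2, 1.0])
        # top-3 restriction: entropy of (5,4,3)/12
        q = np.array([5, 4, 3.0]) / 12
        assert cm_entropy(counts, n_top=3) == pytest.approx(-(q * np.log(q)).sum())
        # fewer expressed genes than n_top: equals whole-transcriptome entropy
        assert cm_entropy(counts, n_top=1000) == pytest.approx(stemid_entropy(counts))
        assert cm_entropy(np.ones(1000), n_top=1000) == pytest.approx(np.log(1000))

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(8)
        c = rng.integers(0, 20, 50).astype(float)
        perm = rng.permutation(50)
        assert gene_count(c[perm]) == gene_count(c)
        assert stemid_entropy(c[perm]) == pytest.approx(stemid_entropy(c))
        assert cm_entropy(c[perm], n_top=10) == pytest.approx(cm_entropy(c, n_top=10))


class TestGcs:
    def test_brute_force_oracle(self, counts_matrix):
        n_top = 2
        scores = gcs(counts_matrix, n_top=n_top)
        # independent recomputation: per-gene PCC with detected-gene counts,
        # top-2 selection, geometric mean of lognorm expression
        counts = counts_matrix.values
        gc = (counts > 0).sum(axis=0).astype(float)
        ln = np.log2(counts + 1.1)
        corr = np.zeros(5)
        for i in range(5):
            if np.std(ln[i]) > 0:
                corr[i] = np.corrcoef(ln[i], gc)[0, 1]
        top = np.argsort(-corr, kind="stable")[:n_top]
        expected = np.exp(np.log(ln[top]).mean(axis=0))
        assert scores == pytest.approx(expected, abs=1e-12)

    def test_proportional_gene_ranked_first(self):
        from scpotency import ExpressionMatrix

        rng = np.random.default_rng(9)
        counts = rng.integers(0, 6, size=(10, 8)).astype(float)
        gc = (counts > 0).sum(axis=0).astype(float)
        # gene 0's lognorm expression exactly proportional to gene count
        counts[0] = np.exp(gc) - 1.1
        m = ExpressionMatrix([f"g{i}" for i in range(10)], [f"c{j}" for j in range(8)],
                             counts - counts.min(), layer="counts")
        # recompute with the perfect gene injected post-floor shift
        m.values[0] = np.exp(gc) - 1.0
        scores_top1 = gcs(m, n_top=1, base=np.e)
        expected = np.log(m.values[0] + 1.1)
        assert np.corrcoef(scores_top1, expected)[0, 1] == pytest.approx(1.0)

    def test_n_top_saturation_warns_and_uses_all(self, counts_matrix):
        with pytest.warns(UserWarning, match="using all"):
            all_genes = gcs(counts_matrix, n_top=99)
        ln = np.log2(counts_matrix.values + 1.1)
        assert all_genes == pytest.approx(np.exp(np.log(ln).mean(axis=0)))


class TestScoreAll:
    def test_columns_match_per_cell_calls(self):
        net = generate_network(50, 2, seed=10)
        ds = simulate_cells(net=net, n_cells=12, seed=10)
        table = score_all(
            ds.expr, net,
            measures=("ccat", "sr", "sr_approx", "gene_count", "stemid_entropy", "cm_entropy"),
        )
        ln = normalize_log(ds.expr)
        for j, cid in enumerate(ds.expr.cell_ids):
            assert table.loc[cid, "ccat"] == pytest.approx(ccat(ln.values[:, j], net.degrees))
            assert table.loc[cid, "sr"] == pytest.approx(entropy_rate(ln.values[:, j], net))
            assert table.loc[cid, "sr_approx"] == pytest.approx(
                sr_approximation(ln.values[:, j], net)
            )
            assert table.loc[cid, "gene_count"] == gene_count(ds.expr.values[:, j])
            assert table.loc[cid, "stemid_entropy"] == pytest.approx(
                stemid_entropy(ds.expr.values[:, j])
            )

    def test_shape_and_range_contracts(self):
        net = generate_network(60, 3, seed=11)
        ds = simulate_cells(net=net, n_cells=40, seed=11)
        table = score_all(ds.expr, net, measures=list(
            ("ccat", "sr", "sr_approx", "gene_count", "gcs", "stemid_entropy", "cm_entropy")
        ))
        assert table.shape == (40, 7)
        assert table["ccat"].between(-1, 1).all()
        assert (table["sr"] >= 0).all()

    def test_network_measures_require_network(self, counts_matrix):
        with pytest.raises(ValueError, match="network"):
            score_all(counts_matrix, None, measures=("ccat",))
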