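"""Correlation graph, encoder blocks, pooling, head."""

import numpy as np
import pytest
from scipy import stats

from sonobag import (
    AggregateEncoderSpec,
    HeadParams,
    build_graph,
    classify_scores,
    forward_subject,
    global_max_pool,
    pearson_correlation,
)
from sonobag._autodiff import Tensor
from sonobag.graph import (
    SubjectGraph,
    forward_tensor,
    gat_block,
    gin_block,
    init_params,
    load_checkpoint,
    mlp_block,
    save_checkpoint,
)

ALL_SPECS = [
    ("gat", 1), ("gat", 2), ("gin", 1), ("gin", 2), ("mlp", 1), ("mlp", 2), ("max", 1),
]


class TestPearson:
    def test_hand_values(self):
        assert pearson_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)
        # direct evaluation of the formula: 9 / (2 sqrt 21)
        assert pearson_correlation([1, 2, 3], [1, 2, 4]) == pytest.approx(
            9.0 / (2.0 * np.sqrt(21.0)), abs=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=(2, 7))
            assert pearson_correlation(a, b) == pytest.approx(
                stats.pearsonr(a, b).statistic, abs=1e-12)

    def test_degenerate_variance_rule(self):
        assert pearson_correlation([2, 2, 2], [2, 2, 2]) == 1.0
        assert pearson_correlation([2, 2, 2], [1, 2, 3]) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [1, 2, 3])


class TestBuildGraph:
    def test_identical_rows_are_linked(self):
        g = build_graph(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]), tau=0.995)
        assert g.adjacency[0, 1] == 1 and g.adjacency[1, 0] == 1

    def test_near_but_below_threshold_is_not_linked(self):
        # corr((1,2,3),(1,2,4)) = 0.9820 < 0.995
        g = build_graph(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]]), tau=0.995)
        assert g.adjacency.sum() == 0

    def test_single_node_graph(self):
        g = build_graph(np.array([[1.0, 2.0, 3.0]]))
        assert g.S == 1 and g.adjacency.sum() == 0

    def test_matches_bruteforce_double_loop(self):
        """Oracle equivalence on 100 random matrices, exact agreement."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            S = int(rng.integers(1, 8))
            X = rng.normal(size=(S, 5))
            if rng.random() < 0.2 and S > 1:
                X[1] = X[0]  # force some exact ties / high correlations
            tau = float(rng.uniform(-0.5, 1.0))
            g = build_graph(X, tau)
            for s in range(S):
                for r in range(S):
                    want = 0 if s == r else int(pearson_correlation(X[s], X[r]) >= tau)
                    assert g.adjacency[s, r] == want
            assert np.array_equal(g.adjacency, g.adjacency.T)


class TestBlocks:
    def test_gat_isolated_node_reduces_to_self_transform(self):
        """With only the self-loop, attention weight is 1 and the output
        is elu(W h) (+ residual if dims match; here they do not)."""
        spec = AggregateEncoderSpec(kind="gat", hidden_dim=4)
        params = init_params(spec, 3, 2, seed=0)
        H = Tensor(np.array([[1.0, -2.0, 0.5]]))
        g = SubjectGraph(adjacency=np.zeros((1, 1), dtype=np.int8))
        out = gat_block(H, g, params, 0, heads=1)
        W = params["block0_head0_W"].data
        want = H.data @ W
        want = np.where(want > 0, want, np.exp(want) - 1)
        assert np.allclose(out.data, want)

    def test_gat_identical_features_full_graph_identical_rows(self):
        spec = AggregateEncoderSpec(kind="gat", hidden_dim=4)
        params = init_params(spec, 3, 2, seed=1)
        H = Tensor(np.tile([0.3, -1.0, 2.0], (4, 1)))
        g = SubjectGraph(adjacency=(np.ones((4, 4)) - np.eye(4)).astype(np.int8))
        out = gat_block(H, g, params, 0, heads=1).data
        assert np.allclose(out, out[0])

    def test_gin_no_neighbours_is_plain_mlp(self):
        spec = AggregateEncoderSpec(kind="gin", hidden_dim=4)
        params = init_params(spec, 3, 2, seed=2)
        H = Tensor(np.array([[0.2, 0.4, -0.6]]))
        g = SubjectGraph(adjacency=np.zeros((1, 1), dtype=np.int8))
        out = gin_block(H, g, params, 0, epsilon=0.0).data
        hidden = np.maximum(H.data @ params["block0_W1"].data + params["block0_b1"].data, 0)
        want = hidden @ params["block0_W2"].data + params["block0_b2"].data
        assert np.allclose(out, want)

    def test_gin_equal_connected_features_equal_outputs(self):
        spec = AggregateEncoderSpec(kind="gin", hidden_dim=4)
        params = init_params(spec, 3, 2, seed=3)
        H = Tensor(np.tile([1.0, 2.0, 3.0], (2, 1)))
        g = SubjectGraph(adjacency=np.array([[0, 1], [1, 0]], dtype=np.int8))
        out = gin_block(H, g, params, 0).data
        assert np.allclose(out[0], out[1])

    @pytest.mark.parametrize("kind", ["gat", "gin"])
    def test_block_permutation_equivariance(self, kind):
        """Oracle: recompute from the block formula on permuted inputs."""
        rng = np.random.default_rng(7)
        S = 5
        X = rng.normal(size=(S, 4))
        adj = (rng.random((S, S)) < 0.5)
        adj = np.triu(adj, 1)
        adj = (adj | adj.T).astype(np.int8)
        spec = AggregateEncoderSpec(kind=kind, hidden_dim=6)
        params = init_params(spec, 4, 2, seed=0)
        perm = rng.permutation(S)
        P = np.eye(S)[perm]

        def run(Xa, adja):
            g = SubjectGraph(adjacency=adja)
            if kind == "gat":
                return gat_block(Tensor(Xa), g, params, 0, heads=1).data
            return gin_block(Tensor(Xa), g, params, 0).data

        assert np.allclose(run(X[perm], (P @ adj @ P.T).astype(np.int8)),
                           run(X, adj)[perm], atol=1e-12)

    def test_mlp_block_ignores_graph_and_maps_rowwise(self):
        spec = AggregateEncoderSpec(kind="mlp", hidden_dim=4)
        params = init_params(spec, 3, 2, seed=4)
        H = Tensor(np.tile([0.1, 0.2, 0.3], (3, 1)))
        out = mlp_block(H, params, 0).data
        assert np.allclose(out, out[0])


class TestPoolingAndHead:
    def test_max_pool_examples(self):
        assert np.array_equal(global_max_pool(np.array([[1.0, 5.0], [3.0, 2.0]])),
                              np.array([3.0, 5.0]))
        row = np.array([[2.0, -1.0, 0.0]])
        assert np.array_equal(global_max_pool(row), row[0])
        with pytest.raises(ValueError):
            global_max_pool(np.empty((0, 3)))

    def test_max_pool_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        U = rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        assert np.array_equal(global_max_pool(U), global_max_pool(U[perm]))

    def test_uniform_head_gives_uniform_scores(self):
        head = HeadParams(deltas=np.zeros(4), betas=np.zeros((4, 3)))
        sv = classify_scores(np.array([1.0, -2.0, 0.5]), head)
        assert np.allclose(sv.sigma, 0.25)
        assert sv.k_hat == 1  # tie broken to the smallest class index

    def test_offset_head_forces_known_softmax(self):
        head = HeadParams(deltas=np.array([0.0, np.log(3.0)]), betas=np.zeros((2, 3)))
        sv = classify_scores(np.zeros(3), head)
        assert np.allclose(sv.sigma, [0.25, 0.75])
        assert sv.k_hat == 2

    def test_random_head_matches_extended_precision_formula(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            K, d = 3, 5
            head = HeadParams(deltas=rng.normal(size=K), betas=rng.normal(size=(K, d)))
            z = rng.normal(size=d)
            sv = classify_scores(z, head)
            logits = (head.deltas.astype(np.longdouble)
                      + head.betas.astype(np.longdouble) @ z.astype(np.longdouble))
            e = np.exp(logits)
            assert np.allclose(sv.sigma, (e / e.sum()).astype(float), atol=1e-12)
            assert abs(sv.sigma.sum() - 1.0) < 1e-9

    def test_overflow_safety(self):
        head = HeadParams(deltas=np.array([1000.0, 0.0]), betas=np.zeros((2, 2)))
        sv = classify_scores(np.zeros(2), head)
        assert np.isfinite(sv.sigma).all() and sv.k_hat == 1


class TestForwardSubject:
    @pytest.mark.parametrize("kind,n_blocks", ALL_SPECS)
    def test_permutation_invariance(self, kind, n_blocks):
        rng = np.random.default_rng(11)
        spec = AggregateEncoderSpec(kind=kind, n_blocks=n_blocks, hidden_dim=8)
        params = init_params(spec, 6, 3, seed=0)
        F = rng.normal(size=(7, 6))
        F[2] = F[0] + 1e-4 * rng.normal(size=6)  # create some edges
        base = forward_subject(F, spec, params).sigma
        for _ in range(5):
            perm = rng.permutation(7)
            out = forward_subject(F[perm], spec, params).sigma
            assert np.allclose(out, base, rtol=1e-5, atol=1e-8)

    def test_single_image_subject_runs_end_to_end(self):
        spec = AggregateEncoderSpec(kind="gat", hidden_dim=8)
        params = init_params(spec, 4, 2, seed=1)
        sv = forward_subject(np.random.default_rng(0).normal(size=(1, 4)), spec, params)
        assert sv.sigma.shape == (2,) and abs(sv.sigma.sum() - 1) < 1e-9

    def test_one_vs_two_blocks_generally_differ(self):
        rng = np.random.default_rng(5)
        F = rng.normal(size=(4, 6))
        s1 = AggregateEncoderSpec(kind="gat", n_blocks=1, hidden_dim=8)
        s2 = AggregateEncoderSpec(kind="gat", n_blocks=2, hidden_dim=8)
        p1 = init_params(s1, 6, 3, seed=2)
        p2 = init_params(s2, 6, 3, seed=2)
        assert not np.allclose(forward_subject(F, s1, p1).sigma,
                               forward_subject(F, s2, p2).sigma)

    def test_mlp_output_independent_of_graph(self):
        """The MLP baseline ignores adjacency by construction: identical
        output whether the features would produce edges or not."""
        rng = np.random.default_rng(8)
        spec = AggregateEncoderSpec(kind="mlp", hidden_dim=8)
        params = init_params(spec, 4, 2, seed=0)
        F = rng.normal(size=(5, 4))
        base = forward_subject(F, spec, params, tau=0.995).sigma
        assert np.allclose(forward_subject(F, spec, params, tau=-1.0).sigma, base)

    def test_max_baseline_pools_features_directly(self):
        spec = AggregateEncoderSpec(kind="max", hidden_dim=8)
        params = init_params(spec, 4, 2, seed=0)
        F = np.random.default_rng(3).normal(size=(5, 4))
        logits = forward_tensor(F, spec, params).data.ravel()
        z = F.max(axis=0)
        want = params["head_beta"].data @ z + params["head_delta"].data.ravel()
        assert np.allclose(logits, want)


def test_checkpoint_roundtrip(tmp_path):
    spec = AggregateEncoderSpec(kind="gin", n_blocks=2, hidden_dim=8)
    params = init_params(spec, 5, 3, seed=6)
    path = tmp_path / "model.json"
    save_checkpoint(path, spec, params, tau=0.995, extra={"classes": [1, 2, 3]})
    spec2, params2, tau, extra = load_checkpoint(path)
    assert spec2 == spec and tau == 0.995 and extra["classes"] == [1, 2, 3]
    F = np.random.default_rng(0).normal(size=(4, 5))
    assert np.allclose(forward_subject(F, spec, params).sigma,
                       forward_subject(F, spec2, params2).sigma)
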