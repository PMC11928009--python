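"""Message-passing layers against dense oracles, hand computations, and
finite-difference gradients."""

import numpy as np
import pytest
import scipy.sparse as sp

from conftest import random_graph
from moglearn.nn import (
    BatchNorm,
    Dropout,
    GATConv,
    GCNConv,
    TransformerConv,
    add_self_loops,
    normalize_adjacency,
    segment_softmax,
)

# ---------------------------------------------------------------------------
# dense reference implementations (independent of the sparse code paths)
# ---------------------------------------------------------------------------

def dense_gcn(X, A, W, b):
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(1)
    Ahat = A_tilde / np.sqrt(np.outer(d, d))
    return Ahat @ X @ W + b


def dense_gat(X, A, W, a_dst, a_src, b, slope=0.2):
    """Masked-softmax matrix formulation of multi-head attention."""
    n = X.shape[0]
    mask = (A + np.eye(n)) > 0
    heads = W.shape[0]
    outs = []
    for h in range(heads):
        Z = X @ W[h]
        logits = np.add.outer(Z @ a_dst[h], Z @ a_src[h])  # [i, j] = a_d.z_i + a_s.z_j
        logits = np.where(logits > 0, logits, slope * logits)
        logits = np.where(mask, logits, -np.inf)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        alpha = e / e.sum(axis=1, keepdims=True)
        outs.append(alpha @ Z)
    return np.concatenate(outs, axis=1) + b


def dense_transformer(X, A, Wq, Wk, Wv, b):
    n = X.shape[0]
    mask = (A + np.eye(n)) > 0
    q, k, v = X @ Wq, X @ Wk, X @ Wv
    scores = q @ k.T / np.sqrt(Wq.shape[1])
    scores = np.where(mask, scores, -np.inf)
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    alpha = e / e.sum(axis=1, keepdims=True)
    return alpha @ v + b


# ---------------------------------------------------------------------------
# adjacency normalization
# ---------------------------------------------------------------------------

class TestNormalizeAdjacency:
    def test_isolated_nodes_give_identity(self):
        out = normalize_adjacency(np.zeros((4, 4))).toarray()
        assert np.allclose(out, np.eye(4))

    def test_two_node_single_edge_all_half(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = normalize_adjacency(A).toarray()
        assert np.allclose(out, 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_spectral_radius_at_most_one(self, seed):
        rng = np.random.default_rng(seed)
        A, _ = random_graph(rng, rng.integers(5, 50))
        eig = np.linalg.eigvalsh(normalize_adjacency(A).toarray())
        assert np.abs(eig).max() <= 1 + 1e-8

    def test_asymmetric_input_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            normalize_adjacency(A)


# ---------------------------------------------------------------------------
# forward-pass oracles
# ---------------------------------------------------------------------------

class TestGCNForward:
    def test_single_node_identity_weight_passthrough(self, rng):
        conv = GCNConv(3, 3, rng)
        conv.W.value[...] = np.eye(3)
        conv.b.value[...] = 0
        H = np.abs(rng.normal(size=(1, 3)))
        out = conv.forward(H, normalize_adjacency(np.zeros((1, 1))))
        assert np.allclose(out, H)

    def test_zero_weight_gives_zero(self, rng):
        A, _ = random_graph(rng, 8)
        conv = GCNConv(4, 5, rng)
        conv.W.value[...] = 0
        conv.b.value[...] = 0
        assert np.allclose(conv.forward(rng.normal(size=(8, 4)), normalize_adjacency(A)), 0)

    def test_matches_dense_oracle(self, rng):
        A, _ = random_graph(rng, 30)
        conv = GCNConv(6, 4, rng)
        H = rng.normal(size=(30, 6))
        out = conv.forward(H, normalize_adjacency(A))
        ref = dense_gcn(H, A, conv.W.value, conv.b.value)
        assert np.abs(out - ref).max() < 1e-5

    def test_dimension_mismatch_errors(self, rng):
        conv = GCNConv(4, 2, rng)
        with pytest.raises(ValueError, match="dim"):
            conv.forward(rng.normal(size=(3, 5)), normalize_adjacency(np.zeros((3, 3))))


class TestGATAttention:
    def test_identical_features_give_uniform_attention(self, rng):
        A, edges = random_graph(rng, 10, 0.4)
        conv = GATConv(4, 8, 2, rng)
        H = np.tile(rng.normal(size=4), (10, 1))
        alpha, e, _, _ = conv.attention(H, edges)
        deg = np.bincount(e[1], minlength=10)
        assert np.allclose(alpha, (1.0 / deg[e[1]])[:, None])

    def test_coefficients_sum_to_one_per_node_per_head(self, rng):
        A, edges = random_graph(rng, 15, 0.3)
        conv = GATConv(5, 6, 3, rng)
        alpha, e, _, _ = conv.attention(rng.normal(size=(15, 5)), edges)
        sums = np.zeros((15, 3))
        np.add.at(sums, e[1], alpha)
        assert np.abs(sums - 1.0).max() < 1e-6

    def test_three_node_path_hand_computation(self):
        """alpha on a 3-node path with hand-set parameters, evaluated by a
        plain-python transcription of the attention formula."""
        edges = np.array([[0, 1, 1, 2], [1, 0, 2, 1]])
        rng = np.random.default_rng(0)
        conv = GATConv(2, 2, 1, rng)
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        a_dst = np.array([0.5, -0.3])
        a_src = np.array([0.2, 0.4])
        conv.W.value[0] = W
        conv.a_dst.value[0] = a_dst
        conv.a_src.value[0] = a_src
        H = np.array([[1.0, 2.0], [0.5, -1.0], [2.0, 0.0]])
        alpha, e, _, _ = conv.attention(H, edges)

        def lrelu(x):
            return x if x > 0 else 0.2 * x

        for idx in range(e.shape[1]):
            j, i = e[0, idx], e[1, idx]
            zi, zj = W.T @ H[i], W.T @ H[j]
            num = np.exp(lrelu(a_dst @ zi + a_src @ zj))
            den = 0.0
            for jj, ii in zip(e[0], e[1]):
                if ii == i:
                    den += np.exp(lrelu(a_dst @ (W.T @ H[ii]) + a_src @ (W.T @ H[jj])))
            assert alpha[idx, 0] == pytest.approx(num / den, abs=1e-12)


class TestGATForward:
    def test_single_node_single_head_is_projected_input(self, rng):
        conv = GATConv(3, 3, 1, rng)
        conv.b.value[...] = 0
        H = rng.normal(size=(1, 3))
        out = conv.forward(H, np.zeros((2, 0), dtype=int))
        assert np.allclose(out, H @ conv.W.value[0])

    def test_output_width_is_total_channels(self, rng):
        _, edges = random_graph(rng, 12, 0.3)
        conv = GATConv(5, 12, 4, rng)
        out = conv.forward(rng.normal(size=(12, 5)), edges)
        assert out.shape == (12, 12)

    def test_matches_dense_masked_softmax_oracle(self, rng):
        A, edges = random_graph(rng, 20, 0.3)
        conv = GATConv(6, 8, 2, rng)
        H = rng.normal(size=(20, 6))
        out = conv.forward(H, edges)
        ref = dense_gat(H, A, conv.W.value, conv.a_dst.value, conv.a_src.value,
                        conv.b.value)
        assert np.abs(out - ref).max() < 1e-5


class TestTransformerConv:
    def test_identical_keys_average_values(self, rng):
        _, edges = random_graph(rng, 8, 0.5)
        conv = TransformerConv(4, 3, rng)
        conv.W_k.value[...] = 0.0  # all keys identical (zero)
        conv.b.value[...] = 0
        H = rng.normal(size=(8, 4))
        out = conv.forward(H, edges)
        v = H @ conv.W_v.value
        e = add_self_loops(edges, 8)
        for i in range(8):
            attended = e[0][e[1] == i]
            assert np.allclose(out[i], v[attended].mean(axis=0), atol=1e-10)

    def test_matches_dense_masked_softmax_oracle(self, rng):
        A, edges = random_graph(rng, 20, 0.3)
        conv = TransformerConv(5, 4, rng)
        H = rng.normal(size=(20, 5))
        out = conv.forward(H, edges)
        ref = dense_transformer(H, A, conv.W_q.value, conv.W_k.value,
                                conv.W_v.value, conv.b.value)
        assert np.abs(out - ref).max() < 1e-5

    def test_attention_invariant_to_key_scaling_with_dk(self, rng):
        """Multiplying K by c and d_k by c^2 leaves the attention unchanged."""
        _, edges = random_graph(rng, 10, 0.4)
        conv = TransformerConv(4, 4, rng)
        H = rng.normal(size=(10, 4))
        alpha1, _, _ = conv.attention(H, edges)
        c = 3.0
        conv.W_k.value *= c
        conv.d_k *= c**2
        alpha2, _, _ = conv.attention(H, edges)
        assert np.allclose(alpha1, alpha2, atol=1e-12)

    def test_zero_key_dimension_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 1"):
            TransformerConv(4, 0, rng)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def _finite_difference_ok(layer, make_forward, X, rng, eps=1e-6, tol=1e-4):
    out = make_forward()
    G = rng.normal(size=out.shape)
    layer.zero_grad()
    dX = layer.backward(G)
    for p in layer.parameters():
        flat = p.value.ravel()
        for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            up = float((make_forward() * G).sum())
            flat[idx] = old - eps
            dn = float((make_forward() * G).sum())
            flat[idx] = old
            num = (up - dn) / (2 * eps)
            if abs(num - p.grad.ravel()[idx]) > tol * max(1.0, abs(num)):
                return False
    for idx in rng.choice(X.size, size=5, replace=False):
        old = X.ravel()[idx]
        X.ravel()[idx] = old + eps
        up = float((make_forward() * G).sum())
        X.ravel()[idx] = old - eps
        dn = float((make_forward() * G).sum())
        X.ravel()[idx] = old
        num = (up - dn) / (2 * eps)
        if abs(num - dX.ravel()[idx]) > tol * max(1.0, abs(num)):
            return False
    return True


@pytest.mark.parametrize("which", ["gcn", "gat", "transformer", "batchnorm"])
def test_backward_matches_finite_differences(which, rng):
    A, edges = random_graph(rng, 12, 0.3)
    X = rng.normal(size=(12, 5))
    if which == "gcn":
        layer = GCNConv(5, 4, rng)
        Ahat = normalize_adjacency(A)
        fwd = lambda: layer.forward(X, Ahat)
    elif which == "gat":
        layer = GATConv(5, 6, 2, rng)
        fwd = lambda: layer.forward(X, edges)
    elif which == "transformer":
        layer = TransformerConv(5, 4, rng)
        fwd = lambda: layer.forward(X, edges)
    else:
        layer = BatchNorm(5)

        def fwd():
            layer.running_mean[:] = 0
            layer.running_var[:] = 1
            return layer.forward(X, training=True)

    assert _finite_difference_ok(layer, fwd, X, rng)


# ---------------------------------------------------------------------------
# structural properties
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("which", ["gcn", "gat", "transformer"])
def test_permutation_equivariance(which, rng):
    A, edges = random_graph(rng, 14, 0.3)
    X = rng.normal(size=(14, 4))
    perm = rng.permutation(14)
    inv = np.argsort(perm)
    A_p = A[np.ix_(perm, perm)]
    src_p, dst_p = np.nonzero(A_p)
    edges_p = np.vstack([src_p, dst_p])
    if which == "gcn":
        layer = GCNConv(4, 3, rng)
        out = layer.forward(X, normalize_adjacency(A))
        out_p = layer.forward(X[perm], normalize_adjacency(A_p))
    elif which == "gat":
        layer = GATConv(4, 4, 2, rng)
        out = layer.forward(X, edges)
        out_p = layer.forward(X[perm], edges_p)
    else:
        layer = TransformerConv(4, 3, rng)
        out = layer.forward(X, edges)
        out_p = layer.forward(X[perm], edges_p)
    assert np.allclose(out_p[inv], out, atol=1e-10)


def test_forward_passes_bit_stable_without_dropout(rng):
    A, edges = random_graph(rng, 10, 0.3)
    X = rng.normal(size=(10, 4))
    conv = GATConv(4, 4, 2, rng)
    out1 = conv.forward(X, edges)
    out2 = conv.forward(X, edges)
    assert (out1 == out2).all()


def test_dropout_identity_in_eval_mode(rng):
    drop = Dropout(0.5)
    X = rng.normal(size=(6, 3))
    assert (drop.forward(X, training=False) == X).all()
    out = drop.forward(X, training=True, rng=rng)
    assert set(np.unique(out[out != 0] / X[out != 0]).round(6)) == {2.0}


def test_segment_softmax_rows_sum_to_one(rng):
    scores = rng.normal(size=(30, 4))
    seg = rng.integers(0, 6, 30)
    alpha = segment_softmax(scores, seg, 6)
    sums = np.zeros((6, 4))
    np.add.at(sums, seg, alpha)
    present = np.unique(seg)
    assert np.allclose(sums[present], 1.0, atol=1e-12)
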