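"""Message-passing layers with explicit forward/backward passes.

All layers are NumPy-based.  Each layer caches what its backward pass
needs during ``forward`` and accumulates parameter gradients in-place on
``Parameter.grad``.  Correctness is guarded by finite-difference gradient
checks and dense-matrix oracles in the test suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


def glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Parameter(glorot(rng, (in_dim, out_dim)), "W")
        self.b = Parameter(np.zeros(out_dim), "b")

    def parameters(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._X = X
        return X @ self.W.value + self.b.value

    def backward(self, G: np.ndarray) -> np.ndarray:
        self.W.grad += self._X.T @ G
        self.b.grad += G.sum(axis=0)
        return G @ self.W.value.T


class ReLU(Layer):
    def forward(self, X):
        self._mask = X > 0
        return X * self._mask

    def backward(self, G):
        return G * self._mask


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope

    def forward(self, X):
        self._mask = X > 0
        return np.where(self._mask, X, self.slope * X)

    def backward(self, G):
        return np.where(self._mask, G, self.slope * G)


class Dropout(Layer):
    """Inverted dropout; identity when not training."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, X, training: bool = False, rng: np.random.Generator | None = None):
        if not training or self.rate == 0.0:
            self._mask = None
            return X
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        self._mask = (rng.random(X.shape) >= self.rate) / (1.0 - self.rate)
        return X * self._mask

    def backward(self, G):
        return G if self._mask is None else G * self._mask


class BatchNorm(Layer):
    """Batch normalization over the node dimension with running statistics."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim), "gamma")
        self.beta = Parameter(np.zeros(dim), "beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, X, training: bool = False):
        if training:
            mean = X.mean(axis=0)
            var = X.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (X - mean) / self._std
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, G):
        self.gamma.grad += (G * self._xhat).sum(axis=0)
        self.beta.grad += G.sum(axis=0)
        gx = G * self.gamma.value
        if not self._training:
            return gx / self._std
        n = G.shape[0]
        return (
            gx - gx.mean(axis=0) - self._xhat * (gx * self._xhat).mean(axis=0)
        ) / self._std


# ---------------------------------------------------------------------------
# graph utilities
# ---------------------------------------------------------------------------

def normalize_adjacency(A) -> sp.csr_matrix:
    """Kipf-style symmetric normalization D^(-1/2) (A + I) D^(-1/2).

    Self-loops are injected here (never stored in the raw adjacency), so an
    isolated node keeps a well-defined row equal to its self-loop entry 1.
    """
    if sp.issparse(A):
        A = A.tocsr().astype(float)
    else:
        A = sp.csr_matrix(np.asarray(A, dtype=float))
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if (abs(A - A.T) > 1e-12).nnz > 0:
        raise ValueError("adjacency must be symmetric")
    n = A.shape[0]
    A_tilde = A + sp.identity(n, format="csr")
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return (D @ A_tilde @ D).tocsr()


def add_self_loops(edge_index: np.ndarray, n_nodes: int) -> np.ndarray:
    """Append (i, i) for every node to a directed (2, E) edge array."""
    loops = np.arange(n_nodes)
    return np.hstack([edge_index.reshape(2, -1), np.vstack([loops, loops])])


def segment_softmax(scores: np.ndarray, seg: np.ndarray, n_segments: int) -> np.ndarray:
    """Numerically stable softmax of edge scores grouped by destination."""
    scores = np.atleast_2d(scores.T).T  # (E, H)
    m = np.full((n_segments, scores.shape[1]), -np.inf)
    np.maximum.at(m, seg, scores)
    ex = np.exp(scores - m[seg])
    denom = np.zeros((n_segments, scores.shape[1]))
    np.add.at(denom, seg, ex)
    return ex / denom[seg]


def _segment_softmax_backward(alpha, d_alpha, seg, n_segments):
    t = np.zeros((n_segments, alpha.shape[1]))
    np.add.at(t, seg, alpha * d_alpha)
    return alpha * (d_alpha - t[seg])


# ---------------------------------------------------------------------------
# graph convolution layers
# ---------------------------------------------------------------------------

class GCNConv(Layer):
    """Symmetric-normalized graph convolution: ``A_hat X W + b``.

    The activation is applied by the model wrapper, not here.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Parameter(glorot(rng, (in_dim, out_dim)), "W")
        self.b = Parameter(np.zeros(out_dim), "b")

    def parameters(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray, A_hat: sp.csr_matrix) -> np.ndarray:
        if X.shape[1] != self.W.value.shape[0]:
            raise ValueError(
                f"feature dim {X.shape[1]} does not match weight rows "
                f"{self.W.value.shape[0]}"
            )
        self._AX = A_hat @ X
        self._A_hat = A_hat
        return self._AX @ self.W.value + self.b.value

    def backward(self, G: np.ndarray) -> np.ndarray:
        self.W.grad += self._AX.T @ G
        self.b.grad += G.sum(axis=0)
        # A_hat is symmetric, so A_hat^T = A_hat
        return self._A_hat @ (G @ self.W.value.T)


class GATConv(Layer):
    """Multi-head graph attention.

    Per head ``h``: ``z_i = W_h x_i``; attention logit on directed edge
    (j -> i) is ``LeakyReLU(a_dst . z_i + a_src . z_j)``; coefficients are
    softmax-normalized over each destination's attended set, which always
    includes the node itself (self-loop), so isolated nodes are well
    defined.  Head outputs are concatenated; ``out_dim`` is the total
    output width and must be divisible by ``heads``.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        heads: int,
        rng: np.random.Generator,
        negative_slope: float = 0.2,
    ):
        if out_dim % heads:
            raise ValueError("out_dim must be divisible by heads")
        self.heads = heads
        self.head_dim = out_dim // heads
        self.slope = negative_slope
        self.W = Parameter(glorot(rng, (heads, in_dim, self.head_dim)), "W")
        self.a_dst = Parameter(
            glorot(rng, (heads, self.head_dim, 1))[..., 0] * 1.0, "a_dst"
        )
        self.a_src = Parameter(
            glorot(rng, (heads, self.head_dim, 1))[..., 0] * 1.0, "a_src"
        )
        self.b = Parameter(np.zeros(out_dim), "b")

    def parameters(self):
        return [self.W, self.a_dst, self.a_src, self.b]

    def attention(self, X: np.ndarray, edge_index: np.ndarray):
        """Attention coefficients per directed edge per head (with self-loops)."""
        n = X.shape[0]
        edges = add_self_loops(edge_index, n)
        src, dst = edges
        Z = np.einsum("nf,hfd->nhd", X, self.W.value)  # (n, H, d)
        logits = (
            np.einsum("ehd,hd->eh", Z[dst], self.a_dst.value)
            + np.einsum("ehd,hd->eh", Z[src], self.a_src.value)
        )
        pre = np.where(logits > 0, logits, self.slope * logits)
        alpha = segment_softmax(pre, dst, n)
        return alpha, edges, Z, logits

    def forward(self, X: np.ndarray, edge_index: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.W.value.shape[1]:
            raise ValueError("feature dim does not match weight shape")
        n = X.shape[0]
        alpha, edges, Z, logits = self.attention(X, edge_index)
        src, dst = edges
        out = np.zeros((n, self.heads, self.head_dim))
        np.add.at(out, dst, alpha[..., None] * Z[src])
        self._cache = (X, edges, Z, logits, alpha)
        return out.reshape(n, -1) + self.b.value

    def backward(self, G: np.ndarray) -> np.ndarray:
        X, edges, Z, logits, alpha = self._cache
        src, dst = edges
        n = X.shape[0]
        self.b.grad += G.sum(axis=0)
        Gh = G.reshape(n, self.heads, self.head_dim)

        dZ = np.zeros_like(Z)
        np.add.at(dZ, src, alpha[..., None] * Gh[dst])
        d_alpha = np.einsum("ehd,ehd->eh", Gh[dst], Z[src])
        ds = _segment_softmax_backward(alpha, d_alpha, dst, n)
        dpre = np.where(logits > 0, ds, self.slope * ds)

        self.a_dst.grad += np.einsum("eh,ehd->hd", dpre, Z[dst])
        self.a_src.grad += np.einsum("eh,ehd->hd", dpre, Z[src])
        np.add.at(dZ, dst, dpre[..., None] * self.a_dst.value[None])
        np.add.at(dZ, src, dpre[..., None] * self.a_src.value[None])

        self.W.grad += np.einsum("nf,nhd->hfd", X, dZ)
        return np.einsum("nhd,hfd->nf", dZ, self.W.value)


class TransformerConv(Layer):
    """Scaled dot-product attention restricted to graph neighborhoods.

    ``q_i = W_Q x_i``, ``k_j = W_K x_j``, ``v_j = W_V x_j``; attention
    weights ``softmax_j((q_i . k_j) / sqrt(d_k))`` over the attended set
    N(i) U {i}.  With ``global_attention`` the attended set is every node
    of the same graph (the complete edge set is supplied by the caller).
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        if out_dim < 1:
            raise ValueError("key dimension must be >= 1")
        self.d_k = out_dim
        self.W_q = Parameter(glorot(rng, (in_dim, out_dim)), "W_q")
        self.W_k = Parameter(glorot(rng, (in_dim, out_dim)), "W_k")
        self.W_v = Parameter(glorot(rng, (in_dim, out_dim)), "W_v")
        self.b = Parameter(np.zeros(out_dim), "b")

    def parameters(self):
        return [self.W_q, self.W_k, self.W_v, self.b]

    def attention(self, X: np.ndarray, edge_index: np.ndarray):
        n = X.shape[0]
        edges = add_self_loops(edge_index, n)
        src, dst = edges
        q = X @ self.W_q.value
        k = X @ self.W_k.value
        v = X @ self.W_v.value
        scores = (q[dst] * k[src]).sum(axis=1, keepdims=True) / np.sqrt(self.d_k)
        alpha = segment_softmax(scores, dst, n)
        return alpha, edges, (q, k, v)

    def forward(self, X: np.ndarray, edge_index: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.W_q.value.shape[0]:
            raise ValueError("feature dim does not match weight shape")
        n = X.shape[0]
        alpha, edges, (q, k, v) = self.attention(X, edge_index)
        src, dst = edges
        out = np.zeros((n, self.d_k))
        np.add.at(out, dst, alpha * v[src])
        self._cache = (X, edges, q, k, v, alpha)
        return out + self.b.value

    def backward(self, G: np.ndarray) -> np.ndarray:
        X, edges, q, k, v, alpha = self._cache
        src, dst = edges
        n = X.shape[0]
        self.b.grad += G.sum(axis=0)

        dv = np.zeros_like(v)
        np.add.at(dv, src, alpha * G[dst])
        d_alpha = (G[dst] * v[src]).sum(axis=1, keepdims=True)
        ds = _segment_softmax_backward(alpha, d_alpha, dst, n) / np.sqrt(self.d_k)

        dq = np.zeros_like(q)
        dk = np.zeros_like(k)
        np.add.at(dq, dst, ds * k[src])
        np.add.at(dk, src, ds * q[dst])

        self.W_q.grad += X.T @ dq
        self.W_k.grad += X.T @ dk
        self.W_v.grad += X.T @ dv
        return dq @ self.W_q.value.T + dk @ self.W_k.value.T + dv @ self.W_v.value.T


class MeanPool(Layer):
    """Global mean pooling of node rows grouped by graph id."""

    def forward(self, X: np.ndarray, batch: np.ndarray, n_graphs: int) -> np.ndarray:
        out = np.zeros((n_graphs, X.shape[1]))
        np.add.at(out, batch, X)
        counts = np.bincount(batch, minlength=n_graphs).astype(float)
        counts[counts == 0] = 1.0
        self._batch, self._counts, self._n = batch, counts, X.shape[0]
        return out / counts[:, None]

    def backward(self, G: np.ndarray) -> np.ndarray:
        return (G / self._counts[:, None])[self._batch]
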