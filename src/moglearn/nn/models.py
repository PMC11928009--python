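"""The three classifier architectures and their configuration.

Reference configurations (the widths used on the full-scale problem):

* GCN — three symmetric-normalized convolutions, 1024 hidden channels
  each, ReLU, dropout 0.5, linear classifier head.
* GAT — four attention convolutions with (channels/heads) schedule
  1024/8, 512/4, 256/2, 32/1, each followed by batch normalization,
  LeakyReLU and dropout 0.5, then a linear classifier head.
* GTN — two transformer convolutions, 1024 channels then one channel per
  class, dropout 0.5.

``ModelSpec`` makes the widths configurable so the same architectures run
at desk scale; ``paper`` classmethod-style constructors give the reference
widths.  Node mode classifies nodes of one transductive graph; graph mode
mean-pools node embeddings per graph before the classifier.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp
import yaml

from .layers import (
    BatchNorm,
    Dropout,
    GATConv,
    GCNConv,
    LeakyReLU,
    Linear,
    MeanPool,
    ReLU,
    TransformerConv,
    add_self_loops,
    normalize_adjacency,
)

ARCHITECTURES = ("gcn", "gat", "gtn")

_REFERENCE_HIDDEN = {
    "gcn": [1024, 1024, 1024],
    "gat": [1024, 512, 256, 32],
    "gtn": [1024],
}
_REFERENCE_HEADS = {"gat": [8, 4, 2, 1]}


@dataclass
class ModelSpec:
    """Architecture and width configuration for one classifier."""

    architecture: str
    in_dim: int
    n_classes: int
    hidden: list = None
    heads: list = None
    dropout: float = 0.5
    negative_slope: float = 0.2  # attention LeakyReLU
    task: str = "node"  # "node" | "graph"
    global_attention: bool = False  # GTN: attend over the whole graph

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.task not in ("node", "graph"):
            raise ValueError("task must be 'node' or 'graph'")
        if self.hidden is None:
            self.hidden = list(_REFERENCE_HIDDEN[self.architecture])
        if self.architecture == "gat" and self.heads is None:
            self.heads = list(_REFERENCE_HEADS["gat"][: len(self.hidden)])
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if any(h < 1 for h in self.hidden):
            raise ValueError("hidden widths must be positive")
        if self.architecture == "gat":
            if len(self.heads) != len(self.hidden):
                raise ValueError("heads and hidden must have equal length")
            if any(h < 1 for h in self.heads):
                raise ValueError("head counts must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls(**yaml.safe_load(text))


@dataclass
class GraphBatch:
    """Model input: node features plus connectivity (and graph ids)."""

    X: np.ndarray  # (n_nodes, in_dim)
    edge_index: np.ndarray  # directed (2, E), both orientations, no self-loops
    adjacency: sp.csr_matrix | None = None  # raw symmetric adjacency
    batch: np.ndarray | None = None  # graph id per node (graph mode)
    n_graphs: int = 1

    def a_hat(self) -> sp.csr_matrix:
        if self.adjacency is None:
            n = self.X.shape[0]
            e = self.edge_index
            data = np.ones(e.shape[1])
            A = sp.coo_matrix((data, (e[0], e[1])), shape=(n, n)).tocsr()
            A.data[:] = 1.0
            self.adjacency = A
        return normalize_adjacency(self.adjacency)

    def complete_edges(self) -> np.ndarray:
        """All ordered node pairs within each graph (global attention)."""
        batch = self.batch if self.batch is not None else np.zeros(self.X.shape[0], int)
        src_all, dst_all = [], []
        for g in range(self.n_graphs):
            idx = np.flatnonzero(batch == g)
            s, d = np.meshgrid(idx, idx)
            keep = s != d  # self-loops are added by the layer
            src_all.append(s[keep])
            dst_all.append(d[keep])
        return np.vstack([np.concatenate(src_all), np.concatenate(dst_all)])


class BaseModel:
    """Shared plumbing: parameter inventory, loss, prediction, checkpointing."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self._layers: list = []

    def parameters(self):
        return [p for layer in self._layers for p in layer.parameters()]

    def zero_grad(self):
        for layer in self._layers:
            layer.zero_grad()

    def forward(self, batch: GraphBatch, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, G: np.ndarray) -> None:
        raise NotImplementedError

    def predict_proba(self, batch: GraphBatch) -> np.ndarray:
        logits = self.forward(batch, training=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grad(self, batch, y, mask, training=True, rng=None):
        """Masked softmax cross-entropy; returns (loss, dlogits)."""
        logits = self.forward(batch, training=training, rng=rng)
        idx = np.flatnonzero(mask)
        z = logits[idx] - logits[idx].max(axis=1, keepdims=True)
        log_p = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        loss = -log_p[np.arange(idx.size), y[idx]].mean()
        dlogits = np.zeros_like(logits)
        p = np.exp(log_p)
        p[np.arange(idx.size), y[idx]] -= 1.0
        dlogits[idx] = p / idx.size
        return float(loss), dlogits

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        for i, layer in enumerate(self._layers):
            if isinstance(layer, BatchNorm):
                arrays[f"bn{i}_mean"] = layer.running_mean
                arrays[f"bn{i}_var"] = layer.running_var
        buf = io.BytesIO()
        np.savez(buf, spec=json.dumps(asdict(self.spec)), **arrays)
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    @staticmethod
    def load(path) -> "BaseModel":
        with np.load(path, allow_pickle=False) as data:
            spec = ModelSpec(**json.loads(str(data["spec"])))
            model = build_model(spec, rng=np.random.default_rng(0))
            for i, p in enumerate(model.parameters()):
                p.value[...] = data[f"p{i}"]
            for i, layer in enumerate(model._layers):
                if isinstance(layer, BatchNorm):
                    layer.running_mean = data[f"bn{i}_mean"]
                    layer.running_var = data[f"bn{i}_var"]
        return model


class GCNModel(BaseModel):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__(spec)
        dims = [spec.in_dim] + list(spec.hidden)
        self.convs = [GCNConv(dims[i], dims[i + 1], rng) for i in range(len(spec.hidden))]
        self.acts = [ReLU() for _ in self.convs]
        self.drops = [Dropout(spec.dropout) for _ in self.convs]
        self.pool = MeanPool() if spec.task == "graph" else None
        self.head = Linear(dims[-1], spec.n_classes, rng)
        self._layers = [*self.convs, *self.acts, *self.drops, self.head]
        if self.pool is not None:
            self._layers.append(self.pool)

    def forward(self, batch, training=False, rng=None):
        A_hat = batch.a_hat()
        H = batch.X
        for conv, act, drop in zip(self.convs, self.acts, self.drops):
            H = drop.forward(act.forward(conv.forward(H, A_hat)), training, rng)
        if self.pool is not None:
            H = self.pool.forward(H, batch.batch, batch.n_graphs)
        return self.head.forward(H)

    def backward(self, G):
        G = self.head.backward(G)
        if self.pool is not None:
            G = self.pool.backward(G)
        for conv, act, drop in zip(self.convs[::-1], self.acts[::-1], self.drops[::-1]):
            G = conv.backward(act.backward(drop.backward(G)))
        return G


class GATModel(BaseModel):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__(spec)
        dims = [spec.in_dim] + list(spec.hidden)
        self.convs = [
            GATConv(dims[i], dims[i + 1], spec.heads[i], rng, spec.negative_slope)
            for i in range(len(spec.hidden))
        ]
        self.norms = [BatchNorm(d) for d in spec.hidden]
        self.acts = [LeakyReLU() for _ in self.convs]
        self.drops = [Dropout(spec.dropout) for _ in self.convs]
        self.pool = MeanPool() if spec.task == "graph" else None
        self.head = Linear(dims[-1], spec.n_classes, rng)
        self._layers = [*self.convs, *self.norms, *self.acts, *self.drops, self.head]
        if self.pool is not None:
            self._layers.append(self.pool)

    def forward(self, batch, training=False, rng=None):
        H = batch.X
        for conv, norm, act, drop in zip(self.convs, self.norms, self.acts, self.drops):
            H = conv.forward(H, batch.edge_index)
            H = drop.forward(act.forward(norm.forward(H, training)), training, rng)
        if self.pool is not None:
            H = self.pool.forward(H, batch.batch, batch.n_graphs)
        return self.head.forward(H)

    def backward(self, G):
        G = self.head.backward(G)
        if self.pool is not None:
            G = self.pool.backward(G)
        for conv, norm, act, drop in zip(
            self.convs[::-1], self.norms[::-1], self.acts[::-1], self.drops[::-1]
        ):
            G = conv.backward(norm.backward(act.backward(drop.backward(G))))
        return G


class GTNModel(BaseModel):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__(spec)
        width = spec.hidden[0]
        self.conv1 = TransformerConv(spec.in_dim, width, rng)
        self.act = ReLU()
        self.drop1 = Dropout(spec.dropout)
        self.conv2 = TransformerConv(width, spec.n_classes, rng)
        self.drop2 = Dropout(spec.dropout)
        self.pool = MeanPool() if spec.task == "graph" else None
        self._layers = [self.conv1, self.act, self.drop1, self.conv2, self.drop2]
        if self.pool is not None:
            self._layers.append(self.pool)

    def _edges(self, batch: GraphBatch) -> np.ndarray:
        return batch.complete_edges() if self.spec.global_attention else batch.edge_index

    def forward(self, batch, training=False, rng=None):
        edges = self._edges(batch)
        H = self.drop1.forward(self.act.forward(self.conv1.forward(batch.X, edges)), training, rng)
        H = self.drop2.forward(self.conv2.forward(H, edges), training, rng)
        if self.pool is not None:
            H = self.pool.forward(H, batch.batch, batch.n_graphs)
        return H

    def backward(self, G):
        if self.pool is not None:
            G = self.pool.backward(G)
        G = self.conv2.backward(self.drop2.backward(G))
        return self.conv1.backward(self.act.backward(self.drop1.backward(G)))


_MODEL_CLASSES = {"gcn": GCNModel, "gat": GATModel, "gtn": GTNModel}


def build_model(spec: ModelSpec, rng: np.random.Generator | None = None) -> BaseModel:
    """Instantiate the architecture named in ``spec`` (Glorot init, seeded)."""
    if spec.architecture not in _MODEL_CLASSES:
        raise ValueError(f"unknown architecture {spec.architecture!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    return _MODEL_CLASSES[spec.architecture](spec, rng)
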