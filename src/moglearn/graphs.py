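"""Multi-omics integration and the two graph constructions.

``integrate`` inner-joins omics layers on sample ID.  ``build_sample_graph``
connects samples whose Pearson correlation over the integrated (z-scored)
feature vector meets a threshold — the transductive "patient similarity"
graph, with samples as nodes.  ``build_feature_graph`` lays per-sample
multi-omics channel vectors onto a shared protein-interaction topology —
one graph per sample, classified as a whole.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import LAYER_ORDER, IntegratedDataset, OmicsMatrix

logger = logging.getLogger(__name__)


class IsolatedNodeWarning(UserWarning):
    """Raised when the correlation threshold leaves samples with no edges."""


def integrate(layers: list[OmicsMatrix], labels: pd.Series) -> IntegratedDataset:
    """Inner-join omics layers on sample ID and concatenate their columns.

    Only samples present in every requested layer (and in ``labels``) are
    retained; classes left without any sample are dropped.  Columns are
    concatenated in the canonical layer order, each tagged with its origin.
    Standardization is deliberately NOT applied here — it is fitted on
    training rows only, downstream.
    """
    if not layers:
        raise ValueError("integrate() needs at least one omics layer")
    ordered = sorted(
        layers, key=lambda m: LAYER_ORDER.index(m.layer) if m.layer in LAYER_ORDER else 99
    )
    common = ordered[0].sample_ids
    for m in ordered[1:]:
        common = common.intersection(m.sample_ids)
    common = common.intersection(labels.index)
    if len(common) == 0:
        names = ", ".join(m.layer for m in ordered)
        raise ValueError(f"empty sample intersection across layers: {names}")
    common = common.sort_values()

    blocks, origins = [], []
    for m in ordered:
        block = m.values.loc[common]
        blocks.append(block)
        origins.extend([m.layer] * block.shape[1])
    X = pd.concat(blocks, axis=1)
    if X.columns.has_duplicates:
        raise ValueError("duplicate feature ids across layers")
    y = labels.loc[common]
    origin = pd.Series(origins, index=X.columns, name="layer")
    return IntegratedDataset(X=X, feature_origin=origin, labels=y)


def pearson(a, b) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Errors on zero-variance input rather than silently returning 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("pearson() needs two equal-length vectors of length >= 2")
    da = a - a.mean()
    db = b - b.mean()
    va = da @ da
    vb = db @ db
    if va == 0 or vb == 0:
        raise ValueError("pearson correlation undefined for zero-variance input")
    return float(da @ db / np.sqrt(va * vb))


@dataclass
class SampleGraph:
    """Transductive sample-similarity graph (nodes = samples)."""

    sample_ids: pd.Index
    adjacency: sp.csr_matrix  # symmetric binary, zero diagonal
    node_features: np.ndarray  # integrated X, row order = sample_ids
    node_labels: np.ndarray
    threshold: float

    @property
    def n_nodes(self) -> int:
        return len(self.sample_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def density(self) -> float:
        n = self.n_nodes
        return 0.0 if n < 2 else 2.0 * self.n_edges / (n * (n - 1))

    def edge_index(self) -> np.ndarray:
        """Directed (2, E) array with both orientations of every edge."""
        coo = self.adjacency.tocoo()
        return np.vstack([coo.row, coo.col])


def build_sample_graph(
    data: IntegratedDataset,
    threshold: float = 0.9,
    absolute: bool = False,
) -> SampleGraph:
    """Connect sample pairs with Pearson correlation >= ``threshold``.

    Correlation is computed between z-scored integrated feature vectors
    (per-feature standardization over all samples; the graph is a
    transductive structure, so this is not label leakage).  With
    ``absolute=True`` the rule becomes ``|r| >= threshold``.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError("correlation threshold must lie in [-1, 1]")
    X = data.X.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples to build a graph")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    # guard: constant rows have undefined correlation
    row_sd = Z.std(axis=1)
    if (row_sd == 0).any():
        bad = data.X.index[row_sd == 0].tolist()
        raise ValueError(f"zero-variance sample row(s): {bad}")
    R = np.corrcoef(Z)
    A = (np.abs(R) >= threshold) if absolute else (R >= threshold)
    np.fill_diagonal(A, False)
    adjacency = sp.csr_matrix(A.astype(np.int8))

    degrees = np.asarray(adjacency.sum(axis=1)).ravel()
    n_isolated = int((degrees == 0).sum())
    if n_isolated:
        warnings.warn(
            f"{n_isolated} of {X.shape[0]} samples are isolated at threshold "
            f"{threshold}",
            IsolatedNodeWarning,
            stacklevel=2,
        )
    graph = SampleGraph(
        sample_ids=data.X.index,
        adjacency=adjacency,
        node_features=X,
        node_labels=data.labels.to_numpy(),
        threshold=threshold,
    )
    logger.info(
        "sample graph: %d nodes, %d edges, density %.4f, %d isolated",
        graph.n_nodes, graph.n_edges, graph.density, n_isolated,
    )
    return graph


@dataclass
class FeatureGraph:
    """Shared gene/protein topology with per-sample node features.

    ``tensors`` has shape (n_samples, n_nodes, n_channels): channel order
    follows the canonical layer order restricted to layers present in the
    integrated data.  ``channel_mask[v, c]`` is True where gene ``v`` has at
    least one mapped feature in layer ``c`` (zero-filled otherwise).
    """

    node_ids: list
    edges: np.ndarray  # (E, 2) int node indices, undirected, no duplicates
    edge_scores: np.ndarray
    channels: list
    tensors: np.ndarray
    channel_mask: np.ndarray
    sample_ids: pd.Index
    graph_labels: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edge_index(self) -> np.ndarray:
        if self.edges.size == 0:
            return np.zeros((2, 0), dtype=int)
        e = self.edges.T
        return np.hstack([e, e[::-1]])


def build_feature_graph(
    edges: pd.DataFrame,
    gene_map: pd.DataFrame,
    data: IntegratedDataset,
    score_threshold: float = 0.0,
) -> FeatureGraph:
    """Assemble the protein-interaction graph with multi-omics node channels.

    Nodes are genes with at least one mapped selected feature; edges are
    kept where the interaction score meets ``score_threshold`` and both
    endpoints are nodes.  Per sample, each node's channel value is the mean
    of that sample's mapped features in the corresponding omics layer.
    """
    fmap = dict(zip(gene_map["feature_id"], gene_map["gene_id"]))
    channels = [l for l in LAYER_ORDER if (data.feature_origin == l).any()]
    gene_features: dict = {}
    for feat in data.X.columns:
        gene = fmap.get(feat)
        if gene is None:
            continue
        layer = data.feature_origin[feat]
        gene_features.setdefault(gene, {}).setdefault(layer, []).append(feat)
    if not gene_features:
        raise ValueError("gene_map covers none of the selected features")

    node_ids = sorted(gene_features)
    node_index = {g: i for i, g in enumerate(node_ids)}

    kept, scores, dropped = [], [], 0
    seen = set()
    for n1, n2, score in edges[["node1", "node2", "score"]].itertuples(index=False):
        if score < score_threshold:
            continue
        if n1 not in node_index or n2 not in node_index or n1 == n2:
            dropped += 1
            continue
        a, b = sorted((node_index[n1], node_index[n2]))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        kept.append((a, b))
        scores.append(score)
    if dropped:
        logger.info("dropped %d interaction edges referencing unmapped genes", dropped)
    if not kept:
        raise ValueError(
            "no interaction edges survive the score threshold and gene mapping"
        )

    n_samples = data.n_samples
    tensors = np.zeros((n_samples, len(node_ids), len(channels)))
    channel_mask = np.zeros((len(node_ids), len(channels)), dtype=bool)
    Xv = data.X
    for gene, per_layer in gene_features.items():
        v = node_index[gene]
        for c, layer in enumerate(channels):
            feats = per_layer.get(layer)
            if feats:
                channel_mask[v, c] = True
                tensors[:, v, c] = Xv[feats].to_numpy(dtype=float).mean(axis=1)

    return FeatureGraph(
        node_ids=node_ids,
        edges=np.asarray(kept, dtype=int).reshape(-1, 2),
        edge_scores=np.asarray(scores, dtype=float),
        channels=channels,
        tensors=tensors,
        channel_mask=channel_mask,
        sample_ids=data.X.index,
        graph_labels=data.labels.to_numpy(),
    )
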