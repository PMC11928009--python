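"""Synthetic multi-omics data with planted class signal.

The generator emulates the statistical structure of a pan-cancer
multi-omics extract: negative-binomial sequencing counts (mRNA, miRNA),
bounded beta-scale DNA-methylation values, class-dependent signal confined
to a sparse "informative" feature subset, partially overlapping sample IDs
across layers, and a STRING-style interaction network enriched for edges
among genes carrying signal.  Every downstream stage of the pipeline is
testable against the planted ground truth.

Counts follow the mean-dispersion parameterization ``Var = mu + a * mu**2``
with one shared dispersion ``a``.  Informative features carry a shared
tumor-vs-normal mean shift (class 0 plays normal tissue) plus a smaller
subtype modulation focused on one tumor class per omics layer, so single
layers hold complementary partial multiclass signal and only their
integration resolves every subtype.  Methylation is simulated on the
logit scale and mapped through a sigmoid, keeping beta values strictly
inside (0, 1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import LAYER_ORDER, OmicsMatrix

DEFAULT_N_FEATURES = {"mrna": 200, "mirna": 60, "methylation": 200}

#: logit-scale noise standard deviation for methylation; comparable
#: per-feature effect size to the count layers (shift/sd ~ 2-3)
_METH_NOISE_SD = 1.0


@dataclass
class SimulationConfig:
    """Study conditions for one simulated multi-omics dataset.

    ``effect_size`` is the log2-fold-change scale for count layers and the
    logit-scale mean shift for methylation.  ``dispersion`` is the shared
    negative-binomial dispersion ``a`` in ``Var = mu + a * mu**2``.
    ``missing_frac`` of samples are dropped independently from each layer so
    the inner join during integration is non-trivial.
    """

    n_samples_per_class: int = 30
    n_classes: int = 4
    n_features: dict = field(default_factory=lambda: dict(DEFAULT_N_FEATURES))
    frac_informative: float = 0.1
    effect_size: float = 2.0
    dispersion: float = 0.2
    missing_frac: float = 0.1
    class_proportions: tuple | None = None  # optional imbalance weights
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_class < 1:
            raise ValueError("n_samples_per_class must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for layer, p in self.n_features.items():
            if p < 1:
                raise ValueError(f"n_features[{layer!r}] must be >= 1")
        if not 0.0 <= self.frac_informative <= 1.0:
            raise ValueError("frac_informative must lie in [0, 1]")
        if not 0.0 <= self.missing_frac <= 1.0:
            raise ValueError("missing_frac must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.effect_size > 0 and self.frac_informative == 0.0:
            raise ValueError(
                "frac_informative=0 cannot carry class signal; "
                "set effect_size=0 for a pure-null dataset"
            )
        if self.class_proportions is not None:
            w = np.asarray(self.class_proportions, dtype=float)
            if len(w) != self.n_classes or (w <= 0).any():
                raise ValueError("class_proportions must be positive, one per class")


@dataclass
class SyntheticDataset:
    """One simulated dataset plus its ground truth."""

    omics: dict  # layer -> OmicsMatrix
    labels: pd.Series  # every simulated sample id -> integer class
    truth: dict  # layer -> frozenset of informative feature ids
    ppi_edges: pd.DataFrame  # columns: node1, node2, score
    gene_map: pd.DataFrame  # columns: feature_id, gene_id
    config: SimulationConfig | None = None

    def equals(self, other: "SyntheticDataset") -> bool:
        return (
            set(self.omics) == set(other.omics)
            and all(self.omics[k].values.equals(other.omics[k].values) for k in self.omics)
            and self.labels.equals(other.labels)
            and self.truth == other.truth
            and self.ppi_edges.equals(other.ppi_edges)
            and self.gene_map.equals(other.gene_map)
        )


def _class_sizes(config: SimulationConfig) -> np.ndarray:
    if config.class_proportions is None:
        return np.full(config.n_classes, config.n_samples_per_class, dtype=int)
    w = np.asarray(config.class_proportions, dtype=float)
    total = config.n_samples_per_class * config.n_classes
    sizes = np.maximum(1, np.round(total * w / w.sum()).astype(int))
    return sizes


def _informative_shifts(
    rng: np.random.Generator, n_classes: int, effect: float, focus_class: int
) -> np.ndarray:
    """Per-class mean shifts for one informative feature.

    Class 0 plays the normal tissue: its shift is 0.  All tumor classes
    share a main up- or down-shift of ``effect`` — the tumor-vs-normal
    contrast the univariate filters are built to detect.  On top of that,
    ``focus_class`` receives a subtype modulation of ``0.75 * effect`` with
    random sign.  Each omics layer focuses on a different tumor subtype,
    so single layers carry complementary (partial) multiclass signal and
    only their integration resolves every subtype.
    """
    sign = rng.choice([-1.0, 1.0])
    shifts = np.full(n_classes, effect * sign)
    shifts[focus_class] += 0.75 * effect * rng.choice([-1.0, 1.0])
    shifts[0] = 0.0
    return shifts


def _simulate_count_layer(
    rng: np.random.Generator,
    layer: str,
    labels: np.ndarray,
    config: SimulationConfig,
    base_range: tuple[float, float],
    focus_class: int,
) -> tuple[pd.DataFrame, frozenset, dict]:
    n = labels.size
    p = config.n_features[layer]
    feature_ids = [f"{layer}_{j:04d}" for j in range(p)]

    n_inf = int(round(config.frac_informative * p)) if config.effect_size > 0 else 0
    inf_idx = np.sort(rng.choice(p, size=n_inf, replace=False)) if n_inf else np.array([], int)

    base_log2 = rng.uniform(*base_range, size=p)
    # class x feature matrix of log2 mean shifts
    shifts = np.zeros((config.n_classes, p))
    patterns = {}
    for j in inf_idx:
        shifts[:, j] = _informative_shifts(
            rng, config.n_classes, config.effect_size, focus_class
        )
        patterns[feature_ids[j]] = shifts[:, j].copy()

    size_factor = np.exp(rng.normal(0.0, 0.3, size=n))
    log2_mu = base_log2[None, :] + shifts[labels, :]
    mu = size_factor[:, None] * np.exp2(log2_mu)
    r = 1.0 / config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    df = pd.DataFrame(counts, columns=feature_ids)
    truth = frozenset(feature_ids[j] for j in inf_idx)
    return df, truth, patterns


def _simulate_methylation(
    rng: np.random.Generator, labels: np.ndarray, config: SimulationConfig,
    focus_class: int,
) -> tuple[pd.DataFrame, frozenset]:
    n = labels.size
    p = config.n_features["methylation"]
    feature_ids = [f"cpg_{j:04d}" for j in range(p)]

    n_inf = int(round(config.frac_informative * p)) if config.effect_size > 0 else 0
    inf_idx = np.sort(rng.choice(p, size=n_inf, replace=False)) if n_inf else np.array([], int)

    base_logit = rng.uniform(-2.0, 2.0, size=p)
    shifts = np.zeros((config.n_classes, p))
    for j in inf_idx:
        shifts[:, j] = _informative_shifts(
            rng, config.n_classes, config.effect_size, focus_class
        )

    logits = base_logit[None, :] + shifts[labels, :] + rng.normal(0.0, _METH_NOISE_SD, (n, p))
    beta = np.clip(expit(logits), 1e-6, 1.0 - 1e-6)
    df = pd.DataFrame(beta, columns=feature_ids)
    truth = frozenset(feature_ids[j] for j in inf_idx)
    return df, truth


def _build_gene_map(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Map every feature to a gene node; mRNA is 1:1, others many-to-one."""
    n_genes = config.n_features["mrna"]
    genes = np.array([f"G{g:04d}" for g in range(n_genes)])
    rows = [(f"mrna_{j:04d}", genes[j]) for j in range(n_genes)]
    for j in range(config.n_features["methylation"]):
        rows.append((f"cpg_{j:04d}", genes[rng.integers(0, n_genes)]))
    for j in range(config.n_features["mirna"]):
        rows.append((f"mirna_{j:04d}", genes[rng.integers(0, n_genes)]))
    return pd.DataFrame(rows, columns=["feature_id", "gene_id"]), genes


def _build_ppi(
    rng: np.random.Generator,
    genes: np.ndarray,
    informative_mrna: frozenset,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Planted edges among informative genes plus random background edges."""
    inf_genes = np.array(
        sorted(genes[int(f.split("_")[1])] for f in informative_mrna), dtype=object
    )
    pairs = set()
    edges = []
    # planted clique-ish neighborhood among signal genes
    n_planted = 2 * len(inf_genes)
    tries = 0
    while len(inf_genes) >= 2 and len(edges) < n_planted and tries < 50 * max(n_planted, 1):
        tries += 1
        a, b = rng.choice(len(inf_genes), size=2, replace=False)
        lo, hi = sorted((inf_genes[a], inf_genes[b]))
        if (lo, hi) in pairs:
            continue
        pairs.add((lo, hi))
        edges.append((lo, hi, rng.uniform(0.85, 1.0)))
    n_background = max(len(genes) // 2, 10)
    tries = 0
    while len(edges) < n_planted + n_background and tries < 50 * n_background:
        tries += 1
        a, b = rng.integers(0, len(genes), size=2)
        if a == b:
            continue
        key = (genes[min(a, b)], genes[max(a, b)])
        if key in pairs:
            continue
        pairs.add(key)
        edges.append((key[0], key[1], rng.uniform(0.4, 0.8)))
    df = pd.DataFrame(edges, columns=["node1", "node2", "score"])
    df["score"] = df["score"].round(3)
    return df


def simulate_multiomics(config: SimulationConfig) -> SyntheticDataset:
    """Generate one multi-omics dataset under the given study conditions.

    Fully reproducible from ``config.seed``; two calls with equal configs
    return identical datasets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sizes = _class_sizes(config)
    labels_arr = np.repeat(np.arange(config.n_classes), sizes)
    n_total = labels_arr.size
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n_total)], name="sample_id")
    labels = pd.Series(labels_arr, index=sample_ids, name="class")

    # one tumor subtype per layer carries that layer's subtype modulation
    n_tumor = config.n_classes - 1
    focus = [1 + (i % n_tumor) for i in range(3)]
    mrna, truth_mrna, _ = _simulate_count_layer(
        rng, "mrna", labels_arr, config, (3.0, 9.0), focus[0]
    )
    mirna, truth_mirna, _ = _simulate_count_layer(
        rng, "mirna", labels_arr, config, (2.0, 7.0), focus[1]
    )
    meth, truth_meth = _simulate_methylation(rng, labels_arr, config, focus[2])

    omics = {}
    for layer, df in (("mrna", mrna), ("mirna", mirna), ("methylation", meth)):
        df.index = sample_ids
        n_drop = int(np.floor(config.missing_frac * n_total))
        drop = rng.choice(n_total, size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(n_total), drop)
        omics[layer] = OmicsMatrix(layer, df.iloc[keep])

    gene_map, genes = _build_gene_map(rng, config)
    ppi = _build_ppi(rng, genes, truth_mrna, config)

    return SyntheticDataset(
        omics=omics,
        labels=labels,
        truth={"mrna": truth_mrna, "mirna": truth_mirna, "methylation": truth_meth},
        ppi_edges=ppi,
        gene_map=gene_map,
        config=config,
    )


def simulate_null(config: SimulationConfig) -> SyntheticDataset:
    """Pure-null twin of :func:`simulate_multiomics` (effect_size forced to 0).

    Used for type-I-error calibration; truth sets are empty by construction.
    """
    null_config = dataclasses.replace(config, effect_size=0.0)
    return simulate_multiomics(null_config)


def m_values(beta: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Logit (base 2) transform of methylation beta values to M-values."""
    return np.log2(beta / (1.0 - beta))


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write all layers and tables as plain-text files; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for layer in LAYER_ORDER:
        if layer in dataset.omics:
            path = outdir / f"{layer}.csv"
            dataset.omics[layer].to_csv(path)
            paths[layer] = str(path)
    labels_path = outdir / "labels.csv"
    dataset.labels.rename("class").to_csv(labels_path, index_label="sample_id")
    paths["labels"] = str(labels_path)
    ppi_path = outdir / "ppi_edges.tsv"
    dataset.ppi_edges.to_csv(ppi_path, sep="\t", index=False)
    paths["ppi_edges"] = str(ppi_path)
    map_path = outdir / "gene_map.tsv"
    dataset.gene_map.to_csv(map_path, sep="\t", index=False)
    paths["gene_map"] = str(map_path)
    truth_path = outdir / "truth.json"
    truth_path.write_text(
        json.dumps({k: sorted(v) for k, v in dataset.truth.items()}, indent=1)
    )
    paths["truth"] = str(truth_path)
    return paths


def read_dataset(indir) -> SyntheticDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    indir = Path(indir)
    omics = {}
    for layer in LAYER_ORDER:
        path = indir / f"{layer}.csv"
        if path.exists():
            omics[layer] = OmicsMatrix.from_csv(layer, path)
    labels_df = pd.read_csv(indir / "labels.csv", index_col=0)
    if labels_df.index.has_duplicates:
        dup = labels_df.index[labels_df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in labels.csv: {dup}")
    labels = labels_df["class"]
    labels.index.name = "sample_id"
    ppi = pd.read_csv(indir / "ppi_edges.tsv", sep="\t")
    gene_map = pd.read_csv(indir / "gene_map.tsv", sep="\t")
    truth_path = indir / "truth.json"
    truth = {}
    if truth_path.exists():
        truth = {k: frozenset(v) for k, v in json.loads(truth_path.read_text()).items()}
    return SyntheticDataset(omics, labels, truth, ppi, gene_map)
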