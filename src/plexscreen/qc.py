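"""Post-demultiplexing cell quality control, normalization, graph
clustering and one-vs-rest marker detection.

QC keeps a cell when its total UMI count lies strictly inside the
configured window and its mitochondrial percentage is strictly below the
model-specific bound.  Expression is log-normalized (ln(1 + CP10K));
clustering builds a shared-nearest-neighbor graph (Jaccard weights,
pruned below 1/15) and partitions it with the Leiden algorithm at a fixed
resolution.  Cluster markers come from one-vs-rest Wilcoxon rank-sum
tests with Bonferroni correction over all features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .io import ConfigError, CountMatrixHandle, ValidationError, log_stage

DEFAULT_MITO_MAX = {"JHOS2": 25.0, "PDC2": 30.0, "PDC3": 20.0}
SNN_PRUNE = 1.0 / 15.0


@dataclass
class QcThresholds:
    """Strict (exclusive) retention bounds for per-cell QC."""

    umi_min: float = 2500.0
    umi_max: float = 80000.0
    mito_pct_max: dict = field(default_factory=lambda: dict(DEFAULT_MITO_MAX))

    def __post_init__(self):
        if not 0 < self.umi_min < self.umi_max:
            raise ConfigError("need 0 < umi_min < umi_max")
        for model, v in self.mito_pct_max.items():
            if not 0 < v <= 100:
                raise ConfigError(f"mito_pct_max[{model!r}]={v} outside (0, 100]")


def qc_filter(gene_counts: CountMatrixHandle, mito_gene_ids,
              thresholds: QcThresholds, model: str):
    """Filter cells on total UMIs and mitochondrial percentage.

    Returns (filtered handle, report dict); report counts satisfy
    kept + removed = input.
    """
    mito_gene_ids = set(mito_gene_ids)
    unknown = mito_gene_ids - set(gene_counts.feature_ids)
    if unknown:
        raise ValidationError(
            f"mitochondrial ids absent from features: {sorted(unknown)[:5]}")
    if model not in thresholds.mito_pct_max:
        raise ConfigError(f"no mitochondrial threshold configured for {model!r}")
    mito_max = thresholds.mito_pct_max[model]

    totals = gene_counts.library_sizes().astype(float)
    mito_idx = [i for i, f in enumerate(gene_counts.feature_ids)
                if f in mito_gene_ids]
    if mito_idx:
        mito = np.asarray(gene_counts.counts[mito_idx, :].sum(axis=0)).ravel()
    else:
        mito = np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(totals > 0, 100.0 * mito / totals, 0.0)

    keep = ((totals > thresholds.umi_min) & (totals < thresholds.umi_max) &
            (mito_pct < mito_max))
    report = {
        "model": model,
        "n_input": int(totals.size),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "n_low_umi": int((totals <= thresholds.umi_min).sum()),
        "n_high_umi": int((totals >= thresholds.umi_max).sum()),
        "n_high_mito": int((mito_pct >= mito_max).sum()),
    }
    log_stage("qc", input=report["n_input"], kept=report["n_kept"])
    return gene_counts.subset_barcodes(keep), report


def normalize_log(gene_counts: CountMatrixHandle, scale: float = 1e4) -> sp.csr_matrix:
    """ln(1 + count / library size * scale), features x cells, sparse."""
    lib = gene_counts.library_sizes().astype(float)
    if np.any(lib == 0):
        raise ValidationError("cell with zero library size; run QC first")
    mat = gene_counts.counts.astype(float).tocsc()
    mat = mat.multiply(scale / lib[None, :]).tocsr()
    mat.data = np.log1p(mat.data)
    return mat


@dataclass
class ClusterAssignment:
    labels: np.ndarray                    # contiguous from 1
    n_neighbors: int
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def _snn_graph(coords: np.ndarray, n_neighbors: int) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph, pruned below 1/15."""
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(coords)
    knn = nn.kneighbors_graph(coords, mode="connectivity")  # includes self? no
    knn = knn.maximum(sp.eye(coords.shape[0], format="csr"))  # add self
    shared = knn @ knn.T
    shared = shared.tocoo()
    k_i = np.asarray(knn.sum(axis=1)).ravel()
    union = k_i[shared.row] + k_i[shared.col] - shared.data
    jaccard = shared.data / union
    keep = (jaccard >= SNN_PRUNE) & (shared.row != shared.col)
    return sp.csr_matrix((jaccard[keep], (shared.row[keep], shared.col[keep])),
                         shape=shared.shape)


def cluster_cells(matrix, n_neighbors: int = 15, resolution: float = 0.3,
                  seed: int = 0, n_pcs: int = 50) -> ClusterAssignment:
    """Leiden community detection on an SNN graph of cells.

    ``matrix`` is cells x features (dense or sparse, already normalized).
    Dimensionality is reduced to ``n_pcs`` components first when the
    feature count exceeds it.
    """
    X = np.asarray(matrix.todense()) if sp.issparse(matrix) else np.asarray(matrix)
    n_cells = X.shape[0]
    if n_cells < n_neighbors + 1:
        raise ValidationError(
            f"{n_cells} cells is fewer than n_neighbors+1={n_neighbors + 1}")
    if X.shape[1] > n_pcs:
        X = TruncatedSVD(n_components=n_pcs, random_state=seed).fit_transform(X)

    adj = _snn_graph(X, n_neighbors)
    adj = adj.maximum(adj.T).tocoo()
    mask = adj.row < adj.col
    edges = list(zip(adj.row[mask], adj.col[mask]))
    weights = adj.data[mask].tolist()
    g = igraph.Graph(n=n_cells, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=weights, resolution_parameter=resolution, seed=seed)
    labels = np.asarray(part.membership)
    # relabel contiguously from 1 in decreasing cluster-size order
    order = np.argsort(-np.bincount(labels), kind="stable")
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    log_stage("cluster", cells=n_cells, clusters=int(labels.max()))
    return ClusterAssignment(labels, n_neighbors, resolution, seed)


def find_markers(matrix, clusters, gene_ids) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    ``matrix`` is cells x genes of normalized expression.  P-values use
    mid-ranks; exact enumeration for small tie-free groups, otherwise the
    continuity-corrected normal approximation (scipy's 'auto' policy).
    Adjusted p = min(1, p * number of features); log2FC compares cluster
    and rest means with pseudocount 1.
    """
    X = np.asarray(matrix.todense()) if sp.issparse(matrix) else np.asarray(matrix)
    labels = np.asarray(clusters.labels if isinstance(clusters, ClusterAssignment)
                        else clusters)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("marker detection needs at least two clusters")
    counts = {c: int((labels == c).sum()) for c in uniq}
    too_small = [c for c, n in counts.items() if n < 3]
    if too_small:
        raise ValidationError(f"clusters with fewer than 3 cells: {too_small}")

    G = X.shape[1]
    frames = []
    for c in uniq:
        in_mask = labels == c
        x_in, x_out = X[in_mask], X[~in_mask]
        method = "auto" if min(counts[c], X.shape[0] - counts[c]) <= 25 \
            else "asymptotic"
        res = scipy.stats.mannwhitneyu(x_in, x_out, axis=0,
                                       alternative="two-sided", method=method)
        pvals = np.asarray(res.pvalue)
        mean_in = x_in.mean(axis=0)
        mean_out = x_out.mean(axis=0)
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        df = pd.DataFrame({
            "cluster": c,
            "gene": gene_ids,
            "log2fc": log2fc,
            "pvalue": pvals,
            "adj_pvalue": np.minimum(1.0, pvals * G),
        })
        df = df.sort_values(["pvalue", "log2fc"],
                            ascending=[True, False], kind="stable")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
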