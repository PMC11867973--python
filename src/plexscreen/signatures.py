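"""Cluster-level signature activity scoring with bootstrap significance.

The procedure scores gene sets against a cluster "marker profile": the
average expression, per cluster, of the union of each cluster's top-k
most up- and downregulated marker genes.  A set's score in a cluster is
the mean profile value over the set's panel genes minus the mean over
the whole panel, so a positive score means the set's genes sit above the
panel average in that cluster.  Significance comes from bootstrapping
genes within the panel; the most variable sets across clusters are then
selected by coefficient of variation.

This is deliberately a marker-profile score, not a per-sample
Kolmogorov-Smirnov-style enrichment statistic: the profile is a summary
over cluster markers and the bootstrap resamples panel genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ConfigError, GeneSetCollection, ValidationError


@dataclass
class SignatureConfig:
    top_k: int = 50
    n_bootstrap: int = 1000
    cv_top_fraction: float = 0.05
    min_set_size: int = 10
    max_set_size: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.top_k < 1:
            raise ConfigError("top_k must be at least 1")
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be at least 1")
        if not 0.0 < self.cv_top_fraction <= 1.0:
            raise ConfigError("cv_top_fraction must lie in (0, 1]")


def filter_gene_sets(collection: GeneSetCollection, min_size: int = 10,
                     max_size: int = 500) -> GeneSetCollection:
    """Keep sets with min_size <= |set| <= max_size (inclusive bounds)."""
    return collection.filter_by_size(min_size, max_size)


def marker_panel_profile(matrix, labels, gene_ids, markers: pd.DataFrame,
                         top_k: int = 50) -> pd.DataFrame:
    """Average expression (panel genes x clusters) over the marker panel.

    The panel is the union over clusters of each cluster's ``top_k`` most
    upregulated and ``top_k`` most downregulated marker genes (ranked by
    log2FC); the profile entry (g, c) is gene g's mean expression over the
    cells of cluster c.
    """
    X = np.asarray(matrix.todense()) if sp.issparse(matrix) else np.asarray(matrix)
    labels = np.asarray(labels)
    panel = []
    for c, sub in markers.groupby("cluster"):
        ranked = sub.sort_values("log2fc", ascending=False, kind="stable")
        panel.extend(ranked["gene"].head(top_k))
        panel.extend(ranked["gene"].tail(top_k))
    panel = sorted(set(panel))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in panel if g not in gene_index]
    if missing:
        raise ValidationError(f"marker genes absent from matrix: {missing[:5]}")
    rows = [gene_index[g] for g in panel]
    clusters = sorted(set(labels))
    profile = np.column_stack([X[labels == c][:, rows].mean(axis=0)
                               for c in clusters])
    return pd.DataFrame(profile, index=panel, columns=clusters)


def score_signatures(profile: pd.DataFrame,
                     gene_sets: GeneSetCollection) -> pd.DataFrame:
    """Score = mean profile over (set ∩ panel) minus mean over the panel.

    Sets with zero overlap with the panel score NaN (flagged, not errors).
    """
    panel_upper = {str(g).upper(): g for g in profile.index}
    panel_mean = profile.mean(axis=0)
    scores = {}
    for name, genes in gene_sets:
        hit = [panel_upper[g] for g in genes if g in panel_upper]
        if not hit:
            scores[name] = pd.Series(np.nan, index=profile.columns)
        else:
            scores[name] = profile.loc[hit].mean(axis=0) - panel_mean
    return pd.DataFrame(scores).T  # sets x clusters


def bootstrap_significance(scores: pd.DataFrame, profile: pd.DataFrame,
                           gene_sets: GeneSetCollection,
                           n_bootstrap: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Two-sided bootstrap p-values for signature scores.

    For each (set, cluster): resample |set ∩ panel| genes from the panel
    with replacement, recompute the centered score, and report
    p = (1 + #{|null| >= |observed|}) / (B + 1).
    """
    if n_bootstrap < 100:
        raise ValidationError("need at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    panel_upper = {str(g).upper(): g for g in profile.index}
    values = profile.to_numpy()                      # panel genes x clusters
    panel_mean = values.mean(axis=0)
    n_panel = values.shape[0]

    pvals = {}
    for name, genes in gene_sets:
        k = sum(1 for g in genes if g in panel_upper)
        obs = scores.loc[name].to_numpy()
        if k == 0 or np.all(np.isnan(obs)):
            pvals[name] = pd.Series(np.nan, index=scores.columns)
            continue
        draws = rng.integers(0, n_panel, size=(n_bootstrap, k))
        null = values[draws].mean(axis=1) - panel_mean[None, :]
        exceed = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
        pvals[name] = pd.Series((exceed + 1.0) / (n_bootstrap + 1.0),
                                index=scores.columns)
    return pd.DataFrame(pvals).T


def cv_select(scores: pd.DataFrame, fraction: float = 0.05) -> list:
    """Select the ceil(fraction * n) sets with the largest coefficient of
    variation across clusters; a zero mean yields CV = +inf (ranked first)."""
    if scores.empty:
        raise ValidationError("no sets to select from")
    sd = scores.std(axis=1, ddof=1)
    mean = scores.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean.to_numpy() == 0.0, np.inf,
                      sd.to_numpy() / np.abs(mean.to_numpy()))
    cv = pd.Series(cv, index=scores.index)
    n_keep = int(np.ceil(fraction * len(scores)))
    order = cv.sort_values(ascending=False, kind="stable")
    return list(order.index[:n_keep])
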