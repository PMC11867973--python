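"""Combinatorial dual-HTO demultiplexing.

Cells are labeled with one row-family tag and one column-family tag; each
family is classified completely independently.  Within a family the tag
counts are CLR-transformed and k-means clustered (k = number of family
tags + 1); for each tag, the cluster with the lowest mean CLR of that tag
is taken as its background population, a negative binomial is fitted to
the background's raw counts, and a cell is called positive for the tag
when its raw count exceeds the fitted NB's upper quantile.  A cell that is
a singlet in both families and whose (row tag, column tag) pair exists in
the plate map is assigned to that well and its treatment; everything else
is discarded with a reason.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from sklearn.cluster import KMeans

from .io import CountMatrixHandle, PlateMap, ValidationError, log_stage


@dataclass
class DemuxConfig:
    positive_quantile: float = 0.99
    k: int | None = None                 # default: n family tags + 1
    clr_pseudocount: float = 1.0
    min_background: int = 10             # minimum background-cluster size
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.positive_quantile < 1.0:
            raise ValidationError("positive_quantile must lie in (0, 1)")
        if self.k is not None and self.k < 2:
            raise ValidationError("k must be at least 2")


@dataclass
class TagFit:
    """Background NB fit and positivity threshold for one tag."""
    mean: float
    size: float | None                   # None => Poisson fallback
    threshold: float


@dataclass
class FamilyCall:
    """Per-cell classification within one tag family."""
    barcodes: list
    status: np.ndarray                   # 'negative' | 'singlet' | 'doublet'
    tags: list                           # list of positive-tag lists per cell
    fits: dict                           # tag -> TagFit

    def singlet_tag(self, i: int) -> str | None:
        return self.tags[i][0] if self.status[i] == "singlet" else None


def clr_transform(tag_counts: CountMatrixHandle, family) -> np.ndarray:
    """Centered log-ratio across the tags of one family (cells x tags).

    clr_it = ln(x_it + 1) - mean_t' ln(x_it' + 1); each row sums to zero.
    """
    family = list(family)
    if not family:
        raise ValidationError("family tag list is empty")
    idx = [tag_counts.feature_ids.index(t) for t in family]
    x = np.asarray(tag_counts.counts[idx, :].todense(), dtype=float).T
    logged = np.log(x + 1.0)
    return logged - logged.mean(axis=1, keepdims=True)


def _fit_nb_background(x: np.ndarray) -> tuple:
    """MLE NB fit (mean, size) with method-of-moments start.

    Returns (mean, size); size is None when the sample is under-dispersed
    (variance <= mean), signaling a Poisson fallback.
    """
    mu = float(np.mean(x))
    var = float(np.var(x, ddof=1)) if x.size > 1 else 0.0
    if var <= mu or mu <= 0.0:
        return mu, None
    size0 = mu ** 2 / (var - mu)

    def nll(log_size):
        r = np.exp(log_size)
        p = r / (r + mu)
        return -np.sum(scipy.stats.nbinom.logpmf(x, r, p))

    res = scipy.optimize.minimize_scalar(
        nll, bracket=(np.log(size0) - 1.0, np.log(size0) + 1.0))
    r = float(np.exp(res.x)) if res.success else size0
    return mu, r


def nb_quantile(q: float, mean: float, size: float | None) -> float:
    """Upper quantile of the fitted background distribution."""
    if mean <= 0.0:
        return 0.0
    if size is None:
        return float(scipy.stats.poisson.ppf(q, mean))
    p = size / (size + mean)
    return float(scipy.stats.nbinom.ppf(q, size, p))


def classify_family(tag_counts: CountMatrixHandle, family,
                    config: DemuxConfig | None = None) -> FamilyCall:
    """Classify every cell as negative/singlet/doublet within one family."""
    config = config or DemuxConfig()
    family = list(family)
    k = config.k if config.k is not None else len(family) + 1
    n_cells = tag_counts.n_barcodes
    if n_cells < k:
        raise ValidationError(f"{n_cells} cells is fewer than k={k} clusters")

    clr = clr_transform(tag_counts, family)
    km = KMeans(n_clusters=k, random_state=config.seed, n_init=10)
    labels = km.fit_predict(clr)
    cluster_sizes = np.bincount(labels, minlength=k)

    idx = [tag_counts.feature_ids.index(t) for t in family]
    raw = np.asarray(tag_counts.counts[idx, :].todense(), dtype=float).T

    fits = {}
    positive = np.zeros((n_cells, len(family)), dtype=bool)
    for j, tag in enumerate(family):
        means = np.array([clr[labels == c, j].mean() if cluster_sizes[c] else np.inf
                          for c in range(k)])
        # lowest mean CLR is the background; ties broken by cluster size
        order = sorted(range(k), key=lambda c: (means[c], -cluster_sizes[c]))
        bg_mask = labels == order[0]
        # accrete next-lowest clusters until the background is big enough
        for c in order[1:]:
            if bg_mask.sum() >= config.min_background:
                break
            bg_mask |= labels == c
        bg = raw[bg_mask, j]
        mu, size = _fit_nb_background(bg)
        if size is None and mu > 0:
            warnings.warn(
                f"tag {tag}: degenerate background (var <= mean), Poisson fallback",
                stacklevel=2)
        thr = nb_quantile(config.positive_quantile, mu, size)
        fits[tag] = TagFit(mean=mu, size=size, threshold=thr)
        positive[:, j] = raw[:, j] > thr

    n_pos = positive.sum(axis=1)
    status = np.where(n_pos == 0, "negative",
                      np.where(n_pos == 1, "singlet", "doublet"))
    tags = [[family[j] for j in np.flatnonzero(positive[i])]
            for i in range(n_cells)]
    return FamilyCall(list(tag_counts.barcode_ids), status, tags, fits)


@dataclass
class DemuxResult:
    assignments: pd.DataFrame            # per-cell row/col call + final status
    summary: dict = field(default_factory=dict)

    def write(self, tsv_path, json_path=None) -> None:
        self.assignments.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary, fh, indent=2)


def demultiplex(row_call: FamilyCall, col_call: FamilyCall,
                plate_map: PlateMap) -> DemuxResult:
    """Intersect row and column singlet calls and map tag pairs to wells."""
    if row_call.barcodes != col_call.barcodes:
        raise ValidationError("row and column calls cover different cells")

    # singlet calls are the ones that drive well assignment; a singlet tag
    # the map does not know is a design inconsistency, not a discard reason
    called_rows = {tags[0] for s, tags in zip(row_call.status, row_call.tags)
                   if s == "singlet"}
    called_cols = {tags[0] for s, tags in zip(col_call.status, col_call.tags)
                   if s == "singlet"}
    missing = (called_rows - set(plate_map.row_tags)) | \
              (called_cols - set(plate_map.col_tags))
    if missing:
        raise ValidationError(f"plate map missing tags present in calls: "
                              f"{sorted(missing)}")

    records = []
    for i, bc in enumerate(row_call.barcodes):
        row_status, col_status = row_call.status[i], col_call.status[i]
        rec = {"barcode": bc,
               "row_call": row_call.singlet_tag(i) or row_status,
               "col_call": col_call.singlet_tag(i) or col_status,
               "status": "discarded", "reason": "",
               "well": "", "drug": "", "moa": ""}
        if row_status != "singlet":
            rec["reason"] = "row_not_singlet"
        elif col_status != "singlet":
            rec["reason"] = "col_not_singlet"
        else:
            well = plate_map.lookup(row_call.singlet_tag(i),
                                    col_call.singlet_tag(i))
            if well is None:
                rec["reason"] = "pair_not_in_map"
            else:
                rec.update(status="retained", reason="",
                           well=well["well"], drug=well["drug"],
                           moa=well["moa"])
        records.append(rec)

    df = pd.DataFrame(records, columns=["barcode", "row_call", "col_call",
                                        "status", "reason", "well", "drug", "moa"])
    n = len(df)
    n_retained = int((df["status"] == "retained").sum())
    reasons = df.loc[df["status"] == "discarded", "reason"].value_counts().to_dict()
    summary = {
        "n_cells": n,
        "n_retained": n_retained,
        "n_discarded": n - n_retained,
        "retained_fraction": (n_retained / n) if n else None,
        "discard_reasons": reasons,
    }
    log_stage("demux", cells=n, retained=n_retained)
    return DemuxResult(df, summary)


def demultiplex_plate(tag_counts: CountMatrixHandle, plate_map: PlateMap,
                      config: DemuxConfig | None = None) -> DemuxResult:
    """Convenience wrapper: classify both families of a plate and intersect."""
    config = config or DemuxConfig()
    row_family = [t for t in tag_counts.feature_ids if t in set(plate_map.row_tags)]
    col_family = [t for t in tag_counts.feature_ids if t in set(plate_map.col_tags)]
    row_call = classify_family(tag_counts, row_family, config)
    col_call = classify_family(tag_counts, col_family, config)
    return demultiplex(row_call, col_call, plate_map)
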