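"""Subsample-pseudobulk differential expression and over-representation.

Cells of each (model, treatment) group are shuffled and partitioned into
subsets of ten; a final short subset is kept only when it has at least
five cells, and a group enters the analysis only with at least two
retained subsets (so groups of 14 or fewer cells are excluded).  Raw
counts are summed within subsets into pseudobulk columns.  After removing
lowly expressed genes (average log2 CPM < 1, prior count 2) and computing
TMM normalization factors, each gene is tested with a negative binomial
generalized linear model and a quasi-likelihood F-test: dispersions are
estimated by adjusted profile likelihood on a grid with empirical-Bayes
shrinkage toward an abundance trend, and the per-gene quasi-dispersion is
moderated with a scaled inverse-chi-square prior before forming the
F-statistic.  P-values are Benjamini-Hochberg adjusted.

DEG counting and MOA-level unions restrict to protein-coding genes with
strict |log2FC| and FDR cutoffs; over-representation uses the upper-tail
hypergeometric test against a gene-set collection, with BH control, an
optional allow-list, and a cap of the 20 most significant pathways.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.special
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import (ConfigError, CountMatrixHandle, GeneAnnotation,
                 GeneSetCollection, ValidationError, log_stage)

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Subsampling and aggregation
# ---------------------------------------------------------------------------

@dataclass
class SubsampleConfig:
    chunk_size: int = 10
    min_remainder: int = 5
    min_subsets: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.min_remainder > self.chunk_size:
            raise ConfigError("min_remainder must not exceed chunk_size")
        if self.min_subsets < 2:
            raise ConfigError("min_subsets must be at least 2")


def _group_rng(config: SubsampleConfig, group_key) -> np.random.Generator:
    # independent, reproducible stream per group: stage seed XOR key hash
    h = zlib.crc32(repr(group_key).encode()) if group_key is not None else 0
    return np.random.default_rng((config.seed ^ h) & 0x7FFFFFFF)


def partition_group(cell_ids, config: SubsampleConfig | None = None,
                    group_key=None):
    """Shuffle and chunk a treatment group's cells into pseudobulk subsets.

    Returns a list of subsets (lists of cell ids), or ``None`` when the
    group is excluded because fewer than ``min_subsets`` subsets survive.
    """
    config = config or SubsampleConfig()
    cell_ids = list(cell_ids)
    if not cell_ids:
        raise ValidationError("cannot partition an empty group")
    rng = _group_rng(config, group_key)
    order = rng.permutation(len(cell_ids))
    shuffled = [cell_ids[i] for i in order]
    subsets = [shuffled[i:i + config.chunk_size]
               for i in range(0, len(shuffled), config.chunk_size)]
    if subsets and len(subsets[-1]) < config.min_remainder:
        subsets = subsets[:-1]
    if len(subsets) < config.min_subsets:
        return None
    return subsets


@dataclass
class PseudobulkMatrix:
    """Summed counts, genes x subsets, with per-subset group labels."""

    counts: np.ndarray
    gene_ids: list
    subset_ids: list
    group_labels: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.subset_ids)):
            raise ValidationError("pseudobulk dimensions do not match labels")
        if len(self.group_labels) != len(self.subset_ids):
            raise ValidationError("one group label per subset required")

    @property
    def n_subsets(self) -> int:
        return len(self.subset_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def subset_columns(self, mask) -> "PseudobulkMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask)
        return PseudobulkMatrix(self.counts[:, mask], self.gene_ids,
                                [self.subset_ids[i] for i in mask],
                                [self.group_labels[i] for i in mask])


def aggregate_pseudobulk(gene_counts: CountMatrixHandle, subsets: dict,
                         group_labels: dict | None = None) -> PseudobulkMatrix:
    """Sum raw counts of each subset's member cells into one column.

    ``subsets`` maps subset id -> list of cell barcodes (disjoint);
    ``group_labels`` maps subset id -> group label (defaults to subset id).
    """
    bc_index = {b: i for i, b in enumerate(gene_counts.barcode_ids)}
    seen = set()
    cols = []
    for sid, cells in subsets.items():
        idx = []
        for c in cells:
            if c not in bc_index:
                raise ValidationError(f"subset {sid!r} references unknown cell {c!r}")
            if c in seen:
                raise ValidationError(f"cell {c!r} appears in multiple subsets")
            seen.add(c)
            idx.append(bc_index[c])
        cols.append(np.asarray(gene_counts.counts[:, idx].sum(axis=1)).ravel())
    counts = np.column_stack(cols) if cols else np.zeros((gene_counts.n_features, 0))
    labels = [group_labels[sid] if group_labels else sid for sid in subsets]
    return PseudobulkMatrix(counts, list(gene_counts.feature_ids),
                            list(subsets), labels)


# ---------------------------------------------------------------------------
# Filtering and normalization
# ---------------------------------------------------------------------------

@dataclass
class DgeThresholds:
    deg_lfc: float = 0.5
    ora_lfc: float = 0.25
    deg_fdr: float = 0.01
    low_expr_avg_log2cpm: float = 1.0
    cpm_prior_count: float = 2.0

    def __post_init__(self):
        for name in ("deg_lfc", "ora_lfc", "deg_fdr",
                     "low_expr_avg_log2cpm", "cpm_prior_count"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


def average_log2_cpm(pseudobulk: PseudobulkMatrix,
                     prior_count: float = 2.0) -> np.ndarray:
    """Per-gene average log2 CPM across subsets with a library-size-scaled
    prior count (edgeR-style): prior_j = prior * lib_j / mean(lib);
    log2((y + prior_j) / (lib_j + 2 * prior_j) * 1e6), averaged over subsets.
    """
    lib = pseudobulk.library_sizes()
    if np.any(lib == 0):
        raise ValidationError("pseudobulk column with zero library size")
    prior = prior_count * lib / lib.mean()
    adj_lib = lib + 2.0 * prior
    vals = np.log2((pseudobulk.counts + prior[None, :]) / adj_lib[None, :] * 1e6)
    return vals.mean(axis=1)


def filter_low_expression(pseudobulk: PseudobulkMatrix,
                          thresholds: DgeThresholds | None = None):
    """Drop genes with average log2 CPM strictly below the cutoff."""
    thresholds = thresholds or DgeThresholds()
    avg = average_log2_cpm(pseudobulk, thresholds.cpm_prior_count)
    keep = avg >= thresholds.low_expr_avg_log2cpm
    filtered = PseudobulkMatrix(pseudobulk.counts[keep],
                                [g for g, k in zip(pseudobulk.gene_ids, keep) if k],
                                pseudobulk.subset_ids, pseudobulk.group_labels)
    log_stage("low_expression_filter", genes_in=len(keep),
              genes_kept=int(keep.sum()))
    return filtered, avg[keep]


def tmm_factors(pseudobulk: PseudobulkMatrix,
                log_ratio_trim: float = 0.3, abs_expr_trim: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference column is the one whose upper-quartile CPM is closest to
    the mean upper quartile; per column, M-values (log2 abundance ratios to
    the reference) are doubly trimmed (30% on M, 5% on A) and averaged with
    inverse-variance weights.
    """
    y = np.asarray(pseudobulk.counts, dtype=float)
    if y.shape[1] < 2:
        raise ValidationError("TMM needs at least two pseudobulk columns")
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        raise ValidationError("column with all-zero counts")
    uq = np.array([np.quantile(y[:, j][y[:, j] > 0] / lib[j], 0.75)
                   if np.any(y[:, j] > 0) else 0.0 for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for j in range(y.shape[1]):
        if j == ref:
            continue
        yj, nj = y[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        if ok.sum() == 0:
            continue
        m = np.log2((yj[ok] / nj) / (yr[ok] / nr))
        a = 0.5 * np.log2((yj[ok] / nj) * (yr[ok] / nr))
        w = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        n = m.size
        m_rank = scipy.stats.rankdata(m, method="ordinal")
        a_rank = scipy.stats.rankdata(a, method="ordinal")
        lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n - np.floor(n * log_ratio_trim)
        lo_a, hi_a = np.floor(n * abs_expr_trim) + 1, n - np.floor(n * abs_expr_trim)
        keep = (m_rank >= lo_m) & (m_rank <= hi_m) & \
               (a_rank >= lo_a) & (a_rank <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(m[keep] * w[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


# ---------------------------------------------------------------------------
# NB GLM with quasi-likelihood F-test
# ---------------------------------------------------------------------------

def _fit_group_means(y, offsets, phi, masks, max_iter=60, tol=1e-10):
    """Vectorized per-gene Fisher scoring of group-mean NB GLMs.

    y: (G, n); offsets: (n,); phi: (G,) dispersions; masks: list of boolean
    column masks (one parameter per mask).  Returns eta (G, n_groups) and
    mu (G, n).
    """
    G, n = y.shape
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,))
    eta = np.empty((G, len(masks)))
    mu = np.empty((G, n))
    for g_idx, mask in enumerate(masks):
        yo = y[:, mask]
        eo = np.exp(offsets[mask])
        e = np.log((yo.sum(axis=1) + 0.5) / eo.sum())
        for _ in range(max_iter):
            m = np.exp(e)[:, None] * eo[None, :]
            denom = 1.0 + phi[:, None] * m
            score = ((yo - m) / denom).sum(axis=1)
            info = (m / denom).sum(axis=1)
            step = np.clip(score / np.maximum(info, 1e-12), -3.0, 3.0)
            e = e + step
            if np.max(np.abs(step)) < tol:
                break
        eta[:, g_idx] = e
        mu[:, mask] = np.exp(e)[:, None] * eo[None, :]
    return eta, mu


def _nb_loglik(y, mu, phi):
    """NB log-likelihood summed over columns; phi: (G,) broadcast over cols."""
    phi = np.maximum(np.asarray(phi, dtype=float), 1e-8)[:, None]
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    ll = (scipy.special.gammaln(y + r) - scipy.special.gammaln(r)
          - scipy.special.gammaln(y + 1.0)
          + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    return ll.sum(axis=1)


def _nb_deviance(y, mu, phi):
    """Residual deviance 2*(ll_saturated - ll_model) summed over columns."""
    phi = np.maximum(np.asarray(phi, dtype=float), 1e-8)[:, None]
    r = 1.0 / phi
    mu = np.maximum(mu, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    t2 = (y + r) * np.log((y + r) / (mu + r))
    return 2.0 * (t1 - t2).sum(axis=1)


def _adjusted_profile_loglik(y, offsets, phi, masks):
    """Cox-Reid adjusted profile log-likelihood at a common dispersion."""
    G = y.shape[0]
    phi_vec = np.full(G, phi)
    _, mu = _fit_group_means(y, offsets, phi_vec, masks)
    ll = _nb_loglik(y, mu, phi_vec)
    w = mu / (1.0 + phi * mu)
    adj = np.zeros(G)
    for mask in masks:
        adj += 0.5 * np.log(np.maximum(w[:, mask].sum(axis=1), 1e-12))
    return ll - adj


def _trigamma_inverse(x: float) -> float:
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = scipy.special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / scipy.special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float):
    """Moderate per-gene variances toward a common prior (limma-style).

    Returns (prior df, prior s2, posterior s2).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)), np.full_like(s2, np.mean(s2))
    z = np.log(s2[ok])
    e = z - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(scipy.special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s2_0 = float(np.exp(emean + scipy.special.digamma(d0 / 2.0)
                            - np.log(d0 / 2.0)))
        post = (d0 * s2_0 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s2_0 = float(np.exp(emean))
        post = np.full_like(s2, s2_0)
    return d0, s2_0, post


@dataclass
class DispersionFit:
    grid: np.ndarray
    trended: np.ndarray
    shrunk: np.ndarray


def estimate_dispersions(y, offsets, masks, avg_log2cpm,
                         grid=None, prior_n: float = 10.0,
                         window_frac: float = 0.1) -> DispersionFit:
    """Grid APL dispersion estimation with an abundance trend and
    empirical-Bayes shrinkage of per-gene estimates toward it."""
    G = y.shape[0]
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-4), np.log(2.0), 30))
    apl = np.empty((G, grid.size))
    for k, phi in enumerate(grid):
        apl[:, k] = _adjusted_profile_loglik(y, offsets, phi, masks)

    order = np.argsort(avg_log2cpm, kind="stable")
    window = max(21, int(window_frac * G)) | 1
    smoothed = np.empty_like(apl)
    smoothed[order] = scipy.ndimage.uniform_filter1d(
        apl[order], size=window, axis=0, mode="nearest")
    trended = grid[np.argmax(smoothed, axis=1)]
    posterior = apl + prior_n * smoothed
    shrunk = grid[np.argmax(posterior, axis=1)]
    return DispersionFit(grid, trended, shrunk)


def nbql_test(pseudobulk: PseudobulkMatrix, group_labels=None,
              factors: np.ndarray | None = None,
              control_label: str = "control",
              avg_log2cpm: np.ndarray | None = None) -> pd.DataFrame:
    """Two-group NB GLM with a quasi-likelihood F-test per gene.

    Returns a DataFrame with columns gene, log2fc (treatment minus
    control), avg_log2cpm, pvalue, fdr.
    """
    labels = list(group_labels if group_labels is not None
                  else pseudobulk.group_labels)
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValidationError(f"need exactly two groups, got {levels}")
    if control_label not in levels:
        raise ValidationError(f"control label {control_label!r} not in {levels}")
    treat_label = next(l for l in levels if l != control_label)
    labels = np.asarray(labels)
    masks = [labels == treat_label, labels == control_label]
    for mask, lvl in zip(masks, (treat_label, control_label)):
        if mask.sum() < 2:
            raise ValidationError(f"group {lvl!r} has fewer than 2 subsets")

    y = np.asarray(pseudobulk.counts, dtype=float)
    G, n = y.shape
    lib = pseudobulk.library_sizes()
    if factors is None:
        factors = tmm_factors(pseudobulk)
    offsets = np.log(lib * np.asarray(factors, dtype=float))
    if avg_log2cpm is None:
        avg_log2cpm = average_log2_cpm(pseudobulk)

    disp = estimate_dispersions(y, offsets, masks, avg_log2cpm)
    phi = disp.shrunk

    eta_full, mu_full = _fit_group_means(y, offsets, phi, masks)
    _, mu_red = _fit_group_means(y, offsets, phi,
                                 [np.ones(n, dtype=bool)])
    dev_full = _nb_deviance(y, mu_full, phi)
    dev_red = _nb_deviance(y, mu_red, phi)

    df_res = n - 2
    s2 = np.maximum(dev_full, 0.0) / df_res
    d0, s2_0, s2_post = _squeeze_var(s2, df_res)
    s2_post = np.maximum(s2_post, 1e-10)
    fstat = np.maximum(dev_red - dev_full, 0.0) / s2_post
    df2 = df_res + (d0 if np.isfinite(d0) else 0.0)
    if np.isfinite(d0):
        pvals = scipy.stats.f.sf(fstat, 1, df2)
    else:
        pvals = scipy.stats.chi2.sf(fstat, 1)

    log2fc = (eta_full[:, 0] - eta_full[:, 1]) / _LN2
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame({
        "gene": pseudobulk.gene_ids,
        "log2fc": log2fc,
        "avg_log2cpm": avg_log2cpm,
        "pvalue": pvals,
        "fdr": fdr,
    })
    log_stage("nbql_test", genes=G, subsets=n)
    return out


# ---------------------------------------------------------------------------
# DEG counting, MOA unions, ORA
# ---------------------------------------------------------------------------

def count_degs(dge: pd.DataFrame, annotation: GeneAnnotation,
               thresholds: DgeThresholds | None = None) -> tuple:
    """(n_up, n_down) protein-coding DEGs at strict |log2FC| and FDR cutoffs."""
    thresholds = thresholds or DgeThresholds()
    coding = annotation.protein_coding()
    sig = dge[(dge["fdr"] < thresholds.deg_fdr) &
              dge["gene"].str.upper().isin(coding)]
    n_up = int((sig["log2fc"] > thresholds.deg_lfc).sum())
    n_down = int((sig["log2fc"] < -thresholds.deg_lfc).sum())
    return n_up, n_down


def moa_union_genes(dge_results, direction: str,
                    annotation: GeneAnnotation,
                    thresholds: DgeThresholds | None = None) -> set:
    """Union over drugs of significant protein-coding genes in one direction."""
    thresholds = thresholds or DgeThresholds()
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    coding = annotation.protein_coding()
    union = set()
    for dge in dge_results:
        sig = dge[(dge["fdr"] < thresholds.deg_fdr) &
                  dge["gene"].str.upper().isin(coding)]
        if direction == "up":
            hits = sig.loc[sig["log2fc"] > thresholds.ora_lfc, "gene"]
        else:
            hits = sig.loc[sig["log2fc"] < -thresholds.ora_lfc, "gene"]
        union |= set(hits.str.upper())
    return union


@dataclass
class OraConfig:
    fdr_cutoff: float = 0.05
    max_pathways: int = 20
    allowlist: list | None = None

    def __post_init__(self):
        if not 0.0 < self.fdr_cutoff < 1.0:
            raise ConfigError("fdr_cutoff must lie in (0, 1)")


def ora(query, collection: GeneSetCollection, background,
        config: OraConfig | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list against gene sets.

    Sets are tested against the supplied background; BH control at the
    configured FDR, optional allow-list filtering, duplicate term names
    collapsed to the most significant instance, and at most
    ``max_pathways`` rows reported.
    """
    config = config or OraConfig()
    query = {str(g).upper() for g in query}
    background = {str(g).upper() for g in background}
    if not query <= background:
        raise ValidationError("query genes must be a subset of the background")
    columns = ["name", "overlap", "set_size", "pvalue", "fdr"]
    if not query:
        return pd.DataFrame(columns=columns)

    rows = []
    M, N = len(background), len(query)
    for name, genes in collection:
        set_bg = set(genes) & background
        if not set_bg:
            continue
        k = len(set_bg & query)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, len(set_bg), N))
        rows.append({"name": name, "overlap": k, "set_size": len(set_bg),
                     "pvalue": p})
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    df = df[df["fdr"] < config.fdr_cutoff]
    if config.allowlist is not None:
        allowed = {str(a).casefold() for a in config.allowlist}
        df = df[df["name"].str.casefold().isin(allowed)]
    df = df.sort_values(["pvalue", "name"], kind="stable")
    df = df.drop_duplicates(subset="name", keep="first")
    return df.head(config.max_pathways).reset_index(drop=True)[columns]
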