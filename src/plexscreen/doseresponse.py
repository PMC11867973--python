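"""Dose-response fitting, drug sensitivity scores and exact rank-sum tests.

A drug's five-point % inhibition curve (concentrations spanning a
10,000-fold range) is summarized by a four-parameter logistic (4PL) fit
and integrated into a drug sensitivity score (DSS): the area of the
response curve above an activity threshold t (responses capped at 100),
normalized by the maximal attainable area over the tested log10
concentration window,

    DSS = 100 * ∫ max(0, min(y(x), 100) - t) dx / ((100 - t) (x_max - x_min)).

Group comparisons of per-sample mean DSS use the exact two-sided
Wilcoxon rank-sum test (full null enumeration for small samples,
tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.optimize
import scipy.stats

from .io import ConfigError, ValidationError


@dataclass
class FourPL:
    """Rising four-parameter logistic: y(x) = b + (T-b)/(1 + 10^(s(m-x))).

    x is log10 concentration; b = bottom, T = top (% inhibition),
    m = log10 EC50, s = hill slope.
    """

    bottom: float
    top: float
    log_ec50: float
    hill: float

    def __post_init__(self):
        if not np.isfinite(self.hill):
            raise ValidationError("hill slope must be finite")
        if self.top < self.bottom:
            raise ValidationError("top must be >= bottom")

    def __call__(self, log10_conc):
        x = np.asarray(log10_conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** (self.hill * (self.log_ec50 - x)))


@dataclass
class DssConfig:
    activity_threshold: float = 10.0   # % inhibition the curve must exceed
    response_cap: float = 100.0
    integration_grid: int = 2049
    cutoff_percentile: float = 75.0

    def __post_init__(self):
        if not 0.0 <= self.activity_threshold < 100.0:
            raise ConfigError("activity_threshold must lie in [0, 100)")


def fit_4pl(pairs) -> FourPL:
    """Bounded least-squares 4PL fit of (concentration, % inhibition) pairs.

    Deterministic multi-start over midpoint/slope initializations; bounds:
    bottom in [-10, 30], top in [0, 110], log EC50 within the tested grid
    plus one log10 unit on each side.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 4:
        raise ValidationError("need at least 4 (concentration, response) pairs")
    conc, resp = pairs[:, 0], pairs[:, 1]
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be positive")
    if np.any(np.diff(conc) <= 0):
        raise ValidationError("concentrations must be strictly increasing")
    x = np.log10(conc)

    if np.allclose(resp, resp[0]):
        warnings.warn("identical responses; degenerate flat fit", stacklevel=2)
        level = float(np.clip(resp[0], 0.0, 110.0))
        return FourPL(bottom=max(level, -10.0) if level < 0 else level,
                      top=level, log_ec50=float(x.mean()), hill=0.0)

    lo = np.array([-10.0, 0.0, x.min() - 1.0, 0.1])
    hi = np.array([30.0, 110.0, x.max() + 1.0, 10.0])

    def residuals(theta):
        b, T, m, s = theta
        return FourPL(b, min(max(T, b), 110.0), m, s)(x) - resp

    best = None
    b0 = float(np.clip(resp.min(), -10.0, 30.0))
    t0 = float(np.clip(resp.max(), 0.0, 110.0))
    for m0 in x:
        for s0 in (0.5, 1.0, 2.0):
            start = np.clip(np.array([b0, max(t0, b0 + 1e-6), m0, s0]), lo, hi)
            try:
                res = scipy.optimize.least_squares(
                    residuals, start, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if best is None or res.cost < best.cost - 1e-12:
                best = res
    if best is None:
        raise ValidationError("4PL fit failed for all starts")
    b, T, m, s = best.x
    return FourPL(float(b), float(max(T, b)), float(m), float(s))


def dss(fit: FourPL, x_range, config: DssConfig | None = None) -> float:
    """Normalized area of the capped response curve above the activity
    threshold, over the log10 concentration window ``x_range``."""
    config = config or DssConfig()
    if config.activity_threshold >= 100.0:
        raise ConfigError("activity threshold must be below 100%")
    x_min, x_max = float(x_range[0]), float(x_range[1])
    if not x_max > x_min:
        raise ValidationError("x_max must exceed x_min")
    t = config.activity_threshold
    grid = np.linspace(x_min, x_max, config.integration_grid)
    y = np.clip(fit(grid), None, config.response_cap)
    integrand = np.maximum(y - t, 0.0)
    area = scipy.integrate.simpson(integrand, x=grid)
    score = 100.0 * area / ((100.0 - t) * (x_max - x_min))
    return float(np.clip(score, 0.0, 100.0))


def dss_cutoff(scores, percentile: float = 75.0) -> float:
    """Linear-interpolation percentile (h = (n-1)p + 1 convention)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 1:
        raise ValidationError("no scores supplied")
    if scores.size < 2:
        return float(scores[0])
    return float(np.percentile(scores, percentile, method="linear"))


# ---------------------------------------------------------------------------
# Exact Wilcoxon rank-sum
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 25


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Exact two-sided p by dynamic programming over all C(n, n_a)
    equiprobable rank assignments (mid-ranks doubled to stay integral)."""
    r2 = np.round(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    n = r2.size
    # dp[k][s] = number of k-subsets of the rank multiset with doubled-sum s
    dp = np.zeros((n_a + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(min(n_a, n), 0, -1):
            dp[k, r:] += dp[k - 1, :total + 1 - r]
    dist = dp[n_a]
    n_total = comb(n, n_a)
    w2 = int(round(2.0 * w_obs))
    p_le = dist[:w2 + 1].sum() / n_total
    p_ge = dist[w2:].sum() / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Tie-corrected, continuity-corrected normal approximation."""
    n = ranks.size
    n_b = n - n_a
    mean = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n_a * n_b * (n + 1) / 12.0 - n_a * n_b * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2.0 * scipy.stats.norm.sf(max(z, 0.0))))


def exact_wilcoxon(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Mid-ranks throughout; the exact null (all C(n, n_a) rank assignments
    equiprobable) is enumerated for total n <= 25, with the tie-corrected
    normal approximation beyond that.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled, method="average")
    w_obs = float(ranks[:a.size].sum())
    if pooled.size <= _EXACT_LIMIT:
        return _exact_ranksum_p(ranks, a.size, w_obs)
    return _normal_ranksum_p(ranks, a.size, w_obs)


def group_dss_comparison(dss_matrix: pd.DataFrame, group_labels: dict,
                         drug_subset) -> tuple:
    """Compare per-sample mean DSS over a drug subset between two groups.

    ``dss_matrix`` is drugs x samples; ``group_labels`` maps sample ->
    group (exactly two groups).  Returns (per-sample mean Series, p).
    """
    drug_subset = list(drug_subset)
    if not drug_subset:
        raise ValidationError("drug subset is empty")
    missing = set(drug_subset) - set(dss_matrix.index)
    if missing:
        raise ValidationError(f"drugs absent from DSS matrix: {sorted(missing)}")
    unlabeled = set(dss_matrix.columns) - set(group_labels)
    if unlabeled:
        raise ValidationError(f"unlabeled samples: {sorted(unlabeled)}")
    means = dss_matrix.loc[drug_subset].mean(axis=0)
    groups = sorted(set(group_labels[s] for s in dss_matrix.columns))
    if len(groups) != 2:
        raise ValidationError(f"need exactly two groups, got {groups}")
    vals = {g: [means[s] for s in dss_matrix.columns if group_labels[s] == g]
            for g in groups}
    for g, v in vals.items():
        if not v:
            raise ValidationError(f"group {g!r} has no samples")
    p = exact_wilcoxon(vals[groups[0]], vals[groups[1]])
    return means, p
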