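import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from plexscreen.doseresponse import (DssConfig, FourPL, dss, dss_cutoff,
                                     exact_wilcoxon, fit_4pl,
                                     group_dss_comparison)
from plexscreen.io import ConfigError, ValidationError

CONC = np.array([1.0, 10.0, 100.0, 1000.0, 10000.0])


class TestFit4pl:
    @pytest.mark.parametrize("truth", [
        FourPL(0.0, 80.0, 2.0, 1.0),
        FourPL(2.0, 85.0, 2.3, 1.3),
        FourPL(5.0, 45.0, 1.2, 0.8),
    ])
    def test_noiseless_round_trip(self, truth):
        pairs = np.column_stack([CONC, truth(np.log10(CONC))])
        fit = fit_4pl(pairs)
        x = np.linspace(0.0, 4.0, 50)
        np.testing.assert_allclose(fit(x), truth(x), atol=1e-4)

    def test_flat_zero_gives_zero_dss(self):
        pairs = np.column_stack([CONC, np.zeros(5)])
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_4pl(pairs)
        assert fit.top == fit.bottom == 0.0
        assert dss(fit, (0.0, 4.0)) == 0.0

    def test_non_increasing_concentrations_rejected(self):
        pairs = np.column_stack([CONC[::-1], np.zeros(5)])
        with pytest.raises(ValidationError):
            fit_4pl(pairs)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_4pl(np.array([[1.0, 0.0], [10.0, 50.0], [100.0, 80.0]]))


class TestDss:
    def test_flat_responses(self):
        assert dss(FourPL(0.0, 0.0, 2.0, 0.0), (0.0, 4.0)) == 0.0
        full = FourPL(100.0, 100.0, 2.0, 0.0)
        np.testing.assert_allclose(
            dss(full, (0.0, 4.0), DssConfig(activity_threshold=10.0)), 100.0)

    def test_matches_fine_grid_trapezoid_oracle(self):
        """Mid-potency curve: DSS equals a 10,000-point trapezoid-rule
        integration within 0.1."""
        fit = FourPL(0.0, 80.0, 2.0, 1.0)
        cfg = DssConfig(activity_threshold=10.0)
        x = np.linspace(0.0, 4.0, 10000)
        y = np.clip(fit(x), None, 100.0)
        area = np.trapezoid(np.maximum(y - 10.0, 0.0), x)
        oracle = 100.0 * area / ((100.0 - 10.0) * 4.0)
        assert abs(dss(fit, (0.0, 4.0), cfg) - oracle) < 0.1

    def test_monotone_in_response_level(self):
        scores = [dss(FourPL(0.0, top, 2.0, 1.0), (0.0, 4.0))
                  for top in (20.0, 40.0, 60.0, 80.0, 100.0)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_bounded_and_unit_invariant(self):
        fit = FourPL(0.0, 90.0, 2.0, 1.2)
        s = dss(fit, (0.0, 4.0))
        assert 0.0 <= s <= 100.0
        # changing the concentration unit shifts the log window; the same
        # curve shifted along with it yields the same score
        shifted = FourPL(0.0, 90.0, 5.0, 1.2)
        np.testing.assert_allclose(dss(shifted, (3.0, 7.0)), s, atol=1e-9)

    def test_threshold_at_or_above_100_rejected(self):
        with pytest.raises(ConfigError):
            DssConfig(activity_threshold=100.0)


class TestDssCutoff:
    def test_linear_interpolation_convention(self):
        # h = (n-1)p + 1 = 3.25 -> 3 + 0.25*(4-3)
        assert dss_cutoff([1.0, 2.0, 3.0, 4.0], 75.0) == 3.25

    def test_degenerate_cases(self):
        assert dss_cutoff([5.0, 5.0, 5.0], 75.0) == 5.0
        assert dss_cutoff([1.0, 9.0, 4.0], 100.0) == 9.0
        with pytest.raises(ValidationError):
            dss_cutoff([], 75.0)


def ranksum_enumeration_oracle(a, b):
    """Brute force: every C(n, n_a) rank assignment equiprobable."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled, method="average")
    n, n_a = pooled.size, len(a)
    w_obs = ranks[:n_a].sum()
    ws = [sum(c) for c in itertools.combinations(ranks, n_a)]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestExactWilcoxon:
    def test_three_vs_five_complete_separation(self):
        p = exact_wilcoxon([10.0, 11.0, 12.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        np.testing.assert_allclose(p, 2.0 / 56.0, rtol=1e-12)
        assert round(p, 3) == 0.036

    def test_one_vs_one_is_uninformative(self):
        assert exact_wilcoxon([1.0], [2.0]) == 1.0

    @pytest.mark.parametrize("n_a,n_b", [(1, 2), (2, 2), (3, 3), (2, 5),
                                         (4, 4), (3, 7), (5, 5)])
    def test_matches_enumeration_oracle_without_ties(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 100 + n_b)
        for _ in range(5):
            vals = rng.permutation(np.arange(n_a + n_b, dtype=float) * 1.3)
            a, b = vals[:n_a], vals[n_a:]
            np.testing.assert_allclose(exact_wilcoxon(a, b),
                                       ranksum_enumeration_oracle(a, b),
                                       rtol=1e-12)

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 4), (4, 5)])
    def test_matches_enumeration_oracle_with_ties(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        for _ in range(5):
            vals = rng.integers(0, 3, size=n_a + n_b).astype(float)
            a, b = vals[:n_a], vals[n_a:]
            np.testing.assert_allclose(exact_wilcoxon(a, b),
                                       ranksum_enumeration_oracle(a, b),
                                       rtol=1e-12)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(0.8, 1.0, 20)
        p = exact_wilcoxon(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic").pvalue
        np.testing.assert_allclose(p, ref, rtol=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            exact_wilcoxon([], [1.0])


class TestGroupComparison:
    def matrix(self):
        rng = np.random.default_rng(1)
        samples = [f"M{i}" for i in range(8)]
        drugs = [f"egfr{i}" for i in range(7)] + ["other"]
        data = rng.uniform(0.0, 10.0, size=(8, 8))
        # three high samples exceed all five low samples on EGFR drugs
        data[:7, :3] += 50.0
        return pd.DataFrame(data, index=drugs, columns=samples)

    def test_separated_groups_give_paper_pvalue(self):
        m = self.matrix()
        labels = {s: ("high" if i < 3 else "low")
                  for i, s in enumerate(m.columns)}
        means, p = group_dss_comparison(m, labels,
                                        [f"egfr{i}" for i in range(7)])
        assert round(p, 3) == 0.036
        assert means.shape == (8,)

    def test_identical_groups_give_p_one(self):
        m = self.matrix()
        m.loc[:] = 3.0
        labels = {s: ("a" if i < 4 else "b") for i, s in enumerate(m.columns)}
        _, p = group_dss_comparison(m, labels, ["egfr0"])
        assert p == 1.0

    def test_single_drug_mean_is_that_drug(self):
        m = self.matrix()
        labels = {s: ("a" if i < 4 else "b") for i, s in enumerate(m.columns)}
        means, _ = group_dss_comparison(m, labels, ["egfr0"])
        pd.testing.assert_series_equal(means, m.loc["egfr0"],
                                       check_names=False)

    def test_empty_group_rejected(self):
        m = self.matrix()
        labels = {s: "a" for s in m.columns}
        with pytest.raises(ValidationError):
            group_dss_comparison(m, labels, ["egfr0"])
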