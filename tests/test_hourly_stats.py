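"""Hourly ANOVA and the directional Tukey-Kramer significance matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diurnalseek import hourly_anova, tukey_kramer
from diurnalseek.diurnal import FoldedDays
from diurnalseek.exceptions import ConfigError, DegenerateDataError
from diurnalseek.hourly_stats import studentized_range_sf

from conftest import permutation_anova_p


def _folded(rng, n_days=31, means=None, sd=1.0):
    m = rng.normal(0, sd, size=(n_days, 24))
    if means is not None:
        m += np.asarray(means)
    return FoldedDays(m)


class TestHourlyAnova:
    def test_identical_group_means_give_zero_f(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 1, size=(10, 1))
        folded = FoldedDays(50.0 + np.tile(noise, (1, 24)))
        f, p = hourly_anova(folded)
        assert f == pytest.approx(0.0, abs=1e-20)
        assert p == pytest.approx(1.0)

    def test_degenerate_constant_input(self):
        with pytest.raises(DegenerateDataError):
            hourly_anova(FoldedDays(np.full((5, 24), 50.0)))

    def test_large_offset_agrees_with_permutation_oracle(self):
        """Two hours offset by 10 SD: both the F test and a permutation
        oracle call it highly significant."""
        rng = np.random.default_rng(1)
        means = np.zeros(24)
        means[[2, 3]] = 10.0       # 10 x SD(=1) offset
        folded = _folded(rng, n_days=31, means=means)
        _, p = hourly_anova(folded)
        assert p < 0.001
        groups = [folded.matrix[:, h] for h in range(24)]
        assert permutation_anova_p(groups, n_perm=2000, seed=5) < 0.01

    def test_null_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(2)
        folded = _folded(rng, n_days=8)
        _, p = hourly_anova(folded)
        groups = [folded.matrix[:, h] for h in range(24)]
        p_perm = permutation_anova_p(groups, n_perm=2000, seed=6)
        assert (p < 0.05) == (p_perm < 0.05)


class TestTukeyKramer:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 1, size=(12, 1))
        sig = tukey_kramer(FoldedDays(50.0 + np.tile(noise, (1, 24))))
        assert not sig.greater.any()

    def test_equal_n_reduces_to_tukey_hsd_oracle(self):
        """With equal group sizes the Kramer form IS Tukey HSD; adjusted
        p-values match statsmodels' pairwise_tukeyhsd."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(4)
        m = rng.normal(0, 1, size=(5, 24)) + np.linspace(0, 3, 24)
        sig = tukey_kramer(FoldedDays(m))
        values = m.ravel(order="F")
        labels = np.repeat(np.arange(24), 5)
        res = pairwise_tukeyhsd(values, labels, alpha=0.05)
        k = 0
        for i in range(24):
            for j in range(i + 1, 24):
                assert sig.p_adjusted[i, j] == pytest.approx(
                    res.pvalues[k], abs=1e-4)
                k += 1

    def test_three_group_toy_against_independent_studentized_range(self):
        """Means 0/0/5 with SD~1, n=5 each: only pairs involving the third
        group are significant; p matches a direct studentized-range calc."""
        from scipy.stats import studentized_range

        rng = np.random.default_rng(7)
        g = rng.normal(0, 1, size=(5, 3))
        g[:, 2] += 5.0
        sig = tukey_kramer(g, alpha=0.05)
        assert bool(sig.greater[2, 0]) and bool(sig.greater[2, 1])
        assert not sig.greater[0, 1] and not sig.greater[1, 0]
        # independent oracle for one pair
        means = g.mean(axis=0)
        ssw = ((g - means) ** 2).sum()
        s2 = ssw / (15 - 3)
        q = abs(means[2] - means[0]) / np.sqrt(s2 / 5)
        p_direct = studentized_range.sf(q, 3, 12)
        assert sig.p_adjusted[2, 0] == pytest.approx(p_direct, abs=1e-4)

    def test_interpolated_sf_matches_scipy(self):
        from scipy.stats import studentized_range

        q = np.array([1.0, 2.5, 3.63, 4.9, 6.2, 8.0])
        exact = studentized_range.sf(q, 24, 312)
        approx = studentized_range_sf(q, 24, 312)
        np.testing.assert_allclose(approx, exact, atol=1e-5)

    def test_alpha_out_of_range(self):
        with pytest.raises(ConfigError):
            tukey_kramer(FoldedDays(np.zeros((3, 24))), alpha=0.7)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matrix_invariants_on_random_inputs(self, seed):
        """Antisymmetry, false/unit diagonal, symmetric adjusted p."""
        rng = np.random.default_rng(seed)
        shift = rng.normal(0, 2, 24)
        sig = tukey_kramer(_folded(rng, n_days=5, means=shift))
        assert not (sig.greater & sig.greater.T).any()
        assert not sig.greater.diagonal().any()
        np.testing.assert_array_equal(sig.p_adjusted.diagonal(), np.ones(24))
        np.testing.assert_allclose(sig.p_adjusted, sig.p_adjusted.T)
        # direction always follows the larger sample mean
        ii, jj = np.nonzero(sig.greater)
        assert (sig.mean_by_hour[ii] > sig.mean_by_hour[jj]).all()

    def test_monotonicity_raising_one_hour(self):
        """Raising every value of one hour never loses that hour wins."""
        rng = np.random.default_rng(8)
        base = _folded(rng, n_days=10, means=np.linspace(0, 2, 24))
        wins_before = tukey_kramer(base).greater[5].sum()
        raised = base.matrix.copy()
        raised[:, 5] += 3.0
        wins_after = tukey_kramer(FoldedDays(raised)).greater[5].sum()
        assert wins_after >= wins_before

    def test_agreement_with_permutation_maxt_oracle(self):
        """6 groups x 8 replicates: Tukey-Kramer significance agrees with
        a permutation max-T null in >= 95% of seeds."""
        from itertools import combinations

        agree = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            m = rng.normal(0, 1, size=(8, 6))
            m[:, 5] += rng.choice([0.0, 2.5])
            sig = tukey_kramer(m, alpha=0.05)
            tk_set = {(i, j) for i, j in np.argwhere(sig.greater)}

            # permutation max-T: largest pairwise q under relabeling
            def max_q(mat):
                mm = mat.mean(axis=0)
                ssw = ((mat - mm) ** 2).sum()
                s2 = ssw / (mat.size - 6)
                return max(abs(mm[a] - mm[b]) / np.sqrt(s2 / 8)
                           for a, b in combinations(range(6), 2))

            obs_q = np.zeros((6, 6))
            mm = m.mean(axis=0)
            s2 = ((m - mm) ** 2).sum() / (m.size - 6)
            for a, b in combinations(range(6), 2):
                obs_q[a, b] = obs_q[b, a] = abs(mm[a] - mm[b]) / np.sqrt(s2 / 8)
            pooled = m.ravel()
            null = np.array([
                max_q(rng.permutation(pooled).reshape(8, 6))
                for _ in range(300)
            ])
            crit = np.quantile(null, 0.95)
            perm_set = set()
            for a, b in combinations(range(6), 2):
                if obs_q[a, b] > crit:
                    hi, lo = (a, b) if mm[a] > mm[b] else (b, a)
                    perm_set.add((hi, lo))
            if tk_set == perm_set:
                agree += 1
        assert agree / n_seeds >= 0.95
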