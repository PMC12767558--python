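"""Inference layer: signed-rank anchor values, exact-vs-asymptotic
agreement, Friedman with ties, alpha splitting and sample size."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from periquant import stats
from periquant.stats import InsufficientDataError

#: Printed two-sided asymptotic p (3 dp) for n = 6, no ties, by
#: minority-sign rank sum; identical to 2*(1-Phi(|T - 10.5|/sqrt(22.75))).
N6_P_TABLE = {
    0: 0.028, 1: 0.046, 2: 0.075, 3: 0.116, 4: 0.173, 5: 0.249,
    6: 0.345, 7: 0.463, 8: 0.600, 9: 0.753, 10: 0.917,
}


def pairs_with_minority_rank_sum(t_minus, n=6):
    """Six distinct-magnitude differences whose negative ranks sum to t_minus."""
    for flips in itertools.chain.from_iterable(
        itertools.combinations(range(1, n + 1), k) for k in range(n + 1)
    ):
        if sum(flips) == t_minus:
            d = np.array(
                [-m if m in flips else m for m in range(1, n + 1)], float
            )
            return d, np.zeros(n)
    raise AssertionError("unreachable for t_minus <= n(n+1)/2")


class TestWilcoxonAsymptotic:
    @pytest.mark.parametrize("t_minus,expected", sorted(N6_P_TABLE.items()))
    def test_n6_p_table_matches_closed_form(self, t_minus, expected):
        x, y = pairs_with_minority_rank_sum(t_minus)
        res = stats.wilcoxon_signed_rank(x, y)
        assert round(res.p_two_sided, 3) == expected
        z = abs(t_minus - 10.5) / math.sqrt(22.75)
        assert res.p_two_sided == pytest.approx(2 * sps.norm.sf(z))

    def test_matches_scipy_normal_approximation_without_correction(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            ours = stats.wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, correction=False, method="approx")
            assert ours.p_two_sided == pytest.approx(ref.pvalue)

    def test_zero_differences_dropped(self):
        x = np.array([5.0, 5.0, 1.0, 2.0, 3.0, 4.0, 6.0, 7.0])
        y = np.array([5.0, 5.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        res = stats.wilcoxon_signed_rank(x, y)
        assert res.n_effective == 6

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            stats.wilcoxon_signed_rank(
                np.array([1.0, 2.0]), np.array([1.0, 2.0])
            )

    def test_tied_magnitudes_use_midranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, -1.0, 4.0])
        y = np.zeros(6)
        res = stats.wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(x, y, correction=False, method="approx")
        assert res.p_two_sided == pytest.approx(ref.pvalue)


class TestWilcoxonExact:
    def test_uniform_signs_give_2_over_64(self):
        x, y = pairs_with_minority_rank_sum(0)
        res = stats.wilcoxon_signed_rank(x, y, mode="exact")
        assert res.p_two_sided == 2.0 / 64.0

    def test_distribution_matches_direct_sign_enumeration(self, rng):
        n = 8
        ranks = np.arange(1, n + 1)
        dist = stats.exact_rank_sum_distribution(ranks)
        direct = {}
        for signs in itertools.product((0, 1), repeat=n):
            s = float(sum(r for r, keep in zip(ranks, signs) if keep))
            direct[s] = direct.get(s, 0) + 1
        assert dist == direct

    def test_matches_scipy_exact_p(self, rng):
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            ours = stats.wilcoxon_signed_rank(x, y, mode="exact")
            ref = sps.wilcoxon(x, y, method="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue)

    def test_exact_mode_refuses_tied_magnitudes(self):
        x = np.array([1.0, -1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            stats.wilcoxon_signed_rank(x, np.zeros(4), mode="exact")

    def test_corrected_normal_gap_shrinks_with_n(self):
        """The continuity-corrected normal CDF approximates the exact
        two-sided p within 0.05 at n = 6 and 0.01 at n = 25; the
        uncorrected variant shipped for the printed anchors is known to
        carry a larger near-centre gap (~0.015 at n = 25)."""
        for n, bound in ((6, 0.05), (25, 0.01)):
            ranks = np.arange(1, n + 1)
            dist = stats.exact_rank_sum_distribution(ranks)
            total = 2.0**n
            mu = n * (n + 1) / 4.0
            sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
            gap = 0.0
            for w in range(int(mu) + 1):
                p_exact = min(
                    2.0 * sum(c for s, c in dist.items() if s <= w) / total,
                    1.0,
                )
                p_asym = min(2.0 * sps.norm.sf((mu - w - 0.5) / sigma), 1.0)
                gap = max(gap, abs(p_exact - p_asym))
            assert gap < bound

    def test_asymptotic_type_I_error_in_band_at_n6(self):
        # exact-null enumeration of the asymptotic test's rejections
        n, alpha = 6, 0.05
        dist = stats.exact_rank_sum_distribution(np.arange(1, n + 1))
        total = 2.0**n
        mu = n * (n + 1) / 4.0
        sigma = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        reject = 0
        for s, count in dist.items():
            w = min(s, n * (n + 1) / 2.0 - s)
            p = 2.0 * sps.norm.sf((mu - w) / sigma)
            if p < alpha:
                reject += count
        assert 0.02 <= reject / total <= 0.08


class TestFriedman:
    def test_identical_columns_give_statistic_zero_p_one(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 4))
        res = stats.friedman(data)
        assert res.statistic == 0.0 and res.p_two_sided == 1.0

    def test_small_integer_example_matches_rank_formula(self):
        data = np.array([[1.0, 2.0, 3.0],
                         [2.0, 3.0, 1.0],
                         [1.0, 3.0, 2.0]])
        # within-row ranks as written; column rank sums 4, 8, 6
        n, k = 3, 3
        expected = 12.0 / (n * k * (k + 1)) * (16 + 64 + 36) - 3 * n * (k + 1)
        res = stats.friedman(data)
        assert res.statistic == pytest.approx(expected)

    def test_matches_scipy_with_and_without_ties(self, rng):
        for _ in range(10):
            data = rng.integers(0, 5, size=(8, 4)).astype(float)
            if np.all(data.max(axis=1) == data.min(axis=1)):
                continue
            res = stats.friedman(data)
            ref = sps.friedmanchisquare(*data.T)
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_column_permutation_leaves_p_unchanged(self, rng):
        data = rng.normal(size=(6, 4))
        res = stats.friedman(data)
        perm = stats.friedman(data[:, [2, 0, 3, 1]])
        assert perm.p_two_sided == pytest.approx(res.p_two_sided)

    def test_matrix_shape_validated(self):
        with pytest.raises(ValueError):
            stats.friedman(np.zeros((1, 3)))


class TestAlphaAndSampleSize:
    def test_bonferroni_across_14_comparisons_is_036_percent(self):
        alpha = stats.familywise_alpha(0.05, 14)
        assert round(100 * alpha, 2) == 0.36

    @pytest.mark.parametrize("fwer,m,expected", [
        (0.05, 1, 0.05), (0.10, 2, 0.05),
    ])
    def test_identity_and_halving(self, fwer, m, expected):
        assert stats.familywise_alpha(fwer, m) == pytest.approx(expected)

    def test_two_sample_unit_effect_needs_16_per_group(self):
        # 2*(z_.975 + z_.80)^2 = 15.70 -> 16
        assert stats.sample_size_z(1.0, 1.0, 0.05, 0.80) == 16

    def test_paired_design_at_bonferroni_alpha(self):
        alpha = 0.05 / 14
        expected = math.ceil(
            (sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(0.80)) ** 2
        )
        n = stats.sample_size_z(10.0, 10.0, alpha, 0.80, design="paired")
        assert n == expected == 15

    def test_doubling_sigma_quadruples_n_before_ceiling(self):
        n1 = stats.sample_size_z(1.0, 1.0, 0.05, 0.80, design="paired")
        n4 = stats.sample_size_z(1.0, 2.0, 0.05, 0.80, design="paired")
        core = (sps.norm.ppf(0.975) + sps.norm.ppf(0.80)) ** 2
        assert n1 == math.ceil(core) and n4 == math.ceil(4 * core)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            stats.sample_size_z(0.0, 1.0)
        with pytest.raises(ValueError):
            stats.sample_size_z(1.0, 1.0, alpha=0.5, power=0.2)


class TestPairwiseMatrix:
    def test_lower_triangle_shape(self, rng):
        import pandas as pd

        table = pd.DataFrame(
            rng.normal(size=(6, 4)), columns=list("abcd")
        )
        mat = stats.pairwise_wilcoxon_matrix(table)
        assert mat.shape == (4, 4)
        assert np.isnan(np.diag(mat)).all()
        assert np.isnan(mat.to_numpy()[np.triu_indices(4, 1)]).all()
        assert np.isfinite(mat.to_numpy()[np.tril_indices(4, -1)]).all()

    def test_strong_planted_effect_reaches_the_n6_floor(self):
        """With n = 6 and a shift far above noise, all six differences are
        one-signed and the asymptotic p hits its floor of 0.028."""
        from periquant import phantom

        data = phantom.generate_paired_cohort(
            6, 2, effect_sizes=np.array([0.0, 25.0]), noise_sd=1.0, seed=42
        )
        res = stats.wilcoxon_signed_rank(data[:, 1], data[:, 0])
        assert round(res.p_two_sided, 3) == 0.028

    def test_null_type_I_rate_near_nominal(self):
        """Wilcoxon rejection rate at alpha = 0.05 under no effect, many
        replicate cohorts, stays near the nominal level."""
        from periquant import phantom

        n_rep, reject = 400, 0
        for rep in range(n_rep):
            data = phantom.generate_paired_cohort(
                30, 2, noise_sd=1.0, seed=rep
            )
            res = stats.wilcoxon_signed_rank(data[:, 0], data[:, 1])
            if res.p_two_sided < 0.05:
                reject += 1
        assert 0.02 <= reject / n_rep <= 0.08
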