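"""Performance metrics: pseudo-R2, AUC, calibration, chi-squared, Spearman."""

import itertools

import numpy as np
import pytest

from lkbntcp.metrics import (auc, hosmer_lemeshow, nagelkerke_r2,
                             pearson_chi2_2x2, pearson_chi2_gof, spearman)


def auc_pairwise_oracle(scores, labels):
    """Exhaustive Mann-Whitney concordance over all event/non-event pairs."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestNagelkerke:
    def test_zero_when_model_equals_null(self):
        assert nagelkerke_r2(-5.0, -5.0, 20) == pytest.approx(0.0, abs=1e-12)

    def test_one_for_perfect_fit_balanced(self):
        ll_null = 10 * np.log(0.5)
        assert nagelkerke_r2(0.0, ll_null, 10) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # n=10, ll0 = 10*log(0.5) = -6.9315, ll = -5.0:
        # CS = 1-exp(-0.386294) = 0.3204295, max = 1-exp(-1.386294) = 0.75
        value = nagelkerke_r2(-5.0, -6.931471805599453, 10)
        assert value == pytest.approx(0.3204295428852387 / 0.75, rel=1e-10)

    def test_model_worse_than_null_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-7.0, -5.0, 10)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [False, False, True, True]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0.5] * 6, [True, False] * 3) == 0.5

    def test_tie_pair_against_enumeration(self):
        scores = [0.1, 0.4, 0.4, 0.6, 0.7, 0.9]
        labels = [False, False, True, False, True, True]
        assert auc(scores, labels) == pytest.approx(
            auc_pairwise_oracle(scores, labels), rel=1e-12)

    def test_random_inputs_against_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 50))
            scores = rng.choice(np.round(rng.uniform(0, 1, 10), 2), size=n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels) == pytest.approx(
                auc_pairwise_oracle(scores, labels), rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.2, 0.8], [True, True])


class TestHosmerLemeshow:
    def test_exact_calibration_gives_zero_chi2(self):
        # each risk group's prediction equals its empirical event rate
        pred, labels = [], []
        for g in range(10):
            p = (g + 1) / 20.0
            pred.extend([p] * 20)
            labels.extend([True] * int(20 * p) + [False] * (20 - int(20 * p)))
        chi2, df, p_value = hosmer_lemeshow(pred, labels, groups=10)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 8
        assert p_value == pytest.approx(1.0)

    def test_df_is_groups_minus_two(self, rng):
        pred = rng.uniform(0.05, 0.95, 200)
        labels = rng.random(200) < pred
        _, df, _ = hosmer_lemeshow(pred, labels, groups=10)
        assert df == 8

    def test_miscalibrated_model_rejected(self, rng):
        pred = rng.uniform(0.05, 0.3, 400)
        labels = rng.random(400) < 0.7  # events far above prediction
        chi2, df, p_value = hosmer_lemeshow(pred, labels)
        assert p_value < 1e-6

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5] * 10, [True] * 10, groups=10)

    def test_ties_stay_in_lower_bin(self, rng):
        # a tie block of 40 at the lowest prediction straddles the first
        # two decile edges (20 and 40 of 160): the first edge is pushed to
        # the end of the block, collides with the second and is dropped,
        # leaving 7 bins and df = 5
        pred = np.concatenate([np.full(40, 0.1),
                               np.linspace(0.2, 0.9, 120)])
        labels = rng.random(160) < pred
        _, df, _ = hosmer_lemeshow(pred, labels, groups=8)
        assert df == 5

    def test_all_tied_predictions_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.4] * 100, [True] * 30 + [False] * 70,
                            groups=10)


class TestPearsonChi2:
    def test_independence_table(self):
        chi2, p = pearson_chi2_2x2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_association(self):
        # margins all 25, E=12.5 everywhere: 4 * 7.5^2/12.5 = 18
        chi2, _ = pearson_chi2_2x2([[20, 5], [5, 20]])
        assert chi2 == pytest.approx(18.0, rel=1e-12)

    def test_transposition_invariance(self):
        table = [[12, 3], [7, 9]]
        assert pearson_chi2_2x2(table)[0] == pytest.approx(
            pearson_chi2_2x2(np.transpose(table))[0], rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2_2x2([[0, 0], [5, 7]])

    def test_gof_statistic_matches_hand_sum(self, rng):
        pred = rng.uniform(0.1, 0.9, 30)
        labels = rng.random(30) < pred
        chi2, _ = pearson_chi2_gof(pred, labels)
        expected = sum((y - p) ** 2 / (p * (1 - p))
                       for p, y in zip(pred, labels))
        assert chi2 == pytest.approx(expected, rel=1e-12)


class TestSpearman:
    def test_monotone_increasing(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 25, 40, 80])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        rho, _ = spearman([1, 2, 3, 4], [9, 7, 4, 1])
        assert rho == pytest.approx(-1.0)

    def test_printed_correlation_squares_to_r2(self):
        # a rank correlation of -0.807 explains 0.651 of rank variance
        assert round((-0.807) ** 2, 3) == 0.651

    def test_matches_rank_permutation_oracle(self, rng):
        # rho = Pearson correlation of average ranks, checked by direct
        # rank construction on small n
        from scipy.stats import rankdata
        for _ in range(20):
            n = int(rng.integers(3, 9))
            x = rng.uniform(0, 1, n)
            y = rng.uniform(0, 1, n)
            rx, ry = rankdata(x), rankdata(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert spearman(x, y)[0] == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [2, 3, 4])
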