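"""Metrics and the nonparametric comparison suite, against hand and
brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from bedpose.stats import (
    DegenerateInputError,
    bonferroni_threshold,
    compare_conditions,
    friedman_test,
    homogeneity_check,
    hypothetical_max_f1,
    macro_f1,
    normality_check,
    paired_wilcoxon,
    summarize,
)


class TestMacroF1:
    def test_perfect_predictions(self):
        y = np.array(["a", "b", "c", "a"])
        assert macro_f1(y, y) == 1.0

    def test_binary_hand_computation(self):
        # TP=2, FP=1, FN=1, TN=2 -> F1 = 2/3 for both classes
        truth = np.array([1, 1, 1, 0, 0, 0])
        pred = np.array([1, 1, 0, 1, 0, 0])
        assert macro_f1(pred, truth) == pytest.approx(2 / 3)

    def test_constant_prediction_three_balanced_classes(self):
        truth = np.repeat(["a", "b", "c"], 4)
        pred = np.full(12, "a")
        # class a: P=1/3, R=1 -> F1=0.5; b and c -> 0
        assert macro_f1(pred, truth, ["a", "b", "c"]) == pytest.approx(0.5 / 3)

    def test_permutation_and_relabel_invariance(self, rng):
        truth = rng.integers(0, 3, 60).astype(str)
        pred = rng.integers(0, 3, 60).astype(str)
        base = macro_f1(pred, truth)
        perm = rng.permutation(60)
        assert macro_f1(pred[perm], truth[perm]) == pytest.approx(base)
        relabel = {"0": "x", "1": "y", "2": "z"}
        assert macro_f1(
            np.array([relabel[p] for p in pred]),
            np.array([relabel[t] for t in truth]),
        ) == pytest.approx(base)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import f1_score

        truth = rng.integers(0, 4, 100)
        pred = rng.integers(0, 4, 100)
        assert macro_f1(pred, truth) == pytest.approx(
            f1_score(truth, pred, average="macro")
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            macro_f1(np.array([]), np.array([]))


class TestNormalityHomogeneity:
    def test_gaussian_passes_shapiro_mostly(self):
        passes = 0
        for seed in range(50):
            x = np.random.default_rng(seed).normal(size=500)
            _, p = normality_check(x)
            passes += p > 0.05
        assert passes >= 45

    def test_exponential_fails_shapiro(self):
        rejects = 0
        for seed in range(20):
            x = np.random.default_rng(seed).exponential(size=100)
            _, p = normality_check(x)
            rejects += p < 0.05
        assert rejects >= 19

    def test_constant_sample_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normality_check(np.ones(10))

    def test_identical_groups_levene_zero(self):
        g = np.arange(10.0)
        stat, p = homogeneity_check(g, g.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)


class TestFriedman:
    def test_identical_columns_null(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 3))
        stat, df, p = friedman_test(m)
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_perfect_ordering_closed_form(self):
        """18 participants, 3 strictly ordered conditions -> chi2 = 36."""
        base = np.random.default_rng(0).normal(size=18)
        m = np.column_stack([base, base + 1, base + 2])
        stat, df, p = friedman_test(m)
        assert stat == pytest.approx(36.0)
        assert df == 2
        assert p < 1e-7

    def test_agrees_with_rank_formula_oracle(self, rng):
        """Brute-force mean-rank formula on random tie-free matrices."""
        for _ in range(20):
            m = rng.normal(size=(6, 4))
            stat, df, _ = friedman_test(m)
            ranks = np.argsort(np.argsort(m, axis=1), axis=1) + 1
            rbar = ranks.mean(axis=0)
            n, k = m.shape
            expected = 12 * n / (k * (k + 1)) * np.sum(
                (rbar - (k + 1) / 2) ** 2
            )
            assert stat == pytest.approx(expected, rel=1e-9)

    def test_null_pvalues_roughly_uniform(self):
        """Independent rows give calibrated (if discrete) null p-values."""
        pvals = np.array([
            friedman_test(np.random.default_rng(seed).normal(size=(12, 3)))[2]
            for seed in range(200)
        ])
        # the rank statistic is discrete, so check calibration rather than
        # an exact KS fit: correct size at 5% and a centred distribution
        assert np.mean(pvals < 0.05) <= 0.10
        assert abs(pvals.mean() - 0.5) < 0.08

    def test_incomplete_matrix_rejected(self):
        m = np.ones((4, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            friedman_test(m)


class TestWilcoxon:
    def test_all_positive_differences_maximal_v(self):
        b = np.arange(1.0, 9.0)
        a = b + 2.0
        v, _ = paired_wilcoxon(a, b)
        assert v == 8 * 9 / 2

    def test_identical_samples_degenerate(self):
        a = np.arange(5.0)
        with pytest.raises(DegenerateInputError):
            paired_wilcoxon(a, a.copy())

    def test_hand_ranked_example(self):
        a = np.array([1.0, 0.0, 3.0])
        b = np.array([0.0, 2.0, 0.0])  # diffs +1, -2, +3 -> ranks 1,2,3
        v, _ = paired_wilcoxon(a, b)
        assert v == 4.0

    def test_exact_p_matches_enumeration(self, rng):
        """Exact two-sided p equals full sign-flip enumeration for n <= 8."""
        for _ in range(10):
            d = rng.normal(size=7)
            while len(np.unique(np.abs(d))) != len(d) or (d == 0).any():
                d = rng.normal(size=7)
            a = d
            b = np.zeros_like(d)
            v, p = paired_wilcoxon(a, b)
            ranks = sst.rankdata(np.abs(d))
            count = 0
            total = 0
            for signs in itertools.product([1, -1], repeat=len(d)):
                vs = ranks[np.array(signs) > 0].sum()
                total += 1
                # two-sided: as or more extreme in either direction
                mu = ranks.sum() / 2
                if abs(vs - mu) >= abs(v - mu) - 1e-12:
                    count += 1
            assert p == pytest.approx(count / total, abs=1e-9)


class TestComposition:
    def test_identity_with_perfect_phase_one(self):
        assert hypothetical_max_f1(1.0, 0.853) == 0.853

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hypothetical_max_f1(1.2, 0.5)

    def test_bonferroni_thresholds(self):
        assert bonferroni_threshold(3) == pytest.approx(0.05 / 3)
        assert bonferroni_threshold(2) == pytest.approx(0.025)


class TestCompareAndSummarize:
    def test_compare_detects_ordered_conditions(self):
        base = np.random.default_rng(4).uniform(0.5, 0.7, 12)
        matrix = pd.DataFrame(
            {"c45": base + 0.2, "c30": base + 0.1, "c15": base}
        )
        report = compare_conditions(matrix)
        assert report["omnibus"]["p"] < 0.001
        assert report["threshold"] == pytest.approx(0.025)
        assert all(pw["significant"] for pw in report["pairwise"])

    def test_summarize_hand_built(self):
        rows = []
        for p, f1 in zip(["a", "b", "c"], [0.8, 0.9, 1.0]):
            rows.append(dict(participant=p, backend="LGB", il_level=0.3,
                             phase="one", scheme="coarse3", side="all",
                             f1=f1, accuracy=f1, n_test=10))
        out = summarize(pd.DataFrame(rows))
        row = out.iloc[0]
        assert row["mean_f1"] == pytest.approx(0.9)
        assert row["sd_f1"] == pytest.approx(0.1)
        assert not row["single_participant"]

    def test_summarize_single_participant_flagged(self):
        df = pd.DataFrame([
            dict(participant="a", backend="LGB", il_level=0.3, phase="two",
                 scheme="bins45", side="left", f1=0.9, accuracy=0.9, n_test=5)
        ])
        out = summarize(df)
        assert out.iloc[0]["sd_f1"] == 0.0
        assert out.iloc[0]["single_participant"]
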