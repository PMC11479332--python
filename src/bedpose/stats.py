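"""Evaluation metrics and the nonparametric model-comparison suite.

Classifier performance is summarized per participant as macro F1 (the
unweighted mean of per-class F1 scores) and accuracy. Models, incremental
learning levels and bin precisions are compared with a Friedman rank test
across participants followed by post-hoc paired Wilcoxon signed-rank tests
with Bonferroni-corrected thresholds (0.05/k for k comparisons). Normality
and variance homogeneity are screened with Shapiro-Wilk and Levene tests.

Because the hierarchical scheme discards Phase One errors before Phase Two,
Phase Two scores overestimate end-to-end performance; the hypothetical
overall F1 is bounded by the product of the two phases' scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sst


class DegenerateInputError(ValueError):
    pass


def confusion_table(
    predictions: np.ndarray, truth: np.ndarray, labels: list
) -> dict:
    """Nested dict confusion counts: ``table[true_label][predicted_label]``."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    return {
        str(t): {
            str(p): int(np.sum((truth == t) & (predictions == p))) for p in labels
        }
        for t in labels
    }


def accuracy_score_simple(predictions: np.ndarray, truth: np.ndarray) -> float:
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) == 0:
        raise ValueError("empty input")
    return float(np.mean(predictions == truth))


def macro_f1(
    predictions: np.ndarray, truth: np.ndarray, label_set: list | None = None
) -> float:
    """Unweighted mean of per-class F1 = 2PR/(P+R).

    Classes absent from both predictions and truth are excluded from the
    average; a class with zero precision and recall contributes 0.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) == 0 or len(predictions) != len(truth):
        raise ValueError("inputs must be non-empty and aligned")
    if label_set is None:
        label_set = sorted(set(truth) | set(predictions))
    scores = []
    for lab in label_set:
        tp = np.sum((predictions == lab) & (truth == lab))
        fp = np.sum((predictions == lab) & (truth != lab))
        fn = np.sum((predictions != lab) & (truth == lab))
        if tp + fp + fn == 0:
            continue  # class absent everywhere
        scores.append(2 * tp / (2 * tp + fp + fn) if tp else 0.0)
    if not scores:
        raise ValueError("no class present in predictions or truth")
    return float(np.mean(scores))


def normality_check(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value."""
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(sample) == 0:
        raise DegenerateInputError("constant sample")
    w, p = sst.shapiro(sample)
    return float(w), float(p)


def homogeneity_check(*groups: np.ndarray) -> tuple[float, float]:
    """Levene statistic and p-value for homogeneity of variances."""
    if len(groups) < 2:
        raise ValueError("Levene needs >= 2 groups")
    stat, p = sst.levene(*[np.asarray(g, dtype=float) for g in groups])
    return float(stat), float(p)


def friedman_test(matrix: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Friedman rank test over a complete participants x conditions matrix.

    Returns (chi-square statistic, df = k - 1, p). Identical columns give a
    zero statistic and p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 participants and >= 2 conditions")
    if np.isnan(m).any():
        raise ValueError("matrix must be complete (no missing cells)")
    k = m.shape[1]
    if np.allclose(m, m[:, [0]]):
        return 0.0, k - 1, 1.0
    stat, p = sst.friedmanchisquare(*m.T)
    return float(stat), k - 1, float(p)


def paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test.

    Returns (V, p) with V the sum of the ranks of positive differences
    (zero differences dropped, average ranks for ties) — the convention R's
    ``wilcox.test`` prints. The p-value is exact for n <= 25 without ties,
    normal-approximated otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise DegenerateInputError("all paired differences are zero")
    ranks = sst.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) != len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    res = sst.wilcoxon(a[: len(a)], b[: len(b)], zero_method="wilcox", method=method)
    return v, float(res.pvalue)


def bonferroni_threshold(k: int, alpha: float = 0.05) -> float:
    """Corrected per-comparison significance threshold alpha/k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


def compare_conditions(
    matrix: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Omnibus Friedman test plus all adjacent-pair Wilcoxon post hocs.

    ``matrix`` is participants x conditions (columns ordered as the
    comparison sequence, e.g. IL levels or bin precisions). Pairwise tests
    compare each column to the next; significance uses the Bonferroni
    threshold for the number of pairs.
    """
    stat, df, p = friedman_test(matrix)
    cols = list(matrix.columns)
    pairs = []
    thr = bonferroni_threshold(max(len(cols) - 1, 1), alpha)
    for c1, c2 in zip(cols[:-1], cols[1:]):
        try:
            v, pv = paired_wilcoxon(
                matrix[c1].to_numpy(), matrix[c2].to_numpy()
            )
        except DegenerateInputError:
            v, pv = np.nan, np.nan
        pairs.append(
            dict(pair=(c1, c2), V=v, p=pv, significant=bool(pv < thr))
            if np.isfinite(pv)
            else dict(pair=(c1, c2), V=v, p=pv, significant=False)
        )
    return dict(
        omnibus=dict(statistic=stat, df=df, p=p),
        pairwise=pairs,
        threshold=thr,
    )


def hypothetical_max_f1(phase_one_f1: float, phase_two_f1: float) -> float:
    """Upper bound on end-to-end F1: the product of the two phases' scores.

    Phase Two is evaluated only on windows Phase One classified correctly,
    so its score overestimates the full pipeline; composing the phases
    multiplicatively gives the achievable ceiling. Reported to 3 decimals.
    """
    for v in (phase_one_f1, phase_two_f1):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"F1 {v} outside [0, 1]")
    return round(phase_one_f1 * phase_two_f1, 3)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of per-participant F1 and accuracy per condition.

    Phase One rows aggregate per (backend, il_level); Phase Two rows per
    (backend, side, scheme). A single-participant group reports sd = 0 and
    ``single_participant = True``.
    """
    if not len(results):
        raise ValueError("empty results")
    out = []
    for phase, keys in (
        ("one", ["backend", "il_level"]),
        ("two", ["backend", "side", "scheme"]),
    ):
        sub = results[results["phase"] == phase]
        for group, g in sub.groupby(keys):
            row = dict(zip(keys, group if isinstance(group, tuple) else (group,)))
            row.update(
                phase=phase,
                n_participants=g["participant"].nunique(),
                mean_f1=float(g["f1"].mean()),
                sd_f1=float(g["f1"].std(ddof=1)) if len(g) > 1 else 0.0,
                mean_accuracy=float(g["accuracy"].mean()),
                sd_accuracy=float(g["accuracy"].std(ddof=1)) if len(g) > 1 else 0.0,
                single_participant=g["participant"].nunique() == 1,
            )
            out.append(row)
    return pd.DataFrame(out)
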