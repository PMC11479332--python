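"""Two-phase hierarchical posture classification under LOPO cross-validation.

Phase One predicts the coarse posture (left / supine / right) from the
twelve window features. Windows Phase One gets wrong are discarded; the
correctly classified left- and right-side windows feed Phase Two, which
refines each side into equal-width angle bins at 45, 30 or 15 degree
precision (supine has fixed width and is never refined).

Evaluation is leave-one-participant-out (LOPO): each fold trains on every
other participant and tests on the held-out one. Personalization is probed
with incremental learning: the held-out participant's windows are split
70/30 into a fixed test set and a learning pool, and a fraction
c in {0, 10, 20, 30}% of their windows (drawn from the pool, nested across
levels) is added to the training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FEATURE_NAMES
from .labels import (
    OUT_OF_RANGE,
    BinScheme,
    coarse_labels,
    scheme_edges,
    side_bin_labels,
)
from .stats import accuracy_score_simple, confusion_table, macro_f1

BACKENDS = ("LGB", "GBC", "ADA", "XGB", "LR", "SVM", "MLP1", "MLP2", "MLP3")


@dataclass(frozen=True)
class ClassifierSpec:
    """A feature-based backend with its hyperparameters and seed."""

    backend: str = "LGB"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}")


@dataclass(frozen=True)
class ILConfig:
    """Incremental-learning levels and the fixed 70/30 participant split."""

    levels: tuple[float, ...] = (0.0, 0.10, 0.20, 0.30)
    test_fraction: float = 0.70
    pool_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.test_fraction + self.pool_fraction - 1.0) > 1e-12:
            raise ValueError("test_fraction + pool_fraction must equal 1")
        if max(self.levels) > self.pool_fraction + 1e-12:
            raise ValueError("max level cannot exceed the pool fraction")


def _build_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    s = spec.seed
    if spec.backend == "LGB":
        return LGBMClassifier(random_state=s, verbose=-1, **hp)
    if spec.backend == "GBC":
        return GradientBoostingClassifier(random_state=s, **hp)
    if spec.backend == "ADA":
        return AdaBoostClassifier(random_state=s, **hp)
    if spec.backend == "XGB":
        return XGBClassifier(random_state=s, verbosity=0, **hp)
    if spec.backend == "LR":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=s, **hp),
        )
    if spec.backend == "SVM":
        return make_pipeline(StandardScaler(), SVC(random_state=s, **hp))
    hidden = {"MLP1": (32,), "MLP2": (64, 32), "MLP3": (128, 64, 32)}[spec.backend]
    return make_pipeline(
        StandardScaler(),
        MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", hidden),
            max_iter=hp.pop("max_iter", 500),
            random_state=s,
            **hp,
        ),
    )


class FittedModel:
    """A fitted backend with uniform string-label predict.

    Labels are integer-encoded before the underlying fit (some backends
    require it); prediction decodes back. Ties in posterior resolve to the
    lowest class index by the encoders' argmax convention.
    """

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self.estimator = _build_estimator(spec)
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FittedModel":
        y = np.asarray(y)
        self.classes_, encoded = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain >= 2 classes")
        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(X, axis=0)
        self._medians = np.where(np.isfinite(med), med, 0.0)
        self.estimator.fit(_fill_nan(X, self._medians), encoded)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _fill_nan(np.asarray(X, dtype=float), self._medians)
        with warnings.catch_warnings():
            # lightgbm auto-names numpy columns at fit, then sklearn's
            # validation complains at predict; harmless either way
            warnings.filterwarnings(
                "ignore", message=".*does not have valid feature names.*"
            )
            pred = self.estimator.predict(X)
        return self.classes_[pred.astype(int)]


def _fill_nan(X: np.ndarray, fill: np.ndarray) -> np.ndarray:
    if not np.isnan(X).any():
        return X
    return np.where(np.isnan(X), fill, X)


def incremental_split(
    participant_windows: pd.DataFrame, c: float, seed: int
) -> tuple[pd.Index, pd.Index]:
    """Deterministic stratified split of one participant's windows.

    Returns ``(test_index, il_index)``: 70% of windows per coarse class go
    to the test set, the remaining 30% form the incremental-learning pool,
    and the first floor(c / 0.30 * pool) windows of the (seed-shuffled)
    pool are the learning subset. The test set is identical across levels
    and subsets are nested, so raising c never removes training data.
    """
    if not 0 <= c <= 0.30 + 1e-12:
        raise ValueError("c must lie in [0, 0.30]")
    coarse = coarse_labels(participant_windows["truth_tpa"].to_numpy())
    rng = np.random.default_rng(seed)
    n_total = len(participant_windows)
    n_pool_total = int(np.floor(n_total * 0.30))

    # per-class pool sizes by largest remainder, so the pool totals
    # floor(0.3 n) exactly while staying stratified
    labels = list(np.unique(coarse))
    counts = {lab: int(np.sum(coarse == lab)) for lab in labels}
    quota = {lab: counts[lab] * 0.30 for lab in labels}
    n_pool = {lab: int(np.floor(quota[lab])) for lab in labels}
    short = n_pool_total - sum(n_pool.values())
    for lab in sorted(labels, key=lambda b: quota[b] - np.floor(quota[b]),
                      reverse=True)[:short]:
        n_pool[lab] += 1

    test_parts, pool_lists = [], []
    for lab in labels:
        idx = participant_windows.index[coarse == lab].to_numpy()
        idx = idx[rng.permutation(len(idx))]
        pool_lists.append(list(idx[: n_pool[lab]]))
        test_parts.append(idx[n_pool[lab]:])
    # round-robin interleave so nested prefixes stay class-balanced
    pool: list = []
    while any(pool_lists):
        for lst in pool_lists:
            if lst:
                pool.append(lst.pop(0))
    test = np.concatenate(test_parts) if test_parts else np.array([], dtype=int)
    n_il = int(np.floor(len(pool) * (c / 0.30))) if c > 0 else 0
    return (
        pd.Index(np.sort(test).astype(int)),
        pd.Index(np.asarray(pool[:n_il], dtype=int)),
    )


def train_phase_one(
    train_features: pd.DataFrame,
    coarse: np.ndarray,
    spec: ClassifierSpec,
) -> FittedModel:
    """Fit the coarse left/supine/right model on the twelve features."""
    X = train_features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    return FittedModel(spec).fit(X, coarse)


def phase_one_filter(
    predictions: np.ndarray, truth: np.ndarray
) -> dict[str, np.ndarray]:
    """Boolean masks of correctly classified windows, one per coarse class.

    Incorrect windows are discarded outright; the supine subset is
    returned for bookkeeping but the supine class has fixed width and is
    not refined further.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must be aligned")
    correct = predictions == truth
    return {
        label: correct & (truth == label) for label in ("left", "supine", "right")
    }


def train_phase_two(
    side_features: pd.DataFrame,
    scheme: BinScheme,
    spec: ClassifierSpec,
) -> FittedModel | None:
    """Fit one side's bin model; ``None`` (with a warning) if < 2 bins present."""
    bins = side_bin_labels(side_features["truth_tpa"].to_numpy(), scheme)
    keep = bins != OUT_OF_RANGE
    if len(np.unique(bins[keep])) < 2:
        warnings.warn(
            f"phase-two training skipped: fewer than 2 {scheme.precision} "
            "bins represented",
            stacklevel=2,
        )
        return None
    X = side_features.loc[keep, list(FEATURE_NAMES)].to_numpy(dtype=float)
    return FittedModel(spec).fit(X, bins[keep])


def _matrix(df: pd.DataFrame) -> np.ndarray:
    return df[list(FEATURE_NAMES)].to_numpy(dtype=float)


def run_lopo(
    cohort_features: pd.DataFrame,
    specs: list[ClassifierSpec] | ClassifierSpec,
    il_config: ILConfig = ILConfig(),
    schemes: tuple[str, ...] = ("bins45", "bins30", "bins15"),
    supplemental: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full LOPO evaluation of both phases.

    ``cohort_features`` holds one row per window with the twelve features,
    ``truth_tpa`` and ``participant_id``. ``supplemental`` optionally adds
    coarse-label-only windows to every fold's Phase One training set.

    Phase One runs for every (backend, level); per backend, the level with
    the best mean F1 across participants is then carried into Phase Two
    for each side and bin scheme. Returns a tidy frame with one row per
    (participant, backend, il_level, phase, scheme, side) and columns
    ``f1``, ``accuracy``, ``n_test`` and a ``confusion`` dict.
    """
    if isinstance(specs, ClassifierSpec):
        specs = [specs]
    participants = sorted(cohort_features["participant_id"].unique())
    if len(participants) < 2:
        raise ValueError("LOPO needs >= 2 participants")
    df = cohort_features.reset_index(drop=True)
    coarse_all = coarse_labels(df["truth_tpa"].to_numpy())

    splits = {
        p: incremental_split(
            df[df["participant_id"] == p], c=0.30, seed=il_config.seed
        )
        for p in participants
    }  # (test_index, full pool) per participant; level subsets re-drawn below

    rows: list[dict] = []
    fold_models: dict[tuple[str, str, float], FittedModel] = {}
    for spec in specs:
        for p in participants:
            p_mask = df["participant_id"] == p
            test_idx, _ = splits[p]
            others_idx = df.index[~p_mask]
            for c in il_config.levels:
                _, il_idx = incremental_split(
                    df[p_mask], c=c, seed=il_config.seed
                )
                train_idx = pd.Index(
                    np.concatenate([others_idx.to_numpy(), il_idx.to_numpy()])
                    .astype(int)
                )
                # leakage guard: held-out test windows never train
                assert len(set(test_idx) & set(train_idx)) == 0
                X_train = df.loc[train_idx]
                y_train = coarse_all[train_idx]
                if supplemental is not None:
                    X_train = pd.concat(
                        [X_train, supplemental], ignore_index=True
                    )
                    y_train = np.concatenate(
                        [y_train, supplemental["coarse"].to_numpy()]
                    )
                model = train_phase_one(X_train, y_train, spec)
                fold_models[(spec.backend, p, c)] = model
                pred = model.predict(_matrix(df.loc[test_idx]))
                truth = coarse_all[test_idx]
                labels = ["left", "supine", "right"]
                rows.append(
                    dict(
                        participant=p,
                        backend=spec.backend,
                        il_level=c,
                        phase="one",
                        scheme="coarse3",
                        side="all",
                        f1=macro_f1(pred, truth, labels),
                        accuracy=accuracy_score_simple(pred, truth),
                        n_test=len(test_idx),
                        confusion=confusion_table(pred, truth, labels),
                    )
                )

    results = pd.DataFrame(rows)
    for spec in specs:
        sub = results[
            (results["backend"] == spec.backend) & (results["phase"] == "one")
        ]
        best_c = (
            sub.groupby("il_level")["f1"].mean().sort_values(ascending=False).index[0]
        )
        rows.extend(
            _run_phase_two(
                df, coarse_all, participants, splits, fold_models, spec,
                float(best_c), schemes, il_config,
            )
        )
    return pd.DataFrame(rows)


def _run_phase_two(
    df: pd.DataFrame,
    coarse_all: np.ndarray,
    participants: list[str],
    splits: dict,
    fold_models: dict,
    spec: ClassifierSpec,
    best_c: float,
    schemes: tuple[str, ...],
    il_config: ILConfig,
) -> list[dict]:
    rows: list[dict] = []
    for p in participants:
        model = fold_models[(spec.backend, p, best_c)]
        p_mask = df["participant_id"] == p
        test_idx, _ = splits[p]
        _, il_idx = incremental_split(df[p_mask], c=best_c, seed=il_config.seed)
        train_idx = pd.Index(
            np.concatenate([df.index[~p_mask].to_numpy(), il_idx.to_numpy()])
            .astype(int)
        )

        pred_train = model.predict(_matrix(df.loc[train_idx]))
        masks_train = phase_one_filter(pred_train, coarse_all[train_idx])
        pred_test = model.predict(_matrix(df.loc[test_idx]))
        masks_test = phase_one_filter(pred_test, coarse_all[test_idx])

        for side in ("left", "right"):
            train_side = df.loc[train_idx[masks_train[side]]]
            test_side = df.loc[test_idx[masks_test[side]]]
            for scheme_name in schemes:
                scheme = scheme_edges(scheme_name)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    m2 = train_phase_two(train_side, scheme, spec)
                if m2 is None or not len(test_side):
                    continue
                truth_bins = side_bin_labels(
                    test_side["truth_tpa"].to_numpy(), scheme
                )
                keep = truth_bins != OUT_OF_RANGE
                if not keep.any():
                    continue
                pred_bins = m2.predict(_matrix(test_side.loc[keep]))
                labels = sorted(set(truth_bins[keep]) | set(pred_bins))
                rows.append(
                    dict(
                        participant=p,
                        backend=spec.backend,
                        il_level=best_c,
                        phase="two",
                        scheme=scheme_name,
                        side=side,
                        f1=macro_f1(pred_bins, truth_bins[keep], labels),
                        accuracy=accuracy_score_simple(
                            pred_bins, truth_bins[keep]
                        ),
                        n_test=int(keep.sum()),
                        confusion=confusion_table(
                            pred_bins, truth_bins[keep], labels
                        ),
                    )
                )
    return rows
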