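"""Repeated leave-one-out gradient-boosting classification.

Two problems share one fold pipeline (train-fold standardization -> PCA ->
gradient boosting): ASD-vs-TD group classification on the 120
change-from-baseline features, and within-group four-emotion classification
(happy / fear / neutral / sad) on each clip's 20-index delta vector.  Each
leave-one-out pass is repeated over seeds; group results are summarized as
per-participant mean ASD probabilities, thresholded counts and the five
standard metrics, emotion results as mean confusion matrices, per-class hit
rates and pairwise cosine similarities of the rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .feature_pipeline import FEATURE_NAMES, PCModel, Standardizer
from .hrv_indices import INDEX_NAMES

__all__ = [
    "EMOTION_CLIPS",
    "GB_PARAMS",
    "MetricCounts",
    "Metrics",
    "loocv_group",
    "repeat_loocv",
    "classify_threshold",
    "compute_metrics",
    "sweep_n_pcs",
    "emotion_rows",
    "loocv_emotion",
    "repeat_loocv_emotion",
    "mean_confusion",
    "hit_rates",
    "cosine_similarity_matrix",
]

#: Emotion classes in their fixed reporting order.
EMOTION_CLIPS = ("happy", "fear", "neutral", "sad")

#: Gradient-boosting hyperparameters: 100 trees of depth 3, learning rate
#: 0.1, all features considered per split; row subsampling 0.9 so the
#: repetition seed has an effect.
GB_PARAMS = dict(
    n_estimators=100,
    max_depth=3,
    learning_rate=0.1,
    subsample=0.9,
    colsample_bytree=1.0,
)


def _make_classifier(seed: int, n_classes: int = 2) -> XGBClassifier:
    extra = {}
    if n_classes > 2:
        extra = dict(objective="multi:softprob", num_class=n_classes)
    return XGBClassifier(
        **GB_PARAMS,
        random_state=int(seed) % (2**31),
        n_jobs=1,
        verbosity=0,
        tree_method="exact",
        eval_metric="logloss",
        **extra,
    )


@dataclass(frozen=True)
class MetricCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float


@dataclass
class GroupLOOCVResult:
    """Output of :func:`repeat_loocv`."""

    prob_matrix: pd.DataFrame  # participants x repetitions, P(ASD)
    labels: pd.Series  # true group per participant
    per_rep_metrics: list  # Metrics per repetition (0.5 threshold)
    importances: np.ndarray  # mean per-PC importance over folds and reps

    @property
    def mean_probabilities(self) -> pd.Series:
        return self.prob_matrix.mean(axis=1)

    def metric_summary(self) -> pd.DataFrame:
        rows = pd.DataFrame([m.__dict__ for m in self.per_rep_metrics])
        return pd.DataFrame({"mean": rows.mean(), "sd": rows.std(ddof=1)})


def _fold_predict(
    train_X: pd.DataFrame,
    train_y: np.ndarray,
    test_X: pd.DataFrame,
    n_pcs: int,
    seed: int,
    n_classes: int,
    fold_safe: bool = True,
    prefit: tuple | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize + PCA (train rows only unless prefit) -> GB -> class
    probabilities for the test rows; also returns per-PC importances."""
    if prefit is not None:
        standardizer, pca = prefit
    else:
        standardizer = Standardizer().fit(train_X)
        pca = PCModel().fit(standardizer.transform(train_X))
    scores_train = pca.project(standardizer.transform(train_X), n_pcs)
    scores_test = pca.project(standardizer.transform(test_X), n_pcs)
    clf = _make_classifier(seed, n_classes)
    # balanced class weights: leave-one-out tilts every training fold
    # against the held-out participant's class, which an overfitting
    # booster converts into a systematic below-chance bias
    counts = np.bincount(train_y, minlength=n_classes)
    weights = len(train_y) / (n_classes * counts[train_y])
    clf.fit(scores_train, train_y, sample_weight=weights)
    probs = clf.predict_proba(scores_test)
    importances = np.asarray(clf.feature_importances_, dtype=float)
    if importances.sum() > 0:
        importances = importances / importances.sum()
    return probs, importances


def _check_group_table(features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    if "group" not in features.columns:
        raise ValueError("feature table must carry a 'group' column")
    X = features[list(FEATURE_NAMES)]
    y = (features["group"] == "ASD").to_numpy().astype(int)
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 participants per group")
    return X, y


def loocv_group(
    features: pd.DataFrame, n_pcs: int, seed: int, fold_safe: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """One leave-one-participant-out pass over the cohort.

    Returns ``(probabilities, importances)``: the ASD-class probability for
    each held-out participant, and the mean per-PC importance over folds.
    ``fold_safe=False`` fits the standardizer and PCA once on the full
    table before cross-validation (the optimistic variant).
    """
    X, y = _check_group_table(features)
    prefit = None
    if not fold_safe:
        standardizer = Standardizer().fit(X)
        prefit = (standardizer, PCModel().fit(standardizer.transform(X)))
    n = len(X)
    probs = np.empty(n)
    importances = np.zeros(n_pcs)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("degenerate fold: a training fold has one class")
        p, imp = _fold_predict(
            X.iloc[mask], y[mask], X.iloc[[i]], n_pcs, seed, 2, fold_safe, prefit
        )
        probs[i] = p[0, 1]
        importances += imp
    return probs, importances / n


def repeat_loocv(
    features: pd.DataFrame,
    n_pcs: int,
    n_reps: int = 20,
    master_seed: int = 0,
    fold_safe: bool = True,
) -> GroupLOOCVResult:
    """Repeat group LOOCV ``n_reps`` times with seeds ``master_seed + rep``."""
    X, y = _check_group_table(features)
    labels = features["group"]
    prob_cols = {}
    per_rep = []
    importances = np.zeros(n_pcs)
    for rep in range(n_reps):
        probs, imp = loocv_group(features, n_pcs, master_seed + rep, fold_safe)
        prob_cols[rep] = probs
        importances += imp
        per_rep.append(compute_metrics(classify_threshold(probs, y)))
    prob_matrix = pd.DataFrame(prob_cols, index=features.index)
    return GroupLOOCVResult(
        prob_matrix=prob_matrix,
        labels=labels,
        per_rep_metrics=per_rep,
        importances=importances / n_reps,
    )


def classify_threshold(
    probabilities: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
    threshold: float = 0.5,
) -> MetricCounts:
    """Tally TP/FP/TN/FN at a probability threshold.

    A probability exactly at the threshold classifies as ASD (the positive
    class).  ``labels`` may be 0/1 or "TD"/"ASD".
    """
    probs = np.asarray(probabilities, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels)
    if y.dtype.kind in "OU":
        y = (y == "ASD").astype(int)
    pred = (probs >= threshold).astype(int)
    return MetricCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def compute_metrics(counts: MetricCounts) -> Metrics:
    """Accuracy, sensitivity, specificity, precision, F1 from counts.

    A zero denominator yields NaN for that metric (flagged undefined).
    """

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    sens = ratio(counts.tp, counts.tp + counts.fn)
    spec = ratio(counts.tn, counts.tn + counts.fp)
    prec = ratio(counts.tp, counts.tp + counts.fp)
    if np.isnan(sens) or np.isnan(prec) or (sens + prec) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * sens * prec / (sens + prec)
    return Metrics(
        accuracy=ratio(counts.tp + counts.tn, counts.n),
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
    )


def sweep_n_pcs(
    features: pd.DataFrame,
    n_pcs_range: range = range(1, 11),
    n_reps: int = 20,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Mean accuracy/F1 per PC count; selects the best ``n``.

    Selection maximizes accuracy, then F1, then prefers the smaller ``n``.
    """
    rows = []
    for n_pcs in n_pcs_range:
        result = repeat_loocv(features, n_pcs, n_reps, master_seed)
        summary = result.metric_summary()["mean"]
        rows.append(
            {
                "n_pcs": n_pcs,
                "accuracy": summary["accuracy"],
                "f1": summary["f1"],
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["accuracy", "f1", "n_pcs"], ascending=[False, False, True], kind="stable"
    )
    return table, int(order.iloc[0]["n_pcs"])


# ---------------------------------------------------------------------------
# Emotion classification


def emotion_rows(features: pd.DataFrame, group: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-(participant, clip) 20-index delta vectors for one group.

    Returns ``(X, y)`` with 4 rows per participant (one per emotion clip)
    and clip labels encoded 0..3 in ``EMOTION_CLIPS`` order.
    """
    sub = features[features["group"] == group]
    if sub.empty:
        raise ValueError(f"no participants in group {group!r}")
    records, y = [], []
    for participant, row in sub.iterrows():
        for ci, clip in enumerate(EMOTION_CLIPS):
            vec = {idx: row[f"{idx}_{clip}"] for idx in INDEX_NAMES}
            if any(pd.isna(v) for v in vec.values()):
                raise ValueError(
                    f"missing clip features for {participant}/{clip}"
                )
            records.append(pd.Series(vec, name=f"{participant}_{clip}"))
            y.append(ci)
    return pd.DataFrame(records), np.asarray(y)


def loocv_emotion(
    X: pd.DataFrame, y: np.ndarray, n_pcs: int, seed: int
) -> pd.DataFrame:
    """Leave-one-datum-out four-emotion classification.

    Each of the ``4 x n_participants`` rows is held out once; the confusion
    matrix accumulates rows = true clip, columns = predicted clip, in
    ``EMOTION_CLIPS`` order.
    """
    n = len(X)
    cm = np.zeros((4, 4))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        probs, _ = _fold_predict(
            X.iloc[mask], y[mask], X.iloc[[i]], n_pcs, seed, n_classes=4
        )
        pred = int(np.argmax(probs[0]))
        cm[y[i], pred] += 1
    return pd.DataFrame(cm, index=list(EMOTION_CLIPS), columns=list(EMOTION_CLIPS))


def repeat_loocv_emotion(
    features: pd.DataFrame,
    group: str,
    n_pcs: int,
    n_reps: int = 20,
    master_seed: int = 0,
) -> list[pd.DataFrame]:
    """Emotion LOOCV repeated over seeds; returns the per-rep confusion
    matrices (defaults elsewhere: 6 PCs for TD, 1 for ASD)."""
    X, y = emotion_rows(features, group)
    return [
        loocv_emotion(X, y, n_pcs, master_seed + rep) for rep in range(n_reps)
    ]


def mean_confusion(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Entrywise mean of repeated confusion matrices (entries may be
    fractional)."""
    if not matrices:
        raise ValueError("no confusion matrices to average")
    return sum(matrices) / len(matrices)


def hit_rates(cm: pd.DataFrame) -> pd.Series:
    """Per-class hit rate in percent: diagonal over row sum x 100."""
    diag = pd.Series(np.diag(cm.to_numpy()), index=cm.index)
    return diag / cm.sum(axis=1) * 100.0


def cosine_similarity_matrix(cm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity between the emotions' predicted-class
    distributions (the confusion-matrix rows).

    ``CS_jk = sum_i N_ij N_ik / sqrt(sum_i N_ij^2 * sum_i N_ik^2)``; a zero
    row yields NaN entries for its pairs.
    """
    M = cm.to_numpy(dtype=float)
    norms = np.linalg.norm(M, axis=1)
    out = np.full((len(M), len(M)), np.nan)
    for j in range(len(M)):
        for k in range(len(M)):
            if norms[j] > 0 and norms[k] > 0:
                out[j, k] = float(M[j] @ M[k] / (norms[j] * norms[k]))
    return pd.DataFrame(out, index=cm.index, columns=cm.index)
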