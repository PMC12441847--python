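"""Model-building protocol: stratified 4:1:1 split, forward feature
selection capped at two features, logistic classification with the
score-sign decision rule, and evaluation metrics.

The protocol keeps the test subset strictly out of model development: the
standardization, the feature selection (which scores candidate features on
the pooled training + validation predictions) and the logistic fit all see
train/validation rows only.  The decision rule maps a linear score >= 0 to
the positive (treated / susceptible) class, with the boundary itself counted
as positive.

A weak L2 penalty is always on: single separable features make the
unregularized logistic likelihood diverge, and the decision boundary is what
matters here, not calibrated coefficients.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, precision_recall_curve
from sklearn.model_selection import StratifiedKFold

from .features import FeatureDescriptor, FeatureMatrix

logger = logging.getLogger(__name__)

SUBSETS = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    """Per-sample subset assignment under the stratified 4:1:1 protocol."""

    subsets: np.ndarray  # array of "train" / "validation" / "test"
    strata: list

    def indices(self, *subset: str) -> np.ndarray:
        return np.nonzero(np.isin(self.subsets, subset))[0]

    def counts(self, stratum=None) -> dict[str, int]:
        mask = (
            np.ones(len(self.subsets), bool)
            if stratum is None
            else np.array([s == stratum for s in self.strata])
        )
        return {s: int(np.sum((self.subsets == s) & mask)) for s in SUBSETS}


def stratified_split(
    labels: Sequence,
    strata: Sequence | None = None,
    seed: int = 0,
) -> SplitAssignment:
    """Assign samples to train/validation/test in a 4:1:1 ratio per stratum.

    Within a stratum of size n the counts are train = floor(4n/6),
    validation = floor(n/6), test = the remainder — the unique simple
    rounding consistent with the printed split tables (34 -> 22/5/7,
    24 -> 16/4/4, 38 -> 25/6/7, 36 -> 24/6/6).  Membership within a stratum
    is randomized by the seed; the counts are deterministic.
    """
    labels = list(labels)
    strata = list(strata) if strata is not None else list(labels)
    if len(strata) != len(labels):
        raise ValueError("strata and labels must align")
    rng = np.random.default_rng(seed)
    subsets = np.empty(len(labels), dtype=object)
    for stratum in sorted(set(strata), key=repr):
        idx = np.array([i for i, s in enumerate(strata) if s == stratum])
        n = idx.size
        if n < 3:
            warnings.warn(
                f"stratum {stratum!r} has only {n} samples; "
                "validation/test may be empty",
                stacklevel=2,
            )
        n_train = (4 * n) // 6
        n_val = n // 6
        perm = rng.permutation(idx)
        subsets[perm[:n_train]] = "train"
        subsets[perm[n_train : n_train + n_val]] = "validation"
        subsets[perm[n_train + n_val :]] = "test"
    return SplitAssignment(subsets=subsets, strata=strata)


@dataclass
class TrainedClassifier:
    """A <=2-feature logistic model on z-scored features.

    Standardization means/scales come from training rows only.  The score of
    a sample is the linear decision value; class = positive iff score >= 0.
    """

    selected: list[FeatureDescriptor]
    means: np.ndarray
    scales: np.ndarray
    coef: np.ndarray
    intercept: float
    positive_label: str = "positive"

    @property
    def selected_names(self) -> list[str]:
        return [d.name for d in self.selected]

    def _columns(self, features: FeatureMatrix) -> np.ndarray:
        names = features.names
        cols = []
        for want in self.selected_names:
            if want not in names:
                raise KeyError(f"feature {want!r} missing from matrix")
            cols.append(names.index(want))
        return features.values[:, cols]

    def scores(self, features: FeatureMatrix) -> np.ndarray:
        z = (self._columns(features) - self.means) / self.scales
        return z @ self.coef + self.intercept

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "selected": self.selected_names,
                    "means": self.means.tolist(),
                    "scales": self.scales.tolist(),
                    "coef": self.coef.tolist(),
                    "intercept": self.intercept,
                    "positive_label": self.positive_label,
                },
                indent=1,
            )
        )
        return path


def score_and_classify(
    model: TrainedClassifier, features: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Linear decision scores and the score-sign classification.

    A score of exactly 0 is classified positive (susceptible), matching the
    stated decision rule.
    """
    s = model.scores(features)
    return s, s >= 0


def _accuracy(scores: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((scores >= 0) == y))


def _fit_logistic(X: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    return LogisticRegression(C=C, solver="lbfgs", max_iter=1000).fit(X, y)


def _standardize(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X_train.mean(axis=0)
    scales = X_train.std(axis=0)
    scales[scales == 0] = 1.0
    return means, scales


def _greedy_select(
    X_fit: np.ndarray,
    y_fit: np.ndarray,
    X_pool: np.ndarray,
    y_pool: np.ndarray,
    names: list[str],
    max_features: int,
    C: float,
) -> list[int]:
    """Greedy forward selection: fit on (X_fit, y_fit), score accuracy on the
    pool; stop at the cap or when no addition improves accuracy."""
    usable = [i for i in range(X_fit.shape[1]) if X_fit[:, i].std() > 0]
    skipped = sorted(set(range(X_fit.shape[1])) - set(usable))
    if skipped:
        logger.info("skipping %d zero-variance features in training", len(skipped))
    selected: list[int] = []
    best_acc = -np.inf
    while len(selected) < max_features:
        best = None
        for i in usable:
            if i in selected:
                continue
            cols = selected + [i]
            means, scales = _standardize(X_fit[:, cols])
            clf = _fit_logistic((X_fit[:, cols] - means) / scales, y_fit, C)
            scores = ((X_pool[:, cols] - means) / scales) @ clf.coef_[0] + clf.intercept_[0]
            acc = _accuracy(scores, y_pool)
            # ties broken by the lowest canonical descriptor name
            if best is None or acc > best[0] + 1e-12 or (
                abs(acc - best[0]) <= 1e-12 and names[i] < names[best[1]]
            ):
                best = (acc, i)
        if best is None or (selected and best[0] <= best_acc + 1e-12):
            break
        best_acc = best[0]
        selected.append(best[1])
    if not selected:
        raise ValueError("no usable candidate features")
    return selected


def forward_select(
    features: FeatureMatrix,
    split: SplitAssignment,
    max_features: int = 2,
    C: float = 1000.0,
    positive_label: str = "positive",
    pool: str = "train+validation",
) -> list[FeatureDescriptor]:
    """Forward sequential feature selection with a logistic model.

    Candidate models are fit on the training rows; selection accuracy is
    scored on the combined training + validation pool (training rows via
    in-sample prediction).  Set ``pool="validation"`` to score on the
    validation rows alone.
    """
    y = np.array([lab == positive_label for lab in features.labels])
    tr = split.indices("train")
    pool_idx = (
        split.indices("train", "validation")
        if pool == "train+validation"
        else split.indices("validation")
    )
    if tr.size == 0 or pool_idx.size == 0:
        raise ValueError("train and selection pool must be non-empty")
    idx = _greedy_select(
        features.values[tr],
        y[tr],
        features.values[pool_idx],
        y[pool_idx],
        features.names,
        max_features,
        C,
    )
    return [features.descriptors[i] for i in idx]


def fit(
    features: FeatureMatrix,
    split: SplitAssignment,
    selected: list[FeatureDescriptor],
    C: float = 1000.0,
    positive_label: str = "positive",
) -> TrainedClassifier:
    """Fit the logistic model on training rows only; deterministic."""
    y = np.array([lab == positive_label for lab in features.labels])
    tr = split.indices("train")
    names = features.names
    cols = [names.index(d.name) for d in selected]
    X = features.values[np.ix_(tr, cols)]
    means, scales = _standardize(X)
    clf = _fit_logistic((X - means) / scales, y[tr], C)
    return TrainedClassifier(
        selected=list(selected),
        means=means,
        scales=scales,
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        positive_label=positive_label,
    )


@dataclass
class EvaluationReport:
    subset: str
    accuracy: float
    recall_positive: float
    recall_negative: float
    average_precision: float
    baseline_ap: float
    precision_curve: np.ndarray
    recall_curve: np.ndarray
    scores: np.ndarray
    predicted_positive: np.ndarray

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "accuracy": self.accuracy,
            "recall_positive": self.recall_positive,
            "recall_negative": self.recall_negative,
            "average_precision": self.average_precision,
            "baseline_ap": self.baseline_ap,
        }


def prevalence_baseline(n_pos: int, n_neg: int) -> float:
    """Expected average precision of a random classifier: the positive
    prevalence of the evaluated subset."""
    if n_pos + n_neg == 0:
        raise ValueError("empty subset")
    return n_pos / (n_pos + n_neg)


def evaluate(
    model: TrainedClassifier,
    features: FeatureMatrix,
    split: SplitAssignment,
    subset: str = "test",
) -> EvaluationReport:
    """Accuracy (proportion of correct classifications over all samples of
    the subset), per-class recall, and average precision with its
    random-classifier baseline."""
    idx = split.indices(subset)
    if idx.size == 0:
        raise ValueError(f"subset {subset!r} is empty")
    y = np.array([features.labels[i] == model.positive_label for i in idx])
    if not y.any():
        raise ValueError("average precision undefined: subset has no positives")
    sub = FeatureMatrix(
        values=features.values[idx],
        descriptors=features.descriptors,
        sample_ids=[features.sample_ids[i] for i in idx],
        labels=[features.labels[i] for i in idx],
        concentrations_uM=[features.concentrations_uM[i] for i in idx],
    )
    scores, predicted = score_and_classify(model, sub)
    acc = float(np.mean(predicted == y))
    recall_pos = float(np.mean(predicted[y]))
    recall_neg = float(np.mean(~predicted[~y])) if (~y).any() else float("nan")
    ap = float(average_precision_score(y, scores))
    precision, recall, _ = precision_recall_curve(y, scores)
    return EvaluationReport(
        subset=subset,
        accuracy=acc,
        recall_positive=recall_pos,
        recall_negative=recall_neg,
        average_precision=ap,
        baseline_ap=prevalence_baseline(int(y.sum()), int((~y).sum())),
        precision_curve=precision,
        recall_curve=recall,
        scores=scores,
        predicted_positive=predicted,
    )


@dataclass
class ExposureSweep:
    exposure_min: np.ndarray
    accuracies: np.ndarray
    plateau_min: float


def exposure_sweep(
    feature_builder: Callable[[float], FeatureMatrix],
    split: SplitAssignment,
    grid: Sequence[float],
    tolerance: float = 0.0,
    max_features: int = 2,
    n_folds: int = 6,
    seed: int = 0,
    C: float = 1000.0,
    positive_label: str = "positive",
) -> ExposureSweep:
    """Cross-validated accuracy as a function of drug-exposure duration.

    ``feature_builder(duration_min)`` must return a FeatureMatrix built from
    drug-phase windows ending within that exposure duration.  Selection and
    fitting run inside each fold on the pooled train+validation rows; the
    plateau is the first grid point that no later point exceeds by more than
    ``tolerance``.  Durations too short to yield features are skipped.
    """
    dev = split.indices("train", "validation")
    durations: list[float] = []
    accuracies: list[float] = []
    for duration in grid:
        try:
            fm = feature_builder(float(duration))
        except (ValueError, LookupError) as exc:
            logger.info("skipping exposure %s min: %s", duration, exc)
            continue
        y = np.array([fm.labels[i] == positive_label for i in dev])
        X = fm.values[dev]
        n_splits = min(n_folds, int(y.sum()), int((~y).sum()))
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        fold_accs = []
        for fit_idx, test_idx in cv.split(X, y):
            sel = _greedy_select(
                X[fit_idx], y[fit_idx], X[fit_idx], y[fit_idx],
                fm.names, max_features, C,
            )
            means, scales = _standardize(X[np.ix_(fit_idx, sel)])
            clf = _fit_logistic(
                (X[np.ix_(fit_idx, sel)] - means) / scales, y[fit_idx], C
            )
            s = ((X[np.ix_(test_idx, sel)] - means) / scales) @ clf.coef_[0] + clf.intercept_[0]
            fold_accs.append(_accuracy(s, y[test_idx]))
        durations.append(float(duration))
        accuracies.append(float(np.mean(fold_accs)))
    if not durations:
        raise ValueError("no grid duration yielded features")
    acc = np.array(accuracies)
    plateau = durations[-1]
    for i in range(len(durations)):
        later = acc[i + 1 :]
        if later.size == 0 or np.max(later) <= acc[i] + tolerance:
            plateau = durations[i]
            break
    return ExposureSweep(
        exposure_min=np.array(durations), accuracies=acc, plateau_min=plateau
    )
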