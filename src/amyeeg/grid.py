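"""The feature-set x classifier model grid with positive-class augmentation.

Eight standard classifiers are trained on each of the six selected feature
sets (48 models).  Because amyloid-positive subjects are outnumbered roughly
1:2.5, every positive *training* recording is split into its first and
second halves, features are recomputed on each half, and the two halves
enter training as separate samples (doubling the positive class).  Halves of
one subject always share a cross-validation fold; validation subjects are
never augmented.

Cells whose 5-fold cross-validated accuracy clears a predetermined gate are
refitted on all training samples and scored once on the untouched held-out
validation set; candidates are ranked by validation accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from amyeeg.recording import Recording
from amyeeg.select import FeatureSet

logger = logging.getLogger(__name__)

ALGORITHM_NAMES = (
    "svm", "logistic", "knn", "naive_bayes", "rf", "adaboost", "gbm", "xgb",
)

DEFAULT_GATE_THRESHOLD = 0.75


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the eight grid classifiers with library defaults."""
    if name == "svm":
        from sklearn.svm import SVC
        return SVC(random_state=seed)
    if name == "logistic":
        from sklearn.linear_model import LogisticRegression
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "knn":
        from sklearn.neighbors import KNeighborsClassifier
        return KNeighborsClassifier()
    if name == "naive_bayes":
        from sklearn.naive_bayes import GaussianNB
        return GaussianNB()
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if name == "adaboost":
        from sklearn.ensemble import AdaBoostClassifier
        return AdaBoostClassifier(random_state=seed)
    if name == "gbm":
        from sklearn.ensemble import GradientBoostingClassifier
        return GradientBoostingClassifier(random_state=seed)
    if name == "xgb":
        from xgboost import XGBClassifier
        # exact split enumeration: histogram binning can place thresholds at
        # a class cluster's edge instead of mid-gap, which matters at the
        # small sample sizes this grid runs at
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss", tree_method="exact")
    raise ValueError(f"unknown algorithm {name!r}; choose from {ALGORITHM_NAMES}")


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous class-1 scores in [0, 1].

    Predicted probability where available; otherwise the decision-function
    value min-max scaled over the scored samples.
    """
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    df = np.asarray(model.decision_function(X), dtype=float)
    lo, hi = df.min(), df.max()
    if hi - lo < 1e-12:
        return np.full(df.shape, 0.5)
    return (df - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Positive-class augmentation


@dataclass
class AugmentedSample:
    """One training sample: a whole recording or one half of a positive."""

    origin_id: str
    segment: int  # 0 = whole, 1 = first half, 2 = second half
    features: pd.Series
    label: int  # 1 = amyloid positive


def split_halves(rec: Recording) -> tuple[Recording, Recording]:
    """First and second half of a recording (0..T/2 and T/2..T)."""
    n = rec.n_samples
    half = n // 2
    first = rec.copy_with(data=rec.data[:, :half])
    second = rec.copy_with(data=rec.data[:, half:2 * half])
    return first, second


def augment_positives(
    train: Sequence[Recording],
    extractor: Callable[[Recording], pd.Series],
    min_half_duration: float = 8.0,
) -> list[AugmentedSample]:
    """Build the augmented training sample list.

    Every amyloid-positive recording yields two half-duration samples
    (features recomputed on each half, replacing the whole); every negative
    yields one whole-recording sample.  ``min_half_duration`` guards against
    halves too short to epoch (seconds).
    """
    samples: list[AugmentedSample] = []
    for rec in train:
        if rec.profile is None or rec.profile.amyloid not in ("POS", "NEG"):
            raise ValueError(f"recording {rec.subject_id} lacks a POS/NEG amyloid label")
        if rec.profile.amyloid == "POS":
            if rec.duration / 2.0 < min_half_duration:
                raise ValueError(
                    f"half of recording {rec.subject_id} ({rec.duration / 2:.1f} s) "
                    f"is shorter than {min_half_duration} s; cannot augment"
                )
            first, second = split_halves(rec)
            samples.append(AugmentedSample(rec.subject_id, 1, extractor(first), 1))
            samples.append(AugmentedSample(rec.subject_id, 2, extractor(second), 1))
        else:
            samples.append(AugmentedSample(rec.subject_id, 0, extractor(rec), 0))
    return samples


def samples_to_table(samples: Sequence[AugmentedSample]) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Stack augmented samples into (X, y, groups-by-origin-subject)."""
    X = pd.DataFrame([s.features for s in samples])
    X.index = [f"{s.origin_id}#{s.segment}" for s in samples]
    y = np.array([s.label for s in samples])
    groups = np.array([s.origin_id for s in samples])
    return X, y, groups


# ---------------------------------------------------------------------------
# The grid


@dataclass
class GridCell:
    set_method: str
    algorithm: str
    cv_accuracies: list[float]
    degenerate: bool = False

    @property
    def cv_mean(self) -> float:
        return float(np.mean(self.cv_accuracies))

    @property
    def cv_sd(self) -> float:
        return float(np.std(self.cv_accuracies, ddof=1))


@dataclass
class GridResult:
    cells: list[GridCell]
    fold_map: dict[str, int]  # origin subject_id -> fold index
    folds: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set": c.set_method, "algorithm": c.algorithm,
                    "cv_mean": c.cv_mean, "cv_sd": c.cv_sd,
                    "degenerate": c.degenerate,
                }
                for c in self.cells
            ]
        )


def _fit_cell(set_: FeatureSet, algorithm: str, X: pd.DataFrame, y: np.ndarray, seed: int):
    """Fit one cell's classifier on the full training table."""
    if len(set_) == 0:
        from sklearn.dummy import DummyClassifier
        model = DummyClassifier(strategy="most_frequent")
        model.fit(np.zeros((len(y), 1)), y)
        return model
    model = make_classifier(algorithm, seed)
    model.fit(X[set_.names].to_numpy(), y)
    return model


def _cell_predict(set_: FeatureSet, model, X: pd.DataFrame) -> np.ndarray:
    cols = X[set_.names].to_numpy() if len(set_) else np.zeros((len(X), 1))
    return np.asarray(model.predict(cols))


def run_grid(
    sets: Sequence[FeatureSet],
    algorithms: Sequence[str],
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> GridResult:
    """Cross-validate every (feature set, algorithm) cell.

    Folds are stratified by label and grouped by origin subject, so both
    halves of an augmented positive always land in the same fold.  Empty
    feature sets are scored with a majority-class dummy and flagged
    degenerate.  Deterministic under ``seed``.
    """
    from sklearn.metrics import accuracy_score
    from sklearn.model_selection import StratifiedGroupKFold

    y = np.asarray(y)
    for fs in sets:
        missing = [n for n in fs.names if n not in X.columns]
        if missing:
            raise ValueError(f"{fs.method} set names missing from table: {missing[:5]}")

    cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y, groups=groups))
    fold_map: dict[str, int] = {}
    for k, (_, test_idx) in enumerate(splits):
        for g in np.unique(groups[test_idx]):
            fold_map[str(g)] = k
    for _, test_idx in splits:
        if np.unique(y[test_idx]).size < 2:
            raise ValueError("a cross-validation fold contains a single class")

    cells = []
    for fs in sets:
        for alg in algorithms:
            accs = []
            for train_idx, test_idx in splits:
                model = _fit_cell(fs, alg, X.iloc[train_idx], y[train_idx], seed)
                pred = _cell_predict(fs, model, X.iloc[test_idx])
                accs.append(float(accuracy_score(y[test_idx], pred)))
            cells.append(GridCell(fs.method, alg, accs, degenerate=len(fs) == 0))
    return GridResult(cells=cells, fold_map=fold_map, folds=folds, seed=seed)


@dataclass
class CandidateModel:
    set_method: str
    algorithm: str
    cv_mean: float
    validation_accuracy: float
    validation_sensitivity: float
    validation_specificity: float
    n_features: int
    model: object
    feature_set: FeatureSet
    scores: np.ndarray  # validation class-1 scores
    predictions: np.ndarray


@dataclass
class FinalModelReport:
    threshold: float
    candidates: list[CandidateModel]  # ranked best first

    @property
    def best(self) -> CandidateModel:
        return self.candidates[0]


def gate_and_select(
    gr: GridResult,
    sets: Sequence[FeatureSet],
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_val: pd.DataFrame,
    y_val: np.ndarray,
    threshold: float = DEFAULT_GATE_THRESHOLD,
    seed: int = 0,
) -> FinalModelReport:
    """Refit gated cells on all training samples and rank on validation.

    Cells with CV accuracy > ``threshold`` are refitted and scored on the
    held-out validation table; candidates are ranked by validation accuracy,
    ties broken by higher sensitivity, then by smaller feature set.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    sets_by_method = {fs.method: fs for fs in sets}
    y_val = np.asarray(y_val)
    gated = [c for c in gr.cells if c.cv_mean > threshold]
    if not gated:
        best = max(c.cv_mean for c in gr.cells)
        raise RuntimeError(
            f"no grid cell exceeded the accuracy gate {threshold}; "
            f"best cross-validated accuracy was {best:.3f}"
        )
    candidates = []
    for cell in gated:
        fs = sets_by_method[cell.set_method]
        model = _fit_cell(fs, cell.algorithm, X_train, y_train, seed)
        pred = _cell_predict(fs, model, X_val)
        cols = X_val[fs.names].to_numpy() if len(fs) else np.zeros((len(X_val), 1))
        scores = predict_scores(model, cols)
        tp = int(np.sum((pred == 1) & (y_val == 1)))
        tn = int(np.sum((pred == 0) & (y_val == 0)))
        fn = int(np.sum((pred == 0) & (y_val == 1)))
        fp = int(np.sum((pred == 1) & (y_val == 0)))
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        candidates.append(
            CandidateModel(
                set_method=cell.set_method, algorithm=cell.algorithm,
                cv_mean=cell.cv_mean,
                validation_accuracy=(tp + tn) / len(y_val),
                validation_sensitivity=sens, validation_specificity=spec,
                n_features=len(fs), model=model, feature_set=fs,
                scores=scores, predictions=pred,
            )
        )
    candidates.sort(
        key=lambda c: (-c.validation_accuracy, -c.validation_sensitivity, c.n_features)
    )
    return FinalModelReport(threshold=threshold, candidates=candidates)


def tune_cutoff(
    scores: np.ndarray, labels: np.ndarray, target_sensitivity: float
) -> float:
    """Probability cut-off achieving the target sensitivity on given scores.

    Candidate cut-offs are the midpoints between adjacent distinct scores
    (plus one below the minimum and one above the maximum); among those
    reaching ``sensitivity >= target`` the one with the highest specificity
    is returned (largest cut-off on ties).  If the target is unreachable the
    minimum score is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.size != labels.size or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    distinct = np.unique(scores)
    cand = [distinct[0] - 1.0]
    cand += [0.5 * (a + b) for a, b in zip(distinct[:-1], distinct[1:])]
    cand += [distinct[-1] + 1.0]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    best = None
    for c in cand:
        pred = scores >= c
        sens = np.sum(pred & labels) / n_pos if n_pos else 1.0
        spec = np.sum(~pred & ~labels) / n_neg if n_neg else 1.0
        if sens >= target_sensitivity:
            key = (spec, c)
            if best is None or key > best[0]:
                best = (key, c)
    if best is None:
        logger.warning("target sensitivity %.2f unreachable; cut-off set to min score",
                       target_sensitivity)
        return float(scores.min())
    return float(best[1])
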