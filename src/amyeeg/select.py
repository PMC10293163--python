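"""Multi-method feature selection with cognitive-impairment confound exclusion.

Six candidate feature sets are produced for the amyloid contrast — Welch
t-test, Mann-Whitney rank-sum, elastic-net logistic regression, random-forest
importance, gradient boosting and XGBoost — then any feature that the same
six methods also flag for the SCD-vs-MCI contrast (cognitive impairment,
ignoring amyloid) is removed, leaving amyloid-specific candidates.

A normality-gated correlation diagnostic is provided alongside: Pearson when
both vectors pass a normality screen (Shapiro-Wilk or Kolmogorov-Smirnov),
Spearman otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

UNIVARIATE_METHODS = ("ttest", "mannwhitney")
MODEL_METHODS = ("elasticnet", "rf", "gbm", "xgb")
ALL_METHODS = UNIVARIATE_METHODS + MODEL_METHODS

DEFAULT_ALPHA = 0.05
DEFAULT_K = 50


@dataclass
class FeatureSet:
    """An ordered list of selected feature names with their scores."""

    method: str
    names: list[str]
    scores: list[float]  # p-values (univariate) or importances/|coefs|
    rule: str  # e.g. "p<alpha" or "top-k"
    rule_value: float

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError(f"duplicate feature names in {self.method} set")
        if len(self.names) != len(self.scores):
            raise ValueError("names and scores must align")

    def __len__(self) -> int:
        return len(self.names)

    def without(self, excluded: set[str]) -> "FeatureSet":
        keep = [(n, s) for n, s in zip(self.names, self.scores) if n not in excluded]
        return FeatureSet(
            method=self.method,
            names=[n for n, _ in keep],
            scores=[s for _, s in keep],
            rule=self.rule,
            rule_value=self.rule_value,
        )


def _check_labels(y: np.ndarray, min_per_class: int = 3) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if counts.min() < min_per_class:
        raise ValueError(f"each class needs >= {min_per_class} members, got {counts.tolist()}")


def rank_univariate(
    X: pd.DataFrame,
    y: np.ndarray,
    method: str = "ttest",
    alpha: float = DEFAULT_ALPHA,
    k_max: int = DEFAULT_K,
) -> FeatureSet:
    """Univariate per-feature screening of the group contrast.

    ``ttest`` uses the Welch two-sample statistic; ``mannwhitney`` the
    two-sided rank-sum.  Features with p < ``alpha`` are kept, ordered by
    ascending p and capped at ``k_max``.  Constant features get p = 1.
    """
    if method not in UNIVARIATE_METHODS:
        raise ValueError(f"method must be one of {UNIVARIATE_METHODS}, got {method!r}")
    y = np.asarray(y).astype(bool)
    _check_labels(y)
    a = X.loc[y].to_numpy()
    b = X.loc[~y].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "ttest":
            res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        else:
            res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    constant = (X.to_numpy().std(axis=0) == 0) | ~np.isfinite(p)
    p[constant] = 1.0
    order = np.lexsort((np.arange(p.size), p))  # stable: p asc, column order
    chosen = [i for i in order if p[i] < alpha][:k_max]
    return FeatureSet(
        method=method,
        names=[X.columns[i] for i in chosen],
        scores=[float(p[i]) for i in chosen],
        rule="p<alpha,k_max", rule_value=alpha,
    )


def _elasticnet_importance(X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    """|coefficients| of an L1/L2 logistic fit, C picked by internal 3-fold CV."""
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        best_c, best_acc = 1.0, -np.inf
        for c in (0.01, 0.1, 1.0):
            clf = LogisticRegression(
                solver="saga", l1_ratio=0.5, C=c, max_iter=2000, random_state=seed,
            )
            cv = StratifiedKFold(3, shuffle=True, random_state=seed)
            acc = cross_val_score(clf, X, y, cv=cv).mean()
            if acc > best_acc:
                best_acc, best_c = acc, c
        clf = LogisticRegression(
            solver="saga", l1_ratio=0.5, C=best_c, max_iter=5000, random_state=seed,
        )
        clf.fit(X, y)
    return np.abs(clf.coef_[0])


def rank_model_based(
    X: pd.DataFrame,
    y: np.ndarray,
    method: str = "rf",
    k: int = DEFAULT_K,
    seed: int = 0,
) -> FeatureSet:
    """Model-based feature ranking, top-k by importance (nonzero only).

    ``elasticnet``: nonzero |coefficients| of a penalized logistic fit;
    ``rf``/``gbm``: impurity importances; ``xgb``: gain importances.
    Deterministic under ``seed``.
    """
    if method not in MODEL_METHODS:
        raise ValueError(f"method must be one of {MODEL_METHODS}, got {method!r}")
    y = np.asarray(y).astype(int)
    _check_labels(y)
    Xv = X.to_numpy()
    if method == "elasticnet":
        imp = _elasticnet_importance(Xv, y, seed)
    elif method == "rf":
        from sklearn.ensemble import RandomForestClassifier

        model = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        imp = model.fit(Xv, y).feature_importances_
    elif method == "gbm":
        from sklearn.ensemble import GradientBoostingClassifier

        model = GradientBoostingClassifier(random_state=seed)
        imp = model.fit(Xv, y).feature_importances_
    else:
        from xgboost import XGBClassifier

        model = XGBClassifier(
            n_estimators=100, random_state=seed, n_jobs=1, verbosity=0,
            eval_metric="logloss", importance_type="gain",
        )
        imp = model.fit(Xv, y).feature_importances_
    imp = np.nan_to_num(np.asarray(imp, dtype=float))
    order = np.lexsort((np.arange(imp.size), -imp))
    chosen = [i for i in order if imp[i] > 0][:k]
    return FeatureSet(
        method=method,
        names=[X.columns[i] for i in chosen],
        scores=[float(imp[i]) for i in chosen],
        rule="top-k", rule_value=k,
    )


@dataclass
class CorrelationReport:
    """Outcome of the normality-gated correlation between two vectors."""

    method: str  # pearson | spearman
    statistic: float
    pvalue: float
    normal_a: bool
    normal_b: bool
    detail: dict = field(default_factory=dict)


def _is_normal(v: np.ndarray, alpha: float = 0.05) -> tuple[bool, dict]:
    """Shapiro-Wilk and KS screens; 'normal' if either test's p > alpha."""
    sw = stats.shapiro(v)
    z = (v - v.mean()) / v.std(ddof=1)
    ks = stats.kstest(z, "norm")
    return (sw.pvalue > alpha or ks.pvalue > alpha), {
        "shapiro_p": float(sw.pvalue), "ks_p": float(ks.pvalue)
    }


def normality_gated_correlation(a, b) -> CorrelationReport:
    """Pearson if both vectors pass the normality screen, Spearman otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 4:
        raise ValueError("a and b must be equal-length 1-D vectors of length >= 4")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    normal_a, det_a = _is_normal(a)
    normal_b, det_b = _is_normal(b)
    if normal_a and normal_b:
        r = stats.pearsonr(a, b)
        method = "pearson"
    else:
        r = stats.spearmanr(a, b)
        method = "spearman"
    return CorrelationReport(
        method=method, statistic=float(r.statistic), pvalue=float(r.pvalue),
        normal_a=normal_a, normal_b=normal_b,
        detail={"a": det_a, "b": det_b},
    )


def select_all(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> list[FeatureSet]:
    """Run all six selection methods on one binary contrast."""
    sets = [rank_univariate(X, y, m, alpha=alpha, k_max=k) for m in UNIVARIATE_METHODS]
    sets += [rank_model_based(X, y, m, k=k, seed=seed) for m in MODEL_METHODS]
    return sets


def exclude_cognitive_confounds(
    amyloid_sets: list[FeatureSet],
    X: pd.DataFrame,
    diagnosis_labels: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_K,
    seed: int = 0,
) -> tuple[list[FeatureSet], set[str]]:
    """Remove cognitive-impairment-associated features from the amyloid sets.

    The same six selection methods are run on the SCD-vs-MCI contrast
    (ignoring amyloid); the union of those sets is the confound set, and
    each amyloid set is returned with confound members removed, order
    preserved.  Returns ``(filtered_sets, confound_set)``.
    """
    diagnosis_labels = np.asarray(diagnosis_labels)
    uniq = set(np.unique(diagnosis_labels))
    if not {"SCD", "MCI"} <= uniq:
        raise ValueError(f"diagnosis labels must cover both SCD and MCI, got {sorted(uniq)}")
    y_diag = diagnosis_labels == "MCI"
    confound_sets = select_all(X, y_diag, alpha=alpha, k=k, seed=seed)
    confounds: set[str] = set()
    for fs in confound_sets:
        confounds.update(fs.names)
    filtered = []
    for fs in amyloid_sets:
        out = fs.without(confounds)
        removed = sorted(set(fs.names) - set(out.names))
        if removed:
            logger.info("confound exclusion removed %d feature(s) from %s set: %s",
                        len(removed), fs.method, removed[:10])
        if len(fs) and not len(out):
            logger.warning("confound exclusion emptied the %s set entirely", fs.method)
        filtered.append(out)
    return filtered, confounds
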