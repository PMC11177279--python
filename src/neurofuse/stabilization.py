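"""Feature stabilization and site-bias auditing.

Features are ranked by random-forest Gini importance (mean decrease in
impurity), then eliminated from the bottom of the ranking while a 10-fold
cross-validated forest accuracy curve is recorded. The retained set is the
top-N prefix of the ranking, where N is the smallest feature count whose
mean accuracy is within a tolerance of the curve's maximum (default
tolerance: one standard error of the best point), i.e. using more features
no longer improves the classifier.

The site audit trains a forest to predict the *acquisition site* from the
features: if residual site effects survive harmonization, site is decodable
above chance. Significance is assessed by a site-label permutation test on
the cross-validated accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict, cross_val_score

from ._rng import subseed
from .errors import ConfigError
from .table import FeatureTable

logger = logging.getLogger(__name__)

__all__ = ["FeatureRanking", "EliminationCurve", "SelectionResult",
           "SiteAuditReport", "gini_rank", "elimination_curve",
           "choose_optimal_n", "select_features", "site_audit"]


@dataclass
class FeatureRanking:
    """Features ordered by non-increasing Gini importance (ties alphabetical)."""

    features: list[str]
    importances: pd.Series
    seed: int

    def __post_init__(self) -> None:
        imp = self.importances[self.features].to_numpy()
        if np.any(imp < 0):
            raise ConfigError("negative importances")
        if np.any(np.diff(imp) > 1e-12):
            raise ConfigError("ranking not sorted by importance")


@dataclass
class EliminationCurve:
    """(feature count, mean CV accuracy, SD) along the elimination path."""

    counts: list[int]
    mean_accuracy: list[float]
    sd_accuracy: list[float]
    rankings: list[FeatureRanking] = field(default_factory=list, repr=False)
    log_scale_hint: bool = True

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.counts, self.counts[1:])):
            raise ConfigError("elimination counts must be strictly decreasing")
        for a in self.mean_accuracy:
            if not (0.0 <= a <= 1.0):
                raise ConfigError("accuracy outside [0,1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_features": self.counts, "mean_acc": self.mean_accuracy,
                             "sd_acc": self.sd_accuracy})


@dataclass
class SelectionResult:
    """Chosen optimal N and the retained top-N prefix of the ranking."""

    n_optimal: int
    selected: list[str]
    max_accuracy: float
    accuracy_at_n: float
    tolerance: float


@dataclass
class SiteAuditReport:
    """Site-decodability audit: CV accuracy, confusion matrix, permutation p."""

    confusion: pd.DataFrame
    accuracy: float
    p_value: float
    n_permutations: int
    chance_level: float
    biased: bool


def _forest(seed: int, n_estimators: int = 100) -> RandomForestClassifier:
    # paper-style default hyper-parameters, seeded, single-thread for determinism
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)


def gini_rank(table: FeatureTable | pd.DataFrame, labels: pd.Series | np.ndarray,
              seed: int = 0, n_estimators: int = 100) -> FeatureRanking:
    """Rank features by mean Gini impurity decrease in a default random forest."""
    X = table.values if isinstance(table, FeatureTable) else table
    y = np.asarray(labels)
    if X.shape[1] == 0:
        raise ConfigError("empty feature table")
    if len(np.unique(y)) < 2:
        raise ConfigError("need at least 2 classes")
    if X.isna().any().any():
        raise ConfigError("missing values present; impute first")
    rf = _forest(seed, n_estimators)
    rf.fit(X.to_numpy(), y)
    imp = pd.Series(rf.feature_importances_, index=X.columns)
    order = sorted(X.columns, key=lambda f: (-imp[f], f))
    return FeatureRanking(features=order, importances=imp, seed=seed)


def default_schedule(n_features: int, block_frac: float = 0.10,
                     fine_below: int = 100) -> list[int]:
    """Elimination schedule: 10% blocks above ``fine_below``, then 1-at-a-time."""
    counts = [n_features]
    c = n_features
    while c > 1:
        if c > fine_below:
            c = max(fine_below, c - max(1, int(round(block_frac * c))))
        else:
            c -= 1
        counts.append(c)
    return counts


def geometric_schedule(n_features: int, factor: float = 0.75) -> list[int]:
    """Coarser geometric schedule for large feature sets."""
    counts = [n_features]
    c = n_features
    while c > 1:
        c = min(c - 1, max(1, int(np.floor(c * factor))))
        counts.append(c)
    return counts


def elimination_curve(table: FeatureTable | pd.DataFrame,
                      labels: pd.Series | np.ndarray, k: int = 10, seed: int = 0,
                      schedule: list[int] | None = None,
                      refit_ranking: bool = True,
                      n_estimators: int = 100) -> EliminationCurve:
    """Backward elimination by Gini rank with a k-fold CV accuracy curve.

    At each retained feature count the forest's stratified k-fold CV accuracy
    (mean ± SD over folds) is recorded, and the lowest-ranked features are
    dropped to reach the next count. ``refit_ranking=False`` freezes the
    initial ranking instead of recomputing it after each elimination step.
    """
    X = (table.values if isinstance(table, FeatureTable) else table).copy()
    y = np.asarray(labels)
    classes, counts_per_class = np.unique(y, return_counts=True)
    if counts_per_class.min() < k:
        raise ConfigError(f"k={k} exceeds smallest class count {counts_per_class.min()}")
    if schedule is None:
        schedule = default_schedule(X.shape[1])
    if schedule[0] != X.shape[1]:
        raise ConfigError("schedule must start at the full feature count")

    ranking = gini_rank(X, y, seed=seed, n_estimators=n_estimators)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=subseed(seed, "elim-cv"))
    counts, means, sds, rankings = [], [], [], []
    current = list(ranking.features)
    for target in schedule:
        current = current[:target]
        Xc = X[current]
        if refit_ranking and target < len(ranking.features) and target > 1:
            ranking = gini_rank(Xc, y, seed=seed, n_estimators=n_estimators)
            current = list(ranking.features)
            Xc = X[current]
        scores = cross_val_score(_forest(subseed(seed, "elim-rf", target), n_estimators),
                                 Xc.to_numpy(), y, cv=cv, scoring="accuracy")
        counts.append(target)
        means.append(float(scores.mean()))
        sds.append(float(scores.std(ddof=0)))
        rankings.append(ranking)
    return EliminationCurve(counts=counts, mean_accuracy=means, sd_accuracy=sds,
                            rankings=rankings)


def choose_optimal_n(curve: EliminationCurve, tolerance: float | None = None,
                     k: int = 10) -> SelectionResult:
    """Smallest N whose mean accuracy is within ``tolerance`` of the maximum.

    Default tolerance is one standard error (SD/√k) of the best point.
    The selected set is the top-N prefix of the ranking recorded at that
    point of the path.
    """
    if not curve.counts:
        raise ConfigError("empty elimination curve")
    accs = np.asarray(curve.mean_accuracy)
    best_idx = int(np.argmax(accs))
    max_acc = float(accs[best_idx])
    if tolerance is None:
        tolerance = float(curve.sd_accuracy[best_idx]) / np.sqrt(k)
    # smallest count ⇒ scan from the tail of the (strictly decreasing) path.
    # A point qualifies when it is strictly inside the tolerance band of the
    # maximum (or attains the maximum itself); accuracy exactly at the band
    # edge does not count as "failing to improve".
    chosen = best_idx
    for i in range(len(curve.counts) - 1, -1, -1):
        if accs[i] > max_acc - tolerance or accs[i] == max_acc:
            chosen = i
            break
    n_opt = curve.counts[chosen]
    ranking = curve.rankings[chosen] if curve.rankings else None
    selected = ranking.features[:n_opt] if ranking is not None else []
    return SelectionResult(n_optimal=n_opt, selected=selected, max_accuracy=max_acc,
                           accuracy_at_n=float(accs[chosen]), tolerance=float(tolerance))


def select_features(table: FeatureTable | pd.DataFrame, labels, k: int = 10,
                    seed: int = 0, schedule: list[int] | None = None,
                    tolerance: float | None = None,
                    refit_ranking: bool = True,
                    n_estimators: int = 100) -> tuple[SelectionResult, EliminationCurve]:
    """Convenience wrapper: elimination curve + optimal-N choice."""
    curve = elimination_curve(table, labels, k=k, seed=seed, schedule=schedule,
                              refit_ranking=refit_ranking, n_estimators=n_estimators)
    return choose_optimal_n(curve, tolerance=tolerance, k=k), curve


def site_audit(table: FeatureTable | pd.DataFrame, sites: pd.Series | np.ndarray,
               n_perm: int = 1000, seed: int = 0, k: int = 10,
               n_estimators: int = 100, alpha: float = 0.05) -> SiteAuditReport:
    """Residual site-bias audit with a label-permutation significance test.

    A default random forest predicts the acquisition site under stratified
    k-fold CV; the pooled out-of-fold confusion matrix and accuracy are
    reported with ``p = (1 + #{perm acc >= observed}) / (1 + n_perm)`` under
    site-label permutation. ``biased`` flags p < alpha.
    """
    X = (table.values if isinstance(table, FeatureTable) else table).to_numpy()
    y = np.asarray(sites)
    site_names = np.unique(y)
    if len(site_names) < 2:
        raise ConfigError("need at least 2 sites")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: coarse p-value resolution", stacklevel=2)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=subseed(seed, "audit-cv"))
    pred = cross_val_predict(_forest(subseed(seed, "audit-rf"), n_estimators), X, y, cv=cv)
    # observed statistic must match the permuted one (mean of fold accuracies)
    obs = cross_val_score(_forest(subseed(seed, "audit-rf"), n_estimators),
                          X, y, cv=cv, scoring="accuracy")
    acc = float(obs.mean())
    conf = pd.DataFrame(confusion_matrix(y, pred, labels=site_names),
                        index=site_names, columns=site_names)

    rng = np.random.Generator(np.random.PCG64(subseed(seed, "audit-perm")))
    exceed = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        scores = cross_val_score(_forest(subseed(seed, "audit-rf"), n_estimators),
                                 X, yp, cv=cv, scoring="accuracy")
        if scores.mean() >= acc:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    _, counts = np.unique(y, return_counts=True)
    chance = float(counts.max() / counts.sum())
    return SiteAuditReport(confusion=conf, accuracy=acc, p_value=float(p),
                           n_permutations=n_perm, chance_level=chance,
                           biased=p < alpha)
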