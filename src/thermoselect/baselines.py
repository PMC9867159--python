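"""Classical feature rankers: L1-logistic (LASSO) and random forest.

Both emit the same :class:`~thermoselect.selectors.RankingResult` contract as
the dropout selectors so that rank aggregation and evaluation treat all four
methods interchangeably. Scores are averaged over cross-validation training
folds when folds are supplied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .preprocess import CVSplit, feature_columns, zscore_apply, zscore_fit
from .selectors import RankingResult


def _as_xy(table: pd.DataFrame, labels: np.ndarray | None):
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)
    if labels is None:
        from .preprocess import LABEL_COL

        labels = table[LABEL_COL].to_numpy()
    return X, np.asarray(labels).astype(int), cols


def _fold_train_indices(folds: CVSplit | None, n: int):
    if folds is None:
        yield np.arange(n)
    else:
        for train, _ in folds.iter_folds():
            yield train


def lasso_rank(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    folds: CVSplit | None = None,
    Cs: int | list[float] = 10,
    seed: int = 0,
) -> RankingResult:
    """L1-penalized logistic ranking: relevance = |coefficient|, fold-averaged.

    The penalty strength is chosen per training fold by internal
    cross-validation. Features are standardized with training-fold statistics
    before fitting. The keep mask marks features whose averaged |coefficient|
    is nonzero; the complement is the LASSO sparse rate.
    """
    X, y, cols = _as_xy(table, labels)
    coefs = []
    for train in _fold_train_indices(folds, len(y)):
        mu, sd = zscore_fit(X[train])
        Xs = zscore_apply(X[train], mu, sd)
        model = LogisticRegressionCV(
            Cs=Cs,
            cv=3,
            penalty="l1",
            solver="liblinear",
            scoring="roc_auc",
            random_state=seed,
            max_iter=2000,
        )
        model.fit(Xs, y[train])
        coefs.append(np.abs(model.coef_.ravel()))
    score = np.mean(coefs, axis=0)
    return RankingResult(
        method="lasso",
        feature_names=list(cols),
        scores=score,
        keep_mask=score > 1e-10,
    )


def unpenalized_logistic_rank(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
) -> RankingResult:
    """|coefficient| ranking of a plain logistic fit (no penalty); the
    zero-penalty limit that LASSO rankings approach as C grows."""
    X, y, cols = _as_xy(table, labels)
    mu, sd = zscore_fit(X)
    model = LogisticRegression(penalty=None, max_iter=5000)
    model.fit(zscore_apply(X, mu, sd), y)
    score = np.abs(model.coef_.ravel())
    return RankingResult(
        method="logistic",
        feature_names=list(cols),
        scores=score,
        keep_mask=np.ones(len(cols), dtype=bool),
    )


def rf_rank(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    folds: CVSplit | None = None,
    n_trees: int = 500,
    seed: int = 0,
    top_k: int = 10,
) -> RankingResult:
    """Random-forest impurity-importance ranking, fold-averaged.

    The forest is a dense method (no intrinsic sparsity); the keep mask marks
    the ``top_k`` features by averaged importance.
    """
    X, y, cols = _as_xy(table, labels)
    importances = []
    for f, train in enumerate(_fold_train_indices(folds, len(y))):
        model = RandomForestClassifier(n_estimators=n_trees, random_state=seed + f, n_jobs=1)
        model.fit(X[train], y[train])
        importances.append(model.feature_importances_)
    score = np.mean(importances, axis=0)
    order = sorted(range(len(cols)), key=lambda i: (-score[i], cols[i]))
    keep = np.zeros(len(cols), dtype=bool)
    keep[order[: min(top_k, len(cols))]] = True
    return RankingResult(method="random_forest", feature_names=list(cols), scores=score, keep_mask=keep)
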