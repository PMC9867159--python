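"""Dataset fusion, SMOTE class balancing, correlation pruning and CV folds.

The intended order mirrors the study design this package supports: several
feature tables with identical schemas are row-concatenated, the minority
class is oversampled to parity with SMOTE, redundant features (|Pearson r|
above a threshold) are pruned keeping the more predictive member of each
correlated pair, and stratified five-fold splits are built for everything
downstream.

SMOTE is implemented directly on scikit-learn's nearest-neighbour index:
each synthetic row is a convex combination of a minority row and one of its
k nearest minority neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

LABEL_COL = "label"
PROVENANCE_COL = "provenance"
_META_COLS = (LABEL_COL, PROVENANCE_COL)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table: everything except label/provenance."""
    return [c for c in table.columns if c not in _META_COLS]


# ---------------------------------------------------------------------------
# fusion


def fuse_datasets(
    tables: list[pd.DataFrame],
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Row-concatenate feature tables with identical feature-name sets.

    No value transformation is applied. A provenance column records which
    input table each row came from.
    """
    if not tables:
        raise ValueError("no tables to fuse")
    if names is None:
        names = [f"dataset_{i}" for i in range(len(tables))]
    ref = set(feature_columns(tables[0]))
    for i, t in enumerate(tables[1:], start=1):
        other = set(feature_columns(t))
        if other != ref:
            missing = sorted(ref - other)
            extra = sorted(other - ref)
            raise ValueError(
                f"feature name mismatch in table {i}: missing {missing}, unexpected {extra}"
            )
    parts = []
    for t, name in zip(tables, names):
        part = t.copy()
        if PROVENANCE_COL not in part.columns:
            part[PROVENANCE_COL] = name
        parts.append(part)
    return pd.concat(parts, axis=0, ignore_index=True)


# ---------------------------------------------------------------------------
# SMOTE


def smote_balance(
    table: pd.DataFrame,
    k_neighbors: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Oversample the minority class to parity by SMOTE interpolation.

    Each synthetic sample is x_i + u·(x_j − x_i) with u ~ U(0, 1), where x_j
    is one of the k nearest minority neighbours of minority row x_i.
    Original rows are preserved verbatim; synthetic rows carry provenance
    ``"smote"``. An already balanced table is returned unchanged (copy).
    """
    if LABEL_COL not in table.columns:
        raise ValueError(f"table lacks a {LABEL_COL!r} column")
    counts = table[LABEL_COL].value_counts()
    if len(counts) != 2:
        raise ValueError(f"smote_balance requires exactly two classes, got {len(counts)}")
    if counts.iloc[0] == counts.iloc[1]:
        return table.copy()
    minority_label = counts.idxmin()
    n_needed = int(counts.max() - counts.min())
    cols = feature_columns(table)
    X_min = table.loc[table[LABEL_COL] == minority_label, cols].to_numpy(dtype=float)
    if X_min.shape[0] <= k_neighbors:
        raise ValueError(
            f"minority class has {X_min.shape[0]} samples, need > k_neighbors={k_neighbors}; "
            "use a smaller k"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, X_min.shape[0], size=n_needed)
    pick = rng.integers(1, k_neighbors + 1, size=n_needed)
    gap = rng.uniform(0.0, 1.0, size=n_needed)
    neigh = idx[base, pick]
    X_new = X_min[base] + gap[:, None] * (X_min[neigh] - X_min[base])
    new = pd.DataFrame(X_new, columns=cols)
    new[LABEL_COL] = minority_label
    if PROVENANCE_COL in table.columns:
        new[PROVENANCE_COL] = "smote"
    return pd.concat([table, new], axis=0, ignore_index=True)


# ---------------------------------------------------------------------------
# correlation pruning


def _single_feature_auc(x: np.ndarray, y: np.ndarray) -> float:
    """AUCROC of a single-feature logistic model (fit on the full data)."""
    model = LogisticRegression(max_iter=1000)
    model.fit(x.reshape(-1, 1), y)
    return float(roc_auc_score(y, model.predict_proba(x.reshape(-1, 1))[:, 1]))


def prune_correlated(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    r_threshold: float = 0.95,
) -> tuple[pd.DataFrame, list[dict]]:
    """Greedy removal of highly correlated features.

    Every feature is scored by the AUCROC of a single-feature logistic
    model; features are visited in descending score (ties broken by name)
    and any unvisited feature with |Pearson r| > ``r_threshold`` against an
    already kept one is dropped. Constant features are dropped with a
    warning (their Pearson correlation is undefined).

    Returns the pruned table and a report listing, for each dropped
    feature, its keeper and the correlation that triggered the drop.
    """
    if labels is None:
        if LABEL_COL not in table.columns:
            raise ValueError("labels not given and table lacks a label column")
        labels = table[LABEL_COL].to_numpy()
    labels = np.asarray(labels)
    if min(np.bincount(pd.factorize(labels)[0])) < 2:
        raise ValueError("need at least 2 samples per class")
    cols = feature_columns(table)
    X = table[cols].to_numpy(dtype=float)

    report: list[dict] = []
    sds = X.std(axis=0)
    usable = []
    for j, c in enumerate(cols):
        if sds[j] < 1e-12:
            warnings.warn(f"constant feature {c!r} dropped (Pearson r undefined)")
            report.append({"dropped": c, "keeper": None, "r": None, "reason": "constant"})
        else:
            usable.append(j)

    scores = {cols[j]: _single_feature_auc(X[:, j], labels) for j in usable}
    # descending AUCROC, ties by name, so pruning is column-order invariant
    order = sorted(usable, key=lambda j: (-scores[cols[j]], cols[j]))

    Xs = (X[:, usable] - X[:, usable].mean(axis=0)) / sds[usable]
    corr = (Xs.T @ Xs) / X.shape[0]
    pos = {j: k for k, j in enumerate(usable)}

    kept: list[int] = []
    for j in order:
        r_vs_kept = [(abs(corr[pos[j], pos[k]]), k) for k in kept]
        hits = [(r, k) for r, k in r_vs_kept if r > r_threshold]
        if hits:
            r, keeper = max(hits)
            report.append(
                {"dropped": cols[j], "keeper": cols[keeper], "r": float(r), "reason": "correlated"}
            )
        else:
            kept.append(j)

    kept_names = [c for c in cols if c in {cols[j] for j in kept}]  # original order
    meta = [c for c in table.columns if c in _META_COLS]
    return table[kept_names + meta].copy(), report


# ---------------------------------------------------------------------------
# cross-validation folds


@dataclass
class CVSplit:
    """Stratified fold assignment per sample."""

    fold: np.ndarray  # fold index per sample
    n_folds: int
    seed: int

    def __post_init__(self):
        self.fold = np.asarray(self.fold, dtype=int)

    def iter_folds(self):
        """Yield (train_indices, test_indices) per fold."""
        for f in range(self.n_folds):
            test = np.nonzero(self.fold == f)[0]
            train = np.nonzero(self.fold != f)[0]
            yield train, test

    def to_json(self) -> dict:
        return {"fold": self.fold.tolist(), "n_folds": self.n_folds, "seed": self.seed}

    @classmethod
    def from_json(cls, d: dict) -> "CVSplit":
        return cls(fold=np.array(d["fold"]), n_folds=d["n_folds"], seed=d["seed"])


def make_folds(labels: np.ndarray, n_folds: int = 5, seed: int = 0) -> CVSplit:
    """Stratified n-fold partition of the samples."""
    labels = np.asarray(labels)
    if min(np.bincount(pd.factorize(labels)[0])) < n_folds:
        raise ValueError(f"fewer than {n_folds} samples in a class; cannot stratify")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold = np.empty(len(labels), dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold[test] = f
    return CVSplit(fold=fold, n_folds=n_folds, seed=seed)


# ---------------------------------------------------------------------------
# standardization helper (train-fold statistics)


def zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and SDs for standardization; constant columns get SD 1."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def zscore_apply(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mu) / sd
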