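"""Fixed-configuration SVM harness for scoring feature subsets.

An RBF-kernel SVM with frozen hyperparameters (γ = 0.1, C = 1) is trained on
each cross-validation training fold, with features standardized by
training-fold statistics, and binary metrics (positive class = diabetic) are
averaged over folds. Freezing the classifier makes the comparison about the
*features*, not about per-subset hyperparameter luck. A randomized-search
optimizer is provided for the optimized-reference configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.svm import SVC

from .preprocess import CVSplit, feature_columns, zscore_apply, zscore_fit

#: diabetic encoded as 1 is the positive class for precision/recall/F1
POSITIVE_LABEL = 1


@dataclass
class MetricsReport:
    """Per-fold and aggregated binary classification metrics."""

    accuracy: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray

    def __post_init__(self):
        for name in ("accuracy", "precision", "recall", "f1"):
            v = np.asarray(getattr(self, name), dtype=float)
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{name} outside [0, 1]")
            setattr(self, name, v)

    def mean(self, metric: str) -> float:
        return float(np.mean(getattr(self, metric)))

    def sd(self, metric: str) -> float:
        v = getattr(self, metric)
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.sd(m)) for m in ("accuracy", "precision", "recall", "f1")}

    def to_json(self) -> dict:
        return {
            "per_fold": {
                m: getattr(self, m).tolist() for m in ("accuracy", "precision", "recall", "f1")
            },
            "mean": {m: self.mean(m) for m in ("accuracy", "precision", "recall", "f1")},
            "sd": {m: self.sd(m) for m in ("accuracy", "precision", "recall", "f1")},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))


def svm_evaluate(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    folds: CVSplit | None = None,
    features: list[str] | None = None,
    gamma: float = 0.1,
    C: float = 1.0,
    n_folds: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Score a feature subset with the fixed RBF-SVM over CV folds."""
    if labels is None:
        from .preprocess import LABEL_COL

        if LABEL_COL not in table.columns:
            raise ValueError("labels not given and table lacks a label column")
        labels = table[LABEL_COL].to_numpy()
    y = np.asarray(labels).astype(int)
    cols = features if features is not None else feature_columns(table)
    if not cols:
        raise ValueError("empty feature subset")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"features absent from table: {missing}")
    X = table[cols].to_numpy(dtype=float)
    if folds is None:
        from .preprocess import make_folds

        folds = make_folds(y, n_folds=n_folds, seed=seed)

    acc, prec, rec, f1 = [], [], [], []
    for train, test in folds.iter_folds():
        if len(np.unique(y[train])) < 2:
            raise ValueError("single-class training fold")
        mu, sd = zscore_fit(X[train])
        clf = SVC(kernel="rbf", gamma=gamma, C=C)
        clf.fit(zscore_apply(X[train], mu, sd), y[train])
        pred = clf.predict(zscore_apply(X[test], mu, sd))
        acc.append(accuracy_score(y[test], pred))
        prec.append(precision_score(y[test], pred, pos_label=POSITIVE_LABEL, zero_division=0))
        rec.append(recall_score(y[test], pred, pos_label=POSITIVE_LABEL, zero_division=0))
        f1.append(f1_score(y[test], pred, pos_label=POSITIVE_LABEL, zero_division=0))
    return MetricsReport(accuracy=acc, precision=prec, recall=rec, f1=f1)


def svm_optimize(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    folds: CVSplit | None = None,
    features: list[str] | None = None,
    n_iter: int = 200,
    seed: int = 0,
    gamma_range: tuple[float, float] = (1e-4, 1e1),
    C_range: tuple[float, float] = (1e-2, 1e2),
) -> tuple[float, float, MetricsReport]:
    """Random log-uniform search over (γ, C); returns the best CV-F1 config.

    Candidates are drawn sequentially from one seeded stream, so increasing
    ``n_iter`` only appends draws and can never worsen the best score.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_iter):
        gamma = 10 ** rng.uniform(np.log10(gamma_range[0]), np.log10(gamma_range[1]))
        C = 10 ** rng.uniform(np.log10(C_range[0]), np.log10(C_range[1]))
        report = svm_evaluate(table, labels, folds, features, gamma=gamma, C=C)
        score = report.mean("f1")
        if best is None or score > best[0]:
            best = (score, gamma, C, report)
    _, gamma, C, report = best
    return float(gamma), float(C), report


# ---------------------------------------------------------------------------
# prior-work reference feature list

#: the ten prior-work features, already remapped onto this schema's NTR
#: classes by temperature range (original C_k = [27+k, 28+k) °C maps to this
#: table's C_{k+4}; the two remaps the source states explicitly are
#: NTR_C4→NTR_C8 and NTR_C3→NTR_C7, and the same offset is applied to
#: NTR_C2→NTR_C6 and NTR_C1→NTR_C5). "highest" is the highest foot
#: temperature.
REFERENCE_FEATURES = (
    "TCI",
    "NTR_C8",
    "NTR_C7",
    "MPA_mean",
    "LPA_mean",
    "LPA_ET",
    "LCA_mean",
    "highest",
    "NTR_C6",
    "NTR_C5",
)


def reference_feature_list() -> list[str]:
    """The ten prior-work comparison features (schema-remapped names)."""
    return list(REFERENCE_FEATURES)


def resolve_reference_features(table: pd.DataFrame) -> pd.DataFrame:
    """Materialize the reference features by averaging the two feet.

    The prior work did not separate feet, so each reference feature is the
    mean of this schema's ``L_<name>`` and ``R_<name>`` columns. Raises a
    KeyError naming the first missing column.
    """
    out = {}
    for name in REFERENCE_FEATURES:
        lcol, rcol = f"L_{name}", f"R_{name}"
        for c in (lcol, rcol):
            if c not in table.columns:
                raise KeyError(f"reference feature {name!r} needs column {c!r}, absent from table")
        out[name] = (table[lcol].to_numpy(float) + table[rcol].to_numpy(float)) / 2.0
    return pd.DataFrame(out, index=table.index)
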