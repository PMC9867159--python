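"""End-to-end pipeline: generate → extract → preprocess → rank → coincide → evaluate.

All randomness fans out from one root seed via numpy SeedSequence spawning;
every artifact written carries the root seed and a hash of the configuration
that produced it, so reruns with the same config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines, evaluation, preprocess, synthetic
from .aggregate import coincidence
from .features import extract_feature_table
from .selectors import TrainConfig, rank_and_sparsify, train_selector

SELECTOR_METHODS = ("concrete", "variational", "lasso", "random_forest")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, YAML round-trippable."""

    seed: int = 0
    outdir: str = "run"
    # generation
    n_healthy: int = 50
    n_diabetic: int = 50
    grid_height: int = 80
    grid_width: int = 48
    # preprocessing
    smote: bool = True
    smote_k: int = 5
    prune_r: float = 0.95
    n_folds: int = 5
    # selector training
    epochs: int = 500
    batch_size: int = 32
    tau: float = 0.9
    hidden: tuple[int, ...] = (64, 32)
    # evaluation
    svm_gamma: float = 0.1
    svm_C: float = 1.0
    top_k: int = 10
    methods: tuple[str, ...] = SELECTOR_METHODS

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["hidden"] = list(self.hidden)
        d["methods"] = list(self.methods)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["hidden"] = tuple(d.get("hidden", (64, 32)))
        d["methods"] = tuple(d.get("methods", SELECTOR_METHODS))
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir")  # the hash identifies the scientific configuration
        d["hidden"] = list(self.hidden)
        d["methods"] = list(self.methods)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _stage_seeds(root: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(root)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stages: generate synthetic subjects, extract thermal features, balance
    and prune, rank features with all configured methods, aggregate the
    cross-method coincidence, and score each method's top-k subset with the
    fixed SVM.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(outdir / "config.yaml")
    seeds = _stage_seeds(config.seed, 6)
    stamp = {"seed": config.seed, "config_hash": chash}
    manifest: dict = {"stages": [], **stamp}

    def _done(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})

    # 1. generate
    geometry = synthetic.FootGeometry(config.grid_height, config.grid_width)
    subjects = synthetic.make_cohort(
        config.n_healthy, config.n_diabetic, geometry=geometry, seed=seeds[0]
    )
    _done("generate", n_subjects=len(subjects))

    # 2. extract
    table = extract_feature_table(subjects)
    table.to_csv(outdir / "features.csv", index_label="subject_id")
    _done("extract", n_features=table.shape[1] - 1, file="features.csv")

    # 3. preprocess
    counts = table["label"].value_counts()
    if config.smote:
        table = preprocess.smote_balance(table, k_neighbors=config.smote_k, seed=seeds[1])
    elif counts.iloc[0] != counts.iloc[-1]:
        warnings.warn(
            f"class imbalance left in place ({dict(counts)}); "
            "evaluation metrics may be biased"
        )
        manifest["imbalance_warning"] = {int(k): int(v) for k, v in counts.items()}
    pruned, prune_report = preprocess.prune_correlated(table, r_threshold=config.prune_r)
    pruned.to_csv(outdir / "pruned.csv", index=False)
    (outdir / "prune_report.json").write_text(json.dumps({**stamp, "dropped": prune_report}, indent=2))
    labels = pruned["label"].to_numpy()
    folds = preprocess.make_folds(labels, n_folds=config.n_folds, seed=seeds[2])
    (outdir / "folds.json").write_text(json.dumps({**stamp, **folds.to_json()}))
    _done(
        "preprocess",
        n_samples=int(len(pruned)),
        n_features=int(pruned.shape[1] - 2),
        n_dropped=len(prune_report),
    )

    # 4. rank with each method
    rankings = {}
    tcfg = TrainConfig(
        epochs=config.epochs,
        batch_size=config.batch_size,
        tau=config.tau,
        hidden=config.hidden,
        seed=seeds[3],
    )
    feat_only = pruned.drop(columns=[c for c in ("provenance",) if c in pruned.columns])
    for method in config.methods:
        if method in ("concrete", "variational"):
            state, _log = train_selector(feat_only, labels, kind=method, config=tcfg)
            ranking = rank_and_sparsify(state, tau=config.tau)
        elif method == "lasso":
            ranking = baselines.lasso_rank(feat_only, labels, folds, seed=seeds[3])
        elif method == "random_forest":
            ranking = baselines.rf_rank(feat_only, labels, folds, seed=seeds[3], top_k=config.top_k)
        else:
            raise ValueError(f"unknown ranking method {method!r}")
        ranking.save(outdir / f"ranking_{method}.json", extra=stamp)
        rankings[method] = ranking
    _done("rank", methods=list(rankings))

    # 5. coincidence
    report = coincidence(list(rankings.values()))
    report_d = report.to_json()
    report_d.update(stamp)
    (outdir / "coincidence.json").write_text(json.dumps(report_d, indent=2))
    _done("coincide", n_features=len(report.features))

    # 6. evaluate each method's top-k (and the coincidence set) with the fixed SVM
    metrics = {}
    for method, ranking in rankings.items():
        rep = evaluation.svm_evaluate(
            feat_only,
            labels,
            folds,
            features=ranking.top(config.top_k),
            gamma=config.svm_gamma,
            C=config.svm_C,
        )
        metrics[method] = rep.to_json()
    if report.features:
        rep = evaluation.svm_evaluate(
            feat_only,
            labels,
            folds,
            features=report.features[: config.top_k],
            gamma=config.svm_gamma,
            C=config.svm_C,
        )
        metrics["coincidence"] = rep.to_json()
    (outdir / "metrics.json").write_text(json.dumps({**stamp, "metrics": metrics}, indent=2))
    _done("evaluate", methods=list(metrics))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
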