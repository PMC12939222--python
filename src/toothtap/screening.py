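"""Screening-level classification and robustness experiments.

A 200-tree random forest on the 13 time-averaged MFCCs separates the three
screening classes (healthy / enamel caries / dentin caries).  The protocol
is deliberately plain: stratified 80/20 split, fixed default
hyperparameters, no tuning, and the whole generate-featurize-train-evaluate
cycle repeated over five master seeds with freshly generated data per seed.
The robustness sweep reruns that protocol over a grid of measurement-noise
and parameter-variability conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import train_test_split

from .dataset import DatasetBundle, GenerationConfig, generate_dataset


@dataclass(frozen=True)
class ClassifierConfig:
    """Randomized-tree ensemble settings, fixed a priori (no tuning)."""

    n_trees: int = 200
    criterion: str = "gini"
    max_depth: int | None = None
    max_features: str = "sqrt"
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees <= 0:
            raise ValueError("n_trees must be positive")


@dataclass(frozen=True)
class ExperimentResult:
    """Metrics of a single train/test run."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    classes: tuple[str, ...]
    per_class: pd.DataFrame  # precision/recall/f1/support indexed by class
    confusion: np.ndarray  # rows = true class, in `classes` order
    importances: np.ndarray  # 13 impurity-based importances, sum to 1
    seed: int = 0


@dataclass(frozen=True)
class AggregateResult:
    """Mean +/- SD over repeated seeded runs."""

    runs: tuple[ExperimentResult, ...]
    mean_accuracy: float
    sd_accuracy: float
    mean_macro_f1: float
    sd_macro_f1: float


@dataclass(frozen=True)
class RobustnessCondition:
    label: str
    sigma: float
    variability_pct: float


#: the default noise x variability grid of the robustness sweep
DEFAULT_CONDITIONS: tuple[RobustnessCondition, ...] = (
    RobustnessCondition("baseline", 0.01, 0.05),
    RobustnessCondition("more_noise", 0.03, 0.05),
    RobustnessCondition("more_variability", 0.01, 0.10),
    RobustnessCondition("noise_plus_variability", 0.03, 0.10),
)


def train_classifier(
    features: np.ndarray, labels: np.ndarray, cfg: ClassifierConfig = ClassifierConfig()
) -> RandomForestClassifier:
    """Fit the randomized-tree ensemble on the given training data."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training labels are degenerate (single class)")
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion=cfg.criterion,
        max_depth=cfg.max_depth,
        max_features=cfg.max_features,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(np.asarray(features), labels)
    return model


def evaluate(
    model: RandomForestClassifier, features: np.ndarray, labels: np.ndarray, seed: int = 0
) -> ExperimentResult:
    """Test-set metrics: accuracy, per-class and macro P/R/F1, confusion, importances."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty test set")
    unknown = set(labels) - set(model.classes_)
    if unknown:
        raise ValueError(f"test labels unseen in training: {sorted(unknown)}")
    classes = tuple(model.classes_)
    pred = model.predict(np.asarray(features))
    acc = accuracy_score(labels, pred)
    prec, rec, f1, support = precision_recall_fscore_support(
        labels, pred, labels=list(classes), zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=list(classes),
    )
    cm = confusion_matrix(labels, pred, labels=list(classes))
    return ExperimentResult(
        accuracy=float(acc),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        classes=classes,
        per_class=per_class,
        confusion=cm,
        importances=np.asarray(model.feature_importances_),
        seed=seed,
    )


def split_dataset(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified (by default) train/test split at the configured fraction."""
    labels = np.asarray(labels)
    return train_test_split(
        np.asarray(features),
        labels,
        train_size=cfg.train_fraction,
        stratify=labels if cfg.stratified else None,
        random_state=cfg.seed,
        shuffle=True,
    )


def run_single_experiment(
    features: np.ndarray, labels: np.ndarray, cfg: ClassifierConfig = ClassifierConfig()
) -> ExperimentResult:
    """Split, train and evaluate once; deterministic given the config seed."""
    X_train, X_test, y_train, y_test = split_dataset(features, labels, cfg)
    model = train_classifier(X_train, y_train, cfg)
    return evaluate(model, X_test, y_test, seed=cfg.seed)


def _aggregate(runs: list[ExperimentResult]) -> AggregateResult:
    acc = np.array([r.accuracy for r in runs])
    f1 = np.array([r.macro_f1 for r in runs])
    ddof = 1 if len(runs) > 1 else 0
    return AggregateResult(
        runs=tuple(runs),
        mean_accuracy=float(acc.mean()),
        sd_accuracy=float(acc.std(ddof=ddof)),
        mean_macro_f1=float(f1.mean()),
        sd_macro_f1=float(f1.std(ddof=ddof)),
    )


def repeated_experiment(
    gen_cfg: GenerationConfig,
    clf_cfg: ClassifierConfig = ClassifierConfig(),
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
) -> AggregateResult:
    """Full generate -> featurize -> split -> train -> evaluate cycle per seed.

    Each seed generates a fresh dataset (no resampling from a shared pool)
    and drives the split and the forest initialization, so runs are fully
    independent and reproducible.
    """
    if len(seeds) < 1:
        raise ValueError("need at least one seed")
    runs = []
    for seed in seeds:
        g = replace(gen_cfg, master_seed=int(seed), output_dir=None)
        c = replace(clf_cfg, seed=int(seed))
        try:
            bundle = generate_dataset(g)
            runs.append(
                run_single_experiment(bundle.feature_matrix, bundle.labels, c)
            )
        except Exception as exc:
            raise RuntimeError(f"run with seed {seed} failed: {exc}") from exc
    return _aggregate(runs)


def robustness_sweep(
    conditions: tuple[RobustnessCondition, ...] = DEFAULT_CONDITIONS,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    gen_cfg: GenerationConfig = GenerationConfig(),
    clf_cfg: ClassifierConfig = ClassifierConfig(),
) -> tuple[dict[str, AggregateResult], pd.DataFrame]:
    """Repeat the seeded experiment for each noise/variability condition.

    Returns the per-condition aggregates and a summary table with one row
    per condition (mean +/- SD of accuracy and macro-F1).
    """
    if not conditions:
        raise ValueError("empty condition grid")
    results: dict[str, AggregateResult] = {}
    rows = []
    for cond in conditions:
        g = replace(gen_cfg, sigma=cond.sigma, variability_pct=cond.variability_pct)
        agg = repeated_experiment(g, clf_cfg, seeds)
        results[cond.label] = agg
        rows.append(
            {
                "condition": cond.label,
                "noise_sd": cond.sigma,
                "variability_pct": cond.variability_pct,
                "accuracy_mean": agg.mean_accuracy,
                "accuracy_sd": agg.sd_accuracy,
                "macro_f1_mean": agg.mean_macro_f1,
                "macro_f1_sd": agg.sd_macro_f1,
            }
        )
    return results, pd.DataFrame(rows)


def feature_importance_report(result: ExperimentResult) -> list[tuple[int, float]]:
    """Coefficient indices ranked by normalized impurity importance."""
    imp = np.asarray(result.importances, dtype=float)
    total = imp.sum()
    if total <= 0:
        raise ValueError("importances are all zero")
    imp = imp / total
    order = np.argsort(imp)[::-1]
    return [(int(i), float(imp[i])) for i in order]


def render_sweep_table(table: pd.DataFrame) -> str:
    """Markdown rendering of the robustness summary table."""
    lines = [
        "| Condition | Noise SD | Parameter variability | Accuracy (mean ± SD) | Macro-F1 (mean ± SD) |",
        "|---|---|---|---|---|",
    ]
    for row in table.itertuples():
        lines.append(
            f"| {row.condition} | {row.noise_sd:g} | ±{row.variability_pct:.0%} "
            f"| {row.accuracy_mean:.3f} ± {row.accuracy_sd:.3f} "
            f"| {row.macro_f1_mean:.3f} ± {row.macro_f1_sd:.3f} |"
        )
    return "\n".join(lines)
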