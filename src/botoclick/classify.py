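"""Random-forest classification of lineages from click parameters.

The protocol: stratified 80/20 train/test split, a 500-tree bagged forest
of unpruned classification trees with out-of-bag (OOB) validation, mean
decrease accuracy (MDA) and Gini variable importance for the three
frequency-domain predictors (Fp, BW3, BW10), a row-percentage confusion
matrix, per-class balanced accuracy, and one-vs-rest ROC/AUC with the
AUC >= 0.7 acceptability rule.

The ensemble itself is scikit-learn's RandomForestClassifier (bootstrap
bagging, fully grown trees, OOB score).  The evaluation statistics —
balanced accuracy, the Mann-Whitney AUC — are computed here from their
formulas.  AUC scores are the forests' vote fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "ForestConfig",
    "ForestReport",
    "FEATURES",
    "split",
    "fit_forest",
    "evaluate",
    "roc_auc",
    "mann_whitney_auc",
    "run_classification",
    "AUC_ACCEPTABLE",
]

#: Predictors used for classification (frequency-domain parameters only).
FEATURES = ["fp_khz", "bw3_khz", "bw10_khz"]
#: Acceptability rule for one-vs-rest AUC.
AUC_ACCEPTABLE = 0.7


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    train_fraction: float = 0.8
    features_per_split: int | str = "sqrt"  # floor(sqrt(p)) = 1 for p = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ForestReport:
    classes: list[str]
    confusion_pct: pd.DataFrame  # rows = true class, row-normalized %
    overall_accuracy: float  # %
    balanced_accuracy: dict[str, float]  # % per class
    oob_error: float  # %
    importance: pd.DataFrame  # per feature: mda, gini
    auc: dict[str, float]  # one-vs-rest AUC per class (NaN if undefined)
    auc_acceptable: dict[str, bool]

    def to_json_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion_pct": self.confusion_pct.round(4).to_dict(),
            "overall_accuracy_pct": round(self.overall_accuracy, 4),
            "balanced_accuracy_pct": {
                k: round(v, 4) for k, v in self.balanced_accuracy.items()
            },
            "oob_error_pct": round(self.oob_error, 4),
            "importance": self.importance.round(6).to_dict(),
            "auc": {k: (None if np.isnan(v) else round(v, 4)) for k, v in self.auc.items()},
            "auc_acceptable": self.auc_acceptable,
        }


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in FEATURES + ["label"] if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    if table[FEATURES].isna().any().any():
        raise ValueError("feature table contains missing values")
    if table["label"].nunique() < 2:
        raise ValueError("classification needs at least two classes")


def split(table: pd.DataFrame, cfg: ForestConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded stratified split into train/test by ``train_fraction``."""
    _check_table(table)
    if (table["label"].value_counts() < 2).any():
        raise ValueError("every class needs at least 2 rows for a stratified split")
    train, test = train_test_split(
        table,
        train_size=cfg.train_fraction,
        stratify=table["label"],
        random_state=cfg.seed,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def fit_forest(train: pd.DataFrame, cfg: ForestConfig) -> RandomForestClassifier:
    """Fit the 500-tree bagged forest of unpruned trees with OOB scoring."""
    _check_table(train)
    model = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.features_per_split,
        bootstrap=True,
        oob_score=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    model.fit(train[FEATURES].to_numpy(), train["label"].to_numpy())
    return model


def mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """One-vs-rest AUC by the rank (Mann-Whitney) formulation with midranks.

    AUC = (sum of positive ranks - n_pos(n_pos+1)/2) / (n_pos * n_neg).
    All-tied scores give exactly 0.5.
    """
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = ss.rankdata(scores)
    r_pos = float(ranks[positive].sum())
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _balanced_accuracy(counts: np.ndarray, i: int) -> float:
    """(sensitivity + specificity)/2 for class i of a count confusion matrix."""
    tp = counts[i, i]
    fn = counts[i].sum() - tp
    fp = counts[:, i].sum() - tp
    tn = counts.sum() - tp - fn - fp
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return (sens + spec) / 2.0


def evaluate(
    model: RandomForestClassifier,
    test: pd.DataFrame,
    mda_repeats: int = 10,
    seed: int = 0,
) -> ForestReport:
    """Held-out evaluation: confusion %, accuracies, importances, AUC."""
    _check_table(test)
    classes = list(model.classes_)
    unseen = set(test["label"]) - set(classes)
    if unseen:
        raise ValueError(f"test set contains classes unseen in training: {unseen}")
    X = test[FEATURES].to_numpy()
    y = test["label"].to_numpy()
    pred = model.predict(X)

    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y, pred):
        counts[idx[t], idx[p]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        row_pct = 100.0 * counts / counts.sum(axis=1, keepdims=True)
    confusion = pd.DataFrame(row_pct, index=classes, columns=classes)

    overall = 100.0 * float((pred == y).mean())
    balanced = {c: 100.0 * _balanced_accuracy(counts, i) for i, c in enumerate(classes)}
    oob_error = 100.0 * (1.0 - float(model.oob_score_))

    # mean decrease accuracy: per-feature permutation on the held-out set
    rng = np.random.default_rng(seed)
    base_acc = float((pred == y).mean())
    mda = []
    for j in range(len(FEATURES)):
        drops = []
        for _ in range(mda_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(base_acc - float((model.predict(Xp) == y).mean()))
        mda.append(float(np.mean(drops)))
    importance = pd.DataFrame(
        {"mda": mda, "gini": model.feature_importances_}, index=FEATURES
    )

    proba = model.predict_proba(X)  # vote fractions across trees
    auc = {
        c: mann_whitney_auc(proba[:, i], y == c) for i, c in enumerate(classes)
    }
    acceptable = {c: bool(v >= AUC_ACCEPTABLE) if np.isfinite(v) else False
                  for c, v in auc.items()}
    return ForestReport(
        classes=classes,
        confusion_pct=confusion,
        overall_accuracy=overall,
        balanced_accuracy=balanced,
        oob_error=oob_error,
        importance=importance,
        auc=auc,
        auc_acceptable=acceptable,
    )


def roc_auc(model: RandomForestClassifier, test: pd.DataFrame) -> dict[str, float]:
    """Per-class one-vs-rest AUC from forest vote fractions."""
    _check_table(test)
    X = test[FEATURES].to_numpy()
    y = test["label"].to_numpy()
    proba = model.predict_proba(X)
    return {
        c: mann_whitney_auc(proba[:, i], y == c)
        for i, c in enumerate(model.classes_)
    }


def run_classification(
    table: pd.DataFrame, cfg: ForestConfig = ForestConfig()
) -> ForestReport:
    """Split, fit and evaluate in one call (the pipeline entry point).

    ``table`` needs a ``label`` column plus the three feature columns;
    the same routine serves both the lineage run (Ia/Igg/Igh) and the
    cluster run (Ispp1..k + Igg).
    """
    train, test = split(table, cfg)
    model = fit_forest(train, cfg)
    return evaluate(model, test, seed=cfg.seed)
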