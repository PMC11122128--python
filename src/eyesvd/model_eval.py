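"""Attentional-state classifier training and evaluation.

Stratified 5-fold cross-validation with random undersampling of the
majority class in the training folds only (test folds keep the natural
class imbalance).  Two model kinds:

* ``xgboost`` — gradient-boosted trees, 1000 boosting rounds, AUC
  evaluation metric on a held-out 20% stratified slice of the training
  fold (no early stopping by default), single-threaded for reproducibility.
* ``mlp`` — a two-layer perceptron: 12 ReLU hidden units and one sigmoid
  output, binary cross-entropy loss, Adam optimizer.

Reported metrics follow the per-class convention: "accuracy" of a class is
its recall (row-normalized confusion diagonal), F1 treats that class as
positive, and AUROC is threshold-free on the predicted class-1
probabilities.  Everything is mean ± SD across folds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .feature_select import META_COLUMNS

__all__ = [
    "CVConfig",
    "EvalReport",
    "stratified_folds",
    "undersample_training",
    "fit_predict",
    "evaluate",
    "compare_datasets",
]


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 5
    undersample: bool = True
    seed: int = 0
    model_kind: str = "xgboost"  # {"xgboost", "mlp"}
    model_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.model_kind not in ("xgboost", "mlp"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")


@dataclass
class EvalReport:
    """Across-fold mean ± SD of per-class accuracy/F1 and AUROC."""

    metrics: dict[str, tuple[float, float]]  # name -> (mean, sd)
    confusions: list[np.ndarray]
    per_fold: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": k, "mean": m, "sd": s} for k, (m, s) in self.metrics.items()
        ]
        return pd.DataFrame(rows)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.metrics[name]


def _split_xy(table: pd.DataFrame):
    feats = [c for c in table.columns if c not in META_COLUMNS]
    return table[feats].to_numpy(dtype=float), table["label"].to_numpy(dtype=int), feats


def stratified_folds(labels, n_folds: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Test-fold index arrays; per-fold class counts are within 1 of the
    proportional allocation."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("each class must have at least n_folds members")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def undersample_training(rows: np.ndarray, labels: np.ndarray, seed: int = 0):
    """Randomly subsample the majority class (without replacement) down to
    the minority count.  Returns (rows, labels) in original relative order."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return rows[keep], labels[keep]


def _make_model(kind: str, seed: int, params: dict):
    if kind == "xgboost":
        defaults = dict(
            n_estimators=1000,
            eval_metric="auc",
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
        defaults.update(params)
        return XGBClassifier(**defaults)
    defaults = dict(
        hidden_layer_sizes=(12,),
        activation="relu",
        solver="adam",
        batch_size=16,
        max_iter=100,
        random_state=seed,
    )
    defaults.update(params)
    return MLPClassifier(**defaults)


def fit_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    model_kind: str = "xgboost",
    seed: int = 0,
    model_params: dict | None = None,
) -> np.ndarray:
    """Train on ``train`` only and return class-1 probabilities for ``test``.

    For xgboost a 20% stratified slice of the training fold serves as the
    AUC evaluation set.  MLP features are standardized with statistics
    learned from the training rows.
    """
    Xtr, ytr, feats_tr = _split_xy(train)
    Xte, yte, feats_te = _split_xy(test)
    if feats_tr != feats_te:
        raise ValueError("train/test feature columns differ")
    model = _make_model(model_kind, seed, model_params or {})
    if model_kind == "xgboost":
        stratify = ytr if min(np.bincount(ytr)) >= 2 else None
        Xfit, Xval, yfit, yval = train_test_split(
            Xtr, ytr, test_size=0.2, random_state=seed, stratify=stratify
        )
        if len(np.unique(yfit)) < 2:  # tiny folds: fall back to full fit
            model.fit(Xtr, ytr)
        else:
            model.fit(Xfit, yfit, eval_set=[(Xval, yval)], verbose=False)
        return model.predict_proba(Xte)[:, 1]
    scaler = StandardScaler().fit(Xtr)
    model.fit(scaler.transform(Xtr), ytr)
    return model.predict_proba(scaler.transform(Xte))[:, 1]


def _fold_metrics(y_true: np.ndarray, scores: np.ndarray) -> dict[str, float]:
    pred = (scores >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    f1_pos = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    f1_neg = 2 * tn / (2 * tn + fp + fn) if (2 * tn + fp + fn) else 0.0
    return {
        "accuracy_focus": tp / (tp + fn) if (tp + fn) else np.nan,
        "accuracy_notfocus": tn / (tn + fp) if (tn + fp) else np.nan,
        "f1_focus": f1_pos,
        "f1_notfocus": f1_neg,
        "auroc": roc_auc_score(y_true, scores),
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
    }


def _rows_checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        np.ascontiguousarray(df.to_numpy(dtype=float)).tobytes()
    ).hexdigest()


def evaluate(table: pd.DataFrame, cv: CVConfig | None = None) -> EvalReport:
    """Stratified k-fold evaluation of one feature table.

    Undersampling (when enabled) touches the training folds only; a
    checksum assertion guards the test rows against any modification.
    Folds whose test set contains a single class are skipped with a warning.
    """
    if cv is None:
        cv = CVConfig()
    y = table["label"].to_numpy(dtype=int)
    folds = stratified_folds(y, cv.n_folds, cv.seed)
    feats = [c for c in table.columns if c not in META_COLUMNS]
    keep_cols = feats + ["label"]
    fold_rows = []
    confusions = []
    for fold_i, test_idx in enumerate(folds):
        test_mask = np.zeros(len(y), dtype=bool)
        test_mask[test_idx] = True
        test = table.loc[test_mask, keep_cols].reset_index(drop=True)
        train = table.loc[~test_mask, keep_cols].reset_index(drop=True)
        if len(np.unique(test["label"])) < 2:
            import warnings

            warnings.warn(f"fold {fold_i}: single-class test set skipped")
            continue
        test_checksum = _rows_checksum(test)
        if cv.undersample:
            Xy = train.to_numpy(dtype=float)
            sub, _ = undersample_training(
                Xy, train["label"].to_numpy(dtype=int), seed=cv.seed + fold_i
            )
            train = pd.DataFrame(sub, columns=keep_cols)
            train["label"] = train["label"].astype(int)
        scores = fit_predict(
            train, test, cv.model_kind, seed=cv.seed, model_params=cv.model_params
        )
        assert _rows_checksum(test) == test_checksum, "test rows were modified"
        m = _fold_metrics(test["label"].to_numpy(dtype=int), scores)
        confusions.append(
            np.array([[m["tn"], m["fp"]], [m["fn"], m["tp"]]], dtype=int)
        )
        m["fold"] = fold_i
        fold_rows.append(m)
    per_fold = pd.DataFrame(fold_rows)
    metric_names = ["accuracy_focus", "accuracy_notfocus", "f1_focus", "f1_notfocus", "auroc"]
    metrics = {
        name: (float(per_fold[name].mean()), float(per_fold[name].std(ddof=0)))
        for name in metric_names
    }
    return EvalReport(metrics=metrics, confusions=confusions, per_fold=per_fold)


def compare_datasets(
    tables: dict[str, pd.DataFrame],
    cv: CVConfig | None = None,
    model_kinds: tuple[str, ...] = ("xgboost", "mlp"),
) -> pd.DataFrame:
    """Dataset x model grid of mean ± SD metrics (one row per pair)."""
    if not tables:
        raise ValueError("need at least one dataset")
    if cv is None:
        cv = CVConfig()
    rows = []
    for name, table in tables.items():
        for kind in model_kinds:
            cfg = CVConfig(
                n_folds=cv.n_folds,
                undersample=cv.undersample,
                seed=cv.seed,
                model_kind=kind,
                model_params=cv.model_params,
            )
            rep = evaluate(table, cfg)
            row = {"dataset": name, "model": kind}
            for metric, (m, s) in rep.metrics.items():
                row[f"{metric}_mean"] = m
                row[f"{metric}_sd"] = s
            rows.append(row)
    return pd.DataFrame(rows)
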