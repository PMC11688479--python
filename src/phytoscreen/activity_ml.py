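"""Fingerprint-based inhibitor-classification benchmark harness.

Labeled SMILES (active/inactive) are featurized under any of the five
fingerprint schemes and classified with tree ensembles: random forest
(scikit-learn) or gradient-boosted trees (XGBoost).  The protocol is the
standard QSAR benchmark: stratified 80/20 train/test split, 5-fold
cross-validated grid search scored by ROC AUC, refit on the training set,
then test-set metrics — SE, SP, ACC, MCC, precision, F1, balanced
accuracy, AUC — plus the confusion matrix in counts and row percentages.

Metric definitions, from confusion counts (tp, fp, tn, fn):

    SE  = tp / (tp + fn)            SP  = tn / (tn + fp)
    ACC = (tp + tn) / total         BA  = (SE + SP) / 2
    P   = tp / (tp + fp)            F1  = 2 P·SE / (P + SE)
    MCC = (tp·tn − fp·fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))

AUC is threshold-free, from predicted probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .chemlib import CompoundRecord, canonical_smiles
from .fingerprints import ML_MORGAN, SCHEMES, fingerprint_matrix

ALGORITHMS = ("random_forest", "gradient_boosted_trees")

#: Compact default grids (the protocol's hyperparameter families, kept to
#: a handful of combinations so a full scheme x algorithm sweep stays
#: desk-sized).  Fully logged in TrainedModel.best_params.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [100, 300],
        "max_depth": [None, 10],
        "min_samples_split": [2, 5],
        "min_samples_leaf": [1],
        "bootstrap": [True],
    },
    "gradient_boosted_trees": {
        "n_estimators": [100, 300],
        "max_depth": [3, 6],
        "learning_rate": [0.1, 0.3],
        "subsample": [1.0],
        "colsample_bytree": [1.0],
    },
}

#: Minimal grids for quick runs/tests (1-2 combinations).
FAST_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [100], "max_depth": [None]},
    "gradient_boosted_trees": {"n_estimators": [100], "max_depth": [3]},
}


@dataclass(frozen=True)
class ActivityDataset:
    """Labeled SMILES records: (id, smiles, label) with binary labels."""

    records: tuple[tuple[str, str, int], ...]  # label 1=active, 0=inactive
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r[2] for r in self.records], dtype=int)

    def to_compounds(self) -> list[CompoundRecord]:
        return [CompoundRecord(id=r[0], name="", smiles=r[1]) for r in self.records]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "") -> "ActivityDataset":
        """Build from a DataFrame with id/smiles/label columns.

        Labels may be 0/1 or the strings active/inactive.  Records whose
        SMILES do not parse are dropped; duplicate canonical SMILES with
        conflicting labels raise.
        """
        seen: dict[str, int] = {}
        records = []
        for _, row in df.iterrows():
            canon = canonical_smiles(str(row["smiles"]))
            if canon is None:
                continue
            raw = row["label"]
            label = int(raw) if str(raw) in ("0", "1") else int(str(raw).lower() == "active")
            if canon in seen:
                if seen[canon] != label:
                    raise ValueError(f"conflicting labels for canonical SMILES {canon}")
                continue
            seen[canon] = label
            records.append((str(row["id"]), canon, label))
        return cls(tuple(records), provenance)


@dataclass(frozen=True)
class MetricsReport:
    se: float
    sp: float
    acc: float
    mcc: float
    precision: float
    f1: float
    ba: float
    auc: float
    confusion: tuple[int, int, int, int]  # tp, fp, tn, fn

    def confusion_percent(self) -> dict[str, float]:
        """Row-normalized confusion percentages (TPR/FNR over actual positives, etc.)."""
        tp, fp, tn, fn = self.confusion
        pos, neg = tp + fn, tn + fp
        return {
            "tp_pct": 100.0 * tp / pos if pos else math.nan,
            "fn_pct": 100.0 * fn / pos if pos else math.nan,
            "tn_pct": 100.0 * tn / neg if neg else math.nan,
            "fp_pct": 100.0 * fp / neg if neg else math.nan,
        }


@dataclass
class TrainedModel:
    estimator: object
    scheme: str
    algorithm: str
    best_params: dict
    cv_auc: float


def _featurize(ds: ActivityDataset, scheme: str) -> np.ndarray:
    params = ML_MORGAN if scheme == "morgan" else None
    x, _ = fingerprint_matrix(ds.to_compounds(), scheme, params)
    return x.astype(np.float32)


def split_dataset(
    d: ActivityDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[ActivityDataset, ActivityDataset]:
    """Stratified train/test split (default 80/20), deterministic given seed."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    y = d.labels
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("each class needs at least 2 members to split")
    idx = np.arange(len(d))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    rec = d.records
    return (
        ActivityDataset(tuple(rec[i] for i in sorted(train_idx)), d.provenance),
        ActivityDataset(tuple(rec[i] for i in sorted(test_idx)), d.provenance),
    )


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "gradient_boosted_trees":
        return XGBClassifier(
            random_state=seed,
            eval_metric="logloss",
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def train_model(
    train: ActivityDataset,
    scheme: str = "morgan",
    algorithm: str = "random_forest",
    grid: Mapping[str, list] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Grid-search hyperparameters by mean CV AUC, refit on the full train set.

    Folds are stratified (a plain k-fold can produce single-class folds on
    small data, which breaks AUC scoring) and seeded.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training set has a single class; stratify the split")
    x = _featurize(train, scheme)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _make_estimator(algorithm, seed),
        param_grid=dict(grid) if grid is not None else DEFAULT_GRIDS[algorithm],
        scoring="roc_auc",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(x, y)
    return TrainedModel(
        estimator=search.best_estimator_,
        scheme=scheme,
        algorithm=algorithm,
        best_params=dict(search.best_params_),
        cv_auc=float(search.best_score_),
    )


def metrics_from_confusion(
    tp: int, fp: int, tn: int, fn: int, auc: float = math.nan
) -> MetricsReport:
    """All threshold metrics from confusion counts; undefined ratios give NaN."""
    pos, neg = tp + fn, tn + fp
    se = tp / pos if pos else math.nan
    sp = tn / neg if neg else math.nan
    total = pos + neg
    acc = (tp + tn) / total if total else math.nan
    prec = tp / (tp + fp) if (tp + fp) else math.nan
    f1 = (
        2 * prec * se / (prec + se)
        if (tp + fp) and pos and (prec + se) > 0
        else (0.0 if pos else math.nan)
    )
    ba = (se + sp) / 2 if pos and neg else math.nan
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn) - (fp * fn)) / denom if denom > 0 else 0.0
    return MetricsReport(se, sp, acc, mcc, prec, f1, ba, auc, (tp, fp, tn, fn))


def evaluate(model: TrainedModel, test: ActivityDataset) -> MetricsReport:
    """Test-set metrics: labels at probability 0.5, AUC threshold-free."""
    if len(test) == 0:
        raise ValueError("empty test set")
    x = _featurize(test, model.scheme)
    y = test.labels
    prob = model.estimator.predict_proba(x)[:, 1]
    pred = (prob >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    auc = float(roc_auc_score(y, prob)) if len(np.unique(y)) == 2 else math.nan
    return metrics_from_confusion(tp, fp, tn, fn, auc)


def benchmark(
    dataset: ActivityDataset,
    schemes: Sequence[str] = SCHEMES,
    algorithms: Sequence[str] = ALGORITHMS,
    test_fraction: float = 0.2,
    folds: int = 5,
    seed: int = 0,
    grids: Mapping[str, Mapping[str, list]] | None = None,
) -> pd.DataFrame:
    """Run the full scheme x algorithm sweep; one metrics row per cell."""
    train, test = split_dataset(dataset, test_fraction, seed)
    rows = []
    for scheme in schemes:
        for algo in algorithms:
            grid = grids[algo] if grids is not None else None
            model = train_model(train, scheme, algo, grid=grid, folds=folds, seed=seed)
            rep = evaluate(model, test)
            tp, fp, tn, fn = rep.confusion
            rows.append(
                {
                    "scheme": scheme,
                    "algorithm": algo,
                    "cv_auc": model.cv_auc,
                    "se": rep.se,
                    "sp": rep.sp,
                    "acc": rep.acc,
                    "mcc": rep.mcc,
                    "precision": rep.precision,
                    "f1": rep.f1,
                    "ba": rep.ba,
                    "auc": rep.auc,
                    "tp": tp,
                    "fp": fp,
                    "tn": tn,
                    "fn": fn,
                }
            )
    return pd.DataFrame(rows)
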