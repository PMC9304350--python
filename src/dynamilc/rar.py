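"""Retain-And-Retrain (RAR) validation of saliency estimates.

The top-p fraction of cells named by an importance estimator is retained
and every other cell replaced with zeros; static functional network
connectivity (FNC, Pearson correlation between component time courses)
is recomputed from the masked data; the upper-triangle correlations are
fed to an independent RBF SVM tuned by an inner 3-fold grid search on
the training folds only; and the test performance ξ obtained with the
model-derived importance g_i is compared against the random-permutation
baseline g^R over the same folds and repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .attribution import RetainMask
from .cohort import TimecourseRecord

__all__ = [
    "FNCMatrix",
    "RARReport",
    "apply_retain_mask",
    "compute_fnc",
    "fnc_features",
    "rar_auc",
    "compare_estimators",
    "group_fnc_summary",
]


@dataclass
class FNCMatrix:
    """C × C Pearson correlation matrix; zero-variance pairs are zeroed."""

    values: np.ndarray
    n_degenerate_pairs: int = 0


@dataclass
class RARReport:
    """Per-(fold, repeat) SVM test performance for one importance estimator."""

    estimator: str
    retain_fraction: float
    table: pd.DataFrame  # columns: fold, repeat, auc, accuracy
    manifest: list = field(default_factory=list)

    def xi(self) -> float:
        """ξ: mean test AUC over folds and repeats."""
        return float(self.table["auc"].mean())

    def summary(self) -> pd.DataFrame:
        return self.table.agg({"auc": ["mean", "std"], "accuracy": ["mean", "std"]})


def apply_retain_mask(record: TimecourseRecord, mask: RetainMask) -> TimecourseRecord:
    """Zero every cell outside the retain mask (non-informative replacement)."""
    m = mask.mask if isinstance(mask, RetainMask) else np.asarray(mask, dtype=bool)
    if m.shape != record.data.shape:
        raise ValueError(f"mask shape {m.shape} != data shape {record.data.shape}")
    return replace(record, data=record.data * m)


def compute_fnc(record: TimecourseRecord) -> FNCMatrix:
    """Static FNC: Pearson correlation over the full time axis per pair.

    Components left with zero variance (e.g. fully masked rows) yield 0
    entries; the count of such degenerate pairs is reported.  Diagonal is 1.
    """
    data = record.data
    if data.shape[1] < 3:
        raise ValueError("need at least 3 time points for a correlation")
    std = data.std(axis=1)
    degenerate = std == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r = np.nan_to_num(r, nan=0.0)
    r = (r + r.T) / 2  # corrcoef is symmetric only up to rounding
    np.fill_diagonal(r, 1.0)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    r = np.clip(r, -1.0, 1.0)
    n_deg = int(degenerate.sum())
    C = data.shape[0]
    n_deg_pairs = n_deg * (C - n_deg) + n_deg * (n_deg - 1) // 2
    return FNCMatrix(values=r, n_degenerate_pairs=n_deg_pairs)


def fnc_features(fnc: FNCMatrix) -> np.ndarray:
    """Strict upper triangle, row-major: length C(C−1)/2 feature vector."""
    v = fnc.values if isinstance(fnc, FNCMatrix) else np.asarray(fnc)
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def _fit_svm(X_train, y_train, seed: int):
    """Grid-searched RBF SVM with inner 3-fold CV on the training data only."""
    scale = 1.0 / (X_train.shape[1] * max(X_train.var(), 1e-12))
    grid = {
        "C": [0.1, 1.0, 10.0, 100.0],
        "gamma": [scale * 0.1, scale, scale * 10.0],
    }
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    search = GridSearchCV(SVC(kernel="rbf"), grid, cv=inner, scoring="roc_auc", n_jobs=None)
    search.fit(X_train, y_train)
    return search.best_estimator_


def rar_auc(
    masked_records: Sequence[TimecourseRecord],
    labels: Optional[Sequence[int]] = None,
    folds=5,
    repeats: int = 1,
    seed: int = 0,
    estimator_tag: str = "g_i",
    retain_fraction: float = 0.05,
) -> RARReport:
    """RAR evaluation: masked FNC features → grid-searched RBF SVM → test AUC.

    ``folds`` is either an integer K (stratified folds seeded by ``seed``) or
    an explicit list of (train_idx, test_idx) pairs, so the same splits can be
    reused across estimators and shared with the deep model's CV.  AUC uses
    the SVM's continuous decision values.
    """
    if labels is None:
        labels = [r.label for r in masked_records]
    y = np.asarray(labels, dtype=int)
    X = np.stack([fnc_features(compute_fnc(r)) for r in masked_records])
    if isinstance(folds, int):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        fold_list = list(skf.split(X, y))
    else:
        fold_list = list(folds)

    rows, manifest = [], []
    for rep in range(repeats):
        for fold, (tr, te) in enumerate(fold_list):
            tr, te = np.asarray(tr), np.asarray(te)
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                raise ValueError(f"fold {fold} does not contain both classes")
            inner_seed = (seed + 1000003 * rep + 7919 * fold) % (2**31)
            svm = _fit_svm(X[tr], y[tr], inner_seed)
            scores = svm.decision_function(X[te])
            rows.append(
                {
                    "fold": fold,
                    "repeat": rep,
                    "auc": roc_auc_score(y[te], scores),
                    "accuracy": accuracy_score(y[te], svm.predict(X[te])),
                }
            )
            manifest.append({"fold": fold, "repeat": rep,
                             "train_idx": tr.tolist(), "test_idx": te.tolist()})
    return RARReport(estimator=estimator_tag, retain_fraction=retain_fraction,
                     table=pd.DataFrame(rows), manifest=manifest)


def compare_estimators(report_salient: RARReport, report_random: RARReport) -> dict:
    """ξ(X^M|g_i) vs ξ(X^M|g^R): per-cell differences and a paired rank test."""
    from .temporal import wilcoxon_rank

    keys = ["fold", "repeat"]
    a = report_salient.table.set_index(keys)["auc"]
    b = report_random.table.set_index(keys)["auc"]
    if not a.index.equals(b.index):
        raise ValueError("reports must share the same fold/repeat grid")
    diffs = (a - b).values
    stat, p = wilcoxon_rank(a.values, b.values, paired=True)
    return {
        "xi_salient": float(a.mean()),
        "xi_random": float(b.mean()),
        "mean_diff": float(diffs.mean()),
        "per_cell_diff": diffs,
        "statistic": stat,
        "p_value": p,
        "salient_exceeds_random": bool(a.mean() > b.mean()),
    }


def group_fnc_summary(records: Sequence[TimecourseRecord], edge_fraction: float = 0.10):
    """Group-mean FNC, its top-|r| edge list, and a pairwise-difference helper.

    Returns ``(mean_fnc, edges)`` where ``edges`` is a DataFrame with columns
    component_i, component_j, mean_r holding the round(edge_fraction·C(C−1)/2)
    edges of largest absolute mean correlation.
    """
    if not records:
        raise ValueError("empty group")
    mats = [compute_fnc(r).values for r in records]
    mean_fnc = np.mean(mats, axis=0)
    C = mean_fnc.shape[0]
    iu = np.triu_indices(C, k=1)
    vals = mean_fnc[iu]
    n_edges = int(round(edge_fraction * len(vals)))
    order = np.argsort(-np.abs(vals), kind="stable")[:n_edges]
    edges = pd.DataFrame(
        {
            "component_i": iu[0][order],
            "component_j": iu[1][order],
            "mean_r": vals[order],
        }
    )
    return mean_fnc, edges


def fnc_difference(mean_fnc_a: np.ndarray, mean_fnc_b: np.ndarray) -> np.ndarray:
    """Pairwise difference matrix between two group-mean FNC matrices."""
    return np.asarray(mean_fnc_a) - np.asarray(mean_fnc_b)
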