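"""Leave-one-group-out and cross-cancer-transfer validation of biomarkers.

Candidate predictors are the log-ratio biomarker, the Shannon index and the
summed relative abundance of Proteobacteria (either the NCBI or the GTDB
phylum label is recognized).  Classification uses unregularized logistic
regression by maximum likelihood, falling back to a weak ridge (strength
1e-4) only on non-convergence; the decision threshold for the
confusion-matrix metrics is 0.5 on the predicted probability.  AUC is the
rank statistic (Mann-Whitney form); ROC curves are averaged vertically on a
fixed false-positive grid of step 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .core_io import OguCountTable, OguMetadata
from .diversity import shannon
from .markers import LogRatioResult

PROTEOBACTERIA_LABELS = frozenset({"Proteobacteria", "Pseudomonadota"})
FPR_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


@dataclass
class FoldResult:
    held_out_id: str
    n_test: int
    auc: float | None
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    n_dropped_invalid: int = 0


@dataclass
class CvResult:
    folds: list[FoldResult]
    mean_auc: float
    sd_auc: float
    averaged_roc: list[tuple[float, float]]
    predictors_used: list[str]


def rank_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC via the rank (Mann-Whitney) statistic; ties share ranks."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    r = rankdata(s)
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def build_predictors(
    table: OguCountTable,
    logratios: Mapping[str, LogRatioResult],
    ogu_meta: Mapping[str, OguMetadata],
) -> pd.DataFrame:
    """Per-sample predictor frame: log_ratio, shannon, proteobacteria_relabund.

    The table should be TSS-normalized (the Proteobacteria predictor is a
    relative-abundance sum).  OGUs with unparseable taxonomy are skipped and
    counted in the frame's ``attrs['n_taxonomy_skipped']``.
    """
    if not table.is_relative:
        raise ValueError("build_predictors expects a TSS-normalized table")
    proteo_idx = []
    skipped = 0
    for j, ogu in enumerate(table.ogu_ids):
        m = ogu_meta.get(ogu)
        if m is None or not m.taxonomy:
            skipped += 1
            continue
        phylum = m.phylum()
        if phylum is None:
            skipped += 1
            continue
        if phylum in PROTEOBACTERIA_LABELS:
            proteo_idx.append(j)
    proteo = (
        table.values[:, proteo_idx].sum(axis=1)
        if proteo_idx
        else np.zeros(table.n_samples)
    )
    rows = []
    for i, sid in enumerate(table.sample_ids):
        lr = logratios.get(sid)
        rows.append(
            {
                "sample_id": sid,
                "log_ratio": lr.value if lr is not None and lr.valid else np.nan,
                "log_ratio_valid": bool(lr is not None and lr.valid),
                "shannon": shannon(table.values[i]),
                "proteobacteria_relabund": float(proteo[i]),
            }
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    df.attrs["n_taxonomy_skipped"] = skipped
    return df


def _fit_logistic(x: np.ndarray, y: np.ndarray, seed: int | None):
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000,
                                     random_state=seed)
            clf.fit(x, y)
            return clf
        except ConvergenceWarning:
            pass
    # documented ridge fallback for separation / non-convergence
    clf = LogisticRegression(C=1.0 / 1e-4, solver="lbfgs", max_iter=5000,
                             random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x, y)
    return clf


def _fold_metrics(
    held_out: str, prob: np.ndarray, y: np.ndarray, n_dropped: int
) -> FoldResult:
    pred = (prob >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = (tp + tn) / y.size
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    auc = rank_auc(prob, y) if 0 < y.sum() < y.size else None
    return FoldResult(held_out, int(y.size), auc, acc, sens, spec, prec, f1, n_dropped)


def _roc_tpr_on_grid(prob: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-fold TPR at each FPR grid point (step function, right-continuous)."""
    order = np.argsort(-prob, kind="stable")
    y_sorted = y[order]
    n_pos = y.sum()
    n_neg = y.size - n_pos
    tps = np.concatenate([[0], np.cumsum(y_sorted)])
    fps = np.concatenate([[0], np.cumsum(1 - y_sorted)])
    fpr = fps / n_neg
    tpr = tps / n_pos
    out = np.empty(FPR_GRID.size)
    for k, g in enumerate(FPR_GRID):
        out[k] = tpr[fpr <= g + 1e-12].max()
    return out


def _prepare(
    predictors: pd.DataFrame, predictors_used: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    x = predictors[list(predictors_used)].values.astype(float)
    keep = ~np.isnan(x).any(axis=1)
    return x, keep


def logo_cv(
    predictors: pd.DataFrame,
    labels: Sequence[int],
    groups: Sequence[str],
    predictors_used: Sequence[str] = ("log_ratio",),
    model: str = "logistic",
    seed: int | None = None,
) -> CvResult:
    """Leave-one-group-out cross-validation.

    One fold per group: the logistic model is trained on all other groups
    and evaluated on the held-out one.  Samples with missing predictor
    values (invalid log ratios) are dropped from the fold and counted in
    its record.  A fold whose test set has one class reports no AUC.
    """
    if model != "logistic":
        raise ValueError("only the logistic model is implemented")
    y = np.asarray(labels, dtype=int)
    g = np.asarray(groups, dtype=object)
    if len(predictors) != y.size or y.size != g.size:
        raise ValueError("predictors, labels and groups must align")
    uniq = list(pd.unique(g))
    if len(uniq) < 2:
        raise ValueError("LOGO needs at least two groups")
    x, keep = _prepare(predictors, predictors_used)

    folds: list[FoldResult] = []
    tprs: list[np.ndarray] = []
    for held in uniq:
        test_mask = (g == held) & keep
        train_mask = (g != held) & keep
        y_tr = y[train_mask]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"training set for fold {held!r} has one class")
        clf = _fit_logistic(x[train_mask], y_tr, seed)
        prob = clf.predict_proba(x[test_mask])[:, 1]
        y_te = y[test_mask]
        n_dropped = int(((g == held) & ~keep).sum())
        fold = _fold_metrics(str(held), prob, y_te, n_dropped)
        folds.append(fold)
        if fold.auc is not None:
            tprs.append(_roc_tpr_on_grid(prob, y_te))
    aucs = [f.auc for f in folds if f.auc is not None]
    mean_auc = float(np.mean(aucs)) if aucs else np.nan
    sd_auc = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    mean_tpr = np.mean(tprs, axis=0) if tprs else np.full(FPR_GRID.size, np.nan)
    roc = [(float(fp), float(tp)) for fp, tp in zip(FPR_GRID, mean_tpr)]
    return CvResult(folds, mean_auc, sd_auc, roc, list(predictors_used))


def transfer_validation(
    predictors: pd.DataFrame,
    labels: Sequence[int],
    train_mask: Sequence[bool],
    test_mask: Sequence[bool],
    predictors_used: Sequence[str] = ("log_ratio",),
    model: str = "logistic",
    seed: int | None = None,
) -> CvResult:
    """Single train/test split defined by boolean masks (e.g. cancer types)."""
    if model != "logistic":
        raise ValueError("only the logistic model is implemented")
    y = np.asarray(labels, dtype=int)
    tr = np.asarray(train_mask, dtype=bool)
    te = np.asarray(test_mask, dtype=bool)
    if (tr & te).any():
        raise ValueError("train and test masks overlap")
    if not tr.any() or not te.any():
        raise ValueError("train and test masks must both select samples")
    x, keep = _prepare(predictors, predictors_used)
    tr = tr & keep
    te = te & keep
    if np.unique(y[tr]).size < 2:
        raise ValueError("training set has one class")
    clf = _fit_logistic(x[tr], y[tr], seed)
    prob = clf.predict_proba(x[te])[:, 1]
    n_dropped = int((np.asarray(test_mask, dtype=bool) & ~keep).sum())
    fold = _fold_metrics("transfer", prob, y[te], n_dropped)
    tpr = (
        _roc_tpr_on_grid(prob, y[te]) if fold.auc is not None
        else np.full(FPR_GRID.size, np.nan)
    )
    roc = [(float(fp), float(tp)) for fp, tp in zip(FPR_GRID, tpr)]
    return CvResult(
        [fold],
        fold.auc if fold.auc is not None else np.nan,
        0.0,
        roc,
        list(predictors_used),
    )
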