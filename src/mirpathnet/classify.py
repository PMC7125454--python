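"""Single-feature disease-classification accuracy by cross-validated ROC AUC.

Each candidate feature (a gene's or miRNA's expression vector) is scored
for its ability to separate tumor from control samples.  The evaluation
is stratified ten-fold cross-validation: on each training split a
direction-calibrated scorer is fitted (the sign of the tumor-minus-control
class-mean difference), held-out samples are scored as value x direction,
and the pooled out-of-fold scores yield one AUC per feature.  AUC is the
Mann-Whitney rank statistic with ties counted one half — the probability
that a random tumor sample outscores a random control sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = ["CVResult", "auc", "cv_feature_auc", "rank_candidates"]


@dataclass
class CVResult:
    feature: str
    pooled_auc: float
    fold_aucs: list[float] = field(default_factory=list)
    n_folds: int = 10
    seed: int = 0


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUC: P(random positive outscores random negative).

    ``labels`` is binary (1 = tumor / positive).  Ties contribute 1/2.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _fold_scorer(train_x, train_y, test_x, model: str):
    if model == "direction":
        diff = train_x[train_y == 1].mean() - train_x[train_y == 0].mean()
        direction = 1.0 if diff >= 0 else -1.0
        return test_x * direction
    if model == "logistic":
        clf = LogisticRegression()
        clf.fit(train_x.reshape(-1, 1), train_y)
        return clf.predict_proba(test_x.reshape(-1, 1))[:, 1]
    raise ValueError(f"unknown scorer model: {model!r}")


def cv_feature_auc(
    values: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    feature: str = "",
    model: str = "direction",
) -> CVResult:
    """Stratified k-fold cross-validated AUC for one feature.

    Folds preserve the class ratio to within one sample.  The pooled
    out-of-fold AUC is primary; per-fold AUCs are kept for inspection.
    If a training split lacks a class, folds are re-drawn once with a
    derived seed before raising.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    for attempt_seed in (seed, seed + 104729):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=attempt_seed % 2**31)
        pooled = np.empty_like(values)
        fold_aucs: list[float] = []
        ok = True
        for train_idx, test_idx in splitter.split(values.reshape(-1, 1), labels):
            train_y = labels[train_idx]
            if len(np.unique(train_y)) < 2:
                ok = False
                break
            test_scores = _fold_scorer(values[train_idx], train_y, values[test_idx], model)
            pooled[test_idx] = test_scores
            test_y = labels[test_idx]
            if len(np.unique(test_y)) == 2:
                fold_aucs.append(auc(test_scores, test_y))
            else:
                fold_aucs.append(float("nan"))
        if ok:
            return CVResult(
                feature=feature,
                pooled_auc=auc(pooled, labels),
                fold_aucs=fold_aucs,
                n_folds=k,
                seed=seed,
            )
    raise ValueError("degenerate folds: a training split contained one class")


def rank_candidates(
    matrix,
    candidates: list[str],
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    model: str = "direction",
) -> list[CVResult]:
    """CV AUC for each candidate row of ``matrix``, best first.

    ``matrix`` is a features x samples DataFrame; ties in pooled AUC break
    by feature id.  Unknown candidate ids raise, listing every offender.
    """
    missing = [c for c in candidates if c not in matrix.index]
    if missing:
        raise KeyError(f"candidates not in matrix: {missing}")
    results = [
        cv_feature_auc(
            matrix.loc[c].to_numpy(), labels, k=k, seed=seed, feature=c, model=model
        )
        for c in candidates
    ]
    return sorted(results, key=lambda r: (-r.pooled_auc, r.feature))
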