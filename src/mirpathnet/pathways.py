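"""Pathway-level scoring, differential expression, and correlated pairs.

The activity of a pathway in a sample is summarized by the median
depth-adjusted expression of its member genes measured in the matrix
(midpoint convention for even counts).  Pathway-level differential
expression reuses the NB count machinery on rounded scores, mirroring an
edgeR-style analysis of pathway values (a rank-based Wilcoxon backend is
available as a sensitivity check).  Correlated pathway pairs are the
unordered pairs whose score vectors have |Pearson r| strictly above the
threshold in BOTH the tumor and the control samples.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .diffexpr import bh_adjust, depth_adjusted_counts, differential_expression
from .types import CONTROL, TUMOR, CountMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayScoreMatrix",
    "score_pathways",
    "pathway_differential",
    "pearson",
    "correlated_pairs",
]


class ConstantVectorError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclass
class PathwayScoreMatrix:
    """Pathway x sample activity scores with per-sample condition labels."""

    scores: pd.DataFrame  # pathways x samples, float
    condition: pd.Series  # sample -> tumor/control
    n_members: pd.Series  # measured member genes per pathway

    def samples_of(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])


def score_pathways(
    m: CountMatrix,
    sets: GeneSetCollection,
    min_members: int = 1,
    effective_sizes: pd.Series | None = None,
) -> PathwayScoreMatrix:
    """Median depth-adjusted member-gene expression per pathway and sample.

    Pathway membership is intersected with the measured features; pathways
    with fewer than ``min_members`` measured genes are dropped with a
    warning.  Even-cardinality medians use the midpoint of the two central
    values.
    """
    adj = depth_adjusted_counts(m, effective_sizes)
    measured = set(m.feature_ids)
    rows, counts, kept = [], [], []
    for pid in sets.pathway_ids:
        members = [g for g in sets.sets[pid] if g in measured]
        if len(members) < max(min_members, 1):
            logger.warning(
                "pathway %s dropped: %d measured members < %d", pid, len(members), min_members
            )
            continue
        rows.append(np.median(adj.loc[members].to_numpy(), axis=0))
        counts.append(len(members))
        kept.append(pid)
    scores = pd.DataFrame(rows, index=kept, columns=m.sample_ids, dtype=float)
    return PathwayScoreMatrix(
        scores, m.condition.copy(), pd.Series(counts, index=kept, name="n_members")
    )


def _as_count_matrix(scores: PathwayScoreMatrix) -> CountMatrix:
    rounded = scores.scores.round().astype(np.int64)
    return CountMatrix(rounded, scores.condition.copy())


def pathway_differential(
    scores: PathwayScoreMatrix,
    alpha: float = 0.05,
    lfc_cut: float = 1.0,
    backend: str = "nb",
) -> pd.DataFrame:
    """Differentially active pathways, tumor vs control.

    The significance rule is inclusive on the fold change: adjusted
    p < alpha AND |log2FC| >= lfc_cut.  The default backend rounds scores
    to integers and applies the NB exact-test machinery; ``"wilcoxon"``
    uses a rank-sum test on the raw scores instead.
    """
    if backend == "nb":
        return differential_expression(
            _as_count_matrix(scores), alpha=alpha, lfc_cut=lfc_cut, lfc_inclusive=True
        )
    if backend != "wilcoxon":
        raise ValueError(f"unknown pathway DE backend: {backend!r}")
    tumor = scores.scores[scores.samples_of(TUMOR)].to_numpy()
    control = scores.scores[scores.samples_of(CONTROL)].to_numpy()
    p_values = np.array(
        [
            mannwhitneyu(t, c, alternative="two-sided").pvalue if (np.ptp(t) or np.ptp(c)) else 1.0
            for t, c in zip(tumor, control)
        ]
    )
    log2fc = np.log2((tumor.mean(axis=1) + 0.5) / (control.mean(axis=1) + 0.5))
    p_adj = bh_adjust(p_values)
    sig = (p_adj < alpha) & (np.abs(log2fc) >= lfc_cut)
    return pd.DataFrame(
        {
            "feature": scores.scores.index,
            "log2fc": log2fc,
            "p_value": p_values,
            "p_adj": p_adj,
            "direction": np.where(sig, np.where(log2fc > 0, "up", "down"), "ns"),
            "mean_expr": scores.scores.to_numpy().mean(axis=1),
        }
    )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return float((dx * dy).sum() / denom)


def correlated_pairs(
    scores: PathwayScoreMatrix,
    threshold: float = 0.8,
    restrict_to: set[str] | None = None,
) -> pd.DataFrame:
    """Unordered pathway pairs with |r| > threshold in tumor AND control.

    Correlations are computed separately over tumor-condition and
    control-condition samples; both must exceed the threshold strictly.
    Pathways whose scores are constant in either condition are excluded
    (their correlation is undefined).  Returns columns pathway_x,
    pathway_y (x < y lexicographically), r_tumor, r_control.
    """
    ids = list(scores.scores.index)
    if restrict_to is not None:
        ids = [p for p in ids if p in restrict_to]
    groups = {}
    for cond in (TUMOR, CONTROL):
        cols = scores.samples_of(cond)
        if len(cols) < 3:
            raise ValueError(f"need at least 3 {cond} samples for correlation")
        groups[cond] = scores.scores.loc[ids, cols].to_numpy()
    usable = np.ones(len(ids), dtype=bool)
    for cond, block in groups.items():
        const = block.std(axis=1) == 0
        if const.any():
            for pid in np.asarray(ids)[const]:
                logger.warning("pathway %s constant in %s samples; excluded", pid, cond)
            usable &= ~const
    keep_idx = np.flatnonzero(usable)
    kept_ids = [ids[i] for i in keep_idx]
    if len(kept_ids) < 2:
        return pd.DataFrame(columns=["pathway_x", "pathway_y", "r_tumor", "r_control"])
    r = {
        cond: np.corrcoef(groups[cond][keep_idx]) for cond in (TUMOR, CONTROL)
    }
    records = []
    for i, j in itertools.combinations(range(len(kept_ids)), 2):
        rt, rc = r[TUMOR][i, j], r[CONTROL][i, j]
        if abs(rt) > threshold and abs(rc) > threshold:
            x, y = sorted((kept_ids[i], kept_ids[j]))
            records.append((x, y, rt, rc))
    out = pd.DataFrame(records, columns=["pathway_x", "pathway_y", "r_tumor", "r_control"])
    # self-audit: every retained pair satisfies both thresholds
    assert bool(((out["r_tumor"].abs() > threshold) & (out["r_control"].abs() > threshold)).all())
    return out.sort_values(["pathway_x", "pathway_y"], ignore_index=True)
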