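"""Negative-binomial differential expression for count matrices.

The test is the classic conditional exact test for two groups of NB counts
sharing a common dispersion phi (variance = mu + phi * mu^2): counts are
quantile-adjusted to a common effective library size, group totals are
formed, and the two-sided p-value is the minimum-likelihood tail of the
conditional distribution of the group-A total given the grand total.  The
sum of n i.i.d. NB(mu, phi) variables is NB(n*mu, phi/n), which makes the
conditional distribution exactly computable; at phi = 0 it reduces to the
binomial conditional test for Poisson counts.

Library sizes are normalized by a trimmed-mean-of-M-values (TMM) scheme:
log-ratios against the deepest sample are trimmed (30% on M, 5% on A) and
combined by precision weights.  Multiple testing uses Benjamini-Hochberg.
Significance follows the strict rule: adjusted p < alpha AND |log2FC| >
lfc_cut (the inclusive ">=" variant is used for pathway-level calls).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, nbinom

from .types import CONTROL, TUMOR, CountMatrix, FormatError

__all__ = [
    "normalize_library_sizes",
    "depth_adjusted_counts",
    "quantile_adjusted_counts",
    "estimate_common_dispersion",
    "exact_test_feature",
    "exact_nb_pvalue",
    "bh_adjust",
    "differential_expression",
]


def normalize_library_sizes(m: CountMatrix) -> pd.Series:
    """TMM-style effective library sizes, one per sample.

    Returns normalization factors (geometric mean 1) multiplied by raw
    depth.  The reference is the highest-depth sample; M-values are trimmed
    30% each tail, A-values 5% each tail, and the surviving log-ratios are
    averaged with inverse-variance (delta-method) weights.
    """
    counts = m.counts.to_numpy(dtype=np.float64)
    depths = counts.sum(axis=0)
    if np.any(depths == 0):
        bad = m.sample_ids[int(np.argmin(depths))]
        raise FormatError(f"all-zero sample: {bad!r}")
    ref = int(np.argmax(depths))
    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_log2_factor(
            counts[:, j], depths[j], counts[:, ref], depths[ref]
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors * depths, index=m.sample_ids, name="effective_size")


def _tmm_log2_factor(obs, n_obs, ref, n_ref, m_trim=0.30, a_trim=0.05):
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m_val = np.log2(p_obs / p_ref)
    a_val = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M
    weight = 1.0 / (
        (n_obs - obs[keep]) / (n_obs * obs[keep])
        + (n_ref - ref[keep]) / (n_ref * ref[keep])
    )
    lo_m, hi_m = np.quantile(m_val, [m_trim, 1 - m_trim])
    lo_a, hi_a = np.quantile(a_val, [a_trim, 1 - a_trim])
    sel = (m_val >= lo_m) & (m_val <= hi_m) & (a_val >= lo_a) & (a_val <= hi_a)
    if not sel.any() or weight[sel].sum() == 0:
        return 0.0
    return float(np.average(m_val[sel], weights=weight[sel]))


def depth_adjusted_counts(m: CountMatrix, effective_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts rescaled to the geometric-mean effective library size (float)."""
    if effective_sizes is None:
        effective_sizes = normalize_library_sizes(m)
    eff = effective_sizes.reindex(m.sample_ids).to_numpy()
    common = np.exp(np.mean(np.log(eff)))
    return m.counts * (common / eff)


def quantile_adjusted_counts(m: CountMatrix, effective_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Integer counts rescaled to a common effective size (scale + round).

    An approximation of quantile adjustment: each sample's counts are
    multiplied by common_size / effective_size and rounded to the nearest
    integer, preserving the count nature required by the exact test.
    """
    return depth_adjusted_counts(m, effective_sizes).round().astype(np.int64)


def estimate_common_dispersion(m: CountMatrix, effective_sizes: pd.Series | None = None) -> float:
    """Method-of-moments common NB dispersion phi (>= 0).

    Per feature and condition, on depth-adjusted counts, phi is estimated
    as (s^2 - mean) / mean^2; the common value is the median over features
    of the per-feature average, floored at 0 (the Poisson limit).
    """
    m.require_two_per_condition()
    adj = depth_adjusted_counts(m, effective_sizes)
    per_feature: list[np.ndarray] = []
    for cond in (TUMOR, CONTROL):
        sub = adj[m.samples_of(cond)].to_numpy()
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (var - mean) / mean**2
        per_feature.append(np.where(mean > 0, phi, np.nan))
    stacked = np.vstack(per_feature)
    with np.errstate(invalid="ignore"):
        feat = np.nanmean(stacked, axis=0)
    feat = feat[np.isfinite(feat)]
    if feat.size == 0:
        return 0.0
    return float(max(0.0, np.median(np.maximum(feat, 0.0))))


def exact_nb_pvalue(total_a: int, total_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p-value for NB group totals.

    Conditions the group-A total on the grand total under equal per-sample
    means; two-sided by the minimum-likelihood rule (sum of conditional
    probabilities no larger than the observed outcome's).  phi = 0 is the
    Poisson limit, where the conditional law is Binomial(s, n_a / n).
    """
    if phi < 0:
        raise ValueError("dispersion phi must be >= 0")
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups must be non-empty")
    s = int(total_a) + int(total_b)
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi == 0:
        log_p = binom.logpmf(k, s, n_a / (n_a + n_b))
    else:
        mu = s / (n_a + n_b)
        r_a, r_b = n_a / phi, n_b / phi
        log_a = nbinom.logpmf(k, r_a, r_a / (r_a + n_a * mu))
        log_b = nbinom.logpmf(s - k, r_b, r_b / (r_b + n_b * mu))
        log_p = log_a + log_b
        log_p -= logsumexp(log_p)
    log_obs = log_p[int(total_a)]
    # tolerance for ties under floating point
    included = log_p <= log_obs + 1e-10
    if included.all():
        return 1.0
    p = float(np.exp(logsumexp(log_p[included])))
    return min(p, 1.0)


def exact_test_feature(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    phi: float,
    eff_a: np.ndarray | None = None,
    eff_b: np.ndarray | None = None,
) -> float:
    """Exact NB p-value for one feature's two per-group count vectors.

    If effective sizes are given, counts are first rescaled to their common
    (geometric mean) size and rounded.
    """
    counts_a = np.asarray(counts_a, dtype=np.float64)
    counts_b = np.asarray(counts_b, dtype=np.float64)
    if eff_a is not None or eff_b is not None:
        eff = np.concatenate([np.asarray(eff_a, float), np.asarray(eff_b, float)])
        common = np.exp(np.mean(np.log(eff)))
        counts_a = np.round(counts_a * common / np.asarray(eff_a, float))
        counts_b = np.round(counts_b * common / np.asarray(eff_b, float))
    return exact_nb_pvalue(
        int(counts_a.sum()), int(counts_b.sum()), len(counts_a), len(counts_b), phi
    )


def bh_adjust(p_values: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_expression(
    m: CountMatrix,
    alpha: float = 0.05,
    lfc_cut: float = 1.0,
    lfc_inclusive: bool = False,
    phi: float | None = None,
) -> pd.DataFrame:
    """Per-feature NB exact-test differential expression, tumor vs control.

    Returns a DataFrame with columns feature, log2fc, p_value, p_adj,
    direction (up / down / ns) and mean_expr.  A feature is significant iff
    p_adj < alpha and |log2fc| exceeds lfc_cut (strictly by default;
    ``lfc_inclusive=True`` uses >=, the pathway-level convention).
    log2FC is computed from depth-adjusted group means with pseudocount 0.5.
    """
    m.require_two_per_condition()
    eff = normalize_library_sizes(m)
    if phi is None:
        phi = estimate_common_dispersion(m, eff)
    adj = quantile_adjusted_counts(m, eff)
    tumor_cols = m.samples_of(TUMOR)
    control_cols = m.samples_of(CONTROL)
    a = adj[tumor_cols].to_numpy()
    b = adj[control_cols].to_numpy()
    n_a, n_b = len(tumor_cols), len(control_cols)
    tot_a = a.sum(axis=1)
    tot_b = b.sum(axis=1)
    p_values = np.array(
        [exact_nb_pvalue(int(ta), int(tb), n_a, n_b, phi) for ta, tb in zip(tot_a, tot_b)]
    )
    mean_a = tot_a / n_a
    mean_b = tot_b / n_b
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    p_adj = bh_adjust(p_values)
    passes_lfc = np.abs(log2fc) >= lfc_cut if lfc_inclusive else np.abs(log2fc) > lfc_cut
    sig = (p_adj < alpha) & passes_lfc
    direction = np.where(sig, np.where(log2fc > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {
            "feature": m.feature_ids,
            "log2fc": log2fc,
            "p_value": p_values,
            "p_adj": p_adj,
            "direction": direction,
            "mean_expr": adj.to_numpy().mean(axis=1),
        }
    )
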