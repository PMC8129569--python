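"""Differential expression between two groups with an empirical-Bayes
moderated statistic, fold-change threshold, and a heterogeneity filter.

Per gene g the moderated statistic shrinks the pooled sample variance
s2_g (d_g = n_a + n_b - 2 df) toward a prior s0^2 with d0 prior df:

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)
    t_g     = log2fc_g / (s_post * sqrt(1/n_a + 1/n_b))

with two-sided p-values from the t law on d0 + d_g degrees of freedom.
When the prior is ``"auto"`` both hyperparameters are estimated by the
method of moments on the log sample variances (digamma/trigamma matching,
the standard empirical-Bayes recipe for expression arrays).

Selection keeps genes with |log2fc| >= log2(fc_threshold), BH-adjusted
p <= alpha, and pooled within-group sd (the "heterogeneity") within the
lowest ``heterogeneity_quantile`` fraction of the fc/p-passing genes --
genes that respond but do so inconsistently within groups are dropped.
"""

from __future__ import annotations

import math
import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, group_arrays

__all__ = [
    "log2_fold_changes",
    "moderated_t",
    "differential_table",
    "select_de",
]

Auto = Literal["auto"]


def log2_fold_changes(
    matrix: ExpressionMatrix, group_a: str, group_b: str
) -> np.ndarray:
    """Per-gene difference of class means, mean(B) - mean(A), on log2 scale."""
    a, b = group_arrays(matrix, group_a, group_b)
    return b.mean(axis=1) - a.mean(axis=1)


def _pooled_variance(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")
    dof = n_a + n_b - 2
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    return ss / dof, dof


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        delta = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, dof: int) -> tuple[float, float]:
    """Method-of-moments fit of (prior_df, prior_var) on log sample variances.

    Matches mean and variance of log(s2) against the scaled-F model for
    gene variances; an excess-variance of zero or less yields an infinite
    prior df (complete shrinkage to a common variance).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(dof / 2.0) + math.log(dof / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, dof / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0 = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0 = math.exp(e_mean)
    return d0, s0


def moderated_t(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    prior_df: float | Auto = "auto",
    prior_var: float | Auto = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene moderated two-sample statistic and two-sided p-value.

    ``prior_df = 0`` reproduces the ordinary pooled t; a very large prior
    df drives every posterior variance to ``prior_var``.  Genes whose
    posterior variance is zero (all-constant data with no prior) are
    reported as stat 0, p 1 rather than dividing by zero.
    """
    a, b = group_arrays(matrix, group_a, group_b)
    n_a, n_b = a.shape[1], b.shape[1]
    s2, dof = _pooled_variance(a, b)
    fc = b.mean(axis=1) - a.mean(axis=1)

    if prior_df == "auto" or prior_var == "auto":
        d0_hat, s0_hat = estimate_prior(s2, dof)
        d0 = d0_hat if prior_df == "auto" else float(prior_df)
        s0 = s0_hat if prior_var == "auto" else float(prior_var)
    else:
        d0, s0 = float(prior_df), float(prior_var)
    if d0 < 0:
        raise ValueError("prior_df must be nonnegative")

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        total_df = np.inf
    else:
        s2_post = (d0 * s0 + dof * s2) / (d0 + dof)
        total_df = d0 + dof

    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    stat = np.zeros_like(fc)
    p = np.ones_like(fc)
    nz = se > 0
    stat[nz] = fc[nz] / se[nz]
    if math.isinf(total_df):
        p[nz] = 2.0 * stats.norm.sf(np.abs(stat[nz]))
    else:
        p[nz] = 2.0 * stats.t.sf(np.abs(stat[nz]), df=total_df)
    return stat, p


def heterogeneity(matrix: ExpressionMatrix, group_a: str, group_b: str) -> np.ndarray:
    """Pooled within-group standard deviation per gene."""
    a, b = group_arrays(matrix, group_a, group_b)
    s2, _ = _pooled_variance(a, b)
    return np.sqrt(s2)


def differential_table(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    prior_df: float | Auto = "auto",
    prior_var: float | Auto = "auto",
) -> pd.DataFrame:
    """Full per-gene differential result table (unselected).

    Columns: gene_id (index), log2fc, stat, p, p_adj, heterogeneity,
    selected, direction.  ``p_adj`` and ``selected`` are filled by
    :func:`select_de`.
    """
    fc = log2_fold_changes(matrix, group_a, group_b)
    stat, p = moderated_t(matrix, group_a, group_b, prior_df, prior_var)
    het = heterogeneity(matrix, group_a, group_b)
    return pd.DataFrame(
        {
            "log2fc": fc,
            "stat": stat,
            "p": p,
            "p_adj": np.nan,
            "heterogeneity": het,
            "selected": False,
            "direction": np.where(fc > 0, "up", "down"),
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def select_de(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    heterogeneity_quantile: float = 0.47,
) -> pd.DataFrame:
    """Flag selected genes by fold change, BH-adjusted p, and heterogeneity.

    Among the fc/p-passing genes, the ``ceil(q * k)`` with lowest
    heterogeneity survive (ties broken by gene order), mirroring the
    elimination of genes too heterogeneous within groups.  Returns a copy
    with ``p_adj`` and ``selected`` set.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (linear-scale fold change)")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if not 0 < heterogeneity_quantile <= 1:
        raise ValueError("heterogeneity_quantile must lie in (0, 1]")

    out = results.copy()
    _, p_adj, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
    out["p_adj"] = p_adj
    log_fc_cut = math.log2(fc_threshold)
    passing = (out["log2fc"].abs() >= log_fc_cut) & (out["p_adj"] <= alpha)
    k = int(passing.sum())
    out["selected"] = False
    if k == 0:
        warnings.warn("no gene passes the fold-change/FDR stage; empty selection")
        return out
    keep_n = math.ceil(heterogeneity_quantile * k)
    passing_idx = np.flatnonzero(passing.to_numpy())
    order = passing_idx[
        np.argsort(out["heterogeneity"].to_numpy()[passing_idx], kind="stable")
    ]
    out.iloc[order[:keep_n], out.columns.get_loc("selected")] = True
    return out
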