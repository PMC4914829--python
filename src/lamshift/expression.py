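"""Microarray-style expression statistics.

Quantile normalization, empirical-Bayes moderated t/F statistics (gene-wise
variances shrunk toward a pooled prior estimated by moment matching on the
log sample variances), Benjamini-Hochberg FDR, and the call thresholds used
downstream: |log2 FC| > 0.5 at FDR <= 5%, plus a simple 1.4-fold
up/down/unchanged classification of condition means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .synthetic import ExprMatrix

log = logging.getLogger("lamshift")

__all__ = [
    "ExprMatrix",
    "DEResult",
    "quantile_normalize",
    "estimate_prior",
    "moderated_stat",
    "bh_fdr",
    "select_de",
    "fold_class",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-rank means.

    Each column's sorted values are replaced by the mean sorted profile
    across columns; ties receive the average of their quantile values.
    Idempotent, and a fixed point when columns already share a distribution.
    """
    if matrix.shape[1] < 2:
        log.warning("quantile_normalize: single sample, returning input")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    n = len(mean_sorted)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# moderated statistics


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one contrast."""

    table: pd.DataFrame  # gene_id index: log2fc, stat, df_total, p, (q, call)
    contrast: tuple[str, str]
    prior_df: float
    prior_var: float


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Under the scaled-F model s^2 ~ s0^2 * F(df, d0), log s^2 has variance
    psi'(df/2) + psi'(d0/2); d0 solves that by Newton iteration on the
    trigamma function, and s0^2 follows from the mean of log s^2. Returns
    d0 = inf when the observed spread is no larger than expected under a
    single common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e_z = z.mean()
    v_z = z.var(ddof=1)
    target = v_z - special.polygamma(1, df / 2.0)
    if target <= 0:
        d0 = np.inf
    else:
        # solve trigamma(d0/2) = target
        x = 0.5 + 1.0 / target  # good starting point: trigamma(y) ~ 1/y
        for _ in range(50):
            f = special.polygamma(1, x) - target
            fp = special.polygamma(2, x)
            step = f / fp
            x = max(x - step, 1e-6)
            if abs(step) < 1e-10:
                break
        d0 = 2.0 * x
    if np.isinf(d0):
        s0_log = e_z - special.digamma(df / 2.0) + np.log(df / 2.0)
    else:
        s0_log = (
            e_z
            - special.digamma(df / 2.0)
            + np.log(df / 2.0)
            + special.digamma(d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    return float(d0), float(np.exp(s0_log))


def moderated_stat(
    matrix: ExprMatrix,
    contrast: tuple[str, str] = ("MT", "MB"),
    prior: tuple[float, float] | None = None,
) -> DEResult:
    """Moderated two-group t statistics (limma-style) for contrast A - B.

    Gene-wise pooled variances s^2 with d residual df are shrunk toward the
    prior: s~^2 = (d0*s0^2 + d*s^2) / (d0 + d); t = log2fc / (s~ * c) is
    referred to a t distribution with d + d0 df. ``prior=(d0, s0^2)``
    overrides estimation; (0, anything) recovers the classical t.
    """
    a, b = contrast
    cols_a = matrix.samples(a)
    cols_b = matrix.samples(b)
    n1, n2 = len(cols_a), len(cols_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per compared condition")
    df = n1 + n2 - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    xa = matrix.data[cols_a].to_numpy(dtype=float)
    xb = matrix.data[cols_b].to_numpy(dtype=float)
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    ss = ((xa - ma[:, None]) ** 2).sum(axis=1) + ((xb - mb[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    if prior is None:
        d0, s02 = estimate_prior(s2, df)
    else:
        d0, s02 = prior
    if d0 == 0:
        s2_tilde = s2
        df_total = float(df)
    elif np.isinf(d0):
        s2_tilde = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s02 + df * s2) / (d0 + df)
        df_total = float(df + d0)
    lfc = ma - mb
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {"log2fc": lfc, "stat": t, "df_total": df_total, "p": p},
        index=matrix.data.index,
    )
    return DEResult(table, contrast, float(d0), float(s02))


def moderated_f(matrix: ExprMatrix, prior: tuple[float, float] | None = None) -> DEResult:
    """Moderated F across all conditions: between-group mean square over the
    shrunken variance, F(k-1, d + d0)."""
    groups = {}
    for s, c in matrix.conditions.items():
        groups.setdefault(c, []).append(s)
    k = len(groups)
    if k < 2 or any(len(cols) < 2 for cols in groups.values()):
        raise ValueError("need >= 2 conditions with >= 2 replicates each")
    X = [matrix.data[cols].to_numpy(dtype=float) for cols in groups.values()]
    ns = np.array([x.shape[1] for x in X])
    df = int(ns.sum() - k)
    means = np.column_stack([x.mean(axis=1) for x in X])
    grand = (means * ns).sum(axis=1) / ns.sum()
    msb = ((means - grand[:, None]) ** 2 * ns).sum(axis=1) / (k - 1)
    ss = sum(((x - x.mean(axis=1)[:, None]) ** 2).sum(axis=1) for x in X)
    s2 = ss / df
    d0, s02 = estimate_prior(s2, df) if prior is None else prior
    if d0 == 0:
        s2_tilde, df_total = s2, float(df)
    elif np.isinf(d0):
        s2_tilde, df_total = np.full_like(s2, s02), np.inf
    else:
        s2_tilde, df_total = (d0 * s02 + df * s2) / (d0 + df), float(df + d0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(s2_tilde > 0, msb / s2_tilde, 0.0)
    if np.isinf(df_total):
        p = stats.chi2.sf(F * (k - 1), k - 1)
    else:
        p = stats.f.sf(F, k - 1, df_total)
    table = pd.DataFrame(
        {"log2fc": np.nan, "stat": F, "df_total": df_total, "p": p},
        index=matrix.data.index,
    )
    return DEResult(table, ("F", "all"), float(d0), float(s02))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def select_de(
    deresult: DEResult, lfc_cut: float = 0.5, fdr_cut: float = 0.05
) -> DEResult:
    """Call up/down/nc: |log2fc| strictly above ``lfc_cut`` AND q <= fdr_cut."""
    table = deresult.table.copy()
    table["q"] = bh_fdr(table["p"].to_numpy())
    sig = (np.abs(table["log2fc"]) > lfc_cut) & (table["q"] <= fdr_cut)
    call = np.where(sig & (table["log2fc"] > 0), "up", "nc")
    call = np.where(sig & (table["log2fc"] < 0), "down", call)
    table["call"] = call
    return DEResult(table, deresult.contrast, deresult.prior_df, deresult.prior_var)


def fold_class(
    expr_mb_mean: np.ndarray,
    expr_mt_mean: np.ndarray,
    fold: float = 1.4,
    scale: str = "linear",
) -> np.ndarray:
    """Classify genes as down / nc / up by an at-least-``fold`` change of the
    MT/MB mean ratio (thresholds inclusive: exactly 1.4-fold counts)."""
    mb = np.asarray(expr_mb_mean, dtype=float)
    mt = np.asarray(expr_mt_mean, dtype=float)
    if scale == "linear":
        if np.any(mb <= 0) or np.any(mt <= 0):
            raise ValueError("linear means must be positive")
        ratio = mt / mb
    elif scale == "log2":
        ratio = np.exp2(mt - mb)
    else:
        raise ValueError("scale must be 'linear' or 'log2'")
    out = np.full(len(ratio), "nc", dtype=object)
    out[ratio <= 1.0 / fold] = "down"
    out[ratio >= fold] = "up"
    return out
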