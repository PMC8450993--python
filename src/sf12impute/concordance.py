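"""Concordance of imputed and true values via ICC(2,1).

The agreement between ground-truth scores and fills at the masked cells is
measured by the two-way random-effects, absolute-agreement, single-measures
intraclass correlation ICC(2,1) with k = 2 "raters" (truth, imputation):

    ICC(2,1) = (MSR - MSE) / (MSR + MSE + 2 (MSC - MSE) / n)

where MSR, MSC and MSE are the row (target), column (rater) and residual
mean squares of the two-way ANOVA.  Unlike Pearson's r it penalises mean
and scale disagreement; a constant imputation (item mean) scores exactly 0.
Replicate ICCs are averaged on the Fisher-Z scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imputers import ImputedDataset
from .instrument import ResponseMatrix

__all__ = [
    "icc_2_1",
    "fisher_z",
    "fisher_z_inverse",
    "fisher_mean",
    "evaluate_method",
    "summarize",
    "discrimination_accuracy_correlation",
]

_CLAMP = 1.0 - 1e-12


def icc_2_1(truth, fills) -> float:
    """ICC(2,1) between two aligned measurement vectors.

    Returns NaN when the two-way ANOVA denominator is zero (both columns
    constant); raises for fewer than 3 pairs.
    """
    x = np.asarray(truth, dtype=float)
    y = np.asarray(fills, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("truth and fills must be aligned 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("ICC(2,1) needs at least 3 pairs")
    ratings = np.column_stack([x, y])
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ssr = 2.0 * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((ratings - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / 1.0
    mse = sse / (n - 1)
    denom = msr + mse + 2.0 * (msc - mse) / n
    if abs(denom) < 1e-12 * max(1.0, abs(sst)):
        return float("nan")
    return float((msr - mse) / denom)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilising transform z = atanh(r)."""
    if not np.all(np.abs(r) < 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    return float(np.arctanh(r))


def fisher_z_inverse(z: float) -> float:
    return float(np.tanh(z))


def fisher_mean(rs) -> float:
    """Back-transformed mean of correlations on the Fisher-Z scale.

    Inputs are clamped to +/-(1 - 1e-12) so a replicate with perfect
    agreement keeps the mean finite.
    """
    rs = np.asarray(rs, dtype=float)
    if rs.size == 0:
        raise ValueError("fisher_mean of an empty collection")
    if np.any(np.abs(rs) > 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    clamped = np.clip(rs, -_CLAMP, _CLAMP)
    return float(np.tanh(np.mean(np.arctanh(clamped))))


def evaluate_method(
    imp: ImputedDataset,
    base: ResponseMatrix | None = None,
    mi_policy: str = "per_imputation_mean_z",
) -> float:
    """One replicate's ICC(2,1) between truth and fills at the masked cells.

    Multiple-imputation results are pooled per ``mi_policy``: compute the
    ICC per imputation and average on the Fisher-Z scale (default), or
    average the m fills per cell first (``'average_fills'``).
    """
    if base is None:
        base = imp.source.base
    if base is not imp.source.base:
        truth = base.data.loc[imp.source.mask, imp.source.item].to_numpy(float)
    else:
        truth = imp.source.truth
    fills = imp.fill_matrix()
    if fills.shape[0] != truth.size or np.isnan(fills).any():
        raise ValueError("fills do not align with the masked cells")
    if fills.shape[1] == 1:
        return icc_2_1(truth, fills[:, 0])
    if mi_policy == "per_imputation_mean_z":
        iccs = [icc_2_1(truth, fills[:, k]) for k in range(fills.shape[1])]
        iccs = [v for v in iccs if np.isfinite(v)]
        if not iccs:
            return float("nan")
        return fisher_mean(iccs)
    if mi_policy == "average_fills":
        return icc_2_1(truth, fills.mean(axis=1))
    raise ValueError(f"unknown mi_policy {mi_policy!r}")


def summarize(long: pd.DataFrame) -> pd.DataFrame:
    """Distribution of replicate ICCs per (item, method).

    ``long`` needs columns item, method, replicate, icc.  Min, max, median
    and SD are computed on the raw ICC scale; the mean is a Fisher-Z mean.
    Undefined (NaN) ICCs are dropped and counted in ``n_dropped``.
    """
    required = {"item", "method", "replicate", "icc"}
    if not required <= set(long.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    rows = []
    for (item, method), grp in long.groupby(["item", "method"], sort=False):
        vals = grp["icc"].to_numpy(float)
        ok = vals[np.isfinite(vals)]
        if ok.size == 0:
            raise ValueError(
                f"no defined ICCs for ({item}, {method}); cannot summarize"
            )
        rows.append({
            "item": item,
            "method": method,
            "min": ok.min(),
            "max": ok.max(),
            "median": float(np.median(ok)),
            "mean": fisher_mean(ok),
            "sd": float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0,
            "n_replicates": int(ok.size),
            "n_dropped": int(vals.size - ok.size),
        })
    return pd.DataFrame(rows)


def discrimination_accuracy_correlation(item_totals, mean_iccs) -> float:
    """Pearson r of Fisher-Z item-total correlations with Fisher-Z mean ICCs.

    Quantifies how strongly an item's discriminatory power predicts how
    accurately it can be imputed, across the 12 items.
    """
    it = pd.Series(item_totals, dtype=float)
    icc = pd.Series(mean_iccs, dtype=float)
    it, icc = it.align(icc, join="inner")
    if len(it) < 3:
        raise ValueError("need at least 3 aligned item pairs")
    if not (np.isfinite(it).all() and np.isfinite(icc).all()):
        raise ValueError("inputs must be finite")
    zx = np.arctanh(np.clip(it.to_numpy(), -_CLAMP, _CLAMP))
    zy = np.arctanh(np.clip(icc.to_numpy(), -_CLAMP, _CLAMP))
    if np.ptp(zx) == 0 or np.ptp(zy) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.corrcoef(zx, zy)[0, 1])
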