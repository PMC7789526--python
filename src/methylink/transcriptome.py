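"""Gene-level differential expression and expression binning.

A negative-binomial Wald test on a two-group design: median-of-ratios size
factors, method-of-moments gene dispersions shrunk toward a parametric
mean-dispersion trend (alpha(mu) = a0 + a1/mu), log2 fold change from
normalized group means with a 0.5 pseudo-count, and a delta-method standard
error. Differential calls use strict thresholds FC > fc_up or FC < fc_down
with raw Wald p < alpha; a Benjamini-Hochberg column is reported alongside
but plays no part in the calls.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

LOG2 = np.log(2.0)

#: blend weight given to the trend (vs. the per-gene moment estimate)
TREND_WEIGHT = 0.6


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer count matrix from TSV (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (geometric-mean reference).

    Only genes with strictly positive counts in every sample enter the
    median; if no such gene exists, falls back to total-count scaling with
    a logged warning.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if positive.any():
        logx = np.log(x[positive])
        ref = logx.mean(axis=1, keepdims=True)  # log geometric mean
        sf = np.exp(np.median(logx - ref, axis=0))
    else:
        log.warning("no all-positive gene; using total-count size factors")
        tot = x.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(np.maximum(tot, 1.0))))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _fit_dispersion_trend(mean: np.ndarray, alpha_raw: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu to bin means of raw moment estimates.

    Raw (possibly negative, untruncated) moment estimates are averaged in
    log-spaced mean bins to stay unbiased, then a0, a1 >= 0 are obtained by
    non-negative least squares on the bin summaries.
    """
    ok = np.isfinite(alpha_raw) & (mean > 0)
    if ok.sum() < 10:
        a = float(np.nanmean(np.clip(alpha_raw[ok], 0, None))) if ok.any() else 0.0
        return max(a, 1e-8), 0.0
    m, a = mean[ok], alpha_raw[ok]
    edges = np.quantile(np.log(m), np.linspace(0, 1, 21))
    which = np.clip(np.searchsorted(edges, np.log(m), "right") - 1, 0, 19)
    bm, ba = [], []
    for b in range(20):
        sel = which == b
        if sel.sum() >= 5:
            bm.append(m[sel].mean())
            ba.append(a[sel].mean())
    if len(bm) < 2:
        return max(float(np.mean(a)), 1e-8), 0.0
    A = np.column_stack([np.ones(len(bm)), 1.0 / np.asarray(bm)])
    coef, _ = optimize.nnls(A, np.clip(np.asarray(ba), 0, None))
    return max(float(coef[0]), 1e-8), float(coef[1])


def nb_wald_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    case: str,
    control: str,
) -> pd.DataFrame:
    """Per-gene NB Wald test of case vs control.

    Returns a frame indexed by gene_id with columns baseMean, mean_case,
    mean_control, log2fc, fc, lfcSE, stat, p, padj, alpha. All-zero genes
    get NaN p and are excluded from downstream calling. Each group needs at
    least two samples.
    """
    case_samples = [s for s in counts.columns if groups.get(s) == case]
    ctrl_samples = [s for s in counts.columns if groups.get(s) == control]
    if len(case_samples) < 2 or len(ctrl_samples) < 2:
        raise ValueError("need >=2 samples per group")
    sf = size_factors(counts)
    norm = counts / sf
    xc = norm[case_samples].to_numpy(dtype=float)
    xk = norm[ctrl_samples].to_numpy(dtype=float)
    n1, n2 = xc.shape[1], xk.shape[1]
    m1 = xc.mean(axis=1)
    m2 = xk.mean(axis=1)
    base_mean = norm.mean(axis=1).to_numpy()

    # method-of-moments dispersion, pooled within-group, left untruncated
    s2 = ((xc - m1[:, None]) ** 2).sum(axis=1) + ((xk - m2[:, None]) ** 2).sum(axis=1)
    s2 = s2 / (n1 + n2 - 2)
    xi = float(np.mean(1.0 / sf.to_numpy()))  # Poisson part of Var(K/sf)
    mbar = (m1 + m2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_raw = (s2 - mbar * xi) / mbar**2
    a0, a1 = _fit_dispersion_trend(mbar, alpha_raw)
    with np.errstate(divide="ignore"):
        alpha_trend = a0 + a1 / np.maximum(mbar, 1e-8)
    alpha = TREND_WEIGHT * alpha_trend + (1 - TREND_WEIGHT) * np.clip(
        np.nan_to_num(alpha_raw, nan=0.0), 0.0, None
    )

    mu1 = m1 + 0.5
    mu2 = m2 + 0.5
    log2fc = np.log2(mu1 / mu2)
    invsf_c = (1.0 / sf[case_samples].to_numpy())
    invsf_k = (1.0 / sf[ctrl_samples].to_numpy())
    v1 = (mu1[:, None] * invsf_c[None, :] + alpha[:, None] * mu1[:, None] ** 2).sum(axis=1) / n1**2
    v2 = (mu2[:, None] * invsf_k[None, :] + alpha[:, None] * mu2[:, None] ** 2).sum(axis=1) / n2**2
    se = np.sqrt(v1 / mu1**2 + v2 / mu2**2) / LOG2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    p = 2 * stats.norm.sf(np.abs(stat))
    all_zero = counts.sum(axis=1).to_numpy() == 0
    p = np.where(all_zero, np.nan, p)
    stat = np.where(all_zero, np.nan, stat)
    padj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        padj[ok] = stats.false_discovery_control(p[ok])
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "mean_case": m1,
            "mean_control": m2,
            "log2fc": log2fc,
            "fc": 2.0**log2fc,
            "lfcSE": se,
            "stat": stat,
            "p": p,
            "padj": padj,
            "alpha": alpha,
        },
        index=counts.index,
    )


def call_degs(
    results: pd.DataFrame,
    fc_up: float = 1.5,
    fc_down: float = 0.67,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Label genes up/down/none with strict fold-change and p thresholds.

    up requires fc > fc_up and p < alpha; down requires fc < fc_down and
    p < alpha; everything else (including fc exactly at a threshold, or a
    missing p) is none.
    """
    fc = results["fc"]
    p = results["p"]
    call = np.where(
        (fc > fc_up) & (p < alpha), "up",
        np.where((fc < fc_down) & (p < alpha), "down", "none"),
    )
    call = np.where(p.isna(), "none", call)
    out = results.copy()
    out["call"] = call
    return out


def bin_expression(
    counts: pd.DataFrame, sf: pd.Series | None = None
) -> pd.Series:
    """Partition genes into none/low/medium/high expression bins.

    "none" means zero raw counts in every sample; the remaining genes are
    ranked by mean normalized count and split into near-equal tertiles
    (sizes differing by at most one), ties broken by gene id order.
    """
    if sf is None:
        sf = size_factors(counts)
    norm_mean = (counts / sf).mean(axis=1)
    zero = counts.sum(axis=1) == 0
    bins = pd.Series("none", index=counts.index, name="bin")
    nz = counts.index[~zero]
    order = (
        norm_mean.loc[nz].to_frame("m").assign(gid=nz).sort_values(["m", "gid"]).index
    )
    parts = np.array_split(np.asarray(order), 3)
    for label, part in zip(("low", "medium", "high"), parts):
        bins.loc[part] = label
    return bins
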