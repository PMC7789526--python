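"""Replicate-aware two-group differential methylation testing and DMR calling.

Per cytosine, group methylation proportions are smoothed along the
chromosome (coverage-weighted moving average over a ±span/2 window), a
beta-binomial dispersion is estimated from replicate variation and shrunk
toward the genome-wide median, and a Wald statistic compares the two group
proportions with a variance that accounts for the overdispersion:

    var_g = mu_g (1 - mu_g) * (sum_n + phi * sum_n(n-1)) / sum_n^2

where the sums run over the per-replicate coverages of every site in the
smoothing window (for an isolated site with replicate coverages n_i this is
sum_i mu(1-mu)(1+(n_i-1)phi)/n_i / R^2). Significant same-sign sites are
merged into DMRs. Direction is case minus control: hyper means the case
group is more methylated.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methylome import CONTEXTS, CytosineTable

log = logging.getLogger(__name__)

MU_CLAMP = 1e-6

#: DMR length histogram bin edges (bp), last bin open-ended
LENGTH_BINS = (50, 100, 150, 200, 250, 300, 400)


def shrinkage_weight(coverage, cov0: float = 50.0):
    """Weight given to the site-level dispersion estimate: cov/(cov+cov0)."""
    coverage = np.asarray(coverage, dtype=float)
    w = coverage / (coverage + cov0)
    return float(w) if w.ndim == 0 else w


def smooth_proportions(
    pos0: np.ndarray,
    meth_pooled: np.ndarray,
    total_pooled: np.ndarray,
    span_bp: int = 500,
) -> np.ndarray:
    """Coverage-weighted moving-average methylation proportion per site.

    Sites must be position-sorted within one chromosome. The window is
    positions within ±span_bp/2 of each site; the weighted mean of site MLs
    with coverage weights equals the ratio of window-summed counts. Sites
    whose window has zero total coverage get NaN. Result clamped to
    [1e-6, 1-1e-6].
    """
    if np.any(np.diff(pos0) < 0):
        raise ValueError("smooth_proportions requires position-sorted sites")
    half = span_bp / 2.0
    lo = np.searchsorted(pos0, pos0 - half, "left")
    hi = np.searchsorted(pos0, pos0 + half, "right")
    cm = np.concatenate([[0], np.cumsum(meth_pooled, dtype=float)])
    ct = np.concatenate([[0], np.cumsum(total_pooled, dtype=float)])
    wm = cm[hi] - cm[lo]
    wt = ct[hi] - ct[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(wt > 0, wm / np.maximum(wt, 1.0), np.nan)
    return np.clip(mu, MU_CLAMP, 1 - MU_CLAMP)  # NaN propagates through clip


def _window_sums(pos0: np.ndarray, values: np.ndarray, span_bp: int) -> np.ndarray:
    half = span_bp / 2.0
    lo = np.searchsorted(pos0, pos0 - half, "left")
    hi = np.searchsorted(pos0, pos0 + half, "right")
    c = np.concatenate([[0], np.cumsum(values, dtype=float)])
    return c[hi] - c[lo]


def estimate_dispersion(
    table: CytosineTable,
    groups: Mapping[str, str],
    case: str,
    control: str,
    cov0: float = 50.0,
) -> np.ndarray:
    """Per-site beta-binomial dispersion phi, shrunk toward the median.

    Method of moments from replicate proportion variation within each group
    (sample variance of replicate MLs vs. the binomial expectation), then a
    coverage-weighted pull toward the genome-wide median phi with weight
    w = cov/(cov+cov0) on the site estimate. Falls back to the pooled
    median when fewer than two covered replicates exist in both groups.
    """
    raw = np.full(len(table), np.nan)
    k = np.zeros(len(table))
    for label in (case, control):
        cols = table.sample_columns([s for s, g in groups.items() if g == label])
        if len(cols) < 2:
            log.warning("group %s has <2 replicates; its dispersion evidence is skipped", label)
            continue
        m = table.meth[:, cols].astype(float)
        t = table.total[:, cols].astype(float)
        covered = t > 0
        r = covered.sum(axis=1)
        ok = r >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(covered, m / np.maximum(t, 1.0), np.nan)
        pbar = np.nanmean(np.where(covered, p, np.nan), axis=1)
        nbar = np.where(r > 0, t.sum(axis=1) / np.maximum(r, 1), np.nan)
        dev = np.where(covered, p - pbar[:, None], 0.0)
        s2 = np.where(ok, (dev**2).sum(axis=1) / np.maximum(r - 1, 1), np.nan)
        denom = pbar * (1 - pbar)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi_g = (s2 / denom - 1.0 / nbar) / (1.0 - 1.0 / nbar)
        phi_g = np.where(ok & (denom > 0) & (nbar > 1), phi_g, np.nan)
        phi_g = np.clip(phi_g, 0.0, 0.99)
        have = ~np.isnan(phi_g)
        raw = np.where(have & np.isnan(raw), 0.0, raw)
        raw[have] += phi_g[have]
        k[have] += 1
    with np.errstate(invalid="ignore"):
        raw = np.where(k > 0, raw / np.maximum(k, 1), np.nan)
    defined = ~np.isnan(raw)
    if not defined.any():
        log.warning("no site had >=2 covered replicates; dispersion set to 0")
        return np.zeros(len(table))
    median = float(np.median(raw[defined]))
    cov = table.total.sum(axis=1) / max(len(table.samples), 1)
    w = shrinkage_weight(cov, cov0)
    phi = np.where(defined, w * np.where(defined, raw, 0.0) + (1 - w) * median, median)
    return np.clip(phi, 0.0, 0.99)


def wald_from_window_counts(mu1, mu2, phi, a1, b1, a2, b2):
    """Wald statistic and two-sided normal p from window-pooled counts.

    ``a_g`` is the window sum of per-replicate coverages, ``b_g`` the window
    sum of n(n-1); var_g = mu_g(1-mu_g)(a_g + phi*b_g)/a_g^2.
    """
    mu1 = np.asarray(mu1, float)
    mu2 = np.asarray(mu2, float)
    a1 = np.asarray(a1, float)
    a2 = np.asarray(a2, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        c1 = (a1 + phi * np.asarray(b1, float)) / np.maximum(a1, 1) ** 2
        c2 = (a2 + phi * np.asarray(b2, float)) / np.maximum(a2, 1) ** 2
        # E[mu_hat(1-mu_hat)] = mu(1-mu)(1-c): undo the plug-in shrinkage
        v = (
            mu1 * (1 - mu1) * c1 / np.clip(1 - c1, 0.5, 1.0)
            + mu2 * (1 - mu2) * c2 / np.clip(1 - c2, 0.5, 1.0)
        )
    diff = mu1 - mu2
    ok = (a1 > 0) & (a2 > 0) & np.isfinite(v) & (v > 0)
    stat = np.where(ok, diff / np.sqrt(np.where(ok, v, 1.0)), 0.0)
    p = np.where(ok, 2 * stats.norm.sf(np.abs(stat)), 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return stat, p


def test_sites(
    table: CytosineTable,
    groups: Mapping[str, str],
    case: str,
    control: str,
    context: str | None = "CpG",
    span_bp: int = 500,
    cov0: float = 50.0,
) -> pd.DataFrame:
    """Smoothed beta-binomial Wald test at every site of one context.

    Returns a frame sorted by (chrom, pos) with columns chrom, pos, strand,
    context, mu_case, mu_control, diff, phi, stat, p.
    """
    sub = table.subset_context(context) if context is not None else table
    if not sub.is_sorted():
        raise ValueError("test_sites requires (chrom,pos)-sorted input")
    phi = estimate_dispersion(sub, groups, case, control, cov0=cov0)
    pooled = sub.group_pooled({s: g for s, g in groups.items() if g in (case, control)})
    m1, t1 = pooled[case]
    m2, t2 = pooled[control]
    cols1 = sub.sample_columns([s for s, g in groups.items() if g == case])
    cols2 = sub.sample_columns([s for s, g in groups.items() if g == control])
    n1 = sub.total[:, cols1].astype(float)
    n2 = sub.total[:, cols2].astype(float)
    bsite1 = (n1 * (n1 - 1)).sum(axis=1)
    bsite2 = (n2 * (n2 - 1)).sum(axis=1)
    mu1 = np.full(len(sub), np.nan)
    mu2 = np.full(len(sub), np.nan)
    a1 = np.zeros(len(sub))
    a2 = np.zeros(len(sub))
    b1 = np.zeros(len(sub))
    b2 = np.zeros(len(sub))
    for chrom, sl in sub.chrom_slices().items():
        p0 = sub.pos0[sl]
        mu1[sl] = smooth_proportions(p0, m1[sl], t1[sl], span_bp)
        mu2[sl] = smooth_proportions(p0, m2[sl], t2[sl], span_bp)
        a1[sl] = _window_sums(p0, t1[sl], span_bp)
        a2[sl] = _window_sums(p0, t2[sl], span_bp)
        b1[sl] = _window_sums(p0, bsite1[sl], span_bp)
        b2[sl] = _window_sums(p0, bsite2[sl], span_bp)
    stat, p = wald_from_window_counts(
        np.nan_to_num(mu1, nan=0.5), np.nan_to_num(mu2, nan=0.5), phi, a1, b1, a2, b2
    )
    diff = mu1 - mu2
    out = sub.sites.copy()
    out["mu_case"] = mu1
    out["mu_control"] = mu2
    out["diff"] = diff
    out["phi"] = phi
    out["stat"] = stat
    out["p"] = p
    return out


def call_dmrs(
    site_results: pd.DataFrame,
    p_thresh: float = 1e-5,
    min_len: int = 50,
    min_sites: int = 3,
    merge_gap: int = 100,
    min_frac_sig: float = 0.5,
) -> pd.DataFrame:
    """Merge significant same-sign sites into differentially methylated regions.

    Candidate regions are maximal runs of significant (p < p_thresh) sites
    of one context and one difference sign, with at most ``merge_gap`` bp
    between consecutive significant sites. A candidate spans from its first
    to its last significant site and is kept when its length is >= min_len,
    it contains >= min_sites same-context sites, and the significant
    fraction of those sites is >= min_frac_sig. Runs of opposite sign never
    merge. Returns columns chrom, start, end, context, n_sites, n_sig,
    mean_diff, direction, area_stat, length.
    """
    dmrs = []
    for (chrom, context), grp in site_results.groupby(["chrom", "context"], observed=True, sort=True):
        grp = grp.sort_values("pos")
        pos0 = grp["pos"].to_numpy() - 1
        p = grp["p"].to_numpy()
        diff = grp["diff"].to_numpy()
        stat = grp["stat"].to_numpy()
        sig = (p < p_thresh) & np.isfinite(diff) & (diff != 0)
        sig_idx = np.flatnonzero(sig)
        if len(sig_idx) == 0:
            continue
        runs: list[list[int]] = [[sig_idx[0]]]
        for i in sig_idx[1:]:
            j = runs[-1][-1]
            same_sign = np.sign(diff[i]) == np.sign(diff[j])
            if same_sign and pos0[i] - pos0[j] <= merge_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            start = int(pos0[run[0]])
            end = int(pos0[run[-1]]) + 1
            length = end - start
            members = (pos0 >= start) & (pos0 < end)
            n_sites = int(members.sum())
            n_sig = len(run)
            if length < min_len or n_sites < min_sites:
                continue
            if n_sig / n_sites < min_frac_sig:
                continue
            mean_diff = float(np.nanmean(diff[members]))
            dmrs.append(
                (chrom, start, end, context, n_sites, n_sig, mean_diff,
                 "hyper" if mean_diff > 0 else "hypo",
                 float(stat[run].sum()), length)
            )
    return pd.DataFrame(
        dmrs,
        columns=["chrom", "start", "end", "context", "n_sites", "n_sig",
                 "mean_diff", "direction", "area_stat", "length"],
    )


def length_histogram(lengths: Sequence[int]) -> list[int]:
    """Counts in bins [50,100),[100,150),[150,200),[200,250),[250,300),[300,400),[400,inf)."""
    edges = list(LENGTH_BINS) + [np.inf]
    counts = [0] * (len(edges) - 1)
    for L in lengths:
        for i in range(len(counts)):
            if edges[i] <= L < edges[i + 1]:
                counts[i] += 1
                break
    return counts


def summarize_dmrs(
    dmrs: pd.DataFrame, features: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame | list[int]]:
    """Length histogram, per-chromosome and hyper/hypo counts, feature counts.

    Per-feature counts are multi-assigned (a DMR overlapping exon and
    intron counts once in each), so they may exceed the DMR total; all
    other summaries partition the DMR set.
    """
    out: dict[str, pd.DataFrame | list[int]] = {}
    out["length_hist"] = length_histogram(dmrs["length"].tolist())
    out["per_chromosome"] = (
        dmrs.groupby(["chrom", "direction"], observed=True).size().rename("n").reset_index()
    )
    out["direction"] = dmrs.groupby("direction", observed=True).size().rename("n").reset_index()
    if features is not None:
        from .annotation import FeatureIndex, assign_intervals

        hits = assign_intervals(dmrs[["chrom", "start", "end"]], FeatureIndex(features))
        if len(hits):
            hits = hits.drop_duplicates(["query_index", "feature"])
            dirs = dmrs["direction"].reindex(hits["query_index"]).to_numpy()
            hits = hits.assign(direction=dirs)
            out["per_feature"] = (
                hits.groupby(["feature", "direction"], observed=True).size().rename("n").reset_index()
            )
        else:
            out["per_feature"] = pd.DataFrame(columns=["feature", "direction", "n"])
    return out


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6+ DMR output: name=context, score=floor(1000*|mean_diff|)."""
    with open(path, "w") as fh:
        for r in dmrs.itertuples(index=False):
            score = int(np.floor(1000 * abs(r.mean_diff)))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tm{r.context}\t{score}\t."
                f"\t{r.n_sites}\t{r.mean_diff:.6f}\t{r.direction}\t{r.area_stat:.4f}\n"
            )
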