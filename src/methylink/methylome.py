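"""Methylation levels at site, window, feature, and metagene resolution.

The elementary statistic everywhere is the pooled methylation level
ML = reads(mC) / (reads(mC) + reads(umC)); every window/feature/genome-wide
summary is a ratio of summed counts, never a mean of per-site ratios.
Zero-coverage entities are reported as missing (NaN), never as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel

log = logging.getLogger(__name__)

CONTEXTS = ("CpG", "CHG", "CHH")

CX_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context"]


class MethylationError(ValueError):
    """Invalid methylation counts (e.g. methylated > total)."""


def site_methylation_level(count_methylated, count_total):
    """ML of a cytosine: methylated / total; NaN when total is 0.

    Accepts scalars or numpy arrays. Raises :class:`MethylationError` if a
    methylated count exceeds its total.
    """
    m = np.asarray(count_methylated, dtype=float)
    t = np.asarray(count_total, dtype=float)
    if np.any(m > t):
        bad = int(np.argmax(np.asarray(m > t).ravel()))
        raise MethylationError(
            f"methylated count exceeds total at flat index {bad} "
            f"({m.ravel()[bad]:.0f} > {t.ravel()[bad]:.0f})"
        )
    if np.any(m < 0):
        raise MethylationError("negative methylated count")
    with np.errstate(invalid="ignore", divide="ignore"):
        ml = np.where(t > 0, m / np.where(t > 0, t, 1.0), np.nan)
    if np.ndim(count_methylated) == 0 and np.ndim(count_total) == 0:
        return float(ml)
    return ml


@dataclass
class CytosineTable:
    """Cytosine sites × samples matrix of methylated/total read counts.

    ``sites`` has columns chrom, pos (1-based), strand, context and is
    sorted by (chrom, pos, strand); ``meth``/``total`` are int arrays of
    shape (n_sites, n_samples) aligned to ``sites`` rows and ``samples``.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        n = len(self.sites)
        if self.meth.shape != (n, len(self.samples)) or self.total.shape != self.meth.shape:
            raise MethylationError("count matrices not aligned to sites/samples")
        if np.any(self.meth > self.total):
            i = int(np.argmax(np.any(self.meth > self.total, axis=1)))
            row = self.sites.iloc[i]
            raise MethylationError(
                f"methylated > total at {row['chrom']}:{row['pos']}"
            )

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def pos0(self) -> np.ndarray:
        """0-based site coordinates."""
        return self.sites["pos"].to_numpy() - 1

    def is_sorted(self) -> bool:
        s = self.sites
        key = pd.MultiIndex.from_arrays([s["chrom"], s["pos"], s["strand"]])
        return key.is_monotonic_increasing

    def subset_context(self, context: str) -> "CytosineTable":
        mask = (self.sites["context"] == context).to_numpy()
        return CytosineTable(
            self.sites.loc[mask].reset_index(drop=True),
            self.meth[mask], self.total[mask], list(self.samples),
        )

    def subset_rows(self, mask: np.ndarray) -> "CytosineTable":
        return CytosineTable(
            self.sites.loc[mask].reset_index(drop=True),
            self.meth[mask], self.total[mask], list(self.samples),
        )

    def sample_columns(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.samples.index(s) for s in names]
        return np.asarray(idx, dtype=int)

    def group_pooled(self, groups: Mapping[str, str]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-group (Σ methylated, Σ total) arrays over that group's samples."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for label in dict.fromkeys(groups.values()):
            cols = self.sample_columns([s for s, g in groups.items() if g == label])
            out[label] = (self.meth[:, cols].sum(axis=1), self.total[:, cols].sum(axis=1))
        return out

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice per chromosome (table must be sorted)."""
        chroms = self.sites["chrom"].to_numpy()
        out: dict[str, slice] = {}
        if len(chroms) == 0:
            return out
        change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        bounds = np.concatenate([[0], change, [len(chroms)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            out[str(chroms[a])] = slice(int(a), int(b))
        return out


# ---------------------------------------------------------------------------
# CX-report IO
# ---------------------------------------------------------------------------

def read_cx_report(path: str | Path) -> pd.DataFrame:
    """Read one Bismark-style cytosine report (TSV, no header).

    Columns: chrom, pos (1-based), strand, count methylated, count
    unmethylated, context (CpG|CHG|CHH).
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=CX_COLUMNS,
        dtype={"chrom": str, "pos": np.int64, "strand": str,
               "meth": np.int64, "unmeth": np.int64, "context": str},
    )
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise MethylationError(
            f"{path}: unknown context value {df.loc[bad, 'context'].iloc[0]!r}"
        )
    if (df["meth"] < 0).any() or (df["unmeth"] < 0).any():
        raise MethylationError(f"{path}: negative counts")
    return df


def write_cx_report(df: pd.DataFrame, path: str | Path) -> None:
    df[CX_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def load_cx_tables(sample_paths: Mapping[str, str | Path]) -> CytosineTable:
    """Merge per-sample CX reports into one :class:`CytosineTable`.

    Sites are outer-joined on (chrom, pos, strand, context); a site absent
    from a sample gets zero counts there. Rows come out sorted.
    """
    key = ["chrom", "pos", "strand", "context"]
    samples = list(sample_paths)
    frames = []
    for s in samples:
        df = read_cx_report(sample_paths[s]).set_index(key)
        df["total"] = df["meth"] + df["unmeth"]
        frames.append(df[["meth", "total"]])
    merged = pd.concat(frames, axis=1, keys=samples, join="outer").fillna(0)
    merged = merged.sort_index(level=["chrom", "pos", "strand"])
    sites = merged.index.to_frame(index=False)[["chrom", "pos", "strand", "context"]]
    meth = np.column_stack(
        [merged[(s, "meth")].to_numpy(dtype=np.int64) for s in samples]
    )
    total = np.column_stack(
        [merged[(s, "total")].to_numpy(dtype=np.int64) for s in samples]
    )
    return CytosineTable(sites, meth, total, samples)


def find_cx_dir(cx_dir: str | Path, suffix: str = ".cx.tsv") -> dict[str, Path]:
    """Map sample name -> CX report path for every ``*<suffix>`` file in a dir."""
    cx_dir = Path(cx_dir)
    return {p.name[: -len(suffix)]: p for p in sorted(cx_dir.glob(f"*{suffix}"))}


# ---------------------------------------------------------------------------
# pooled summaries
# ---------------------------------------------------------------------------

def genome_wide_level(
    table: CytosineTable, groups: Mapping[str, str], context: str = "CpG"
) -> dict[str, float]:
    """Pooled ML over all covered sites of one context, per group."""
    sub = table.subset_context(context)
    out: dict[str, float] = {}
    for label, (m, t) in sub.group_pooled(groups).items():
        T = int(t.sum())
        out[label] = float(m.sum()) / T if T > 0 else float("nan")
    return out


def window_methylation(
    table: CytosineTable,
    groups: Mapping[str, str],
    window_bp: int = 10_000,
    step_bp: int | None = None,
    context: str = "CpG",
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Pooled ML in tiling (or stepping) genomic windows, per group.

    Windows tile each chromosome from 0; the last window may be short when
    ``chrom_sizes`` is given, otherwise windows extend to cover the last
    site. Windows without coverage carry NaN. Raises on unsorted input.
    """
    if not table.is_sorted():
        raise MethylationError("window_methylation requires (chrom,pos)-sorted sites")
    step = window_bp if step_bp is None else step_bp
    if step <= 0 or window_bp <= 0:
        raise ValueError("window and step must be positive")
    sub = table.subset_context(context)
    pooled = sub.group_pooled(groups)
    labels = list(pooled)
    rows = []
    for chrom, sl in sub.chrom_slices().items():
        p0 = sub.pos0[sl]
        length = (
            int(chrom_sizes[chrom]) if chrom_sizes is not None
            else (int(p0.max()) + 1 if len(p0) else 0)
        )
        start = 0
        while start < length:
            end = min(start + window_bp, length)
            lo = np.searchsorted(p0, start, "left")
            hi = np.searchsorted(p0, end, "left")
            for label in labels:
                m, t = pooled[label]
                T = int(t[sl][lo:hi].sum())
                ml = float(m[sl][lo:hi].sum()) / T if T > 0 else float("nan")
                rows.append((chrom, start, end, context, label, ml, T))
            start += step
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "context", "group", "ml", "coverage"]
    )


def feature_methylation(
    table: CytosineTable,
    groups: Mapping[str, str],
    features: pd.DataFrame,
    contexts: Sequence[str] = CONTEXTS,
) -> pd.DataFrame:
    """Pooled ML per (feature class, group, context).

    A site inside intervals of several classes contributes to each class;
    classes with no covered site report NaN.
    """
    rows = []
    for context in contexts:
        sub = table.subset_context(context)
        pooled = sub.group_pooled(groups)
        slices = sub.chrom_slices()
        p0 = sub.pos0
        for cls, grp in features.groupby("feature", observed=True):
            mask = np.zeros(len(sub), dtype=bool)
            for chrom, cgrp in grp.groupby("chrom", observed=True):
                sl = slices.get(str(chrom))
                if sl is None:
                    continue
                starts = np.sort(cgrp["start"].to_numpy())
                ends = np.sort(cgrp["end"].to_numpy())
                # merged-interval membership: more intervals started than ended
                pos = p0[sl]
                inside = (
                    np.searchsorted(starts, pos, "right")
                    > np.searchsorted(ends, pos, "right")
                )
                mask[sl] |= inside
            for label, (m, t) in pooled.items():
                T = int(t[mask].sum())
                ml = float(m[mask].sum()) / T if T > 0 else float("nan")
                rows.append((cls, label, context, ml, T))
    return pd.DataFrame(rows, columns=["feature", "group", "context", "ml", "coverage"])


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def metagene_profile(
    table: CytosineTable,
    groups: Mapping[str, str],
    genes: Iterable[GeneModel],
    context: str = "CpG",
    n_body_bins: int = 60,
    flank_bp: int = 2000,
    flank_bin_bp: int = 100,
) -> pd.DataFrame:
    """Coverage-pooled methylation profile across scaled gene bodies ± flanks.

    The profile has ``flank_bp/flank_bin_bp`` upstream bins (absolute
    scale), ``n_body_bins`` body bins (each gene's body scaled to fit), and
    the same number of downstream bins; minus-strand genes are mirrored so
    bin 0 is always the 5'-most. Genes shorter than ``n_body_bins`` bp are
    excluded with a log entry. Returns one row per (bin, group): columns
    bin, segment, group, context, ml, coverage.
    """
    n_flank_bins = flank_bp // flank_bin_bp
    n_bins = 2 * n_flank_bins + n_body_bins
    sub = table.subset_context(context)
    pooled = sub.group_pooled(groups)
    labels = list(pooled)
    slices = sub.chrom_slices()
    p0_all = sub.pos0
    msum = {g: np.zeros(n_bins) for g in labels}
    tsum = {g: np.zeros(n_bins) for g in labels}
    n_used = 0
    for gene in genes:
        body = gene.length
        if body < n_body_bins:
            log.warning("metagene: %s shorter than %d bp, excluded", gene.gene_id, n_body_bins)
            continue
        sl = slices.get(gene.chrom)
        if sl is None:
            continue
        pos = p0_all[sl]
        lo = np.searchsorted(pos, gene.start - flank_bp, "left")
        hi = np.searchsorted(pos, gene.end + flank_bp, "left")
        if hi <= lo:
            continue
        x = pos[lo:hi]
        # signed 5'->3' offset from the start of the upstream flank
        if gene.strand == "+":
            s = x - (gene.start - flank_bp)
        else:
            s = (gene.end + flank_bp - 1) - x
        valid = (s >= 0) & (s < 2 * flank_bp + body)
        s = s[valid]
        binidx = np.empty(len(s), dtype=int)
        up = s < flank_bp
        down = s >= flank_bp + body
        mid = ~up & ~down
        binidx[up] = s[up] // flank_bin_bp
        binidx[mid] = n_flank_bins + ((s[mid] - flank_bp) * n_body_bins) // body
        binidx[down] = (
            n_flank_bins + n_body_bins + (s[down] - flank_bp - body) // flank_bin_bp
        )
        rows = np.arange(sl.start + lo, sl.start + hi)[valid]
        for label in labels:
            m, t = pooled[label]
            np.add.at(msum[label], binidx, m[rows])
            np.add.at(tsum[label], binidx, t[rows])
        n_used += 1
    if n_used == 0:
        log.warning("metagene: no usable genes")
    segs = (
        ["upstream"] * n_flank_bins + ["body"] * n_body_bins + ["downstream"] * n_flank_bins
    )
    out = []
    for label in labels:
        with np.errstate(invalid="ignore", divide="ignore"):
            ml = np.where(tsum[label] > 0, msum[label] / np.maximum(tsum[label], 1), np.nan)
        for b in range(n_bins):
            out.append((b, segs[b], label, context, float(ml[b]), int(tsum[label][b])))
    return pd.DataFrame(
        out, columns=["bin", "segment", "group", "context", "ml", "coverage"]
    )
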