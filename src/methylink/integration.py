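"""DMG classification, DMG x DEG overlap, and expression-stratified profiles.

A differentially methylated gene (DMG) is a gene whose promoter or gene
body overlaps at least one DMR; its direction is hyper, hypo, or both
depending on the directions of the overlapping DMRs. Intersecting DMGs
with differentially expressed genes gives one record per (gene, region)
with a concordance class: hypo_up (hypo-methylated, up-regulated) and
hyper_down are the concordant classes expected under methylation-mediated
repression; genes overlapping both hyper and hypo DMRs are "mixed" and
everything else "discordant".
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import FeatureIndex, GeneModel, assign_intervals
from .methylome import CytosineTable, metagene_profile

log = logging.getLogger(__name__)

REGIONS = ("promoter", "gene_body")
EXPRESSION_BINS = ("none", "low", "medium", "high")

DMG_COLUMNS = ["gene_id", "region", "direction", "dmr_count", "dmr_ids"]


def classify_dmgs(
    dmrs: pd.DataFrame,
    genes: Sequence[GeneModel],
    promoter_bp: int = 2000,
) -> pd.DataFrame:
    """One record per (gene, region) whose region overlaps >= 1 DMR.

    ``dmrs`` needs chrom/start/end/direction columns (row label used as DMR
    id). Direction is "both" when hyper and hypo DMRs both overlap the
    region; a gene may carry records for both regions.
    """
    rows = []
    for g in genes:
        ps, pe = g.promoter(promoter_bp)
        rows.append((g.chrom, ps, pe, "promoter", g.gene_id))
        rows.append((g.chrom, g.start, g.end, "gene_body", g.gene_id))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "region", "gene_id"])
    index = FeatureIndex(regions)
    hits = assign_intervals(dmrs[["chrom", "start", "end"]], index)
    if not len(hits):
        return pd.DataFrame(columns=DMG_COLUMNS)
    hits = hits.assign(direction=dmrs["direction"].reindex(hits["query_index"]).to_numpy())
    out = []
    for (gid, region), grp in hits.groupby(["gene_id", "region"], observed=True):
        dirs = set(grp["direction"])
        direction = "both" if len(dirs) > 1 else next(iter(dirs))
        ids = sorted(set(grp["query_index"].tolist()))
        out.append((gid, region, direction, len(ids), ids))
    return pd.DataFrame(out, columns=DMG_COLUMNS).sort_values(
        ["gene_id", "region"], ignore_index=True
    )


def dmg_venn(records: pd.DataFrame, region: str) -> tuple[int, int, int, int]:
    """(hyper_only, hypo_only, both, total) DMG counts for one region.

    The three classes partition the region's DMGs, so the total is always
    their sum.
    """
    sub = records[records["region"] == region] if len(records) else records
    if not len(sub):
        return (0, 0, 0, 0)
    hyper = int((sub["direction"] == "hyper").sum())
    hypo = int((sub["direction"] == "hypo").sum())
    both = int((sub["direction"] == "both").sum())
    return (hyper, hypo, both, hyper + hypo + both)


def dmr_count_histogram(records: pd.DataFrame) -> list[int]:
    """DMG record counts by per-record DMR count, in bins 1, 2, 3, >=4."""
    counts = [0, 0, 0, 0]
    for c in records["dmr_count"] if len(records) else []:
        counts[min(int(c), 4) - 1] += 1
    return counts


def overlap_dmg_deg(dmgs: pd.DataFrame, degs: pd.DataFrame) -> pd.DataFrame:
    """Inner-join DMG records with called DEGs and assign concordance.

    ``degs`` is indexed by gene_id with call/log2fc columns; only up/down
    calls participate. Concordance: hypo+up -> hypo_up, hyper+down ->
    hyper_down, direction both -> mixed, otherwise discordant. Duplicate
    gene ids in the DEG input, or duplicate (gene, region) DMG records,
    raise.
    """
    if degs.index.has_duplicates:
        raise ValueError("duplicate gene_id in DEG input")
    if len(dmgs) and dmgs.duplicated(["gene_id", "region"]).any():
        raise ValueError("duplicate (gene_id, region) DMG record")
    called = degs[degs["call"].isin(["up", "down"])]
    merged = dmgs.merge(
        called[["call", "log2fc"]], left_on="gene_id", right_index=True, how="inner"
    )
    def concord(row) -> str:
        if row["direction"] == "both":
            return "mixed"
        if row["direction"] == "hypo" and row["call"] == "up":
            return "hypo_up"
        if row["direction"] == "hyper" and row["call"] == "down":
            return "hyper_down"
        return "discordant"
    if len(merged):
        merged["concordance"] = merged.apply(concord, axis=1)
    else:
        merged["concordance"] = pd.Series(dtype=object)
    return merged.reset_index(drop=True)


def rollup_gene_classes(integrated: pd.DataFrame) -> dict[str, list[str]]:
    """Unique gene-id query lists for enrichment: all overlap, hyper_down, hypo_up.

    Genes with both promoter and body records resolve to the promoter
    record when the two disagree (the stronger regulatory prior).
    """
    if not len(integrated):
        return {"all_overlap": [], "hyper_down": [], "hypo_up": []}
    ordered = integrated.assign(
        _rank=(integrated["region"] != "promoter").astype(int)
    ).sort_values(["gene_id", "_rank"])
    per_gene = ordered.drop_duplicates("gene_id", keep="first")
    return {
        "all_overlap": sorted(integrated["gene_id"].unique()),
        "hyper_down": sorted(per_gene.loc[per_gene["concordance"] == "hyper_down", "gene_id"]),
        "hypo_up": sorted(per_gene.loc[per_gene["concordance"] == "hypo_up", "gene_id"]),
    }


def stratified_metagene(
    table: CytosineTable,
    groups: Mapping[str, str],
    genes: Sequence[GeneModel],
    bins: Mapping[str, str],
    context: str = "CpG",
    **profile_kwargs,
) -> pd.DataFrame:
    """One metagene profile per expression bin per group.

    ``bins`` maps gene_id -> none/low/medium/high; genes contribute only to
    their own bin's profile. Empty bins are logged and yield no rows. The
    result adds an ``expression_bin`` column to the metagene frame.
    """
    frames = []
    for label in EXPRESSION_BINS:
        members = [g for g in genes if bins.get(g.gene_id) == label]
        if not members:
            log.warning("expression bin %s is empty; profile skipped", label)
            continue
        prof = metagene_profile(table, groups, members, context=context, **profile_kwargs)
        prof["expression_bin"] = label
        frames.append(prof)
    if not frames:
        return pd.DataFrame(
            columns=["bin", "segment", "group", "context", "ml", "coverage", "expression_bin"]
        )
    return pd.concat(frames, ignore_index=True)
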