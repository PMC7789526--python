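"""End-to-end orchestration of the analysis chain on in-memory inputs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import dmr as dmr_mod
from . import enrichment as enrich_mod
from . import integration as integ_mod
from . import transcriptome as tx_mod
from .annotation import GeneModel
from .enrichment import PathwaySet
from .methylome import CytosineTable


@dataclass
class PipelineResult:
    site_tests: pd.DataFrame
    dmrs: pd.DataFrame
    deg_results: pd.DataFrame
    dmg_records: pd.DataFrame
    integrated: pd.DataFrame
    gene_classes: dict[str, list[str]]
    enrichment: dict[str, pd.DataFrame] | None


def run_pipeline(
    table: CytosineTable,
    counts: pd.DataFrame,
    genes: Sequence[GeneModel],
    groups: Mapping[str, str],
    case: str = "case",
    control: str = "control",
    context: str = "CpG",
    pathways: Sequence[PathwaySet] | None = None,
    promoter_bp: int = 2000,
    dmr_kwargs: dict | None = None,
) -> PipelineResult:
    """DMR calling + DEG calling + integration (+ enrichment) in one pass.

    ``dmr_kwargs`` are forwarded to :func:`methylink.dmr.call_dmrs`.
    """
    site_tests = dmr_mod.test_sites(table, groups, case, control, context=context)
    dmrs = dmr_mod.call_dmrs(site_tests, **(dmr_kwargs or {}))
    deg_results = tx_mod.call_degs(tx_mod.nb_wald_test(counts, groups, case, control))
    dmg_records = integ_mod.classify_dmgs(dmrs, genes, promoter_bp=promoter_bp)
    integrated = integ_mod.overlap_dmg_deg(dmg_records, deg_results)
    gene_classes = integ_mod.rollup_gene_classes(integrated)
    enr = None
    if pathways is not None:
        background = sorted(
            {g.gene_id for g in genes} & {gid for p in pathways for gid in p.genes}
        )
        enr = enrich_mod.run_enrichment_suites(gene_classes, pathways, background)
    return PipelineResult(
        site_tests, dmrs, deg_results, dmg_records, integrated, gene_classes, enr
    )
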