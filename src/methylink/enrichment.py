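"""Hypergeometric over-representation analysis of gene sets.

For a query of n background genes and a pathway covering K background
genes, the enrichment p-value of an observed intersection k is the exact
upper tail P(X >= k) for X ~ Hypergeometric(N, K, n) over a background of
N genes. Raw p < alpha is the significance rule; a Benjamini-Hochberg
column is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwaySet:
    pathway_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id} is empty")


def load_gmt(path: str | Path) -> list[PathwaySet]:
    """Parse a GMT file: name <tab> description <tab> gene ids.

    Lines with fewer than three fields are rejected with a log entry;
    duplicated genes within a set are deduplicated with a log entry.
    """
    out: list[PathwaySet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                log.warning("%s:%d: fewer than 3 fields, line rejected", path, lineno)
                continue
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if len(set(genes)) < len(genes):
                log.warning("%s:%d: duplicate gene ids in set %s, deduplicated", path, lineno, name)
            out.append(PathwaySet(name, desc, frozenset(genes)))
    return out


def write_gmt(pathways: Iterable[PathwaySet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.genes)]) + "\n")


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: Iterable[str],
    pathways: Sequence[PathwaySet],
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every pathway for over-representation in the query.

    Query genes outside the background are dropped with a log entry; an
    empty background raises. Result columns: pathway_id, name, k, K, n, N,
    p, padj, significant; sorted by ascending p.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background gene set")
    q = set(query)
    dropped = q - bg
    if dropped:
        log.warning("%d query genes outside background dropped", len(dropped))
    q &= bg
    N, n = len(bg), len(q)
    rows = []
    for p in pathways:
        pk = p.genes & bg
        K = len(pk)
        k = len(pk & q)
        rows.append((p.pathway_id, p.name, k, K, n, N, hypergeom_pvalue(k, N, K, n)))
    out = pd.DataFrame(rows, columns=["pathway_id", "name", "k", "K", "n", "N", "p"])
    out["padj"] = stats.false_discovery_control(out["p"]) if len(out) else []
    out["significant"] = out["p"] < alpha
    return out.sort_values(["p", "pathway_id"], ignore_index=True)


def run_enrichment_suites(
    gene_classes: Mapping[str, Sequence[str]],
    pathways: Sequence[PathwaySet],
    background: Iterable[str],
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Enrichment tables for the all-overlap, hyper_down and hypo_up queries.

    ``gene_classes`` comes from :func:`methylink.integration.rollup_gene_classes`;
    the three queries are tested against the same background. Empty queries
    yield empty tables with a log entry.
    """
    bg = set(background)
    out: dict[str, pd.DataFrame] = {}
    for suite in ("all_overlap", "hyper_down", "hypo_up"):
        query = gene_classes.get(suite, [])
        if not query:
            log.warning("enrichment suite %s has an empty query", suite)
            out[suite] = pd.DataFrame(
                columns=["pathway_id", "name", "k", "K", "n", "N", "p", "padj", "significant"]
            )
            continue
        out[suite] = hypergeom_enrich(query, pathways, bg, alpha=alpha)
    return out
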