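"""Strand-aware gene models, derived genomic features, and interval overlap.

Coordinates are 0-based half-open everywhere inside the package; GFF3 input
and output use the format's 1-based inclusive convention, BED uses 0-based
half-open. TSS/TES are strand-normalized so the TSS is always the 5' end of
the gene: for a plus-strand gene the TSS coordinate equals ``start``, for a
minus-strand gene it equals ``end`` (the half-open boundary just past the
last transcribed base).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: feature classes emitted by :func:`derive_features` (repeat comes from input BED)
FEATURE_CLASSES = (
    "promoter",
    "tss",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "tes",
    "downstream",
    "repeat",
)

FEATURE_COLUMNS = ["chrom", "start", "end", "feature", "gene_id"]


class AnnotationError(ValueError):
    """Malformed or inconsistent gene annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, exon structure and optional CDS span.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``exons``
    are ordered by genomic coordinate and must lie within the gene span.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if not self.start < self.end:
            raise AnnotationError(f"{self.gene_id}: empty gene span")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise AnnotationError(f"{self.gene_id}: exon [{s},{e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.gene_id}: exons overlap or are unordered")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Strand-normalized transcription start coordinate."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Strand-normalized transcription end coordinate."""
        return self.end if self.strand == "+" else self.start

    def promoter(self, promoter_bp: int = 2000) -> tuple[int, int]:
        """Interval abutting the TSS on its 5' side (clipped at 0)."""
        if self.strand == "+":
            return (max(0, self.start - promoter_bp), self.start)
        return (self.end, self.end + promoter_bp)

    def downstream(self, flank_bp: int = 2000) -> tuple[int, int]:
        """Interval abutting the TES on its 3' side (clipped at 0)."""
        if self.strand == "+":
            return (self.end, self.end + flank_bp)
        return (max(0, self.start - flank_bp), self.start)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return tuple(out)


def _intersect(iv: tuple[int, int], blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    s, e = iv
    out = []
    for bs, be in blocks:
        lo, hi = max(s, bs), min(e, be)
        if lo < hi:
            out.append((lo, hi))
    return out


def derive_features(
    gene: GeneModel,
    promoter_bp: int = 2000,
    flank_bp: int = 2000,
    point_bp: int = 50,
) -> pd.DataFrame:
    """Emit class-labelled intervals for one gene.

    Classes: promoter, TSS point-window (±point_bp), 5'UTR, exon, intron,
    3'UTR, TES point-window, downstream, gene_body. UTRs are derived from
    the CDS span intersected with exons; genes without a CDS get no UTR
    rows (logged at debug level).
    """
    rows: list[tuple[str, int, int, str, str]] = []

    def add(cls: str, s: int, e: int) -> None:
        s = max(0, s)
        if s < e:
            rows.append((gene.chrom, s, e, cls, gene.gene_id))

    add("promoter", *gene.promoter(promoter_bp))
    add("downstream", *gene.downstream(flank_bp))
    add("tss", gene.tss - point_bp, gene.tss + point_bp)
    add("tes", gene.tes - point_bp, gene.tes + point_bp)
    for s, e in gene.exons:
        add("exon", s, e)
    for s, e in gene.introns:
        add("intron", s, e)
    if gene.cds is not None:
        cs, ce = gene.cds
        left = _intersect((gene.start, cs), gene.exons)
        right = _intersect((ce, gene.end), gene.exons)
        five, three = (left, right) if gene.strand == "+" else (right, left)
        for s, e in five:
            add("five_prime_utr", s, e)
        for s, e in three:
            add("three_prime_utr", s, e)
    else:
        log.debug("%s: no CDS, skipping UTR derivation", gene.gene_id)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def derive_feature_table(
    genes: Iterable[GeneModel],
    repeats: pd.DataFrame | None = None,
    promoter_bp: int = 2000,
    flank_bp: int = 2000,
    point_bp: int = 50,
) -> pd.DataFrame:
    """Concatenate :func:`derive_features` over genes, plus repeat intervals.

    ``repeats`` is a BED-like frame with chrom/start/end columns.
    """
    frames = [derive_features(g, promoter_bp, flank_bp, point_bp) for g in genes]
    if repeats is not None and len(repeats):
        rep = repeats[["chrom", "start", "end"]].copy()
        rep["feature"] = "repeat"
        rep["gene_id"] = "."
        frames.append(rep[FEATURE_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 (.gff/.gff3) or BED12 (.bed).

    Exons recorded outside their gene's span are rejected with a logged
    reason; a duplicated gene_id raises :class:`AnnotationError`.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _load_gff3(path)
    if path.suffix.lower() == ".bed":
        return _load_bed12(path)
    raise AnnotationError(f"unrecognised annotation format: {path}")


def _load_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True, merge_strategy="error"
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = g.id
        if gid in seen:
            raise AnnotationError(f"duplicate gene_id {gid!r} in {path}")
        seen.add(gid)
        gstart, gend = g.start - 1, g.end  # to 0-based half-open
        exons = []
        for ex in db.children(g, featuretype="exon", order_by="start"):
            es, ee = ex.start - 1, ex.end
            if es < gstart or ee > gend:
                log.warning(
                    "%s: exon [%d,%d) outside gene span [%d,%d), record rejected",
                    gid, es, ee, gstart, gend,
                )
                continue
            exons.append((es, ee))
        if not exons:
            exons = [(gstart, gend)]
        cds_parts = [(c.start - 1, c.end) for c in db.children(g, featuretype="CDS")]
        cds = (min(s for s, _ in cds_parts), max(e for _, e in cds_parts)) if cds_parts else None
        genes.append(
            GeneModel(gid, g.seqid, gstart, gend, g.strand, tuple(sorted(exons)), cds)
        )
    return genes


_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts",
]


def _load_bed12(path: Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.name in seen:
            raise AnnotationError(f"duplicate gene_id {row.name!r} in {path}")
        seen.add(row.name)
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        offs = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        exons = tuple((row.start + o, row.start + o + z) for o, z in zip(offs, sizes))
        cds = None
        if int(row.thickEnd) > int(row.thickStart):
            cds = (int(row.thickStart), int(row.thickEnd))
        genes.append(
            GeneModel(str(row.name), str(row.chrom), int(row.start), int(row.end),
                      str(row.strand), exons, cds)
        )
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon(/CDS) records in 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            base = f"{g.chrom}\tmethylink\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(f"{base}gene\t{g.start + 1}\t{g.end}{tail}\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{g.start + 1}\t{g.end}{tail}\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{base}exon\t{s + 1}\t{e}{tail}\tID={mrna}.exon{i};Parent={mrna}\n"
                )
            if g.cds is not None:
                cs, ce = g.cds
                for i, (s, e) in enumerate(_intersect((cs, ce), g.exons), 1):
                    fh.write(
                        f"{base}CDS\t{s + 1}\t{e}{tail}\tID={mrna}.cds{i};Parent={mrna}\n"
                    )


def write_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offs = ",".join(str(s - g.start) for s, e in g.exons) + ","
            ts, te = g.cds if g.cds is not None else (g.start, g.start)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{ts}\t{te}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read a BED6 (or BED3+) file into chrom/start/end(/name/score/strand)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# interval overlap engine
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Searchable per-chromosome interval index over class-labelled features.

    Built on interval trees; queries use half-open semantics, so touching
    endpoints do not overlap.
    """

    def __init__(self, features: pd.DataFrame):
        missing = set(("chrom", "start", "end")) - set(features.columns)
        if missing:
            raise AnnotationError(f"feature table lacks columns: {sorted(missing)}")
        self.features = features.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, grp in self.features.groupby("chrom", observed=True):
            tree = IntervalTree()
            for idx, s, e in zip(grp.index, grp["start"], grp["end"]):
                if e > s:
                    tree[int(s):int(e)] = idx
            self._trees[str(chrom)] = tree
        self._warned_chroms: set[str] = set()

    def query(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """All feature rows intersecting [start, end) on ``chrom``."""
        tree = self._trees.get(chrom)
        if tree is None:
            if chrom not in self._warned_chroms:
                log.warning("chromosome %s absent from feature index", chrom)
                self._warned_chroms.add(chrom)
            return self.features.iloc[[]]
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        return self.features.loc[hits]


def assign_intervals(queries: pd.DataFrame, index: FeatureIndex) -> pd.DataFrame:
    """Report every (query, feature) intersecting pair exactly once.

    ``queries`` needs chrom/start/end columns; the result carries the query
    row label as ``query_index`` plus the matched feature columns.
    """
    out = []
    for qidx, row in queries.iterrows():
        hits = index.query(str(row["chrom"]), int(row["start"]), int(row["end"]))
        for fidx, feat in hits.iterrows():
            rec = {"query_index": qidx, "feature_index": fidx}
            rec.update(feat.to_dict())
            out.append(rec)
    cols = ["query_index", "feature_index"] + list(index.features.columns)
    return pd.DataFrame(out, columns=cols)
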