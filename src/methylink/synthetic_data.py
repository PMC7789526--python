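"""Miniature two-group WGBS + RNA-seq study generator with recorded truth.

Emulates the statistical structure of a case/control liver methylome study:
two groups of (by default) four biological replicates, cytosines in the
CpG/CHG/CHH contexts on both strands, genome-wide case-group
hypo-methylation outside gene bodies, planted differentially methylated
regions, planted differentially expressed genes, and an optional negative
promoter-methylation/expression linkage. Methylated counts are
beta-binomial over Poisson coverage; expression counts are negative
binomial. Every planted effect is recorded in a :class:`GroundTruth` so
downstream callers can be scored.

All randomness flows from one master seed; each stage draws from its own
child generator at a fixed offset, so stages are reproducible in isolation
and a fixed config yields byte-identical fixture directories.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, write_gff3
from .enrichment import PathwaySet, write_gmt
from .methylome import CX_COLUMNS, CytosineTable, write_cx_report
from .transcriptome import write_counts

log = logging.getLogger(__name__)

MU_FLOOR = 1e-3

# fixed per-stage seed offsets from the master seed
_STAGE_OFFSETS = {"genome": 1, "truth": 2, "methylome": 3, "expression": 4, "pathways": 5}


class SimulationCapacityError(ValueError):
    """The requested genome cannot hold the requested annotation."""


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic two-group experiment."""

    n_chroms: int = 2
    chrom_len: int = 1_500_000
    n_genes: int = 200
    n_reps_per_group: int = 4
    mean_coverage: float = 30.0
    baseline_meth: dict[str, float] = field(
        default_factory=lambda: {"CpG": 0.7, "CHG": 0.02, "CHH": 0.02}
    )
    global_shift: float = 0.1
    dispersion_bb: float = 0.05
    n_planted_dmrs: int = 20
    dmr_effect: float = 0.3
    n_planted_degs: int = 20
    deg_lfc: float = 1.0
    linkage_fraction: float = 0.5
    nb_dispersion: float = 0.05
    frac_silent: float = 0.1
    monotone_linkage: bool = False
    # site-placement densities (sites per bp) and planted-cluster geometry
    cpg_rate: float = 1 / 100
    chg_rate: float = 1 / 150
    chh_rate: float = 1 / 150
    cluster_sites: int = 8
    cluster_spacing: int = 20
    flank_bp: int = 2000
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "global_shift": self.global_shift,
            "dispersion_bb": self.dispersion_bb,
            "dmr_effect": self.dmr_effect,
            "linkage_fraction": self.linkage_fraction,
            "frac_silent": self.frac_silent,
            **{f"baseline_meth[{k}]": v for k, v in self.baseline_meth.items()},
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name in ("n_chroms", "chrom_len", "n_reps_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_dmrs > self.n_genes:
            raise SimulationCapacityError(
                f"n_planted_dmrs={self.n_planted_dmrs} exceeds n_genes={self.n_genes}: "
                "each planted DMR occupies a distinct gene"
            )
        if self.n_planted_degs > self.n_genes:
            raise SimulationCapacityError(
                f"n_planted_degs={self.n_planted_degs} exceeds n_genes={self.n_genes}"
            )

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + _STAGE_OFFSETS[stage]) % (2**31)

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def samples(self) -> dict[str, str]:
        out = {f"case_{i + 1}": "case" for i in range(self.n_reps_per_group)}
        out.update({f"control_{i + 1}": "control" for i in range(self.n_reps_per_group)})
        return out


@dataclass
class PlantedDMR:
    chrom: str
    start: int
    end: int
    context: str
    direction: str  # hyper|hypo, case minus control
    effect: float
    gene_id: str
    region: str  # promoter|gene_body


@dataclass
class GroundTruth:
    """Planted effects, recorded at generation time."""

    planted_dmrs: list[PlantedDMR]
    planted_degs: list[tuple[str, float]]  # (gene_id, log2fc)
    linkage_pairs: list[tuple[str, tuple[str, int, int]]]
    baseline_expression: dict[str, float]
    expression_bins: dict[str, str]

    def validate(self, genes: Sequence[GeneModel], flank_bp: int = 2000) -> None:
        by_id = {g.gene_id: g for g in genes}
        deg_lfc = dict(self.planted_degs)
        dmr_ivs = {(d.chrom, d.start, d.end): d for d in self.planted_dmrs}
        for gid, iv in self.linkage_pairs:
            d = dmr_ivs.get(iv)
            if d is None:
                raise ValueError(f"linkage for {gid} references an unplanted DMR {iv}")
            gene = by_id.get(gid)
            if gene is None:
                raise ValueError(f"linkage references unknown gene {gid}")
            ps, pe = gene.promoter(flank_bp)
            if not (d.chrom == gene.chrom and ps <= d.start and d.end <= pe):
                raise ValueError(f"linked DMR for {gid} is not inside its promoter")
            lfc = deg_lfc.get(gid)
            if lfc is None:
                raise ValueError(f"linked gene {gid} is not a planted DEG")
            if d.direction == "hypo" and lfc <= 0 or d.direction == "hyper" and lfc >= 0:
                raise ValueError(f"linkage for {gid} violates opposite-sign coupling")
        ivs = sorted((d.chrom, d.start, d.end) for d in self.planted_dmrs)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("planted DMR intervals overlap")


@dataclass
class SimResult:
    """Everything one simulation run produced."""

    config: SimConfig
    genes: list[GeneModel]
    repeats: pd.DataFrame
    sites: pd.DataFrame
    truth: GroundTruth
    methylomes: CytosineTable
    counts: pd.DataFrame
    groups: dict[str, str]


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _cluster_interval(gene: GeneModel, region: str, config: SimConfig) -> tuple[int, int]:
    """Genomic interval of the dense CpG cluster planted in a gene region.

    The cluster holds ``cluster_sites`` CpG pairs spaced ``cluster_spacing``
    bp, centred in the promoter or the gene body.
    """
    span = (config.cluster_sites - 1) * config.cluster_spacing + 2
    if region == "promoter":
        ps, pe = gene.promoter(config.flank_bp)
        mid = (ps + pe) // 2
    else:
        mid = (gene.start + gene.end) // 2
    s0 = mid - span // 2
    return (s0, s0 + span)


def _cluster_positions(iv: tuple[int, int], config: SimConfig) -> np.ndarray:
    return iv[0] + config.cluster_spacing * np.arange(config.cluster_sites)


def generate_genome(
    config: SimConfig,
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame]:
    """Place genes, repeats and cytosine sites on the synthetic genome.

    Returns (gene models, repeat BED-like frame, site map). The site map
    has columns chrom, pos (1-based), strand, context and includes a dense
    CpG cluster in every gene's promoter and body midpoint so planted DMRs
    always satisfy caller minimums. Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.stage_seed("genome"))
    margin = config.flank_bp + 100
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    genes: list[GeneModel] = []
    gaps: list[tuple[str, int, int]] = []
    gi = 0
    for chrom, n_here in zip(config.chrom_names, per_chrom):
        cursor = margin
        for _ in range(n_here):
            gap = int(rng.integers(500, 3000))
            length = int(rng.integers(3000, 8001))
            start = cursor + gap
            end = start + length
            if end + margin > config.chrom_len:
                raise SimulationCapacityError(
                    f"cannot place gene {gi + 1}/{config.n_genes} on {chrom}: "
                    f"needs [{start},{end + margin}) but chrom_len={config.chrom_len}; "
                    "increase chrom_len or reduce n_genes"
                )
            if start - cursor >= 400:
                gaps.append((chrom, cursor, start))
            genes.append(_make_gene(f"gene{gi + 1:04d}", chrom, start, end, rng))
            cursor = end + 2 * config.flank_bp  # keep neighbour flanks disjoint
            gi += 1
        if config.chrom_len - cursor >= 400:
            gaps.append((chrom, cursor, config.chrom_len))

    repeats = _place_repeats(gaps, rng)
    sites = _place_sites(genes, config, rng)
    return genes, repeats, sites


def _make_gene(gid: str, chrom: str, start: int, end: int, rng: np.random.Generator) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    body = end - start
    n_ex = int(rng.integers(1, 5))
    n_seg = 2 * n_ex - 1
    min_seg = 50
    extra = rng.multinomial(body - n_seg * min_seg, np.full(n_seg, 1.0 / n_seg))
    seg_lens = extra + min_seg
    bounds = start + np.concatenate([[0], np.cumsum(seg_lens)])
    exons = tuple(
        (int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex)
    )
    u5 = int(rng.integers(20, max(21, min(200, exons[0][1] - exons[0][0]))))
    u3 = int(rng.integers(20, max(21, min(200, exons[-1][1] - exons[-1][0]))))
    cds = (start + u5, end - u3)
    if cds[0] >= cds[1]:
        cds = None
    return GeneModel(gid, chrom, start, end, strand, exons, cds)


def _place_repeats(gaps: list[tuple[str, int, int]], rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for chrom, gs, ge in gaps:
        if rng.random() < 0.5:
            continue
        max_len = min(1000, ge - gs - 200)
        if max_len < 100:
            continue
        length = int(rng.integers(100, max_len + 1))
        s = int(rng.integers(gs + 100, ge - length - 100 + 1)) if ge - length - 100 >= gs + 100 else gs + 100
        rows.append((chrom, s, s + length, f"repeat{i + 1}", 0, "+"))
        i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def _place_sites(
    genes: Sequence[GeneModel], config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    frames = []
    # dense CpG clusters first so they win deduplication
    for g in genes:
        for region in ("promoter", "gene_body"):
            iv = _cluster_interval(g, region, config)
            p0 = _cluster_positions(iv, config)
            p0 = p0[(p0 >= 0) & (p0 + 1 < config.chrom_len)]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": g.chrom,
                        "pos": np.concatenate([p0 + 1, p0 + 2]),
                        "strand": ["+"] * len(p0) + ["-"] * len(p0),
                        "context": "CpG",
                    }
                )
            )
    for chrom in config.chrom_names:
        n_cpg = rng.poisson(config.chrom_len * config.cpg_rate)
        p0 = np.unique(rng.integers(0, config.chrom_len - 1, size=n_cpg))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([p0 + 1, p0 + 2]),
                    "strand": ["+"] * len(p0) + ["-"] * len(p0),
                    "context": "CpG",
                }
            )
        )
        for context, rate in (("CHG", config.chg_rate), ("CHH", config.chh_rate)):
            n = rng.poisson(config.chrom_len * rate)
            p0 = np.unique(rng.integers(0, config.chrom_len, size=n))
            strand = np.where(rng.random(len(p0)) < 0.5, "+", "-")
            frames.append(
                pd.DataFrame({"chrom": chrom, "pos": p0 + 1, "strand": strand, "context": context})
            )
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.drop_duplicates(["chrom", "pos", "strand"], keep="first")
    return sites.sort_values(["chrom", "pos", "strand"], ignore_index=True)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def make_ground_truth(genes: Sequence[GeneModel], config: SimConfig) -> GroundTruth:
    """Choose planted DMRs, DEGs, linkage pairs, and baseline expression.

    The first ``round(linkage_fraction * n_planted_dmrs)`` planted DMRs are
    promoter hypo-methylation events on genes that are simultaneously
    planted up-regulated DEGs (the negative-coupling pairs); remaining
    planted DMRs sit in gene bodies of other genes with alternating
    direction. Planted DEG baselines are drawn above 100 normalized counts.
    """
    config.validate()
    rng = np.random.default_rng(config.stage_seed("truth"))
    order = rng.permutation(len(genes))
    n_link = int(round(config.linkage_fraction * config.n_planted_dmrs))
    dmr_genes = [genes[i] for i in order[: config.n_planted_dmrs]]

    planted_dmrs: list[PlantedDMR] = []
    linkage: list[tuple[str, tuple[str, int, int]]] = []
    degs: list[tuple[str, float]] = []
    for j, g in enumerate(dmr_genes):
        if j < n_link:
            region, direction = "promoter", "hypo"
        else:
            region = "gene_body"
            direction = "hypo" if j % 2 == 0 else "hyper"
        s, e = _cluster_interval(g, region, config)
        planted_dmrs.append(
            PlantedDMR(g.chrom, s, e, "CpG", direction, config.dmr_effect, g.gene_id, region)
        )
        if j < n_link:
            linkage.append((g.gene_id, (g.chrom, s, e)))
            degs.append((g.gene_id, abs(config.deg_lfc)))

    pool = [genes[i].gene_id for i in order[config.n_planted_dmrs:]]
    need = config.n_planted_degs - len(degs)
    if need > len(pool):
        raise SimulationCapacityError(
            "not enough genes free of planted DMR linkage to host the remaining DEGs"
        )
    for j, gid in enumerate(pool[:max(need, 0)]):
        sign = 1.0 if j % 2 == 0 else -1.0
        degs.append((gid, sign * abs(config.deg_lfc)))

    deg_ids = {gid for gid, _ in degs}
    baselines: dict[str, float] = {}
    silent_pool = [g.gene_id for g in genes if g.gene_id not in deg_ids]
    n_silent = min(int(round(config.frac_silent * len(genes))), len(silent_pool))
    silent = set(rng.choice(silent_pool, size=n_silent, replace=False)) if n_silent else set()
    for g in genes:
        if g.gene_id in silent:
            baselines[g.gene_id] = 0.0
        elif g.gene_id in deg_ids:
            baselines[g.gene_id] = float(10 ** rng.uniform(2.0, 3.0))
        else:
            baselines[g.gene_id] = float(10 ** rng.uniform(0.5, 3.0))

    nonzero = sorted((gid for gid, b in baselines.items() if b > 0),
                     key=lambda gid: (baselines[gid], gid))
    bins = {gid: "none" for gid in silent}
    for label, part in zip(("low", "medium", "high"), np.array_split(nonzero, 3)):
        for gid in part:
            bins[gid] = label

    truth = GroundTruth(planted_dmrs, degs, linkage, baselines, bins)
    truth.validate(genes, config.flank_bp)
    return truth


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

#: promoter methylation targets per expression bin under monotone linkage
MONOTONE_PROMOTER_MU = {"none": 0.80, "low": 0.65, "medium": 0.50, "high": 0.35}


def simulate_methylomes(
    sites: pd.DataFrame,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimConfig,
) -> CytosineTable:
    """Per-sample methylated/total counts at every site.

    Totals are Poisson(mean_coverage); methylated counts are beta-binomial
    with mean mu and dispersion ``dispersion_bb``, where mu is the context
    baseline, lowered by ``global_shift`` outside gene bodies in the case
    group, overridden in promoters by the monotone-linkage targets when
    configured, and shifted by +-``dmr_effect`` inside planted DMRs in the
    case group. Means pushed outside [0,1] are clamped with a logged
    warning.
    """
    if not len(sites):
        raise ValueError("site map is empty")
    n = len(sites)
    base = sites["context"].map(config.baseline_meth).to_numpy(dtype=float)
    pos0 = sites["pos"].to_numpy() - 1
    chrom = sites["chrom"].to_numpy()

    in_body = np.zeros(n, dtype=bool)
    bodies: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        bodies.setdefault(g.chrom, []).append((g.start, g.end))
    for c, ivs in bodies.items():
        starts = np.sort([s for s, _ in ivs])
        ends = np.sort([e for _, e in ivs])
        m = chrom == c
        p = pos0[m]
        in_body[m] = (
            np.searchsorted(starts, p, "right") > np.searchsorted(ends, p, "right")
        )

    mu_control = base.copy()
    mu_case = base.copy()
    mu_case[~in_body] -= config.global_shift

    if config.monotone_linkage:
        for g in genes:
            target = MONOTONE_PROMOTER_MU[truth.expression_bins[g.gene_id]]
            ps, pe = g.promoter(config.flank_bp)
            m = (chrom == g.chrom) & (pos0 >= ps) & (pos0 < pe) & (
                sites["context"].to_numpy() == "CpG"
            )
            mu_control[m] = target
            mu_case[m] = target

    ctx = sites["context"].to_numpy()
    for d in truth.planted_dmrs:
        m = (chrom == d.chrom) & (pos0 >= d.start) & (pos0 < d.end) & (ctx == d.context)
        mu_case[m] += d.effect if d.direction == "hyper" else -d.effect

    n_clamped = int(
        ((mu_case < MU_FLOOR) | (mu_case > 1 - MU_FLOOR)).sum()
        + ((mu_control < MU_FLOOR) | (mu_control > 1 - MU_FLOOR)).sum()
    )
    if n_clamped:
        log.warning("%d site means fell outside [%g, %g] and were clamped",
                    n_clamped, MU_FLOOR, 1 - MU_FLOOR)
    mu_control = np.clip(mu_control, MU_FLOOR, 1 - MU_FLOOR)
    mu_case = np.clip(mu_case, MU_FLOOR, 1 - MU_FLOOR)

    rng = np.random.default_rng(config.stage_seed("methylome"))
    samples = config.samples
    meth = np.empty((n, len(samples)), dtype=np.int64)
    total = np.empty_like(meth)
    phi = config.dispersion_bb
    for j, (sample, grp) in enumerate(samples.items()):
        mu = mu_case if grp == "case" else mu_control
        t = rng.poisson(config.mean_coverage, size=n)
        if phi > 0:
            a = mu * (1 - phi) / phi
            b = (1 - mu) * (1 - phi) / phi
            p = rng.beta(a, b)
        else:
            p = mu
        meth[:, j] = rng.binomial(t, p)
        total[:, j] = t
    table = CytosineTable(sites.reset_index(drop=True), meth, total, list(samples))
    return table


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: Sequence[GeneModel], truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Gene x sample negative-binomial count matrix.

    Case-group means are the baseline times 2**log2fc for planted DEGs;
    genes with zero baseline stay all-zero (the "none" expression bin).
    """
    by_id = {g.gene_id for g in genes}
    for gid, _ in truth.planted_degs:
        if gid not in by_id:
            raise ValueError(f"planted DEG references unknown gene {gid}")
    rng = np.random.default_rng(config.stage_seed("expression"))
    gene_ids = [g.gene_id for g in genes]
    base = np.array([truth.baseline_expression[gid] for gid in gene_ids])
    lfc = dict(truth.planted_degs)
    case_mu = base * np.array([2.0 ** lfc.get(gid, 0.0) for gid in gene_ids])
    samples = config.samples
    out = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    for j, (sample, grp) in enumerate(samples.items()):
        mu = case_mu if grp == "case" else base
        pos = mu > 0
        if config.nb_dispersion > 0:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu[pos])
            out[pos, j] = rng.negative_binomial(r, p)
        else:
            out[pos, j] = rng.poisson(mu[pos])
    return pd.DataFrame(out, index=pd.Index(gene_ids, name="gene_id"), columns=list(samples))


# ---------------------------------------------------------------------------
# pathways + orchestration + fixture writing
# ---------------------------------------------------------------------------

def make_pathways(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SimConfig,
    n_pathways: int = 20,
    min_size: int = 10,
    max_size: int = 40,
    planted_fraction: float = 0.8,
) -> list[PathwaySet]:
    """Random pathway sets over the gene universe, one seeded with linkage genes.

    The first pathway contains ``planted_fraction`` of the linkage genes
    (the hypo-promoter/up-regulated pairs) plus random fillers, giving the
    enrichment stage a recoverable positive.
    """
    rng = np.random.default_rng(config.stage_seed("pathways"))
    ids = [g.gene_id for g in genes]
    link_ids = [gid for gid, _ in truth.linkage_pairs]
    n_core = int(round(planted_fraction * len(link_ids)))
    core = list(rng.choice(link_ids, size=n_core, replace=False)) if n_core else []
    filler_pool = [gid for gid in ids if gid not in set(core)]
    n_fill = max(min_size - len(core), 3)
    planted = core + list(rng.choice(filler_pool, size=min(n_fill, len(filler_pool)), replace=False))
    out = [PathwaySet("PW0001", "planted_linkage_pathway", frozenset(planted))]
    for i in range(1, n_pathways):
        size = int(rng.integers(min_size, max_size + 1))
        members = rng.choice(ids, size=min(size, len(ids)), replace=False)
        out.append(PathwaySet(f"PW{i + 1:04d}", f"random_pathway_{i + 1}", frozenset(members)))
    return out


def simulate(config: SimConfig) -> SimResult:
    """Run every generation stage and bundle the outputs."""
    genes, repeats, sites = generate_genome(config)
    if config.n_genes > 0:
        truth = make_ground_truth(genes, config)
    else:
        truth = GroundTruth([], [], [], {}, {})
    methylomes = simulate_methylomes(sites, genes, truth, config)
    counts = simulate_expression(genes, truth, config)
    return SimResult(config, genes, repeats, sites, truth, methylomes, counts, config.samples)


def write_fixtures(sim: SimResult, out_dir: str | Path, n_pathways: int = 20) -> dict[str, str]:
    """Write the full fixture directory; the JSON manifest is written last.

    Emits per-sample CX reports (<sample>.cx.tsv), genes.gff3, repeats.bed,
    counts.tsv, groups.tsv, pathways.gmt and manifest.json. A failed write
    leaves no manifest, which marks the fixture incomplete.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    table = sim.methylomes
    for j, sample in enumerate(table.samples):
        df = table.sites.copy()
        df["meth"] = table.meth[:, j]
        df["unmeth"] = table.total[:, j] - table.meth[:, j]
        fname = f"{sample}.cx.tsv"
        write_cx_report(df[CX_COLUMNS], out_dir / fname)
        files[sample] = fname
    write_gff3(sim.genes, out_dir / "genes.gff3")
    sim.repeats.to_csv(out_dir / "repeats.bed", sep="\t", header=False, index=False)
    write_counts(sim.counts, out_dir / "counts.tsv")
    with open(out_dir / "groups.tsv", "w") as fh:
        for sample, grp in sim.groups.items():
            fh.write(f"{sample}\t{grp}\n")
    pathways = make_pathways(sim.genes, sim.truth, sim.config, n_pathways=n_pathways)
    write_gmt(pathways, out_dir / "pathways.gmt")
    manifest = {
        "config": dataclasses.asdict(sim.config),
        "samples": sim.groups,
        "files": {**files, "genes": "genes.gff3", "repeats": "repeats.bed",
                  "counts": "counts.tsv", "groups": "groups.tsv", "pathways": "pathways.gmt"},
        "planted_dmrs": [dataclasses.asdict(d) for d in sim.truth.planted_dmrs],
        "planted_degs": [[gid, lfc] for gid, lfc in sim.truth.planted_degs],
        "linkage_pairs": [[gid, list(iv)] for gid, iv in sim.truth.linkage_pairs],
        "expression_bins": sim.truth.expression_bins,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return files
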