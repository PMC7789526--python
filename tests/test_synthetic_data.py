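import filecmp
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from methylink import annotation as ann
from methylink import enrichment as en
from methylink import methylome as me
from methylink import synthetic_data as sd
from methylink import transcriptome as tx


def small_config(**kw):
    base = dict(n_chroms=2, chrom_len=300_000, n_genes=20, n_planted_dmrs=6,
                n_planted_degs=6, seed=5)
    base.update(kw)
    return sd.SimConfig(**base)


class TestConfig:
    def test_fraction_bounds_checked(self):
        with pytest.raises(ValueError, match="global_shift"):
            sd.SimConfig(global_shift=1.5).validate()

    def test_more_dmrs_than_genes_is_capacity_error(self):
        with pytest.raises(sd.SimulationCapacityError, match="n_planted_dmrs"):
            sd.SimConfig(n_genes=5, n_planted_dmrs=6).validate()

    def test_infeasible_gene_placement_names_constraint(self):
        cfg = small_config(chrom_len=30_000, n_genes=20)
        with pytest.raises(sd.SimulationCapacityError, match="chrom_len"):
            sd.generate_genome(cfg)


class TestGenome:
    def test_zero_genes_still_places_intergenic_cytosines(self):
        cfg = small_config(n_genes=0, n_planted_dmrs=0, n_planted_degs=0)
        genes, repeats, sites = sd.generate_genome(cfg)
        assert genes == []
        assert len(sites) > 0

    def test_promoters_stay_inside_chromosomes(self):
        cfg = small_config(n_chroms=2, n_genes=10, n_planted_dmrs=0, n_planted_degs=0)
        genes, _, _ = sd.generate_genome(cfg)
        assert len(genes) == 10
        for g in genes:
            ps, pe = g.promoter(2000)
            assert 0 <= ps < pe <= cfg.chrom_len

    def test_every_gene_has_strand_and_exons(self, default_sim):
        for g in default_sim.genes:
            assert g.strand in "+-"
            assert len(g.exons) >= 1
            assert g.tss != g.tes

    def test_repeats_lie_outside_gene_bodies(self, default_sim):
        bodies = [(g.chrom, g.start, g.end) for g in default_sim.genes]
        for r in default_sim.repeats.itertuples():
            assert not any(c == r.chrom and r.start < e and s < r.end for c, s, e in bodies)

    def test_deterministic_for_fixed_seed(self):
        cfg = small_config()
        a = sd.generate_genome(cfg)
        b = sd.generate_genome(cfg)
        assert [g for g in a[0]] == [g for g in b[0]]
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])


class TestMethylomes:
    def test_counts_conserve_methylated_below_total(self, default_sim):
        tab = default_sim.methylomes
        assert np.all(tab.meth <= tab.total)
        assert np.all(tab.meth >= 0)

    def test_binomial_limit_recovers_mean(self):
        cfg = small_config(dispersion_bb=0.0, mean_coverage=200,
                           baseline_meth={"CpG": 0.5, "CHG": 0.5, "CHH": 0.5},
                           global_shift=0.0, n_planted_dmrs=0, n_planted_degs=0)
        sim = sd.simulate(cfg)
        lv = me.genome_wide_level(sim.methylomes, sim.groups, "CpG")
        n_reads = sim.methylomes.total.sum() / 3  # rough CpG share
        se = 0.5 / np.sqrt(n_reads)
        assert abs(lv["case"] - 0.5) < 3 * se + 1e-3
        assert abs(lv["control"] - 0.5) < 3 * se + 1e-3

    def test_planted_hypo_dmr_shifts_pooled_level(self):
        cfg = small_config(mean_coverage=200, global_shift=0.0,
                           linkage_fraction=0.0, n_planted_dmrs=2, n_planted_degs=2)
        sim = sd.simulate(cfg)
        tab = sim.methylomes
        pos0 = tab.pos0
        pooled = tab.group_pooled(sim.groups)
        hypo = [d for d in sim.truth.planted_dmrs if d.direction == "hypo"]
        assert hypo
        for d in hypo:
            m = ((tab.sites["chrom"] == d.chrom).to_numpy()
                 & (pos0 >= d.start) & (pos0 < d.end)
                 & (tab.sites["context"] == "CpG").to_numpy())
            mcase, tcase = pooled["case"]
            ml = mcase[m].sum() / tcase[m].sum()
            assert ml == pytest.approx(0.4, abs=0.05)

    def test_flank_hypomethylation_matches_shift(self):
        """Pooled case-control CpG difference in flanks equals -global_shift."""
        cfg = small_config(mean_coverage=100, n_planted_dmrs=0, n_planted_degs=0,
                           global_shift=0.1)
        sim = sd.simulate(cfg)
        tab = sim.methylomes.subset_context("CpG")
        pos0 = tab.pos0
        outside = np.ones(len(tab), dtype=bool)
        for g in sim.genes:
            m = (tab.sites["chrom"] == g.chrom).to_numpy()
            outside &= ~(m & (pos0 >= g.start) & (pos0 < g.end))
        sub = tab.subset_rows(outside)
        pooled = sub.group_pooled(sim.groups)
        diff = (pooled["case"][0].sum() / pooled["case"][1].sum()
                - pooled["control"][0].sum() / pooled["control"][1].sum())
        assert diff == pytest.approx(-0.1, abs=0.01)

    def test_zero_coverage_site_emitted_as_zero_zero(self):
        cfg = small_config(mean_coverage=1.0, n_planted_dmrs=0, n_planted_degs=0)
        sim = sd.simulate(cfg)
        zero = sim.methylomes.total == 0
        assert zero.any()
        assert np.all(sim.methylomes.meth[zero] == 0)

    def test_empty_site_map_rejected(self):
        cfg = small_config(n_planted_dmrs=0, n_planted_degs=0)
        truth = sd.GroundTruth([], [], [], {}, {})
        with pytest.raises(ValueError, match="empty"):
            sd.simulate_methylomes(pd.DataFrame(columns=["chrom", "pos", "strand", "context"]),
                                   [], truth, cfg)


class TestExpression:
    def test_poisson_limit_mean_ratio_is_two(self):
        cfg = small_config(nb_dispersion=0.0, deg_lfc=1.0, n_planted_dmrs=0,
                           n_planted_degs=6, linkage_fraction=0.0, frac_silent=0.0)
        sim = sd.simulate(cfg)
        up = [gid for gid, lfc in sim.truth.planted_degs if lfc > 0]
        counts = sim.counts
        case_cols = [s for s, g in sim.groups.items() if g == "case"]
        ctrl_cols = [s for s, g in sim.groups.items() if g == "control"]
        for gid in up:
            mu = sim.truth.baseline_expression[gid]
            ratio = counts.loc[gid, case_cols].mean() / counts.loc[gid, ctrl_cols].mean()
            se = np.sqrt(1 / (4 * 2 * mu) + 1 / (4 * mu)) * 2  # delta-method, generous
            assert ratio == pytest.approx(2.0, abs=3 * se + 0.05)

    def test_silent_gene_rows_are_all_zero(self, default_sim):
        silent = [gid for gid, b in default_sim.truth.baseline_expression.items() if b == 0]
        assert silent
        assert (default_sim.counts.loc[silent] == 0).all().all()

    def test_unknown_linked_gene_rejected(self):
        cfg = small_config()
        truth = sd.GroundTruth([], [("ghost", 1.0)], [], {"ghost": 10.0}, {})
        with pytest.raises(ValueError, match="unknown gene"):
            sd.simulate_expression([], truth, cfg)


class TestGroundTruth:
    def test_linkage_pairs_reference_promoter_dmrs_and_opposite_sign_degs(self, default_sim):
        truth = default_sim.truth
        assert truth.linkage_pairs
        # validate() ran at construction; re-run explicitly as the contract
        truth.validate(default_sim.genes)

    def test_planted_dmrs_do_not_overlap(self, default_sim):
        ivs = sorted((d.chrom, d.start, d.end) for d in default_sim.truth.planted_dmrs)
        for a, b in zip(ivs, ivs[1:]):
            assert a[0] != b[0] or a[2] <= b[1]

    def test_expression_bins_partition_genes(self, default_sim):
        bins = default_sim.truth.expression_bins
        assert set(bins) == {g.gene_id for g in default_sim.genes}
        assert set(bins.values()) <= {"none", "low", "medium", "high"}


class TestFixtures:
    def test_fixture_directory_byte_identical_for_fixed_seed(self, tmp_path):
        cfg = small_config()
        for sub in ("a", "b"):
            sd.write_fixtures(sd.simulate(cfg), tmp_path / sub)
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names == sorted(p.name for p in (tmp_path / "b").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert mismatch == [] and errors == []

    def test_round_trip_through_pipeline_readers(self, tmp_path):
        cfg = small_config()
        sim = sd.simulate(cfg)
        sd.write_fixtures(sim, tmp_path)
        table = me.load_cx_tables(me.find_cx_dir(tmp_path))
        back_cols = [table.samples.index(s) for s in sim.methylomes.samples]
        np.testing.assert_array_equal(table.meth[:, back_cols], sim.methylomes.meth)
        np.testing.assert_array_equal(table.total[:, back_cols], sim.methylomes.total)
        genes = {g.gene_id: g for g in ann.load_gene_models(tmp_path / "genes.gff3")}
        assert genes == {g.gene_id: g for g in sim.genes}
        counts = tx.read_counts(tmp_path / "counts.tsv")
        pd.testing.assert_frame_equal(counts, sim.counts)

    def test_manifest_lists_exactly_the_planted_dmrs(self, tmp_path):
        cfg = small_config()
        sim = sd.simulate(cfg)
        sd.write_fixtures(sim, tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert len(manifest["planted_dmrs"]) == cfg.n_planted_dmrs
        assert len(manifest["linkage_pairs"]) == len(sim.truth.linkage_pairs)

    def test_gmt_references_only_annotated_genes(self, tmp_path):
        cfg = small_config()
        sim = sd.simulate(cfg)
        sd.write_fixtures(sim, tmp_path)
        gene_ids = {g.gene_id for g in ann.load_gene_models(tmp_path / "genes.gff3")}
        for pw in en.load_gmt(tmp_path / "pathways.gmt"):
            assert pw.genes <= gene_ids
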