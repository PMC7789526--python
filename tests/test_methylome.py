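import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylink import methylome as me
from methylink.annotation import GeneModel

from conftest import bb_table, make_table


class TestSiteLevel:
    @pytest.mark.parametrize(
        "m, t, expected", [(3, 10, 0.3), (0, 10, 0.0), (10, 10, 1.0)]
    )
    def test_direct_formula(self, m, t, expected):
        assert me.site_methylation_level(m, t) == pytest.approx(expected)

    def test_zero_coverage_is_missing_not_zero(self):
        assert np.isnan(me.site_methylation_level(0, 0))

    def test_methylated_above_total_raises(self):
        with pytest.raises(me.MethylationError):
            me.site_methylation_level(11, 10)

    @given(st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_always_in_unit_interval_or_missing(self, m, extra):
        ml = me.site_methylation_level(m, m + extra)
        assert np.isnan(ml) or 0.0 <= ml <= 1.0


class TestWindows:
    def test_pooling_arithmetic(self):
        tab = make_table([100, 200], [[2], [0]], [[4], [4]])
        win = me.window_methylation(tab, {"s0": "g"}, window_bp=10_000)
        assert win["ml"].tolist() == [pytest.approx(2 / 8)]

    def test_empty_window_is_missing(self):
        tab = make_table([100], [[2]], [[4]])  # 0-based coordinate 99
        win = me.window_methylation(
            tab, {"s0": "g"}, window_bp=50, chrom_sizes={"chr1": 150})
        assert win.loc[win["start"] == 50, "ml"].tolist() == [0.5]
        assert np.isnan(win.loc[win["start"] == 0, "ml"]).all()
        assert win.loc[win["start"] == 0, "coverage"].tolist() == [0]

    def test_unsorted_input_rejected(self):
        tab = make_table([100, 200], [[2], [0]], [[4], [4]])
        tab.sites = tab.sites.iloc[::-1].reset_index(drop=True)
        with pytest.raises(me.MethylationError, match="sorted"):
            me.window_methylation(tab, {"s0": "g"})

    def test_window_ml_equals_coverage_weighted_site_mean(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 30_000), size=300, replace=False))
        total = rng.poisson(20, size=(300, 4))
        meth = rng.binomial(total, 0.4)
        tab = make_table(pos, meth, total)
        groups = {f"s{i}": "g" for i in range(4)}
        win = me.window_methylation(tab, groups, window_bp=5000)
        m, t = tab.group_pooled(groups)["g"]
        for r in win.itertuples():
            sel = (pos - 1 >= r.start) & (pos - 1 < r.end)
            if t[sel].sum() == 0:
                assert np.isnan(r.ml)
                continue
            sml = m[sel] / np.maximum(t[sel], 1)
            weighted = np.average(sml[t[sel] > 0], weights=t[sel][t[sel] > 0])
            assert r.ml == pytest.approx(weighted)
            assert r.ml == pytest.approx(m[sel].sum() / t[sel].sum())

    def test_tiling_covers_chromosome_exactly(self):
        tab = make_table([100, 23_456], [[1], [1]], [[2], [2]])
        win = me.window_methylation(
            tab, {"s0": "g"}, window_bp=10_000, chrom_sizes={"chr1": 23_456})
        assert (win["end"] - win["start"]).sum() == 23_456
        assert win["start"].tolist() == [0, 10_000, 20_000]


class TestFeatureLevel:
    def test_uniform_methylation_constant_across_classes(self):
        tab = make_table([10, 110, 210], [[1], [2], [3]], [[2], [4], [6]])
        feats = pd.DataFrame(
            [("chr1", 0, 50, "promoter", "g"), ("chr1", 100, 150, "exon", "g"),
             ("chr1", 200, 250, "intron", "g")],
            columns=["chrom", "start", "end", "feature", "gene_id"])
        out = me.feature_methylation(tab, {"s0": "g"}, feats, contexts=["CpG"])
        assert out["ml"].tolist() == pytest.approx([0.5, 0.5, 0.5])

    def test_class_without_sites_is_missing(self):
        tab = make_table([10], [[1]], [[2]])
        feats = pd.DataFrame([("chr1", 500, 600, "exon", "g")],
                             columns=["chrom", "start", "end", "feature", "gene_id"])
        out = me.feature_methylation(tab, {"s0": "g"}, feats, contexts=["CpG"])
        assert np.isnan(out["ml"]).all()

    def test_site_in_overlapping_classes_counts_in_each(self):
        tab = make_table([10], [[3]], [[4]])
        feats = pd.DataFrame(
            [("chr1", 0, 50, "exon", "g"), ("chr1", 5, 20, "five_prime_utr", "g")],
            columns=["chrom", "start", "end", "feature", "gene_id"])
        out = me.feature_methylation(tab, {"s0": "g"}, feats, contexts=["CpG"])
        assert out["ml"].tolist() == pytest.approx([0.75, 0.75])

    def test_planted_promoter_hypomethylation_detected(self):
        pos = np.arange(1, 2001, 10)
        in_prom = (pos - 1) < 2000 // 2
        mu_case = np.where(in_prom, 0.4, 0.7)
        tab, groups = bb_table(mu_case=mu_case, mu_control=0.7, cov=50, seed=3, pos=pos)
        feats = pd.DataFrame([("chr1", 0, 1000, "promoter", "g")],
                             columns=["chrom", "start", "end", "feature", "gene_id"])
        out = me.feature_methylation(tab, groups, feats, contexts=["CpG"])
        case = out.loc[out["group"] == "case", "ml"].iloc[0]
        control = out.loc[out["group"] == "control", "ml"].iloc[0]
        assert case < control - 0.2


def _flat_gene_fixture(strand="+", L=10_000):
    gene = GeneModel("g", "chr1", 4000, 7000, strand, ((4000, 7000),))
    pos = np.arange(1, L, 7)
    meth = np.ones((len(pos), 1), dtype=int)
    total = np.full((len(pos), 1), 2, dtype=int)
    return gene, make_table(pos, meth, total)


class TestMetagene:
    def test_uniform_methylation_gives_flat_profile(self):
        gene, tab = _flat_gene_fixture()
        prof = me.metagene_profile(tab, {"s0": "g"}, [gene])
        assert len(prof) == 100
        assert prof["ml"].tolist() == pytest.approx([0.5] * 100)

    def test_first_exon_signal_lands_in_early_body_bins(self):
        gene = GeneModel("g", "chr1", 4000, 7000, "+", ((4000, 4600), (5000, 7000)))
        pos = np.arange(1, 10_000, 5)
        in_first_exon = ((pos - 1) >= 4000) & ((pos - 1) < 4600)
        meth = np.where(in_first_exon, 5, 0)[:, None]
        total = np.full((len(pos), 1), 5)
        tab = make_table(pos, meth, total)
        prof = me.metagene_profile(tab, {"s0": "g"}, [gene]).set_index("bin")
        body = prof[prof["segment"] == "body"]
        early = body.iloc[:12]["ml"]
        late = body.iloc[20:]["ml"]
        assert early.mean() > 0.9
        assert np.nansum(late.to_numpy()) == 0

    def test_mirrored_minus_strand_fixture_gives_identical_profile(self, rng):
        L = 12_000
        gene = GeneModel("g", "chr1", 4000, 7000, "+", ((4000, 7000),))
        pos = np.sort(rng.choice(np.arange(1, L), size=800, replace=False))
        total = rng.poisson(20, size=(len(pos), 2))
        meth = rng.binomial(total, np.linspace(0.1, 0.9, len(pos))[:, None])
        tab = make_table(pos, meth, total)
        fwd = me.metagene_profile(tab, {"s0": "g", "s1": "g"}, [gene])
        # reverse-complement the fixture: mirror coordinates, flip strand
        mpos = L + 1 - pos[::-1]
        mtab = make_table(mpos, meth[::-1], total[::-1])
        mgene = GeneModel("g", "chr1", L - 7000, L - 4000, "-", ((L - 7000, L - 4000),))
        rev = me.metagene_profile(mtab, {"s0": "g", "s1": "g"}, [mgene])
        np.testing.assert_allclose(fwd["ml"], rev["ml"], atol=1e-12)
        assert fwd["coverage"].tolist() == rev["coverage"].tolist()

    def test_short_gene_excluded(self, caplog):
        gene = GeneModel("g", "chr1", 100, 150, "+", ((100, 150),))
        tab = make_table([120], [[1]], [[2]])
        with caplog.at_level("WARNING"):
            prof = me.metagene_profile(tab, {"s0": "g"}, [gene])
        assert "excluded" in caplog.text
        assert np.isnan(prof["ml"]).all()


class TestGenomeWide:
    def test_fully_methylated_sites_give_one(self):
        tab = make_table([10, 20], [[4], [6]], [[4], [6]])
        assert me.genome_wide_level(tab, {"s0": "g"})["g"] == 1.0

    def test_invariant_to_chromosome_order(self, rng):
        total = rng.poisson(20, size=(100, 2))
        meth = rng.binomial(total, 0.6)
        sites = pd.DataFrame({
            "chrom": ["chr2"] * 50 + ["chr1"] * 50,
            "pos": list(range(1, 51)) * 2, "strand": "+", "context": "CpG"})
        t1 = me.CytosineTable(sites, meth, total, ["a", "b"])
        order = np.lexsort((sites["pos"], sites["chrom"]))
        t2 = me.CytosineTable(sites.iloc[order].reset_index(drop=True),
                              meth[order], total[order], ["a", "b"])
        groups = {"a": "g", "b": "g"}
        assert me.genome_wide_level(t1, groups) == me.genome_wide_level(t2, groups)

    def test_no_covered_site_is_missing(self):
        tab = make_table([10], [[0]], [[0]])
        assert np.isnan(me.genome_wide_level(tab, {"s0": "g"})["g"])


class TestPoolingIdentity:
    """Window/feature/genome summaries must equal per-site count recomputation."""

    def test_genome_level_equals_count_ratio(self, rng):
        total = rng.poisson(15, size=(500, 8))
        meth = rng.binomial(total, 0.3)
        tab = make_table(np.arange(1, 501), meth, total,
                         samples=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        lv = me.genome_wide_level(tab, groups)
        assert lv["a"] == pytest.approx(meth[:, :4].sum() / total[:, :4].sum())
        assert lv["b"] == pytest.approx(meth[:, 4:].sum() / total[:, 4:].sum())


class TestCxIO:
    def test_round_trip(self, tmp_path, rng):
        df = pd.DataFrame({
            "chrom": "chr1", "pos": np.arange(1, 51), "strand": "+",
            "meth": rng.integers(0, 5, 50), "unmeth": rng.integers(0, 5, 50),
            "context": "CpG"})
        me.write_cx_report(df, tmp_path / "s.cx.tsv")
        back = me.read_cx_report(tmp_path / "s.cx.tsv")
        pd.testing.assert_frame_equal(df[me.CX_COLUMNS], back)

    def test_load_cx_tables_outer_joins_missing_sites(self, tmp_path):
        a = pd.DataFrame({"chrom": "chr1", "pos": [1, 5], "strand": "+",
                          "meth": [1, 2], "unmeth": [1, 0], "context": "CpG"})
        b = pd.DataFrame({"chrom": "chr1", "pos": [5], "strand": "+",
                          "meth": [3], "unmeth": [1], "context": "CpG"})
        me.write_cx_report(a, tmp_path / "a.cx.tsv")
        me.write_cx_report(b, tmp_path / "b.cx.tsv")
        tab = me.load_cx_tables(me.find_cx_dir(tmp_path))
        assert len(tab) == 2
        assert tab.total[0].tolist() == [2, 0]  # site 1 absent from b
        assert tab.meth[1].tolist() == [2, 3]
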