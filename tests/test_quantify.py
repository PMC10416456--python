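import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m6adyn import quantify
from m6adyn.io_formats import PeakTable, STAGES
from tests.conftest import make_counts


class TestFilterPeaks:
    def test_strictly_below_five_in_any_sample_removed(self):
        counts = make_counts(
            ip=[[9, 9, 9, 9], [9, 9, 9, 9]],
            inp=[[5, 5, 5, 5], [5, 5, 5, 4]],
        )
        kept, removed = quantify.filter_peaks(counts, min_input=5)
        assert list(kept.peak_ids) == ["p0"]
        assert list(removed) == ["p1"]

    def test_min_input_zero_is_identity(self):
        counts = make_counts(ip=[[1, 1, 1, 1]], inp=[[0, 0, 0, 0]])
        kept, removed = quantify.filter_peaks(counts, min_input=0)
        assert len(removed) == 0

    def test_all_removed_raises(self):
        counts = make_counts(ip=[[1, 1, 1, 1]], inp=[[0, 0, 0, 0]])
        with pytest.raises(ValueError, match="depth"):
            quantify.filter_peaks(counts, min_input=5)


class TestNormalize:
    def test_cpm_definition(self):
        counts = make_counts(ip=[[10, 10, 10, 10]], inp=[[10, 10, 10, 10]])
        ip_cpm, _ = quantify.normalize(counts)
        assert ip_cpm.iloc[0, 0] == pytest.approx(10.0)

    def test_doubling_one_libsize_halves_that_column_only(self):
        c1 = make_counts(ip=[[10, 10, 10, 10]], inp=[[10, 10, 10, 10]])
        c2 = make_counts(
            ip=[[10, 10, 10, 10]], inp=[[10, 10, 10, 10]],
            ip_lib=[2 * 10**6, 10**6, 10**6, 10**6],
        )
        a, _ = quantify.normalize(c1)
        b, _ = quantify.normalize(c2)
        assert b.iloc[0, 0] == pytest.approx(a.iloc[0, 0] / 2)
        assert (b.iloc[0, 1:] == a.iloc[0, 1:]).all()


class TestPeakLevels:
    def test_ip_over_input(self):
        counts = make_counts(ip=[[30, 30, 30, 30]], inp=[[10, 10, 10, 10]])
        lv = quantify.peak_m6a_levels(*quantify.normalize(counts))
        assert lv.iloc[0, 0] == pytest.approx(3.0)

    def test_equal_ip_and_input_gives_one(self):
        counts = make_counts(ip=[[7, 7, 7, 7]], inp=[[7, 7, 7, 7]])
        lv = quantify.peak_m6a_levels(*quantify.normalize(counts))
        assert np.allclose(lv, 1.0)

    def test_unequal_libsizes_hand_computed(self):
        # IP lib 2e6, input lib 1e6, raw IP 60, raw input 10:
        # (60/2)/(10/1) = 3.0
        counts = make_counts(
            ip=[[60] * 4], inp=[[10] * 4], ip_lib=[2 * 10**6] * 4, in_lib=[10**6] * 4
        )
        lv = quantify.peak_m6a_levels(*quantify.normalize(counts))
        assert lv.iloc[0, 0] == pytest.approx(3.0)

    def test_rescaling_all_ip_libsizes_leaves_levels_unchanged(self, small_study):
        from dataclasses import replace

        kept, _ = quantify.filter_peaks(small_study.counts)
        lv1 = quantify.peak_m6a_levels(*quantify.normalize(kept))
        scaled = replace(kept, ip_libsize=kept.ip_libsize * 7)
        lv2 = quantify.peak_m6a_levels(*quantify.normalize(scaled))
        # a common factor on the IP side scales every level identically,
        # so all ratios between stages and peaks are unchanged
        np.testing.assert_allclose(lv2.to_numpy(), lv1.to_numpy() / 7, rtol=1e-12)


class TestAggregateLevels:
    def make_peaks(self, gene_ids):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": range(0, 100 * len(gene_ids), 100),
                "end": range(50, 100 * len(gene_ids) + 50, 100),
                "strand": "+",
                "gene_id": pd.array(gene_ids, dtype="string"),
                "region": "CDS",
            },
            index=pd.Index([f"p{i}" for i in range(len(gene_ids))], name="peak_id"),
        )
        return PeakTable(df)

    def test_pooled_ratio_hand_example(self):
        # peaks of one gene: IP (30,10), input (10,10) -> (30+10)/(10+10) = 2
        counts = make_counts(ip=[[30] * 4, [10] * 4], inp=[[10] * 4, [10] * 4])
        peaks = self.make_peaks(["geneA", "geneA"])
        prof = quantify.aggregate_levels(*quantify.normalize(counts), peaks)
        assert prof.gene_level.loc["geneA", "D0"] == pytest.approx(2.0)

    def test_single_peak_gene_equals_peak_level(self, small_study, small_profile):
        kept, prof = small_profile
        labeled = small_study.peaks.df.loc[kept.peak_ids].dropna(subset=["gene_id"])
        singles = labeled.gene_id.value_counts()
        g = singles[singles == 1].index[0]
        pid = labeled.index[labeled.gene_id == g][0]
        pd.testing.assert_series_equal(
            prof.gene_level.loc[g], prof.peak_level.loc[pid], check_names=False
        )

    def test_sample_level_is_one_when_all_peaks_at_one(self):
        counts = make_counts(ip=[[5] * 4, [9] * 4], inp=[[5] * 4, [9] * 4])
        peaks = self.make_peaks(["geneA", "geneB"])
        prof = quantify.aggregate_levels(*quantify.normalize(counts), peaks)
        assert np.allclose(prof.sample_level, 1.0)

    def test_gene_level_bounded_by_peak_levels(self, small_study, small_profile):
        kept, prof = small_profile
        d = small_study.peaks.df.loc[kept.peak_ids].dropna(subset=["gene_id"])
        grp_min = prof.peak_level.loc[d.index].groupby(d.gene_id).min()
        grp_max = prof.peak_level.loc[d.index].groupby(d.gene_id).max()
        gl = prof.gene_level.loc[grp_min.index]
        assert (gl.to_numpy() >= grp_min.to_numpy() - 1e-12).all()
        assert (gl.to_numpy() <= grp_max.to_numpy() + 1e-12).all()


class TestCountM6aGenes:
    def test_threshold_is_strict(self):
        lv = pd.DataFrame({s: [1.6, 1.4] for s in STAGES},
                          index=pd.Index(["a", "b"], name="gene_id"))
        expr = pd.DataFrame({s: [10.0, 10.0] for s in STAGES}, index=lv.index)
        out = quantify.count_m6a_genes(lv, expr, threshold=1.5)
        assert (out.n_modified == 1).all()
        assert (out.n_expressed == 2).all()

    def test_infinite_threshold_counts_nothing(self):
        lv = pd.DataFrame({s: [5.0] for s in STAGES}, index=pd.Index(["a"]))
        expr = pd.DataFrame({s: [10.0] for s in STAGES}, index=lv.index)
        assert (quantify.count_m6a_genes(lv, expr, threshold=np.inf).n_modified == 0).all()


class TestMetagene:
    def peak_at(self, mid, name="pk"):
        df = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [mid - 50],
                "end": [mid + 50],
                "strand": ["+"],
                "gene_id": pd.array(["geneA"], dtype="string"),
                "region": ["CDS"],
            },
            index=pd.Index([name], name="peak_id"),
        )
        return PeakTable(df)

    def test_cds_start_maps_to_one(self, toy_annotation):
        c = quantify.metagene_coordinates(self.peak_at(1600), toy_annotation)
        assert c.iloc[0] == pytest.approx(1.0)

    def test_cds_midpoint_maps_to_one_point_five(self, toy_annotation):
        c = quantify.metagene_coordinates(self.peak_at(3400), toy_annotation)
        assert c.iloc[0] == pytest.approx(1.5)

    def test_gene_without_utrs_contributes_to_cds_segment(self):
        from m6adyn.io_formats import GeneAnnotation

        ann = GeneAnnotation(
            pd.DataFrame(
                {
                    "chrom": ["chr1"],
                    "strand": ["+"],
                    "tx_start": [1000],
                    "tx_end": [7000],
                    "cds_start": [1000],
                    "cds_end": [7000],
                },
                index=pd.Index(["geneA"], name="gene_id"),
            )
        )
        c = quantify.metagene_coordinates(self.peak_at(4000), toy_annotation := ann)
        assert 1.0 <= c.iloc[0] < 2.0

    def test_uniform_midpoints_give_flat_density(self, toy_annotation):
        rng = np.random.default_rng(0)
        mids = rng.integers(1650, 5150, size=3000)  # inside geneA CDS
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": mids - 10,
                "end": mids + 10,
                "strand": "+",
                "gene_id": pd.array(["geneA"] * len(mids), dtype="string"),
                "region": "CDS",
            },
            index=pd.Index([f"p{i}" for i in range(len(mids))], name="peak_id"),
        )
        coords = quantify.metagene_coordinates(PeakTable(df), toy_annotation)
        hist, _ = np.histogram(coords, bins=30, range=(1.0, 2.0))
        assert stats.chisquare(hist).pvalue > 0.01


class TestScanDrach:
    @pytest.mark.parametrize(
        "seq,n", [("GGACT", 1), ("CCCCC", 0), ("GGACAGGACT", 2), ("AAACA", 1)]
    )
    def test_counts(self, seq, n):
        assert quantify.scan_drach({"x": seq}).loc["x", "drach_count"] == n

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(1)
        motif_ok = (
            lambda w: w[0] in "AGT" and w[1] in "AG" and w[2] == "A" and w[3] == "C"
            and w[4] in "ACT"
        )
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            oracle = sum(motif_ok(seq[i : i + 5]) for i in range(len(seq) - 4))
            assert quantify.scan_drach({"s": seq}).loc["s", "drach_count"] == oracle

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            quantify.scan_drach({"x": "GGACU"})
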