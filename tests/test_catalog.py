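"""Catalog filters and the log-density signal matrix."""

import numpy as np
import pytest

from ernapredict import GeneratorConfig, TrackLibrary
from ernapredict.catalog import (EnhancerRegion, apply_mappability_filter,
                                 compute_signal_matrix,
                                 define_intergenic_enhancers)
from ernapredict.io_formats import (GeneRecord, GenomicInterval,
                                    MappabilitySegment)
from ernapredict.synthetic import generate_annotation

from conftest import build_pipeline_inputs


def _gene(gid="g1", chrom="chr1", strand="+", start=50_000, end=60_000):
    tss = start if strand == "+" else end - 1
    return GeneRecord(gid, chrom, strand, tss, start, end)


def _peak(chrom="chr1", mid=100_000, w=300, name="p"):
    return GenomicInterval(chrom, mid - w // 2, mid + w // 2, name=name)


class TestIntergenicFilter:
    def test_distant_peak_retained(self):
        kept, removed = define_intergenic_enhancers(
            [_peak(mid=100_000)], [_gene()], [])
        assert len(kept) == 1 and not removed
        win = kept[0].interval
        assert (win.start, win.end) == (99_000, 101_000)   # centered window

    def test_peak_window_within_3kb_of_tss_removed(self):
        # TSS at 50,000; window start 52,999 -> gap 2,999 < 3,000
        peak = _peak(mid=53_999)
        gene = _gene(start=50_000, end=51_000)
        kept, removed = define_intergenic_enhancers([peak], [gene], [])
        assert not kept and removed == {"p": "tss_proximal"}

    def test_gap_exactly_3kb_retained(self):
        peak = _peak(mid=54_000)                 # window [53,000, 55,000)
        gene = _gene(start=50_000, end=51_000)   # TSS 50,000: gap exactly 3,000
        kept, _ = define_intergenic_enhancers([peak], [gene], [])
        assert kept and kept[0].interval.start - gene.tss == 3_000

    def test_peak_inside_gene_body_removed(self):
        kept, removed = define_intergenic_enhancers(
            [_peak(mid=55_000)], [_gene()], [])
        assert removed == {"p": "gene_body"}

    def test_k4me3_proximity_removed(self):
        k4 = GenomicInterval("chr1", 104_000, 105_000)
        kept, removed = define_intergenic_enhancers(
            [_peak(mid=100_000)], [], [k4])    # window end 101,000; gap 3,000
        assert kept                              # exactly 3 kb away: retained
        k4_near = GenomicInterval("chr1", 103_999, 105_000)
        kept, removed = define_intergenic_enhancers(
            [_peak(mid=100_000)], [], [k4_near])
        assert removed == {"p": "k4me3_proximal"}

    def test_empty_peak_set_yields_empty_catalog(self):
        kept, removed = define_intergenic_enhancers([], [_gene()], [])
        assert kept == [] and removed == {}


class TestMappabilityFilter:
    def _enh(self):
        return EnhancerRegion("e1", GenomicInterval("chr1", 99_000, 101_000),
                              _peak())

    @pytest.mark.parametrize("value,kept_expected",
                             [(0.84, False), (0.85, True), (1.0, True)])
    def test_strict_less_than_threshold(self, value, kept_expected):
        segs = [MappabilitySegment(GenomicInterval("chr1", 0, 200_000), value)]
        kept, removed = apply_mappability_filter([self._enh()], segs, 0.85)
        assert bool(kept) == kept_expected
        if kept_expected:
            assert kept[0].mean_mappability == pytest.approx(value)

    def test_uncovered_bases_count_as_zero(self):
        # half the window covered at 1.0, half uncovered -> mean 0.5
        segs = [MappabilitySegment(GenomicInterval("chr1", 99_000, 100_000), 1.0)]
        kept, removed = apply_mappability_filter([self._enh()], segs, 0.85)
        assert removed == ["e1"]
        kept, _ = apply_mappability_filter([self._enh()], segs, 0.5)
        assert kept[0].mean_mappability == pytest.approx(0.5)


class TestSignalMatrix:
    def test_density_formula_hand_computed(self):
        # 10 reads in a 1,000 bp window of a 1e6-read track -> density 10,
        # log2(10 + 1) = 3.459...
        enh = [EnhancerRegion("e1", GenomicInterval("chr1", 0, 1000), _peak())]
        reads = [GenomicInterval("chr1", i * 50, i * 50 + 50) for i in range(10)]
        lib = TrackLibrary()
        lib.add_intervals("M", reads, total=1_000_000)
        sm = compute_signal_matrix(enh, lib)
        assert sm.marks.loc["e1", "M"] == pytest.approx(np.log2(11))

    def test_zero_reads_with_pseudocount_one_gives_zero(self):
        enh = [EnhancerRegion("e1", GenomicInterval("chr1", 0, 1000), _peak())]
        lib = TrackLibrary()
        lib.add_intervals("M", [GenomicInterval("chr2", 0, 50)], total=1000)
        sm = compute_signal_matrix(enh, lib)
        assert sm.marks.loc["e1", "M"] == 0.0

    def test_depth_normalization_invariance(self):
        enh = [EnhancerRegion("e1", GenomicInterval("chr1", 0, 1000), _peak())]
        reads = [GenomicInterval("chr1", i, i + 50) for i in range(7)]
        lib1, lib2 = TrackLibrary(), TrackLibrary()
        lib1.add_intervals("M", reads, total=10_000)
        lib2.add_intervals("M", reads + [
            GenomicInterval("chr1", i + 100, i + 150) for i in range(7)],
            total=20_000)
        # doubling both window reads and the total leaves the density fixed
        v1 = compute_signal_matrix(enh, lib1).marks.loc["e1", "M"]
        v2 = compute_signal_matrix(enh, lib2).marks.loc["e1", "M"]
        assert v1 == pytest.approx(v2)

    def test_zero_total_track_rejected(self):
        enh = [EnhancerRegion("e1", GenomicInterval("chr1", 0, 1000), _peak())]
        lib = TrackLibrary()
        lib.add_intervals("M", [])
        with pytest.raises(ValueError, match="zero total"):
            compute_signal_matrix(enh, lib)

    def test_tsv_roundtrip(self, small_data, tmp_path):
        path = str(tmp_path / "signal.tsv")
        small_data.signal.to_tsv(path)
        from ernapredict.catalog import SignalMatrix
        back = SignalMatrix.from_tsv(path)
        assert list(back.marks.columns) == list(small_data.signal.marks.columns)
        np.testing.assert_allclose(back.marks.to_numpy(),
                                   small_data.signal.marks.to_numpy(),
                                   atol=1e-6)
        np.testing.assert_allclose(back.y_plus.to_numpy(),
                                   small_data.signal.y_plus.to_numpy(),
                                   atol=1e-6)


class TestCatalogProperties:
    def test_planted_violations_removed_exactly(self):
        cfg = GeneratorConfig(n_enhancers=80, n_genes=100, seed=21,
                              n_plant_genebody=6, n_plant_tss_proximal=4)
        genes, sites, truth = generate_annotation(cfg)
        kept, removed = define_intergenic_enhancers(
            sites, genes, [], cfg.tss_exclusion_bp, cfg.window_half_bp)
        assert set(removed) == set(truth.violations)
        assert {k: v for k, v in removed.items()} == truth.violations

    def test_filter_order_invariance(self, small_data):
        cfg = small_data.cfg
        from ernapredict.synthetic import _mappability_track
        mapp = _mappability_track(cfg, small_data.genes, small_data.sites,
                                  small_data.truth)
        a, _ = define_intergenic_enhancers(small_data.sites, small_data.genes,
                                           [], cfg.tss_exclusion_bp,
                                           cfg.window_half_bp)
        a, _ = apply_mappability_filter(a, mapp)
        b, _ = apply_mappability_filter(
            [EnhancerRegion(s.name,
                            GenomicInterval(s.chrom, s.midpoint - 1000,
                                            s.midpoint + 1000, name=s.name), s)
             for s in small_data.sites], mapp)
        b, _ = define_intergenic_enhancers(
            [r.source_peak for r in b], small_data.genes, [],
            cfg.tss_exclusion_bp, cfg.window_half_bp)
        assert [r.id for r in a] == [r.id for r in b]

    def test_catalog_idempotent(self, small_data):
        cfg = small_data.cfg
        once = small_data.regions
        again, removed = define_intergenic_enhancers(
            [r.source_peak for r in once], small_data.genes, [],
            cfg.tss_exclusion_bp, cfg.window_half_bp)
        assert not removed
        assert [r.id for r in again] == [r.id for r in once]
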