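"""Gene assignment, H3K27ac status, subgroups, expression, transfer."""

import numpy as np
import pandas as pd
import pytest

from ernapredict import GeneratorConfig
from ernapredict.activity import (assign_genes, classify_h3k27ac,
                                  compare_expression, cross_celltype_predict,
                                  subgroup_enhancers)
from ernapredict.catalog import EnhancerRegion
from ernapredict.io_formats import (ExpressionRecord, GeneRecord,
                                    GenomicInterval)
from ernapredict.labeling import AMBIGUOUS, NEGATIVE, POSITIVE
from ernapredict.logit import fit_logistic
from ernapredict.metrics import auc_score

from conftest import build_pipeline_inputs


def _enh(eid="e1", chrom="chr1", center=500_000):
    return EnhancerRegion(eid, GenomicInterval(chrom, center - 1000,
                                               center + 1000),
                          GenomicInterval(chrom, center - 150, center + 150,
                                          name=eid))


def _gene(gid, tss, chrom="chr1"):
    return GeneRecord(gid, chrom, "+", tss, tss, tss + 1000)


class TestAssignGenes:
    def test_nearest_tss_wins(self):
        links = assign_genes([_enh()], [_gene("far", 580_000),
                                        _gene("near", 550_000)])
        assert links[0].gene_id == "near" and links[0].distance == 50_000

    def test_beyond_100kb_unassigned(self):
        links = assign_genes([_enh()], [_gene("g", 500_000 + 100_001)])
        assert links[0].gene_id is None
        links = assign_genes([_enh()], [_gene("g", 500_000 + 100_000)])
        assert links[0].gene_id == "g"

    def test_equidistant_tie_goes_to_lower_coordinate(self):
        links = assign_genes([_enh()], [_gene("hi", 530_000),
                                        _gene("lo", 470_000)])
        assert links[0].gene_id == "lo"

    def test_translation_invariance(self):
        genes = [_gene("a", 460_000), _gene("b", 540_000)]
        base = assign_genes([_enh()], genes)
        shift = 123_456
        genes2 = [_gene(g.gene_id, g.tss + shift) for g in genes]
        moved = assign_genes([_enh(center=500_000 + shift)], genes2)
        assert [(l.gene_id, l.distance) for l in base] == \
               [(l.gene_id, l.distance) for l in moved]


class TestClassifyK27ac:
    def test_overlapping_peak_is_positive(self):
        peak = GenomicInterval("chr1", 499_500, 500_500)
        assert classify_h3k27ac([_enh()], [peak]).loc["e1"] == "+"

    def test_2kb_boundary(self):
        # window ends at 501,000; peak gap exactly 2,000 -> +, 2,001 -> -
        at = GenomicInterval("chr1", 503_000, 503_500)
        assert classify_h3k27ac([_enh()], [at]).loc["e1"] == "+"
        beyond = GenomicInterval("chr1", 503_001, 503_500)
        assert classify_h3k27ac([_enh()], [beyond]).loc["e1"] == "-"

    def test_no_peaks_everything_negative(self):
        assert classify_h3k27ac([_enh()], []).loc["e1"] == "-"


class TestSubgroups:
    def test_cross_product_and_ambiguous_exclusion(self):
        erna = pd.Series({"a": POSITIVE, "b": NEGATIVE, "c": AMBIGUOUS,
                          "d": POSITIVE})
        k27 = pd.Series({"a": "+", "b": "+", "c": "+", "d": "-"})
        sub = subgroup_enhancers(erna, k27)
        assert sub.to_dict() == {"a": "eRNA+K27ac+", "b": "eRNA-K27ac+",
                                 "d": "eRNA+K27ac-"}

    def test_sizes_sum_to_unambiguous(self, small_data):
        k27 = classify_h3k27ac(small_data.regions, [])
        sub = subgroup_enhancers(small_data.labels.labels, k27)
        assert len(sub) == len(small_data.labels.training_ids)


class TestCompareExpression:
    def _links(self, mapping):
        from ernapredict.activity import EnhancerGeneLink
        return [EnhancerGeneLink(e, g, 0) for e, g in mapping.items()]

    def test_identical_multisets_give_p_one(self):
        sub = pd.Series({"a": "g1", "b": "g2"})
        links = self._links({"a": "x1", "b": "x2"})
        expr = [ExpressionRecord("x1", 5.0), ExpressionRecord("x2", 5.0)]
        out = compare_expression(sub, links, expr, pairs=[("g1", "g2")])
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_minimal_one_vs_one(self):
        sub = pd.Series({"a": "g1", "b": "g2"})
        links = self._links({"a": "x1", "b": "x2"})
        expr = [ExpressionRecord("x1", 5.0), ExpressionRecord("x2", 7.0)]
        out = compare_expression(sub, links, expr, pairs=[("g1", "g2")])
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_gene_deduplicated_within_group(self):
        sub = pd.Series({"a": "g1", "b": "g1", "c": "g2"})
        links = self._links({"a": "x1", "b": "x1", "c": "x2"})
        expr = [ExpressionRecord("x1", 5.0), ExpressionRecord("x2", 6.0)]
        out = compare_expression(sub, links, expr, pairs=[("g1", "g2")])
        assert out["n_a"].iloc[0] == 1                 # x1 counted once

    def test_empty_group_skipped_with_nan(self):
        sub = pd.Series({"a": "g1"})
        links = self._links({"a": None})
        out = compare_expression(sub, links, [], pairs=[("g1", "g2")])
        assert np.isnan(out["p_value"].iloc[0])

    def test_planted_expression_shift_detected(self):
        # measured eRNA groups should separate associated gene expression
        from ernapredict.synthetic import generate_expression
        data = build_pipeline_inputs(GeneratorConfig(
            n_enhancers=600, n_genes=700, seed=23))
        expr = generate_expression(data.cfg, data.truth)
        links = assign_genes(data.regions, data.genes)
        erna = data.labels.labels
        k27 = classify_h3k27ac(data.regions, [])        # all K27ac-
        sub = subgroup_enhancers(erna, k27)
        out = compare_expression(sub, links, expr,
                                 pairs=[("eRNA+K27ac-", "eRNA-K27ac-")])
        assert out["p_value"].iloc[0] < 1e-6
        assert out["median_a"].iloc[0] > out["median_b"].iloc[0]


class TestCrossCellType:
    def test_same_matrix_reproduces_in_sample(self, small_data):
        model = fit_logistic(small_data.signal, small_data.labels)
        from ernapredict.logit import predict_proba
        p_in = predict_proba(model, small_data.signal)
        p_x, ev = cross_celltype_predict(model, small_data.signal,
                                         restandardize=False)
        np.testing.assert_allclose(p_x.to_numpy(), p_in.to_numpy())
        assert ev is None

    def test_missing_mark_named_in_error(self, small_data):
        model = fit_logistic(small_data.signal, small_data.labels)
        crippled = small_data.signal.marks.drop(columns=["H3K9ac"])
        from ernapredict.catalog import SignalMatrix
        with pytest.raises(ValueError, match="H3K9ac"):
            cross_celltype_predict(model, SignalMatrix(crippled))

    def test_transfer_auc_close_to_in_sample(self, small_data):
        # same planted effect structure, different cell type (seed)
        other = build_pipeline_inputs(GeneratorConfig(
            n_enhancers=600, n_genes=700, seed=37))
        model = fit_logistic(small_data.signal, small_data.labels,
                             ["H3K27ac", "H3K9ac", "H2BK120ac", "H3K27me3"])
        from ernapredict.logit import predict_proba
        ids = small_data.labels.training_ids
        in_auc = auc_score(small_data.labels.binary(),
                           predict_proba(model,
                                         small_data.signal.subset_rows(ids)))
        _, ev = cross_celltype_predict(model, other.signal,
                                       other.labels.binary(
                                           other.labels.training_ids))
        assert abs(ev["auc"] - in_auc) < 0.03
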