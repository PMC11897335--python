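"""Annotation-table accounting: lengths, signed gaps, codon calls, validation."""

import pandas as pd
import pytest

from mitochar.annotation import (
    build_annotation_table,
    call_start_codon,
    call_stop_codon,
    feature_length,
    gap_to_next,
    validate_gene_complement,
)
from mitochar.genome import CircularGenome, FeatureAnnotation
from mitochar.simulate import GenomeParams, generate_mitogenome


def feat(name, start, end, cls="PCG", strand="+", wraps=False):
    return FeatureAnnotation(name=name, feature_class=cls, strand=strand,
                             start=start, end=end, wraps_origin=wraps)


class TestFeatureLength:
    @pytest.mark.parametrize("start,end,wraps,expected", [
        (6_464, 8_200, False, 1_737),   # the longest PCG of the reference table
        (3_960, 4_124, False, 165),     # the shortest (atp8)
        (15_394, 3, True, 5),           # wrap arithmetic across the origin
    ])
    def test_lengths(self, start, end, wraps, expected):
        f = feat("x", start, end, wraps=wraps)
        assert feature_length(f, 15_395) == expected


class TestGapToNext:
    @pytest.mark.parametrize("end_i,start_j,expected", [
        (196, 259, 62),    # the longest intergenic spacer
        (66, 67, 0),       # abutting
        (4_124, 4_118, -7),  # the atp8/atp6 overlap
    ])
    def test_signed_gap(self, end_i, start_j, expected):
        a = feat("a", 100, end_i) if end_i >= 100 else feat("a", 1, end_i)
        b = feat("b", start_j, start_j + 500)
        assert gap_to_next(a, b) == expected

    def test_origin_crossing_gap(self):
        a = feat("CR", 15_021, 15_395, cls="control_region")
        b = feat("trnM", 1, 66, cls="tRNA")
        assert gap_to_next(a, b, genome_length=15_395) == 0


class TestStartCodon:
    def test_atg_and_att_are_canonical(self):
        assert call_start_codon("ATGAAATAA").codon == "ATG"
        assert call_start_codon("ATGAAATAA").classification == "canonical"
        assert call_start_codon("ATTAAATAA").classification == "canonical"

    def test_cga_is_alternative(self):
        sc = call_start_codon("CGAAAATAA")
        assert (sc.codon, sc.classification) == ("CGA", "alternative")

    def test_other_starts_flagged(self):
        assert call_start_codon("GGGAAATAA").classification == "unexpected"


class TestStopCodon:
    def test_complete_taa(self):
        st = call_stop_codon("ATGAAATAA")
        assert (st.label, st.complete, st.truncated) == ("TAA", True, False)

    @pytest.mark.parametrize("n_codons,tail,label", [
        (227, "T", "T"),    # cox2-style length 682 = 227*3 + 1
        (446, "T", "T"),    # nad4-style length 1339
        (100, "TA", "TA"),
    ])
    def test_truncated_stops_from_length_mod3(self, n_codons, tail, label):
        cds = "ATG" + "GCA" * (n_codons - 1) + tail
        st = call_stop_codon(cds)
        assert (st.label, st.truncated, st.inconsistent) == (label, True, False)

    def test_truncation_requires_t_tail(self):
        st = call_stop_codon("ATGGCAC")  # trailing C cannot complete to TAA
        assert st.truncated and st.inconsistent

    def test_internal_stop_flagged_with_position(self):
        st = call_stop_codon("ATGTAAGCATAA")
        assert st.inconsistent and "codon 2" in st.note

    def test_polyadenylation_completion_upgrades_truncated_stop(self):
        # appending AA to any T-truncated CDS yields a complete TAA
        for n in (5, 12, 227):
            cds = "ATG" + "GGT" * n + "T"
            assert call_stop_codon(cds).label == "T"
            assert call_stop_codon(cds + "AA").label == "TAA"


class TestPublishedTable:
    """The reconstructed table must reproduce every published value."""

    @pytest.mark.parametrize("assembly", ["cat07", "cat08"])
    def test_lengths_and_gaps_match_printed_columns(self, assembly, request,
                                                    published_values):
        table = request.getfixturevalue(f"{assembly}_table")
        df = table.to_dataframe().set_index("gene")
        for gene, row in published_values.iterrows():
            assert df.loc[gene, "length"] == row[f"length_{assembly}"], gene
            printed_gap = row[f"gap_{assembly}"]
            if not pd.isna(printed_gap):
                assert df.loc[gene, "gap_to_next"] == printed_gap, gene

    def test_spacer_and_overlap_summary(self, cat07_table):
        s = cat07_table.summary()
        assert s["spacer_count"] == 19 and s["spacer_range"] == (1, 62)
        assert s["overlap_range"] == (1, 8)
        assert sorted(cat07_table.overlaps()) == [1, 1, 2, 3, 5, 7, 8]

    def test_circular_closure(self, cat07_table, cat08_table):
        assert cat07_table.closure_residual() == 0
        assert cat08_table.closure_residual() == 0

    def test_truncated_stop_genes_are_exactly_the_mod3_ones(self, cat07_table,
                                                            published_values):
        # the published T-stop genes are precisely those with length % 3 == 1
        printed_t = set(published_values.index[
            published_values.stop_codon == "T"])
        mod3_t = {r.name for r in cat07_table.rows
                  if r.feature.feature_class == "PCG" and r.length % 3 == 1}
        assert printed_t == mod3_t == {"cox2", "nad4"}

    def test_gaps_invariant_under_rotation(self, synth_truth):
        from mitochar.genome import rotate_to_feature
        g, feats = rotate_to_feature(synth_truth.genome, synth_truth.features,
                                     "cox1")
        rotated = build_annotation_table(feats, g)
        gaps = {r.name: r.gap_to_next for r in synth_truth.table.rows}
        gaps_rot = {r.name: r.gap_to_next for r in rotated.rows}
        assert gaps == gaps_rot


class TestRegionLookup:
    def test_overlap_priority_pcg_over_trna(self, cat07_table):
        # position 3 038 sits in both cox1 (PCG) and trnL1 (tRNA)
        assert cat07_table.region_of(3_038)[0] == "cox1"
        assert cat07_table.region_of(3_100)[0] == "trnL1"

    def test_intergenic_and_cr(self, cat07_table):
        assert cat07_table.region_of(230)[0] == "intergenic"  # trnQ-nad2 spacer
        assert cat07_table.region_of(15_100)[0] == "CR"

    def test_spacer_span(self, cat07_table):
        assert cat07_table.spacer_span("trnS2", "nad1") == (11_810, 11_826)


class TestToyTables:
    def test_two_abutting_genes_give_zero_gap(self):
        g = CircularGenome("t", "ATGATTTAA" + "ATGCCCTAA" + "AA")
        feats = [feat("nad2", 1, 9), feat("cox1", 10, 18)]
        table = build_annotation_table(feats, g)
        assert table.rows[0].gap_to_next == 0
        assert table.rows[0].stop_codon == "TAA"
        assert table.rows[1].start_codon == "ATG"

    def test_identical_coordinates_flagged_not_fatal(self):
        g = CircularGenome("t", "A" * 60)
        feats = [feat("trnM", 1, 30, cls="tRNA"), feat("trnI", 1, 30, cls="tRNA")]
        table = build_annotation_table(feats, g)
        assert any("identical coordinates" in f for f in table.rows[0].flags)


class TestComplementValidation:
    def test_published_fixture_passes(self, cat07_table):
        report = validate_gene_complement(cat07_table)
        assert report.passed and report.deviations == []
        assert report.counts == {"PCG": 13, "tRNA": 22, "rRNA": 2,
                                 "control_region": 1}

    def test_flipped_strand_is_one_deviation(self, cat07_features):
        import dataclasses
        flipped = [dataclasses.replace(f, strand="+") if f.name == "nad5" else f
                   for f in cat07_features]
        report = validate_gene_complement(
            build_annotation_table(flipped, genome_length=15_395))
        assert not report.passed
        assert [d for d in report.deviations if "nad5" in d]
        assert len(report.deviations) == 1

    def test_missing_trnk_fails_complement(self, cat07_features):
        pruned = [f for f in cat07_features if f.name != "trnK"]
        report = validate_gene_complement(
            build_annotation_table(pruned, genome_length=15_395))
        assert not report.passed
        assert any("21 tRNA" in d for d in report.deviations)

    def test_swapped_order_detected(self, cat07_features):
        import dataclasses
        by_name = {f.name: f for f in cat07_features}
        a, b = by_name["trnK"], by_name["trnD"]
        swapped = [dataclasses.replace(f, start=b.start, end=b.end)
                   if f.name == "trnK" else
                   dataclasses.replace(f, start=a.start, end=a.end)
                   if f.name == "trnD" else f for f in cat07_features]
        report = validate_gene_complement(
            build_annotation_table(swapped, genome_length=15_395))
        assert any("order" in d for d in report.deviations)
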