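"""Assembly alignment, variant calling and classification."""

import itertools

import pytest

from Bio.Data.CodonTable import unambiguous_dna_by_id

from mitochar.annotation import build_annotation_table
from mitochar.codes import is_synonymous, is_transition
from mitochar.compare import (
    INDEL,
    MICROSATELLITE,
    SNP,
    align_assemblies,
    annotate_variant,
    call_variants,
    compare_report,
)
from mitochar.genome import CircularGenome, FeatureAnnotation, GenomeError


class TestTransitionTransversion:
    def test_agrees_with_purine_pyrimidine_lookup(self):
        purines, pyrimidines = {"A", "G"}, {"C", "T"}
        for r, a in itertools.permutations("ACGT", 2):
            expected = ({r, a} <= purines) or ({r, a} <= pyrimidines)
            assert is_transition(r, a) is expected

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            is_transition("A", "A")


class TestSynonymyExhaustive:
    def test_all_codon_pairs_against_independent_translation(self):
        """Synonymy of every ordered codon pair must agree with an
        independent translation under NCBI table 5 (Biopython)."""
        bio = unambiguous_dna_by_id[5]

        def aa(codon):
            return "*" if codon in bio.stop_codons else bio.forward_table[codon]

        codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
        for c1 in codons:
            for c2 in codons:
                assert is_synonymous(c1, c2) == (aa(c1) == aa(c2))


class TestAlignment:
    def test_identical_genomes_identity_one_zero_variants(self, synth_truth):
        g = synth_truth.genome
        aln, _ = align_assemblies(g, g)
        assert aln.identity == 1.0
        assert call_variants(aln) == []

    def test_rotation_invariance(self, synth_truth):
        g = synth_truth.genome
        rotated = g.rotated(1_000)
        report = compare_report(g, rotated, synth_truth.features)
        assert report.identity == 1.0 and report.variants == []

    def test_divergent_pair_refused(self):
        import random
        rnd = random.Random(5)
        a = "".join(rnd.choice("ACGT") for _ in range(2_000))
        b = "".join(rnd.choice("ACGT") for _ in range(2_000))
        with pytest.raises(GenomeError):
            align_assemblies(CircularGenome("a", a), CircularGenome("b", b))


# fixed flanks keep toy pairs above the conspecific-identity floor without
# touching the interesting middle; positions below are offset by len(_PAD)
_PAD = "GCTAGCTAGGATCGGATCGCTAGGCTAGGC"


def _toy_pair(ref_mid, alt_mid):
    return (CircularGenome("ref", _PAD + ref_mid + _PAD, circular=False),
            CircularGenome("alt", _PAD + alt_mid + _PAD, circular=False))


class TestCallVariants:
    def test_snp_classification(self):
        ref, alt = _toy_pair("CCCCACCCC", "CCCCGCCCC")
        aln, _ = align_assemblies(ref, alt)
        (v,) = call_variants(aln)
        assert (v.position, v.ref, v.alt, v.var_class, v.snp_subclass) == \
               (len(_PAD) + 5, "A", "G", SNP, "transition")

    def test_transversion(self):
        ref, alt = _toy_pair("CCCCACCCC", "CCCCTCCCC")
        aln, _ = align_assemblies(ref, alt)
        assert call_variants(aln)[0].snp_subclass == "transversion"

    def test_indel_left_aligned(self):
        # deletion of one G from a GG pair: anchor must shift to the C at 4
        ref, alt = _toy_pair("CCTCGGAATCC", "CCTCGAATCC")
        aln, _ = align_assemblies(ref, alt)
        (v,) = call_variants(aln)
        assert (v.position, v.ref, v.alt, v.var_class) == \
               (len(_PAD) + 4, "CG", "C", INDEL)

    def test_microsatellite_reclassification(self):
        # two extra AT units next to (AT)5: a copy-number change 5 -> 7
        ref, alt = _toy_pair("GGC" + "AT" * 5 + "CGG",
                             "GGC" + "AT" * 7 + "CGG")
        aln, _ = align_assemblies(ref, alt)
        (v,) = call_variants(aln)
        assert v.var_class == MICROSATELLITE
        assert (v.unit, v.ref_copies, v.alt_copies) == ("AT", 5, 7)
        assert v.position == len(_PAD) + 3  # left-aligned onto the C anchor

    def test_short_repeat_context_stays_indel(self):
        ref, alt = _toy_pair("GGCATATCGG", "GGCATATATCGG")  # only (AT)2 in ref
        aln, _ = align_assemblies(ref, alt)
        (v,) = call_variants(aln)
        assert v.var_class == INDEL


class TestAnnotateVariant:
    def _table(self):
        #          1-9 PCG(+)        10-18 PCG(-)
        seq = "ATGATATAA" + "TTATGCCAT" + "CCCC"
        g = CircularGenome("t", seq, circular=False)
        feats = [
            FeatureAnnotation(name="nad4l", feature_class="PCG", strand="+",
                              start=1, end=9),
            FeatureAnnotation(name="nad1", feature_class="PCG", strand="-",
                              start=10, end=18),
        ]
        return g, build_annotation_table(feats, g)

    def test_third_position_ata_to_att_is_met_to_ile(self):
        g, table = self._table()
        from mitochar.compare import Variant
        v = Variant(position=6, ref="A", alt="T", var_class=SNP,
                    snp_subclass="transversion")
        v = annotate_variant(v, table, g)
        assert (v.gene, v.codon_number, v.codon_position) == ("nad4l", 2, 3)
        assert (v.ref_codon, v.alt_codon) == ("ATA", "ATT")
        assert (v.ref_aa, v.alt_aa, v.synonymous) == ("M", "I", False)

    def test_minus_strand_codon_bookkeeping(self):
        g, table = self._table()
        # CDS of nad1 is revcomp("TTATGCCAT") = "ATGGCATAA"; genome position 13
        # is CDS index 5 (codon 2, position 3): GCA -> GCG, Ala -> Ala
        from mitochar.compare import Variant
        v = Variant(position=13, ref="T", alt="C", var_class=SNP,
                    snp_subclass="transition")
        v = annotate_variant(v, table, g)
        assert (v.gene, v.codon_number, v.codon_position) == ("nad1", 2, 3)
        assert (v.ref_codon, v.alt_codon) == ("GCA", "GCG")
        assert v.synonymous is True

    def test_synonymous_leucine_third_position(self):
        seq = "ATGTTATAA" + "CCCC"
        g = CircularGenome("t", seq, circular=False)
        feats = [FeatureAnnotation(name="cox1", feature_class="PCG",
                                   strand="+", start=1, end=9)]
        table = build_annotation_table(feats, g)
        from mitochar.compare import Variant
        v = annotate_variant(Variant(position=6, ref="A", alt="G",
                                     var_class=SNP, snp_subclass="transition"),
                             table, g)
        assert (v.ref_codon, v.alt_codon, v.synonymous) == ("TTA", "TTG", True)


class TestSymmetry:
    def test_swapping_assemblies_swaps_alleles_only(self, synth_pair):
        truth, sister, _ = synth_pair
        fwd = compare_report(truth.genome, sister)
        rev = compare_report(sister, truth.genome)
        assert fwd.counts() == rev.counts()
        fwd_set = {(v.ref, v.alt, v.var_class) for v in fwd.variants}
        rev_set = {(v.alt, v.ref, v.var_class) for v in rev.variants}
        assert fwd_set == rev_set


class TestReportOutputs:
    def test_vcf_and_tsv_row_counts(self, synth_pair):
        truth, sister, variants = synth_pair
        report = compare_report(truth.genome, sister, truth.features)
        vcf_rows = [l for l in report.to_vcf().splitlines()
                    if l and not l.startswith("#")]
        tsv_rows = report.to_tsv().splitlines()[1:]
        assert len(vcf_rows) == len(tsv_rows) == len(variants)
        assert all(len(r.split("\t")) == 8 for r in vcf_rows)

    def test_identical_pair_empty_report(self, synth_truth):
        g = synth_truth.genome
        report = compare_report(g, g, synth_truth.features)
        assert report.variants == [] and report.identity == 1.0
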