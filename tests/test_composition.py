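"""Composition statistics, skews and codon usage (RSCU)."""

import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import reverse_complement

from mitochar.codes import CODON_TO_AA, FAMILIES, SENSE_CODONS, STOP_CODONS
from mitochar.composition import (
    at_skew,
    base_counts,
    codon_usage,
    gc_skew,
    region_stats,
    stats_to_dataframe,
)
from mitochar.genome import GenomeError


class TestTranslationTable:
    def test_matches_ncbi_table5(self):
        """The hand-coded invertebrate mitochondrial code must agree with
        Biopython's NCBI table 5 on every codon."""
        bio = unambiguous_dna_by_id[5]
        for codon, aa in CODON_TO_AA.items():
            if aa == "*":
                assert codon in bio.stop_codons
            else:
                assert bio.forward_table[codon] == aa, codon

    def test_signature_codons(self):
        assert CODON_TO_AA["ATA"] == "M"
        assert CODON_TO_AA["TGA"] == "W"
        assert CODON_TO_AA["AGA"] == CODON_TO_AA["AGG"] == "S"
        assert STOP_CODONS == {"TAA", "TAG"}


class TestBaseCounts:
    def test_exact_counts(self):
        bc = base_counts("AATT")
        assert (bc.A, bc.T, bc.C, bc.G, bc.n_excluded) == (2, 2, 0, 0, 0)

    def test_ambiguity_codes_excluded(self):
        bc = base_counts("ACGTN")
        assert (bc.A, bc.C, bc.G, bc.T, bc.n_excluded) == (1, 1, 1, 1, 1)

    def test_empty_rejected(self):
        with pytest.raises(GenomeError):
            base_counts("")

    def test_synthetic_genome_matches_generator_tally(self, synth_truth):
        bc = base_counts(synth_truth.genome.sequence)
        assert {b: getattr(bc, b) for b in "ACGT"} == synth_truth.base_tally


class TestSkews:
    def test_printed_composition_reproduces_printed_skews(self):
        # the published whole-genome composition is a valid input because
        # the formula is scale-invariant
        assert round(at_skew(39.9, 37.8), 2) == 0.03
        assert round(gc_skew(7.8, 14.5), 2) == -0.30

    def test_symmetric_input_gives_zero(self):
        assert at_skew(5, 5) == 0 and gc_skew(3, 3) == 0

    def test_boundary_and_undefined(self):
        assert gc_skew(1, 0) == 1.0
        assert at_skew(0, 0) is None

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_skews_negate_under_reverse_complement(self, seq):
        bc = base_counts(seq)
        rc = base_counts(reverse_complement(seq))
        for skew, args, rc_args in ((at_skew, (bc.A, bc.T), (rc.A, rc.T)),
                                    (gc_skew, (bc.G, bc.C), (rc.G, rc.C))):
            s, s_rc = skew(*args), skew(*rc_args)
            if s is None:
                assert s_rc is None
            else:
                assert s_rc == pytest.approx(-s)

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_skews_bounded(self, seq):
        bc = base_counts(seq)
        for s in (at_skew(bc.A, bc.T), gc_skew(bc.G, bc.C)):
            if s is not None:
                assert -1 <= s <= 1


class TestRegionStats:
    def test_whole_genome_percentages_sum_to_100(self, synth_truth):
        s = region_stats(synth_truth.genome, synth_truth.table, "whole_genome")[0]
        assert s.at_percent + s.gc_percent == pytest.approx(100)

    def test_cr_at_richness_matches_generator_target(self, synth_truth):
        per = {s.region: s for s in region_stats(synth_truth.genome,
                                                 synth_truth.table)}
        # the control region is generated at ~93% A+T; planted motifs leave
        # a couple of points of slack at this length (375 bp)
        assert per["CR"].at_percent == pytest.approx(93, abs=3)

    def test_per_class_equals_concatenation_of_per_feature(self, synth_truth):
        per_feat = region_stats(synth_truth.genome, synth_truth.table)
        per_class = region_stats(synth_truth.genome, synth_truth.table,
                                 "per_class")
        by_class = {}
        for s, row in zip(per_feat, synth_truth.table.rows):
            cls = row.feature.feature_class
            by_class[cls] = by_class.get(cls, Counter()) + Counter(
                {b: getattr(s.counts, b) for b in "ACGT"})
        for s in per_class:
            assert {b: getattr(s.counts, b) for b in "ACGT"} == \
                   dict(by_class[s.region]), s.region

    def test_rounding_convention(self, synth_truth):
        df = stats_to_dataframe(
            region_stats(synth_truth.genome, synth_truth.table, "whole_genome"),
            rounded=True)
        at = df.loc[0, "AT_pct"]
        assert at == round(at, 1)
        assert df.loc[0, "AT_skew"] == round(df.loc[0, "AT_skew"], 2)


def brute_force_rscu(cds_list):
    """Independent dictionary-count oracle for RSCU."""
    tally = Counter()
    for cds in cds_list:
        codons = [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
        if codons[-1] in ("TAA", "TAG"):
            codons.pop()
        for c in codons:
            if c not in ("TAA", "TAG"):
                tally[c] += 1
    out = {}
    for aa, fam in FAMILIES.items():
        total = sum(tally[c] for c in fam)
        for c in fam:
            out[c] = None if total == 0 else tally[c] * len(fam) / total
    return out


class TestCodonUsage:
    def test_two_codon_family_single_use(self):
        u = codon_usage(["ATGTTTTAA"])
        assert u.aa_counts == {"M": 1, "F": 1}
        assert u.rscu["TTT"] == 2.0 and u.rscu["TTC"] == 0.0

    def test_uniform_family_gives_rscu_one(self):
        u = codon_usage(["ATGTTTTTCTAA"])  # one TTT + one TTC
        assert u.rscu["TTT"] == u.rscu["TTC"] == 1.0

    def test_terminal_stop_and_truncated_tail_excluded(self):
        full = codon_usage(["ATGAAATAA"])
        trunc = codon_usage(["ATGAAAT"])
        assert full.codon_counts == trunc.codon_counts == {"ATG": 1, "AAA": 1}

    def test_random_cds_matches_bruteforce_oracle(self):
        rnd = random.Random(2024)
        cds_list = ["".join(rnd.choice(SENSE_CODONS) for _ in range(60)) + "TAA"
                    for _ in range(20)]
        u = codon_usage(cds_list)
        oracle = brute_force_rscu(cds_list)
        for codon in oracle:
            if oracle[codon] is None:
                assert u.rscu[codon] is None
            else:
                assert u.rscu[codon] == pytest.approx(oracle[codon], abs=1e-12)

    def test_aa_frequencies_sum_to_one(self, synth_truth):
        u = codon_usage(list(synth_truth.cds.values()))
        assert sum(u.aa_frequencies.values()) == pytest.approx(1, abs=1e-9)
        assert sum(u.aa_counts.values()) == u.total_codons

    def test_family_rscu_sums_to_family_size(self, synth_truth):
        u = codon_usage(list(synth_truth.cds.values()))
        for aa, fam in FAMILIES.items():
            vals = [u.rscu[c] for c in fam]
            if all(v is not None for v in vals):
                assert sum(vals) == pytest.approx(len(fam), abs=1e-9)

    def test_split_leucine_option(self):
        u = codon_usage(["ATGTTATTGCTTTAA"], split_leucine=True)
        # UUR family: TTA + TTG used once each -> RSCU 1; CUN: only CTT -> 4
        assert u.rscu["TTA"] == u.rscu["TTG"] == 1.0
        assert u.rscu["CTT"] == 4.0
        assert u.aa_counts["L"] == 3

    def test_n_containing_codons_dropped(self):
        u = codon_usage(["ATGNNNAAATAA"])
        assert u.codon_counts == {"ATG": 1, "AAA": 1} and u.n_dropped == 1

    def test_short_cds_rejected(self):
        with pytest.raises(GenomeError):
            codon_usage(["ATG"])
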