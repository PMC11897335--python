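"""Pairwise comparison of two conspecific mitogenome assemblies.

Both assemblies are rotated to a shared canonical origin (trnM when an
annotation is available, otherwise the first k-mer unique in both), then
globally aligned with edlib (Needleman-Wunsch path). Alignment columns
yield variants:

* mismatch columns -> SNPs, subclassified transition / transversion;
* gap runs -> indels, normalized to the VCF convention (left-aligned,
  anchor base first);
* indels whose inserted/deleted sequence is a whole number of copies of a
  2-6 bp primitive unit, adjacent to a reference tract of >= 3 copies and
  >= 8 bp of that unit, are reclassified as microsatellite copy-number
  variants.

Variants inside light-strand genes are reported in plus-strand genome
coordinates; codon effects are computed on the oriented CDS under the
invertebrate mitochondrial code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace as dc_replace

import edlib

from .annotation import AnnotationTable, build_annotation_table
from .codes import is_synonymous, is_transition, translate_codon
from .genome import (
    PCG,
    CircularGenome,
    FeatureAnnotation,
    GenomeError,
    extract_subsequence,
    rotate_to_feature,
)
from .motifs import MICROSAT_MIN_COPIES, MICROSAT_MIN_LENGTH, _is_primitive

DEFAULT_K = 21
DEFAULT_BAND = 50
MIN_IDENTITY = 0.95

SNP = "SNP"
INDEL = "indel"
MICROSATELLITE = "microsatellite"


@dataclass(frozen=True)
class Variant:
    """One difference between the reference and alternate assembly."""

    position: int  # 1-based on the (rotated) reference
    ref: str
    alt: str
    var_class: str  # SNP | indel | microsatellite
    snp_subclass: str | None = None  # transition | transversion
    region: str | None = None
    gene: str | None = None
    codon_number: int | None = None
    codon_position: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    synonymous: bool | None = None
    unit: str | None = None  # microsatellite repeat unit
    ref_copies: int | None = None
    alt_copies: int | None = None


@dataclass
class PairwiseAlignment:
    ref: CircularGenome
    alt: CircularGenome
    cigar: list[tuple[int, str]]  # (length, op) with ops =, X, I, D
    identity: float
    edit_distance: int


def _unique_kmer_offset(a: str, b: str, k: int) -> tuple[int, int]:
    """First offset d such that a's k-mer at d occurs exactly once in both
    circular sequences; returns (d, position of that k-mer in b)."""
    da, db = a + a[: k - 1], b + b[: k - 1]
    for d in range(len(a)):
        kmer = da[d : d + k]
        if da.count(kmer) == 1 and db.count(kmer) == 1:
            return d, db.index(kmer)
    raise GenomeError(f"no shared unique {k}-mer between the assemblies")


def align_assemblies(
    genome_a: CircularGenome,
    genome_b: CircularGenome,
    features_a: list[FeatureAnnotation] | None = None,
    *,
    k: int = DEFAULT_K,
    band: int = DEFAULT_BAND,
) -> tuple[PairwiseAlignment, list[FeatureAnnotation] | None]:
    """Canonically rotate and globally align two assemblies.

    Returns the alignment plus ``features_a`` remapped into the rotated
    reference frame (or None when no annotation was supplied). Refuses
    pairs below 95% identity — the comparison is meant for conspecific
    assemblies.
    """
    if features_a is not None and any(f.name == "trnM" for f in features_a):
        genome_a, features_a = rotate_to_feature(genome_a, features_a, "trnM")
    if genome_a.circular and genome_b.circular:
        d, pos_b = _unique_kmer_offset(genome_a.sequence, genome_b.sequence, k)
        genome_b = genome_b.rotated((pos_b - d) % genome_b.length)
    cap = band + int(0.05 * max(genome_a.length, genome_b.length)) + 1
    res = edlib.align(genome_b.sequence, genome_a.sequence, mode="NW",
                      task="path", k=cap)
    if res["editDistance"] < 0:
        raise GenomeError("assemblies too divergent to align (identity < 95%); "
                          "this tool compares conspecific assemblies")
    cigar = [(int(n), op) for n, op in re.findall(r"(\d+)([=XIDM])", res["cigar"])]
    columns = sum(n for n, _ in cigar)
    matches = sum(n for n, op in cigar if op == "=")
    identity = matches / columns if columns else 0.0
    if identity < MIN_IDENTITY:
        raise GenomeError(
            f"alignment identity {identity:.3f} below {MIN_IDENTITY:.2f}; "
            "this tool compares conspecific assemblies")
    aln = PairwiseAlignment(ref=genome_a, alt=genome_b, cigar=cigar,
                            identity=identity, edit_distance=res["editDistance"])
    return aln, features_a


def _left_align(ref_seq: str, pos0: int, seq: str) -> tuple[int, str]:
    """Left-shift an indel: ``seq`` inserted/deleted immediately after
    0-based reference index ``pos0`` (the anchor). Returns the new anchor
    index and rotated sequence."""
    while pos0 >= 0 and seq and ref_seq[pos0] == seq[-1]:
        seq = ref_seq[pos0] + seq[:-1]
        pos0 -= 1
    return pos0, seq


def _repeat_context(ref_seq: str, pos0: int, seq: str) -> tuple[str, int] | None:
    """If ``seq`` is k whole copies of a primitive 2-6 bp unit and the
    reference right of the anchor carries a tract of >= 3 copies / >= 8 bp
    of that unit, return (unit, reference copy count)."""
    for u in range(2, 7):
        if len(seq) % u:
            continue
        unit = seq[:u]
        if not _is_primitive(unit) or seq != unit * (len(seq) // u):
            continue
        m = 0
        i = pos0 + 1
        while ref_seq[i : i + u] == unit:
            m += 1
            i += u
        if m >= MICROSAT_MIN_COPIES and m * u >= MICROSAT_MIN_LENGTH:
            return unit, m
    return None


def call_variants(alignment: PairwiseAlignment) -> list[Variant]:
    """Walk the alignment columns and emit classified variants."""
    ref_seq, alt_seq = alignment.ref.sequence, alignment.alt.sequence
    variants: list[Variant] = []
    i = j = 0  # 0-based cursors on ref / alt
    for n, op in alignment.cigar:
        if op in "=M":
            i += n
            j += n
        elif op == "X":
            for t in range(n):
                r, a = ref_seq[i + t], alt_seq[j + t]
                variants.append(Variant(
                    position=i + t + 1, ref=r, alt=a, var_class=SNP,
                    snp_subclass="transition" if is_transition(r, a)
                    else "transversion"))
            i += n
            j += n
        elif op in "ID":
            seq = alt_seq[j : j + n] if op == "I" else ref_seq[i : i + n]
            anchor0, seq = _left_align(ref_seq, i - 1, seq)
            if anchor0 < 0:
                # indel at the very start: anchor on the following base
                anchor0, ref_allele, alt_allele = 0, ref_seq[0], seq + ref_seq[0]
                if op == "D":
                    ref_allele, alt_allele = alt_allele, ref_allele
                variants.append(Variant(position=1, ref=ref_allele,
                                        alt=alt_allele, var_class=INDEL))
            else:
                anchor = ref_seq[anchor0]
                if op == "I":
                    ref_allele, alt_allele = anchor, anchor + seq
                else:
                    ref_allele, alt_allele = anchor + seq, anchor
                ctx = _repeat_context(ref_seq, anchor0, seq)
                if ctx is not None:
                    unit, m = ctx
                    delta = len(seq) // len(unit)
                    variants.append(Variant(
                        position=anchor0 + 1, ref=ref_allele, alt=alt_allele,
                        var_class=MICROSATELLITE, unit=unit, ref_copies=m,
                        alt_copies=m + delta if op == "I" else m - delta))
                else:
                    variants.append(Variant(position=anchor0 + 1, ref=ref_allele,
                                            alt=alt_allele, var_class=INDEL))
            if op == "I":
                j += n
            else:
                i += n
        else:  # pragma: no cover - edlib emits only =XIDM
            raise GenomeError(f"unexpected CIGAR op {op!r}")
    variants.sort(key=lambda v: v.position)
    return variants


def annotate_variant(variant: Variant, table: AnnotationTable,
                     genome: CircularGenome) -> Variant:
    """Assign a region and, for SNPs in protein-coding genes, the codon
    bookkeeping (codon number/position, ref/alt codon and amino acid,
    synonymy) on the oriented CDS."""
    probe = variant.position if variant.var_class == SNP else min(
        variant.position + 1, genome.length)
    region, feat = table.region_of(probe)
    v = dc_replace(variant, region=region)
    if feat is None or feat.feature_class != PCG or variant.var_class != SNP:
        return v
    cds = extract_subsequence(genome, feat)
    if feat.strand == "+":
        idx = variant.position - feat.start
        alt_base = variant.alt
    else:
        idx = feat.end - variant.position
        alt_base = {"A": "T", "T": "A", "C": "G", "G": "C"}[variant.alt]
    if idx >= 3 * (len(cds) // 3):
        return v  # inside a truncated trailing stop: no codon to report
    codon_number, codon_pos0 = divmod(idx, 3)
    ref_codon = cds[3 * codon_number : 3 * codon_number + 3]
    alt_codon = (ref_codon[:codon_pos0] + alt_base + ref_codon[codon_pos0 + 1:])
    return dc_replace(
        v, gene=feat.name, codon_number=codon_number + 1,
        codon_position=codon_pos0 + 1, ref_codon=ref_codon, alt_codon=alt_codon,
        ref_aa=translate_codon(ref_codon), alt_aa=translate_codon(alt_codon),
        synonymous=is_synonymous(ref_codon, alt_codon))


@dataclass
class ComparisonReport:
    """The two-assembly difference table plus its summary."""

    ref_id: str
    alt_id: str
    identity: float
    variants: list[Variant] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        c = {SNP: 0, INDEL: 0, MICROSATELLITE: 0,
             "transition": 0, "transversion": 0, "synonymous": 0,
             "non_synonymous": 0}
        for v in self.variants:
            c[v.var_class] += 1
            if v.snp_subclass:
                c[v.snp_subclass] += 1
            if v.synonymous is True:
                c["synonymous"] += 1
            elif v.synonymous is False:
                c["non_synonymous"] += 1
        c["total"] = len(self.variants)
        return c

    def region_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.variants:
            key = v.region or "unannotated"
            out[key] = out.get(key, 0) + 1
        return out

    def summary(self) -> str:
        c = self.counts()
        lines = [
            f"{self.ref_id} vs {self.alt_id}: identity {self.identity:.4f}",
            f"total mutations: {c['total']} "
            f"({c[SNP]} SNP, {c[INDEL]} indel, {c[MICROSATELLITE]} microsatellite)",
            f"SNP spectrum: {c['transition']} transitions, "
            f"{c['transversion']} transversions",
            f"codon effects: {c['synonymous']} synonymous, "
            f"{c['non_synonymous']} non-synonymous",
        ]
        return "\n".join(lines)

    def to_tsv(self) -> str:
        cols = ["position", "ref", "alt", "class", "subclass", "region", "gene",
                "codon", "codon_pos", "ref_codon", "alt_codon", "aa_change",
                "synonymous", "unit", "copy_change"]
        lines = ["\t".join(cols)]
        for v in self.variants:
            aa = f"{v.ref_aa}->{v.alt_aa}" if v.ref_aa else "."
            copy = (f"{v.ref_copies}->{v.alt_copies}"
                    if v.ref_copies is not None else ".")
            syn = "." if v.synonymous is None else ("yes" if v.synonymous else "no")
            row = [str(v.position), v.ref, v.alt, v.var_class,
                   v.snp_subclass or ".", v.region or ".", v.gene or ".",
                   str(v.codon_number or "."), str(v.codon_position or "."),
                   v.ref_codon or ".", v.alt_codon or ".", aa, syn,
                   v.unit or ".", copy]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def to_vcf(self) -> str:
        header = [
            "##fileformat=VCFv4.2",
            f"##reference={self.ref_id}",
            '##INFO=<ID=CLASS,Number=1,Type=String,Description="Variant class">',
            '##INFO=<ID=REGION,Number=1,Type=String,Description="Region">',
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">',
            '##INFO=<ID=AA,Number=1,Type=String,Description="Amino acid change">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        body = []
        for v in self.variants:
            info = [f"CLASS={v.var_class}"]
            if v.region:
                info.append(f"REGION={v.region}")
            if v.gene:
                info.append(f"GENE={v.gene}")
            if v.ref_aa:
                info.append(f"AA={v.ref_aa}>{v.alt_aa}")
            body.append("\t".join([self.ref_id, str(v.position), ".", v.ref,
                                   v.alt, ".", "PASS", ";".join(info)]))
        return "\n".join(header + body) + "\n"


def compare_report(
    genome_a: CircularGenome,
    genome_b: CircularGenome,
    features_a: list[FeatureAnnotation] | None = None,
    *,
    k: int = DEFAULT_K,
    band: int = DEFAULT_BAND,
) -> ComparisonReport:
    """End-to-end comparison: rotate, align, call, classify, annotate.

    Coordinates in the report are in the canonically rotated reference
    frame (trnM at position 1 when an annotation is supplied).
    """
    aln, feats = align_assemblies(genome_a, genome_b, features_a, k=k, band=band)
    variants = call_variants(aln)
    if feats is not None:
        table = build_annotation_table(feats, aln.ref)
        variants = [annotate_variant(v, table, aln.ref) for v in variants]
    return ComparisonReport(ref_id=genome_a.id, alt_id=genome_b.id,
                            identity=aln.identity, variants=variants)
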