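"""Annotation-table accounting for a circular mitogenome.

Rebuilds the classic mitogenome annotation table: per-feature lengths, the
signed spacer/overlap column between consecutive features, and start/stop
codon calls for protein-coding genes, including the abbreviated (T / TA)
stop codons completed to TAA by mRNA polyadenylation.

Adjacency is defined on plus-strand coordinate order regardless of feature
strand, matching the convention of published mitogenome tables that list
all features in one ordered column. For a circular genome the last row's
gap is computed across the origin, so the closure identity

    sum over rows of (length + gap_to_next) == genome length

holds exactly whenever overlaps involve only consecutive rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .codes import ALTERNATIVE_STARTS, STOP_CODONS
from .genome import (
    CONTROL_REGION,
    GENE_ORDER,
    LIGHT_STRAND,
    PCG,
    RRNA,
    TRNA,
    CircularGenome,
    FeatureAnnotation,
    GenomeError,
    extract_subsequence,
)

logger = logging.getLogger("mitochar")

COMPLETE_STOPS = ("TAA", "TAG")
TRUNCATED_STOPS = ("T", "TA")


def feature_length(feature: FeatureAnnotation, genome_length: int | None = None) -> int:
    """Length in bp; origin-wrapping features need the genome length."""
    return feature.length(genome_length)


def gap_to_next(feature: FeatureAnnotation, nxt: FeatureAnnotation,
                genome_length: int | None = None) -> int:
    """Signed spacer between consecutive features on the plus-strand order.

    ``start(next) - end(current) - 1``: positive = intergenic spacer of that
    many bp, 0 = abutting, negative = overlap of ``|value|`` bp. When ``nxt``
    precedes ``feature`` on the coordinate axis the junction crosses the
    circular origin and ``genome_length`` is required.
    """
    if feature.wraps_origin or nxt.start >= feature.start:
        # a wrapped feature's end already lies on the far side of the origin
        return nxt.start - feature.end - 1
    if genome_length is None:
        raise GenomeError("origin-crossing gap needs the genome length")
    return nxt.start + genome_length - feature.end - 1
    # (identical coordinates are tolerated; the caller flags them)


@dataclass(frozen=True)
class StartCall:
    codon: str
    classification: str  # canonical | alternative | unexpected


@dataclass(frozen=True)
class StopCall:
    label: str  # TAA / TAG / T / TA / other trinucleotide
    complete: bool
    truncated: bool
    inconsistent: bool = False
    note: str = ""


def call_start_codon(gene_seq: str) -> StartCall:
    """First codon of an oriented 5'->3' CDS, classified as canonical (ATN),
    alternative (CGA, the lepidopteran cox1 start) or unexpected."""
    seq = gene_seq.upper()
    if len(seq) < 3:
        raise GenomeError("CDS shorter than one codon")
    codon = seq[:3]
    if codon.startswith("AT"):
        cls = "canonical"
    elif codon in ALTERNATIVE_STARTS:
        cls = "alternative"
    else:
        cls = "unexpected"
    return StartCall(codon, cls)


def call_stop_codon(gene_seq: str) -> StopCall:
    """Stop-codon call driven by CDS length modulo 3, with base confirmation.

    length % 3 == 0 -> the final trinucleotide (complete only if TAA/TAG);
    == 1 -> 'T' and == 2 -> 'TA' (truncated stops completed by
    polyadenylation), requiring the trailing bases to actually be T / TA.
    An internal in-frame stop upstream of the terminus is flagged as an
    annotation inconsistency with its codon index.
    """
    seq = gene_seq.upper()
    if len(seq) < 3:
        raise GenomeError("CDS shorter than one codon")
    rem = len(seq) % 3
    n_full = len(seq) // 3
    note = ""
    inconsistent = False
    # internal stops: full codons before the terminal one
    last_full = n_full - 1 if rem == 0 else n_full
    for i in range(last_full):
        codon = seq[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            inconsistent = True
            note = f"internal stop {codon} at codon {i + 1}"
            break
    if rem == 0:
        label = seq[-3:]
        complete = label in COMPLETE_STOPS
        if not complete and not note:
            inconsistent = True
            note = f"terminal codon {label} is not a stop"
        return StopCall(label, complete, truncated=False,
                        inconsistent=inconsistent, note=note)
    tail = seq[-rem:]
    expected = "T" if rem == 1 else "TA"
    if tail != expected:
        return StopCall(tail, complete=False, truncated=True, inconsistent=True,
                        note=note or f"trailing {tail!r} cannot complete to TAA")
    return StopCall(expected, complete=False, truncated=True,
                    inconsistent=inconsistent, note=note)


@dataclass(frozen=True)
class AnnotationRow:
    feature: FeatureAnnotation
    length: int
    gap_to_next: int | None  # None only for the last row of a linear genome
    start_codon: str | None = None
    start_class: str | None = None
    stop_codon: str | None = None
    stop_truncated: bool | None = None
    flags: tuple[str, ...] = ()

    @property
    def name(self) -> str:
        return self.feature.name


@dataclass
class AnnotationTable:
    """Ordered annotation rows plus the genome-level summary."""

    genome_id: str
    genome_length: int
    circular: bool
    rows: list[AnnotationRow]

    # --- summary -----------------------------------------------------------

    def class_counts(self) -> dict[str, int]:
        counts = {PCG: 0, TRNA: 0, RRNA: 0, CONTROL_REGION: 0}
        for r in self.rows:
            counts[r.feature.feature_class] += 1
        return counts

    def spacers(self) -> list[int]:
        """Positive gaps (intergenic spacers), in row order."""
        return [r.gap_to_next for r in self.rows
                if r.gap_to_next is not None and r.gap_to_next > 0]

    def overlaps(self) -> list[int]:
        """Overlap magnitudes (|negative gaps|), in row order."""
        return [-r.gap_to_next for r in self.rows
                if r.gap_to_next is not None and r.gap_to_next < 0]

    def closure_residual(self) -> int:
        """sum(length + gap) - genome_length; 0 when overlaps are consecutive-only."""
        total = sum(r.length + (r.gap_to_next or 0) for r in self.rows)
        return total - self.genome_length

    def summary(self) -> dict:
        spacers, overlaps = self.spacers(), self.overlaps()
        counts = self.class_counts()
        return {
            "genome": self.genome_id,
            "genome_length": self.genome_length,
            "features": len(self.rows),
            "PCG": counts[PCG], "tRNA": counts[TRNA], "rRNA": counts[RRNA],
            "control_region": counts[CONTROL_REGION],
            "spacer_count": len(spacers),
            "spacer_range": (min(spacers), max(spacers)) if spacers else None,
            "overlap_count": len(overlaps),
            "overlap_range": (min(overlaps), max(overlaps)) if overlaps else None,
            "closure_residual": self.closure_residual(),
        }

    def feature_by_name(self, name: str) -> FeatureAnnotation | None:
        for r in self.rows:
            if r.name == name:
                return r.feature
        return None

    def _covers(self, f: FeatureAnnotation, pos: int) -> bool:
        if f.wraps_origin:
            return pos >= f.start or pos <= f.end
        return f.start <= pos <= f.end

    def region_of(self, pos: int) -> tuple[str, FeatureAnnotation | None]:
        """Region assignment of a 1-based position.

        Overlap ties resolve by class priority PCG > tRNA/rRNA > control
        region; positions inside no feature are 'intergenic'.
        """
        if not 1 <= pos <= self.genome_length:
            raise GenomeError(f"position {pos} outside genome of length "
                              f"{self.genome_length}")
        priority = {PCG: 0, TRNA: 1, RRNA: 1, CONTROL_REGION: 2}
        hits = [r.feature for r in self.rows if self._covers(r.feature, pos)]
        if not hits:
            return "intergenic", None
        best = min(hits, key=lambda f: priority[f.feature_class])
        return best.name, best

    def spacer_span(self, left: str, right: str) -> tuple[int, int]:
        """1-based inclusive span of the intergenic spacer between two named
        features that are consecutive in the table (positive gap required)."""
        names = [r.name for r in self.rows]
        try:
            i = names.index(left)
        except ValueError:
            raise GenomeError(f"feature {left!r} not in table") from None
        j = (i + 1) % len(self.rows)
        if names[j] != right:
            raise GenomeError(f"{left!r} and {right!r} are not consecutive rows")
        row = self.rows[i]
        if row.gap_to_next is None or row.gap_to_next <= 0:
            raise GenomeError(f"no spacer between {left!r} and {right!r}")
        start = row.feature.end + 1
        end = start + row.gap_to_next - 1
        L = self.genome_length
        return ((start - 1) % L + 1, (end - 1) % L + 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": [r.name for r in self.rows],
            "class": [r.feature.feature_class for r in self.rows],
            "strand": [r.feature.strand for r in self.rows],
            "start": [r.feature.start for r in self.rows],
            "end": [r.feature.end for r in self.rows],
            "length": [r.length for r in self.rows],
            "gap_to_next": pd.array([r.gap_to_next for r in self.rows], dtype="Int64"),
            "start_codon": [r.start_codon for r in self.rows],
            "stop_codon": [r.stop_codon for r in self.rows],
        })

    def to_tsv(self) -> str:
        """Human-readable table mirroring the published layout: the last
        (control-region) row prints '-' for its gap in linear display."""
        df = self.to_dataframe()
        lines = ["\t".join(df.columns)]
        for i, row in df.iterrows():
            vals = []
            for col in df.columns:
                v = row[col]
                if col == "gap_to_next" and i == len(df) - 1:
                    vals.append("-")
                else:
                    vals.append("." if pd.isna(v) or v is None else str(v))
            lines.append("\t".join(vals))
        return "\n".join(lines) + "\n"


def _check_nonconsecutive_overlaps(rows: list[AnnotationRow], genome_length: int) -> list[str]:
    """Any coordinate overlap between NON-consecutive rows is reported."""
    flagged = []
    n = len(rows)
    spans = []
    for r in rows:
        f = r.feature
        if f.wraps_origin:
            spans.append(set(range(f.start, genome_length + 1)) | set(range(1, f.end + 1)))
        else:
            spans.append(set(range(f.start, f.end + 1)))
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # first/last are circular neighbours
            if spans[i] & spans[j]:
                flagged.append(f"non-consecutive overlap: {rows[i].name} vs {rows[j].name}")
    return flagged


def build_annotation_table(
    features: list[FeatureAnnotation],
    genome: CircularGenome | None = None,
    *,
    genome_length: int | None = None,
    genome_id: str = "genome",
    circular: bool = True,
) -> AnnotationTable:
    """Build the full annotation table with derived columns.

    ``genome`` may be omitted (coordinate-only mode, e.g. a published
    annotation without sequence); codon columns then stay empty. For a
    circular genome without sequence, ``genome_length`` must be given so the
    origin-crossing gap of the last row can be computed.
    """
    if genome is not None:
        genome_length = genome.length
        genome_id = genome.id
        circular = genome.circular
    if circular and genome_length is None:
        raise GenomeError("circular table needs a genome or an explicit genome_length")
    feats = sorted(features, key=lambda f: f.start)
    rows: list[AnnotationRow] = []
    for i, f in enumerate(feats):
        flags: list[str] = []
        if i + 1 < len(feats):
            gap = gap_to_next(f, feats[i + 1], genome_length)
            if (f.start, f.end) == (feats[i + 1].start, feats[i + 1].end):
                flags.append(f"identical coordinates with {feats[i + 1].name}")
                logger.warning("%s and %s share identical coordinates", f.name,
                               feats[i + 1].name)
        elif circular:
            gap = gap_to_next(f, feats[0], genome_length)
        else:
            gap = None
        start_codon = start_class = stop_codon = None
        stop_trunc = None
        if genome is not None and f.feature_class == PCG:
            cds = extract_subsequence(genome, f)
            sc = call_start_codon(cds)
            start_codon, start_class = sc.codon, sc.classification
            st = call_stop_codon(cds)
            stop_codon, stop_trunc = st.label, st.truncated
            if st.inconsistent:
                flags.append(f"stop-codon inconsistency: {st.note}")
        rows.append(AnnotationRow(
            feature=f, length=f.length(genome_length), gap_to_next=gap,
            start_codon=start_codon, start_class=start_class,
            stop_codon=stop_codon, stop_truncated=stop_trunc,
            flags=tuple(flags)))
    table = AnnotationTable(genome_id=genome_id, genome_length=genome_length or 0,
                            circular=circular, rows=rows)
    for msg in _check_nonconsecutive_overlaps(rows, genome_length or 0):
        logger.warning("%s: %s", genome_id, msg)
    return table


# --- gene-complement validation --------------------------------------------

@dataclass
class ComplementReport:
    passed: bool
    counts: dict[str, int]
    deviations: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        lines = [f"gene complement: {status} "
                 f"({self.counts[PCG]} PCG / {self.counts[TRNA]} tRNA / "
                 f"{self.counts[RRNA]} rRNA / {self.counts[CONTROL_REGION]} CR)"]
        lines += [f"  - {d}" for d in self.deviations]
        return "\n".join(lines)


def validate_gene_complement(table: AnnotationTable) -> ComplementReport:
    """Check the 13/22/2/1 complement, light-strand assignments and the
    canonical lepidopteran gene order; report-only, never raises."""
    counts = table.class_counts()
    deviations: list[str] = []
    expected = {PCG: 13, TRNA: 22, RRNA: 2, CONTROL_REGION: 1}
    for cls, n in expected.items():
        if counts[cls] != n:
            deviations.append(f"complement failure: {counts[cls]} {cls} (expected {n})")
    names = [r.name for r in table.rows]
    by_name = {r.name: r for r in table.rows}
    for name, row in by_name.items():
        want = "-" if name in LIGHT_STRAND else "+"
        if name in {n for n, *_ in GENE_ORDER} and row.feature.strand != want:
            deviations.append(f"strand deviation: {name} on {row.feature.strand} "
                              f"(expected {want})")
    canonical = [n for n, *_ in GENE_ORDER]
    present = [n for n in names if n in set(canonical)]
    if present:
        # compare as a cyclic sequence anchored at the first present canonical gene
        anchor = canonical.index(present[0]) if present[0] in canonical else 0
        expected_cycle = [n for n in canonical[anchor:] + canonical[:anchor]
                          if n in set(present)]
        if present != expected_cycle:
            deviations.append("gene order deviates from the canonical lepidopteran order")
    return ComplementReport(passed=not deviations, counts=counts, deviations=deviations)
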