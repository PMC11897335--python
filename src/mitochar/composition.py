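"""Base composition, strand-asymmetry skews, amino-acid frequency and RSCU.

Skews follow Perna & Kocher: AT-skew = (A - T)/(A + T) and
GC-skew = (G - C)/(G + C), computed on counts or (equivalently, the formula
is scale-invariant) on percentages. Codon usage is computed under the
invertebrate mitochondrial genetic code; relative synonymous codon usage is

    RSCU(c) = count(c) * |family(c)| / sum of counts over family(c)

so uniform usage within a synonymous family gives RSCU = 1 for each member.
Reported tables round percentages to 1 decimal and skews to 2 decimals;
raw values are retained in the machine-readable output.

Conventions (deliberate, since external codon-usage servers leave them
unstated): terminal complete stop codons and truncated T/TA tails are
excluded from codon counts; start codons count as their table-5 sense
translation (a CGA start counts toward Arg, not Met); codons containing
N are dropped, not imputed; Leu is treated as a single six-codon family
unless ``split_leucine=True`` splits it into UUR and CUN sub-families.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .codes import FAMILIES, STOP_CODONS
from .genome import (
    CONTROL_REGION,
    PCG,
    RRNA,
    TRNA,
    CircularGenome,
    GenomeError,
    extract_subsequence,
)

# re-exported grouping modes for region_stats
GROUPINGS = ("per_feature", "per_class", "whole_genome")


@dataclass(frozen=True)
class BaseCounts:
    A: int = 0
    C: int = 0
    G: int = 0
    T: int = 0
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return self.A + self.C + self.G + self.T

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(self.A + other.A, self.C + other.C, self.G + other.G,
                          self.T + other.T, self.n_excluded + other.n_excluded)


def base_counts(seq: str) -> BaseCounts:
    """Exact A/C/G/T counts; N and other ambiguity codes go to n_excluded."""
    if not seq:
        raise GenomeError("empty sequence")
    c = Counter(seq.upper())
    acgt = c["A"] + c["C"] + c["G"] + c["T"]
    return BaseCounts(A=c["A"], C=c["C"], G=c["G"], T=c["T"],
                      n_excluded=len(seq) - acgt)


def at_skew(a: float, t: float) -> float | None:
    """(A - T)/(A + T); accepts raw counts or percentages. None if A+T == 0."""
    if a + t == 0:
        return None
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float | None:
    """(G - C)/(G + C); accepts raw counts or percentages. None if G+C == 0."""
    if g + c == 0:
        return None
    return (g - c) / (g + c)


@dataclass(frozen=True)
class RegionCompositionStats:
    region: str
    counts: BaseCounts
    at_percent: float
    gc_percent: float
    at_skew: float | None
    gc_skew: float | None

    @classmethod
    def from_counts(cls, region: str, counts: BaseCounts) -> "RegionCompositionStats":
        tot = counts.total
        if tot == 0:
            raise GenomeError(f"{region}: no unambiguous bases")
        return cls(
            region=region, counts=counts,
            at_percent=100.0 * (counts.A + counts.T) / tot,
            gc_percent=100.0 * (counts.G + counts.C) / tot,
            at_skew=at_skew(counts.A, counts.T),
            gc_skew=gc_skew(counts.G, counts.C),
        )


def region_stats(genome: CircularGenome, table, grouping: str = "per_feature",
                 ) -> list[RegionCompositionStats]:
    """Composition statistics per feature, per feature class, or genome-wide.

    Gene rows (PCG/tRNA/rRNA) use the oriented 5'->3' gene sequence; the
    control region and the whole-genome row use the plus strand. ``table``
    is an :class:`~mitochar.annotation.AnnotationTable`.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    if grouping == "whole_genome":
        return [RegionCompositionStats.from_counts(
            "whole_genome", base_counts(genome.sequence))]
    per_feature = []
    for row in table.rows:
        seq = extract_subsequence(genome, row.feature)
        per_feature.append((row.feature, base_counts(seq)))
    if grouping == "per_feature":
        return [RegionCompositionStats.from_counts(f.name, bc)
                for f, bc in per_feature]
    by_class: dict[str, BaseCounts] = {}
    for f, bc in per_feature:
        by_class[f.feature_class] = by_class.get(f.feature_class, BaseCounts()) + bc
    order = [PCG, TRNA, RRNA, CONTROL_REGION]
    return [RegionCompositionStats.from_counts(cls_, by_class[cls_])
            for cls_ in order if cls_ in by_class]


def stats_to_dataframe(stats: list[RegionCompositionStats], *,
                       rounded: bool = False) -> pd.DataFrame:
    """Composition table (region, A%, C%, G%, T%, AT%, AT-skew, GC-skew).

    With ``rounded=True``, percentages print at 1 decimal and skews at 2,
    the usual reporting precision for mitogenome tables.
    """
    rows = []
    for s in stats:
        tot = s.counts.total
        row = {
            "region": s.region,
            "A_pct": 100.0 * s.counts.A / tot,
            "C_pct": 100.0 * s.counts.C / tot,
            "G_pct": 100.0 * s.counts.G / tot,
            "T_pct": 100.0 * s.counts.T / tot,
            "AT_pct": s.at_percent,
            "GC_pct": s.gc_percent,
            "AT_skew": math.nan if s.at_skew is None else s.at_skew,
            "GC_skew": math.nan if s.gc_skew is None else s.gc_skew,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if rounded and not df.empty:
        for col in ("A_pct", "C_pct", "G_pct", "T_pct", "AT_pct", "GC_pct"):
            df[col] = df[col].round(1)
        for col in ("AT_skew", "GC_skew"):
            df[col] = df[col].round(2)
    return df


# --- codon usage ------------------------------------------------------------

def _families(split_leucine: bool) -> dict[str, tuple[str, ...]]:
    fams = dict(FAMILIES)
    if split_leucine:
        leu = fams.pop("L")
        fams["L(UUR)"] = tuple(c for c in leu if c.startswith("TT"))
        fams["L(CUN)"] = tuple(c for c in leu if c.startswith("CT"))
    return fams


@dataclass
class CodonUsage:
    """Codon counts, per-amino-acid frequencies and RSCU values."""

    codon_counts: dict[str, int]
    aa_counts: dict[str, int]
    rscu: dict[str, float | None]  # None for members of unobserved families
    n_dropped: int  # codons containing ambiguity codes
    split_leucine: bool = False

    @property
    def total_codons(self) -> int:
        return sum(self.codon_counts.values())

    @property
    def aa_frequencies(self) -> dict[str, float]:
        tot = sum(self.aa_counts.values())
        return {aa: n / tot for aa, n in self.aa_counts.items()}

    def most_frequent_aas(self, n: int = 4) -> list[str]:
        ranked = sorted(self.aa_counts, key=lambda a: (-self.aa_counts[a], a))
        return ranked[:n]

    def to_dataframe(self) -> pd.DataFrame:
        fams = _families(self.split_leucine)
        fam_of = {c: aa for aa, codons in fams.items() for c in codons}
        rows = [{"codon": c, "amino_acid": fam_of[c],
                 "count": self.codon_counts.get(c, 0), "rscu": self.rscu[c]}
                for aa in sorted(fams) for c in fams[aa]]
        return pd.DataFrame(rows)


def codon_usage(pcg_sequences: list[str], *, split_leucine: bool = False) -> CodonUsage:
    """Count in-frame codons over a set of oriented CDSs and compute RSCU.

    Codons are read from position 1 of each CDS; a terminal complete stop
    codon and any trailing truncated T/TA tail are excluded, as is a
    frame-breaking trailing partial codon. Each CDS must be >= 6 bp.
    """
    counts: Counter[str] = Counter()
    dropped = 0
    for seq in pcg_sequences:
        seq = seq.upper()
        if len(seq) < 6:
            raise GenomeError("CDS shorter than 6 bp")
        n_codons = len(seq) // 3
        codons = [seq[3 * i : 3 * i + 3] for i in range(n_codons)]
        if codons and codons[-1] in STOP_CODONS:
            codons.pop()
        for codon in codons:
            if set(codon) <= set("ACGT"):
                if codon in STOP_CODONS:
                    # internal stops are an annotation problem, not usage signal
                    dropped += 1
                else:
                    counts[codon] += 1
            else:
                dropped += 1
    fams = _families(split_leucine)
    rscu: dict[str, float | None] = {}
    aa_counts: dict[str, int] = {}
    for aa, codons in fams.items():
        fam_total = sum(counts[c] for c in codons)
        aa_counts[aa] = fam_total
        for c in codons:
            rscu[c] = None if fam_total == 0 else counts[c] * len(codons) / fam_total
    # translation-level amino-acid counts (merge split-Leu back for frequencies)
    if split_leucine:
        aa_counts["L"] = aa_counts.pop("L(UUR)") + aa_counts.pop("L(CUN)")
    aa_counts = {aa: n for aa, n in aa_counts.items() if n > 0}
    return CodonUsage(codon_counts=dict(counts), aa_counts=aa_counts, rscu=rscu,
                      n_dropped=dropped, split_leucine=split_leucine)
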