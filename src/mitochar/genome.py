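"""Core data model: circular genomes, feature annotations, coordinate arithmetic.

External coordinates are 1-based inclusive (GenBank / annotation-table
convention). Internal slicing converts to 0-based half-open via
:func:`to_zero_based` / :func:`to_one_based`. A feature may wrap the
circular origin at most once; after canonical rotation (tRNA-Met at
position 1) only the control-region -> trnM junction can wrap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from Bio.Seq import reverse_complement

IUPAC_RE = re.compile(r"^[ACGTRYSWKMBDHVN]*$")

PCG = "PCG"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL_REGION = "control_region"
FEATURE_CLASSES = (PCG, TRNA, RRNA, CONTROL_REGION)

#: Canonical lepidopteran mitogenome gene order: (symbol, class, strand, anticodon).
#: Heavy strand is "+", light strand is "-".
GENE_ORDER = (
    ("trnM", TRNA, "+", "CAU"),
    ("trnI", TRNA, "+", "GAU"),
    ("trnQ", TRNA, "-", "UUG"),
    ("nad2", PCG, "+", None),
    ("trnW", TRNA, "+", "UCA"),
    ("trnC", TRNA, "-", "GCA"),
    ("trnY", TRNA, "-", "GUA"),
    ("cox1", PCG, "+", None),
    ("trnL1", TRNA, "+", "UAA"),
    ("cox2", PCG, "+", None),
    ("trnK", TRNA, "+", "UUU"),
    ("trnD", TRNA, "+", "GUC"),
    ("atp8", PCG, "+", None),
    ("atp6", PCG, "+", None),
    ("cox3", PCG, "+", None),
    ("trnG", TRNA, "+", "UCC"),
    ("nad3", PCG, "+", None),
    ("trnA", TRNA, "+", "UGC"),
    ("trnR", TRNA, "+", "UCG"),
    ("trnN", TRNA, "+", "GUU"),
    ("trnS1", TRNA, "+", "UCU"),
    ("trnE", TRNA, "+", "UUC"),
    ("trnF", TRNA, "-", "GAA"),
    ("nad5", PCG, "-", None),
    ("trnH", TRNA, "-", "GUG"),
    ("nad4", PCG, "-", None),
    ("nad4l", PCG, "-", None),
    ("trnT", TRNA, "+", "UGU"),
    ("trnP", TRNA, "-", "UGG"),
    ("nad6", PCG, "+", None),
    ("cytb", PCG, "+", None),
    ("trnS2", TRNA, "+", "UGA"),
    ("nad1", PCG, "-", None),
    ("trnL2", TRNA, "-", "UAG"),
    ("rrnL", RRNA, "-", None),
    ("trnV", TRNA, "-", "UAC"),
    ("rrnS", RRNA, "-", None),
    ("CR", CONTROL_REGION, "+", None),
)

PCG_SYMBOLS = tuple(n for n, c, _, _ in GENE_ORDER if c == PCG)
TRNA_SYMBOLS = tuple(n for n, c, _, _ in GENE_ORDER if c == TRNA)
RRNA_SYMBOLS = tuple(n for n, c, _, _ in GENE_ORDER if c == RRNA)
CANONICAL_STRAND = {n: s for n, _, s, _ in GENE_ORDER}
CANONICAL_CLASS = {n: c for n, c, _, _ in GENE_ORDER}
CANONICAL_ANTICODON = {n: a for n, _, _, a in GENE_ORDER}

#: Light-strand feature set of the typical lepidopteran arrangement.
LIGHT_STRAND = frozenset(n for n, _, s, _ in GENE_ORDER if s == "-")


class GenomeError(ValueError):
    """Invalid genome or feature input."""


@dataclass(frozen=True)
class CircularGenome:
    """A (usually circular) mitochondrial genome sequence."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise GenomeError(f"{self.id}: empty sequence")
        if not IUPAC_RE.match(seq):
            bad = sorted(set(seq) - set("ACGTRYSWKMBDHVN"))
            raise GenomeError(f"{self.id}: non-IUPAC characters {bad}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Plus-strand slice by 1-based inclusive coordinates, wrapping if end < start."""
        if not (1 <= start <= self.length and 1 <= end <= self.length):
            raise GenomeError(
                f"coordinates {start}..{end} outside genome of length {self.length}"
            )
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise GenomeError("wrapping slice requested on a linear genome")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def rotated(self, offset: int) -> "CircularGenome":
        """Rotate so that 1-based position ``offset+1`` becomes position 1."""
        if not self.circular:
            raise GenomeError("cannot rotate a linear genome")
        k = offset % self.length
        return replace(self, sequence=self.sequence[k:] + self.sequence[:k])


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated feature with 1-based inclusive genome coordinates."""

    name: str
    feature_class: str
    strand: str
    start: int
    end: int
    wraps_origin: bool = False
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise GenomeError(f"{self.name}: unknown feature class {self.feature_class!r}")
        if self.strand not in "+-":
            raise GenomeError(f"{self.name}: strand must be '+' or '-'")
        if self.start < 1 or self.end < 1:
            raise GenomeError(f"{self.name}: coordinates must be >= 1")
        if not self.wraps_origin and self.start > self.end:
            raise GenomeError(
                f"{self.name}: start {self.start} > end {self.end} without wraps_origin"
            )

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise GenomeError(f"{self.name}: wrapping feature needs genome length")
        return (genome_length - self.start + 1) + self.end

    def validate_against(self, genome: CircularGenome) -> None:
        if self.end > genome.length or self.start > genome.length:
            raise GenomeError(
                f"{self.name}: {self.start}..{self.end} beyond genome length {genome.length}"
            )
        if self.wraps_origin and not genome.circular:
            raise GenomeError(f"{self.name}: wrapping feature on a linear genome")


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def extract_subsequence(genome: CircularGenome, feature: FeatureAnnotation) -> str:
    """The 5'->3' sequence of a feature (reverse complement for '-' strand)."""
    feature.validate_against(genome)
    if feature.wraps_origin:
        plus = genome.slice(feature.start, feature.end)
    else:
        plus = genome.slice(feature.start, feature.end)
    return plus if feature.strand == "+" else reverse_complement(plus)


def remap_position(pos: int, origin_start: int, genome_length: int) -> int:
    """Remap a 1-based position after rotating ``origin_start`` to position 1."""
    return (pos - origin_start) % genome_length + 1


def rotate_to_feature(
    genome: CircularGenome,
    features: list[FeatureAnnotation],
    origin_name: str = "trnM",
) -> tuple[CircularGenome, list[FeatureAnnotation]]:
    """Rotate a circular genome so the named feature starts at coordinate 1.

    All feature coordinates are remapped and wrap flags recomputed; the
    sequence content is preserved up to rotation.
    """
    origin = next((f for f in features if f.name == origin_name), None)
    if origin is None:
        raise GenomeError(f"origin feature {origin_name!r} not annotated")
    if origin.strand != "+":
        raise GenomeError(f"origin feature {origin_name!r} must lie on the plus strand")
    new_genome = genome.rotated(origin.start - 1)
    L = genome.length
    out = []
    for f in features:
        s = remap_position(f.start, origin.start, L)
        e = remap_position(f.end, origin.start, L)
        out.append(replace(f, start=s, end=e, wraps_origin=s > e))
    out.sort(key=lambda f: f.start)
    return new_genome, out


# --- gene-label canonicalization -------------------------------------------

_AA3 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

_TRNA_BY_AA = {
    "M": "trnM", "I": "trnI", "Q": "trnQ", "W": "trnW", "C": "trnC",
    "Y": "trnY", "K": "trnK", "D": "trnD", "G": "trnG", "A": "trnA",
    "R": "trnR", "N": "trnN", "E": "trnE", "F": "trnF", "H": "trnH",
    "T": "trnT", "P": "trnP", "V": "trnV",
}
# Leu and Ser are duplicated; disambiguated by anticodon.
_TRNA_BY_ANTICODON = {"UAA": "trnL1", "UAG": "trnL2", "UCU": "trnS1", "UGA": "trnS2"}

_PLAIN_ALIASES = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "nadh1": "nad1", "nadh2": "nad2", "nadh3": "nad3", "nadh4": "nad4",
    "nadh4l": "nad4l", "nadh5": "nad5", "nadh6": "nad6",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
    "cob": "cytb", "cytochromeb": "cytb", "cytb": "cytb",
    "atpase6": "atp6", "atpase8": "atp8", "atp6": "atp6", "atp8": "atp8",
    "rrns": "rrnS", "rrnl": "rrnL", "12s": "rrnS", "16s": "rrnL",
    "12srrna": "rrnS", "16srrna": "rrnL", "12sribosomalrna": "rrnS",
    "16sribosomalrna": "rrnL", "srrna": "rrnS", "lrrna": "rrnL",
    "smallsubunitribosomalrna": "rrnS", "largesubunitribosomalrna": "rrnL",
    "cr": "CR", "dloop": "CR", "atrichregion": "CR", "controlregion": "CR",
}
for _n, _c, _s, _a in GENE_ORDER:
    _PLAIN_ALIASES.setdefault(_n.lower(), _n)


class UnknownGeneLabel(KeyError):
    """A feature label with no alias mapping; caller must resolve, not guess."""


def canonical_gene_name(label: str, anticodon: str | None = None) -> str:
    """Map an annotation-source gene label to its canonical symbol.

    Handles the common mitochondrial vocabularies (``ND5``, ``COX1``,
    ``12S ribosomal RNA``, ``tRNA-Met(CAU)``, ``trnL2`` ...). Raises
    :class:`UnknownGeneLabel` for anything unrecognized rather than guessing.
    """
    raw = label.strip()
    # embedded anticodon, e.g. "tRNA-Leu (UAA)" or "trnM(cau)"
    m = re.search(r"\(([ACGUTacgut]{3})\)", raw)
    if m and anticodon is None:
        anticodon = m.group(1).upper().replace("T", "U")
        raw = raw[: m.start()] + raw[m.end() :]
    key = re.sub(r"[\s_*+-]+", "", raw).lower()
    m = re.match(r"^trna-?([a-z]{3})$", key)
    if m and m.group(1) in _AA3:
        aa = _AA3[m.group(1)]
        if aa in ("L", "S"):
            if anticodon in _TRNA_BY_ANTICODON:
                return _TRNA_BY_ANTICODON[anticodon]
            raise UnknownGeneLabel(
                f"{label!r}: Leu/Ser tRNA needs an anticodon to disambiguate"
            )
        return _TRNA_BY_AA[aa]
    if key in ("trnl", "trns") and anticodon in _TRNA_BY_ANTICODON:
        return _TRNA_BY_ANTICODON[anticodon]
    try:
        return _PLAIN_ALIASES[key]
    except KeyError:
        raise UnknownGeneLabel(f"no canonical mapping for gene label {label!r}") from None
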