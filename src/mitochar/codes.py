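"""Invertebrate mitochondrial genetic code (NCBI translation table 5).

The table is spelled out explicitly because several downstream rules
(synonymy of variants, RSCU families, stop handling) depend on its
idiosyncrasies: ATA = Met, TGA = Trp, AGA/AGG = Ser, stops are TAA/TAG only.
The mapping is cross-checked in the test suite against Biopython's codon
table with the same NCBI id.
"""

from __future__ import annotations

BASES = "TCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

# NCBI layout: first base slowest, third base fastest (TTT, TTC, TTA, TTG, TCT, ...).
_TABLE5_AA = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG"

CODON_TO_AA: dict[str, str] = {
    b1 + b2 + b3: _TABLE5_AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(BASES)
    for j, b2 in enumerate(BASES)
    for k, b3 in enumerate(BASES)
}

STOP_CODONS = frozenset(c for c, aa in CODON_TO_AA.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))

#: Synonymous families keyed by amino acid (stops excluded).
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in sorted(CODON_TO_AA):
    _aa = CODON_TO_AA[_codon]
    if _aa != "*":
        FAMILIES[_aa] = FAMILIES.get(_aa, ()) + (_codon,)

ALL_CODONS = tuple(sorted(CODON_TO_AA))

#: Start codons the annotation layer labels "canonical" (ATN) vs "alternative".
CANONICAL_START_PREFIX = "AT"
ALTERNATIVE_STARTS = frozenset({"CGA"})


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter, '*' for stop) of a codon; 'X' if ambiguous bases."""
    return CODON_TO_AA.get(codon.upper(), "X")


def translate_cds(seq: str, *, strip_trailing_stop: bool = True) -> str:
    """Translate an in-frame CDS; a trailing partial codon (truncated stop) is ignored."""
    seq = seq.upper()
    aas = [translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)]
    if strip_trailing_stop and aas and aas[-1] == "*":
        aas.pop()
    return "".join(aas)


def is_synonymous(ref_codon: str, alt_codon: str) -> bool:
    """True if the two codons translate identically under table 5."""
    return translate_codon(ref_codon) == translate_codon(alt_codon)


def is_transition(ref: str, alt: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine single-base change."""
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt are identical")
    return (ref in PURINES and alt in PURINES) or (
        ref in PYRIMIDINES and alt in PYRIMIDINES
    )
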