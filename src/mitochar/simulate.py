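"""Ground-truthed synthetic mitogenomes and mutated assembly pairs.

The generator emulates the structure of a typical lepidopteran
mitogenome: a ~15.4 kb AT-rich (~78% A+T) circle carrying 13
protein-coding genes, 22 tRNAs, 2 rRNAs and one control region in the
canonical gene order, with the mixed overlap/spacer profile of real
assemblies. Protein-coding genes are synthesized codon-by-codon from an
AT-biased distribution over sense codons of the invertebrate
mitochondrial code, so translation validity (valid start, no internal
stop, complete TAA or truncated T stop) holds by construction. The
conserved non-coding elements are planted at known coordinates: ATAGA
plus a poly-T run and a terminal poly-A in the control region, ATACTAA in
the trnS2-nad1 spacer, ATGATAA across the atp8/atp6 overlap, and (AT)n
microsatellites in three long intergenic spacers.

``mutate_assembly`` derives a sister assembly with a planted variant set
(SNPs at a configurable transition/transversion mix, indels, and
microsatellite copy-number changes) whose truth records — position,
alleles, class, region, codon effect — are computed from the generator's
own coordinate bookkeeping, independently of the comparison pipeline that
is tested against them.

All randomness flows through one seeded numpy Generator; the same seed
and parameters give byte-identical output. tRNA/rRNA filler is random
AT-biased sequence: no secondary-structure realism is attempted (nothing
downstream needs it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationTable, build_annotation_table, gap_to_next
from .codes import SENSE_CODONS, translate_codon
from .compare import INDEL, MICROSATELLITE, SNP, Variant
from .datasets import load_published_annotation
from .genome import (
    CONTROL_REGION,
    PCG,
    CircularGenome,
    FeatureAnnotation,
    GenomeError,
)
from .motifs import RepeatRun

DEFAULT_SEED = 42

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Start codons of the default synthetic genome: the published mix of the
#: reference assemblies (seven ATG, five ATT, the lepidopteran CGA in cox1).
DEFAULT_START_CODONS = {
    "nad2": "ATT", "cox1": "CGA", "cox2": "ATG", "atp8": "ATT", "atp6": "ATG",
    "cox3": "ATG", "nad3": "ATT", "nad5": "ATT", "nad4": "ATG", "nad4l": "ATG",
    "nad6": "ATT", "cytb": "ATG", "nad1": "ATG",
}

#: Spacers that receive a planted microsatellite (left feature of the junction).
MSAT_SPACERS = ("trnQ", "trnK", "trnE")


@dataclass
class GenomeParams:
    """Tunable knobs of the synthetic genome.

    ``at_fraction`` is the background A+T fraction (tRNA/rRNA/spacers),
    ``pcg_at_fraction`` biases the codon sampler, and ``cr_at_fraction``
    the control region, mirroring the composition gradient of real
    mitogenomes (CR richest in A+T). Truncated stops are not a free
    choice: they fall out of the gene lengths (length mod 3 = 1 -> single
    T tail), which for the published lengths places them exactly in cox2
    and nad4.
    """

    at_fraction: float = 0.78
    pcg_at_fraction: float = 0.765
    cr_at_fraction: float = 0.93
    a_share_of_at: float = 0.513  # A/(A+T), from the published composition
    c_share_of_gc: float = 0.650  # C/(G+C)
    gap_profile: str = "published"  # or "sampled"
    poly_t_len: int = 18
    poly_a_len: int = 4
    msat_unit: str = "AT"
    msat_copies: int = 6
    start_codons: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_START_CODONS))


@dataclass
class MutationSpec:
    """Requested variant spectrum for the sister assembly; the default
    mirrors the published two-assembly comparison: 6 SNPs (5 transitions,
    one transversion), 2 indels, 3 microsatellite copy-number changes."""

    n_ts: int = 5
    n_tv: int = 1
    n_indel: int = 2
    n_msat: int = 3


@dataclass
class SyntheticTruth:
    """Everything the generator knows about what it emitted."""

    genome: CircularGenome
    features: list[FeatureAnnotation]
    table: AnnotationTable
    cds: dict[str, str]  # oriented CDS per PCG, as written
    motifs: dict[str, tuple[int, int]]  # planted element -> 1-based span
    repeats: list[RepeatRun]  # planted microsatellites, genome coordinates
    base_tally: dict[str, int]  # independent per-base tally of the emission
    params: GenomeParams
    seed: int


def _published_layout() -> list[tuple[str, str, str, int, int, str | None]]:
    """(name, class, strand, length, gap_after, anticodon) rows, in order."""
    feats = load_published_annotation("cat07")
    rows = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        gap = gap_to_next(f, nxt, genome_length=15_395)
        rows.append((f.name, f.feature_class, f.strand, f.length(15_395), gap,
                     f.anticodon))
    return rows


def _sample_gaps(rows, rng: np.random.Generator):
    """Resample nonzero gap magnitudes, keeping signs and the two
    codon-sharing PCG junctions (atp8->atp6, atp6->cox3) fixed."""
    fixed = {"atp8", "atp6"}
    out = []
    for name, cls, strand, length, gap, anti in rows:
        if name in fixed or gap == 0:
            new = gap
        elif gap < 0:
            new = -int(rng.integers(1, 9))
        elif name == "trnS2":  # must hold the 7 bp ATACTAA motif
            new = int(rng.integers(9, 31))
        elif name in MSAT_SPACERS:  # must hold a flanked (AT)n plant
            new = int(rng.integers(16, 63))
        else:
            new = int(rng.integers(1, 63))
        out.append((name, cls, strand, length, new, anti))
    return out


def _base_probs(at: float, a_share: float, c_share: float) -> np.ndarray:
    return np.array([at * a_share, (1 - at) * c_share,
                     (1 - at) * (1 - c_share), at * (1 - a_share)])


def _codon_table(at: float, a_share: float, c_share: float):
    probs = dict(zip("ACGT", _base_probs(at, a_share, c_share)))
    weights = np.array([probs[c[0]] * probs[c[1]] * probs[c[2]]
                        for c in SENSE_CODONS])
    return list(SENSE_CODONS), weights / weights.sum()


def _random_bases(rng, n: int, probs: np.ndarray) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=probs)) if n else ""


def _make_cds(rng, name: str, length: int, start_codon: str, codons, weights) -> str:
    """Codon-by-codon CDS synthesis: forced start, sampled sense interior,
    complete TAA or truncated T/TA tail per length mod 3."""
    rem = length % 3
    n_codons = length // 3
    body = list(rng.choice(codons, size=n_codons, p=weights))
    body[0] = start_codon
    if rem == 0:
        body[-1] = "TAA"
        tail = ""
    else:
        tail = "T" if rem == 1 else "TA"
    if name == "atp8":
        # terminal codons ATA TGA TAA put the conserved ATGATAA heptamer in
        # the last 7 bases, which the atp6 overlap shares
        if n_codons < 5:
            raise GenomeError("atp8 too short for the conserved terminus")
        body[-3:] = ["ATA", "TGA", "TAA"]
    if name == "atp6":
        # first 7 bases ATGATAA (codon3 then starts with A, never a stop)
        body[1] = "ATA"
        c3 = body[2]
        body[2] = "A" + c3[1:]
        if translate_codon(body[2]) == "*":  # pragma: no cover - A.. never stops
            body[2] = "AAA"
    return "".join(body) + tail


def generate_mitogenome(params: GenomeParams | None = None,
                        seed: int = DEFAULT_SEED) -> SyntheticTruth:
    """Generate one annotated synthetic mitogenome with full ground truth."""
    params = params or GenomeParams()
    rng = np.random.default_rng(seed)
    if params.start_codons.get("atp6") != "ATG" or not \
            params.start_codons.get("cox3", "A").startswith("A"):
        # atp6 must open the shared ATGATAA heptamer and cox3's first base is
        # also atp6's terminal stop base, which TAA fixes to A
        raise GenomeError("atp6 start must be ATG and cox3 start must begin with A")
    rows = _published_layout()
    if params.gap_profile == "sampled":
        rows = _sample_gaps(rows, rng)
    elif params.gap_profile != "published":
        raise GenomeError("gap_profile must be 'published' or 'sampled'")

    # --- coordinates ---
    features: list[FeatureAnnotation] = []
    pos = 1
    cr_gap = rows[-1][4]
    for name, cls, strand, length, gap, anti in rows:
        features.append(FeatureAnnotation(name=name, feature_class=cls,
                                          strand=strand, start=pos,
                                          end=pos + length - 1, anticodon=anti))
        pos = pos + length + gap
    L = features[-1].end + cr_gap  # CR->trnM junction closes the circle

    # --- sequence synthesis ---
    bg = _base_probs(params.at_fraction, params.a_share_of_at, params.c_share_of_gc)
    cr_probs = _base_probs(params.cr_at_fraction, params.a_share_of_at,
                           params.c_share_of_gc)
    genome_arr = list(_random_bases(rng, L, bg))
    motifs: dict[str, tuple[int, int]] = {}
    repeats: list[RepeatRun] = []

    def write(start1: int, text: str) -> None:
        genome_arr[start1 - 1 : start1 - 1 + len(text)] = list(text)

    cr = next(f for f in features if f.feature_class == CONTROL_REGION)
    write(cr.start, _random_bases(rng, cr.length(L), cr_probs))
    # replication-origin block: ATAGA + poly-T, flanked so the run is exact
    block = "ATAGA" + "T" * params.poly_t_len + "A"
    off = cr.start + 5
    write(off, block)
    motifs["ATAGA"] = (off, off + 4)
    motifs["polyT"] = (off + 5, off + 4 + params.poly_t_len)
    # terminal poly-A toward trnM
    write(cr.end - params.poly_a_len, "T" + "A" * params.poly_a_len)
    motifs["polyA"] = (cr.end - params.poly_a_len + 1, cr.end)

    by_name = {f.name: f for f in features}
    order = [f.name for f in features]

    def spacer(after: str) -> tuple[int, int]:
        f = by_name[after]
        nxt = by_name[order[(order.index(after) + 1) % len(order)]]
        return f.end + 1, nxt.start - 1

    # ATACTAA in the trnS2-nad1 spacer
    s, e = spacer("trnS2")
    write(s + 1, "ATACTAA")
    motifs["ATACTAA"] = (s + 1, s + 7)
    # microsatellite plants, flanked by C so the run is exactly n copies
    unit, copies = params.msat_unit.upper(), params.msat_copies
    for left in MSAT_SPACERS:
        s, e = spacer(left)
        span = len(unit) * copies
        if e - s + 1 < span + 2:
            raise GenomeError(f"spacer after {left} too short for the repeat plant")
        off = s + (e - s + 1 - span - 2) // 2
        write(off, "C" + unit * copies + "C")
        repeats.append(RepeatRun(unit=unit, copies=copies, start=off + 1,
                                 end=off + span, region="intergenic"))

    # protein-coding genes, codon-sampled; '+' writes forward, '-' writes
    # the reverse complement; PCGs written last so their constraints win
    codons, weights = _codon_table(params.pcg_at_fraction, params.a_share_of_at,
                                   params.c_share_of_gc)
    cds_truth: dict[str, str] = {}
    for f in features:
        if f.feature_class != PCG:
            continue
        cds = _make_cds(rng, f.name, f.length(L), params.start_codons[f.name],
                        codons, weights)
        cds_truth[f.name] = cds
        if f.strand == "+":
            write(f.start, cds)
        else:
            write(f.start, "".join(_COMPLEMENT[b] for b in reversed(cds)))
    # atp6 overwrote the shared atp8/atp6 heptamer with identical bases and
    # cox3's ATG start begins on atp6's terminal A; re-assert cox3's start
    motifs["ATGATAA"] = (by_name["atp6"].start, by_name["atp8"].end)

    sequence = "".join(genome_arr)
    genome = CircularGenome(id=f"synthetic-{seed}", sequence=sequence, circular=True)
    table = build_annotation_table(features, genome)
    tally = {b: sequence.count(b) for b in "ACGT"}
    return SyntheticTruth(genome=genome, features=features, table=table,
                          cds=cds_truth, motifs=motifs, repeats=repeats,
                          base_tally=tally, params=params, seed=seed)


# --- the mutated sister assembly -------------------------------------------

@dataclass
class _Edit:
    """A planned edit on the reference string (all 1-based)."""

    position: int  # SNP site, or indel anchor
    ref: str
    alt: str
    variant: Variant


def _left_align(seq: str, pos0: int, ins: str) -> tuple[int, str]:
    while pos0 >= 0 and ins and seq[pos0] == ins[-1]:
        ins = seq[pos0] + ins[:-1]
        pos0 -= 1
    return pos0, ins


def _blocked_spans(truth: SyntheticTruth) -> list[tuple[int, int]]:
    spans = [(1, 30)]  # keep the anchoring region clean
    spans += [(s - 2, e + 2) for s, e in truth.motifs.values()]
    # wide margin around repeats so SNPs/indels never crowd the copy-number edits
    spans += [(r.start - 25, r.end + 25) for r in truth.repeats]
    return spans


def _free(pos: int, spans, edits: list[_Edit], min_dist: int = 25) -> bool:
    if any(s <= pos <= e for s, e in spans):
        return False
    return all(abs(pos - e.position) >= min_dist for e in edits)


def _genome_pos(f: FeatureAnnotation, idx: int) -> int:
    return f.start + idx if f.strand == "+" else f.end - idx


def _plan_pcg_snp(rng, truth: SyntheticTruth, gene: str, *, transition: bool,
                  codon_pos: int, synonymous: bool, spans, edits) -> _Edit:
    """Pick a codon in ``gene`` where the requested change type exists."""
    f = next(x for x in truth.features if x.name == gene)
    cds = truth.cds[gene]
    n_codons = len(cds) // 3
    candidates = list(rng.permutation(np.arange(2, n_codons - 2)))
    for ci in candidates:
        ci = int(ci)
        codon = cds[3 * ci : 3 * ci + 3]
        base = codon[codon_pos - 1]
        alts = ([_TRANSITION[base]] if transition
                else [b for b in "ACGT" if b != base and b != _TRANSITION[base]])
        for alt in alts:
            new_codon = codon[: codon_pos - 1] + alt + codon[codon_pos:]
            if translate_codon(new_codon) == "*":
                continue
            if (translate_codon(new_codon) == translate_codon(codon)) != synonymous:
                continue
            idx = 3 * ci + codon_pos - 1
            pos = _genome_pos(f, idx)
            if not _free(pos, spans, edits):
                continue
            ref_g = truth.genome.sequence[pos - 1]
            alt_g = alt if f.strand == "+" else _COMPLEMENT[alt]
            v = Variant(position=pos, ref=ref_g, alt=alt_g, var_class=SNP,
                        snp_subclass="transition" if transition else "transversion",
                        region=gene, gene=gene, codon_number=ci + 1,
                        codon_position=codon_pos, ref_codon=codon,
                        alt_codon=new_codon, ref_aa=translate_codon(codon),
                        alt_aa=translate_codon(new_codon), synonymous=synonymous)
            return _Edit(pos, ref_g, alt_g, v)
    raise GenomeError(f"no feasible {'ts' if transition else 'tv'} site in {gene}")


def _plan_noncoding_snp(rng, truth: SyntheticTruth, region_class: str,
                        spans, edits) -> _Edit:
    """A transition inside the CR or inside a tRNA free of PCG overlap."""
    table = truth.table
    if region_class == "CR":
        f = next(x for x in truth.features if x.feature_class == CONTROL_REGION)
        pool = [f]
    else:
        pcg_spans = [(x.start, x.end) for x in truth.features
                     if x.feature_class == PCG]
        pool = [x for x in truth.features if x.feature_class == "tRNA"
                and not any(s <= x.start <= e or s <= x.end <= e
                            for s, e in pcg_spans)]
    for fi in rng.permutation(len(pool)):
        f = pool[int(fi)]
        positions = list(rng.permutation(np.arange(f.start + 2, f.end - 1)))
        for pos in positions:
            pos = int(pos)
            if not _free(pos, spans, edits):
                continue
            if table.region_of(pos)[0] != f.name:
                continue
            ref = truth.genome.sequence[pos - 1]
            v = Variant(position=pos, ref=ref, alt=_TRANSITION[ref],
                        var_class=SNP, snp_subclass="transition", region=f.name)
            return _Edit(pos, ref, _TRANSITION[ref], v)
    raise GenomeError(f"no feasible SNP site in region class {region_class}")


def _has_msat_context(seq: str, anchor0: int, ins: str) -> bool:
    from .compare import _repeat_context
    return _repeat_context(seq, anchor0, ins) is not None


def _plan_indel(rng, truth: SyntheticTruth, where: str, *, delete: bool,
                size: int, spans, edits) -> _Edit:
    """A plain indel (never reclassifiable as a microsatellite change)."""
    seq = truth.genome.sequence
    if where == "rRNA":
        pool = [x for x in truth.features if x.feature_class == "rRNA"]
    else:
        pool = [x for x in truth.features if x.feature_class == CONTROL_REGION]
    f = pool[int(rng.integers(len(pool)))]
    for pos in rng.permutation(np.arange(f.start + 5, f.end - 5 - size)):
        pos = int(pos)
        frag = seq[pos : pos + size] if delete else "".join(
            rng.choice(list("ACGT"), size=size))
        anchor0, frag_la = _left_align(seq, pos - 1, frag)
        if anchor0 < 0 or _has_msat_context(seq, anchor0, frag_la):
            continue
        # require an unambiguous site: already left-aligned, and the bases
        # flanking the fragment share no letters with it (otherwise an
        # equal-cost alignment can split the gap around a matching base)
        if anchor0 != pos - 1:
            continue
        if delete:
            flank = seq[pos - size : pos] + seq[pos + size : pos + 2 * size]
        else:
            flank = seq[pos - size : pos + size]
        if set(flank) & set(frag):
            continue
        if not _free(pos, spans, edits):
            continue
        anchor = seq[anchor0]
        if delete:
            ref, alt = anchor + frag_la, anchor
        else:
            ref, alt = anchor, anchor + frag_la
        v = Variant(position=anchor0 + 1, ref=ref, alt=alt, var_class=INDEL,
                    region=f.name)
        return _Edit(anchor0 + 1, ref, alt, v)
    raise GenomeError(f"no feasible indel site in {where}")


def _plan_msat(rng, truth: SyntheticTruth, run: RepeatRun, edits) -> _Edit:
    """Copy-number +-1 at a planted repeat, recorded left-aligned."""
    seq = truth.genome.sequence
    u = len(run.unit)
    gain = bool(rng.integers(2))
    anchor0 = run.start - 2  # the C flank
    anchor = seq[anchor0]
    if gain:
        ref, alt = anchor, anchor + run.unit
        alt_copies = run.copies + 1
    else:
        ref, alt = anchor + run.unit, anchor
        alt_copies = run.copies - 1
    v = Variant(position=anchor0 + 1, ref=ref, alt=alt,
                var_class=MICROSATELLITE, region="intergenic", unit=run.unit,
                ref_copies=run.copies, alt_copies=alt_copies)
    return _Edit(anchor0 + 1, ref, alt, v)


def mutate_assembly(truth: SyntheticTruth, spec: MutationSpec | None = None,
                    seed: int = 7) -> tuple[CircularGenome, list[Variant]]:
    """Derive a sister assembly with a planted, fully recorded variant set.

    Default placement mirrors the published spectrum: the transversion and
    three of the transitions hit four distinct PCGs (one of them a
    synonymous third-position transition), one transition falls in the
    control region and one in a tRNA; indels go to an rRNA and the control
    region; microsatellite changes use the planted intergenic repeats.
    """
    spec = spec or MutationSpec()
    rng = np.random.default_rng(seed)
    spans = _blocked_spans(truth)
    edits: list[_Edit] = []

    pcgs = [str(g) for g in rng.permutation(
        [f.name for f in truth.features if f.feature_class == PCG])]
    # transversions: third-position non-synonymous PCG changes
    for _ in range(spec.n_tv):
        if not pcgs:
            raise GenomeError("not enough PCGs for the requested transversions")
        edits.append(_plan_pcg_snp(rng, truth, pcgs.pop(), transition=False,
                                   codon_pos=3, synonymous=False,
                                   spans=spans, edits=edits))
    # transitions: one synonymous third-position, one CR, one tRNA, the
    # rest first-position non-synonymous, cycling if counts exceed the plan
    ts_plan = ["syn3", "CR", "tRNA"]
    for i in range(spec.n_ts):
        kind = ts_plan[i] if i < len(ts_plan) else "pos1"
        if kind == "syn3":
            edits.append(_plan_pcg_snp(rng, truth, pcgs.pop(), transition=True,
                                       codon_pos=3, synonymous=True,
                                       spans=spans, edits=edits))
        elif kind in ("CR", "tRNA"):
            edits.append(_plan_noncoding_snp(rng, truth, kind, spans, edits))
        else:
            if not pcgs:
                raise GenomeError("not enough PCGs for the requested transitions")
            edits.append(_plan_pcg_snp(rng, truth, pcgs.pop(), transition=True,
                                       codon_pos=1, synonymous=False,
                                       spans=spans, edits=edits))
    # indels: first in an rRNA (a 2 bp length polymorphism), then the CR
    for i in range(spec.n_indel):
        where = "rRNA" if i % 2 == 0 else "CR"
        edits.append(_plan_indel(rng, truth, where, delete=i % 2 == 0,
                                 size=2 if i % 2 == 0 else 1,
                                 spans=spans, edits=edits))
    # microsatellite copy-number changes at the planted repeats
    if spec.n_msat > len(truth.repeats):
        raise GenomeError(f"only {len(truth.repeats)} planted repeats available")
    for run in truth.repeats[: spec.n_msat]:
        edits.append(_plan_msat(rng, truth, run, edits))

    # apply right-to-left so earlier coordinates stay valid
    seq = truth.genome.sequence
    for e in sorted(edits, key=lambda x: -x.position):
        i0 = e.position - 1
        assert seq[i0 : i0 + len(e.ref)] == e.ref
        seq = seq[:i0] + e.alt + seq[i0 + len(e.ref) :]
    mutated = CircularGenome(id=truth.genome.id + "-sister", sequence=seq,
                             circular=True)
    variants = sorted((e.variant for e in edits), key=lambda v: v.position)
    return mutated, variants
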