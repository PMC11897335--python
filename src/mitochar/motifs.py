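"""Conserved-motif and perfect-repeat scanning in non-coding regions.

The characteristic lepidopteran mitogenome elements checked here:

* the ``ATAGA`` motif followed by a poly-T run in the control region,
  upstream of rrnS (replication-origin block);
* a short poly-A run at the control region's 3' end, toward trnM;
* the ``ATACTAA`` motif in the trnS2-nad1 intergenic spacer
  (transcription-termination signal);
* the ``ATGATAA`` heptamer spanning the atp8/atp6 overlap.

All matching is exact (no PWM or fuzzy matching) and repeats are perfect
(ungapped, mismatch-free). The microsatellite definition used by
:func:`find_runs` — unit 2-6 bp, >= 3 copies, >= 8 bp total — is this
package's own operational threshold; published mitogenome reports rarely
state their detector's parameters, so the thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import reverse_complement

from .annotation import AnnotationTable
from .genome import CircularGenome, GenomeError

HOMOPOLYMER_MIN_COPIES = 2
MICROSAT_MIN_COPIES = 3
MICROSAT_MIN_LENGTH = 8
MICROSAT_UNITS = (2, 6)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    pattern: str
    region: str
    strand: str
    start: int  # 1-based genome coordinates; end < start only when wrapping
    end: int
    context: str = ""


@dataclass(frozen=True)
class RepeatRun:
    unit: str
    copies: int
    start: int  # 1-based inclusive
    end: int
    region: str = ""

    @property
    def total_length(self) -> int:
        return len(self.unit) * self.copies


def _resolve_region(genome: CircularGenome, table: AnnotationTable | None,
                    region) -> tuple[int, int, str]:
    """Resolve a region constraint to a 1-based inclusive (start, end, label)."""
    if region is None:
        return 1, genome.length, "genome"
    if isinstance(region, tuple):
        return region[0], region[1], f"{region[0]}..{region[1]}"
    if table is None:
        raise GenomeError("named region constraint needs an annotation table")
    feat = table.feature_by_name(region)
    if feat is None:
        raise GenomeError(f"unknown region name {region!r}")
    return feat.start, feat.end, region


def scan_motif(genome: CircularGenome, pattern: str,
               region=None, table: AnnotationTable | None = None,
               strand_policy: str = "plus", motif_id: str | None = None,
               context: str = "") -> list[MotifHit]:
    """All exact occurrences of a motif, optionally constrained to a region.

    ``region`` may be None (whole genome, wrapping the origin if circular),
    a feature name from the table, or a 1-based inclusive ``(start, end)``
    tuple (end < start spans the origin). ``strand_policy`` is 'plus' or
    'both'; minus-strand hits are reported in plus-strand coordinates with
    strand '-'.
    """
    pattern = pattern.upper()
    if not set(pattern) <= set("ACGT"):
        raise GenomeError(f"motif pattern must be over ACGT, got {pattern!r}")
    if strand_policy not in ("plus", "both"):
        raise ValueError("strand_policy must be 'plus' or 'both'")
    start, end, label = _resolve_region(genome, table, region)
    seq = genome.slice(start, end)
    offset0 = start - 1
    whole_genome_circular = region is None and genome.circular
    if whole_genome_circular:
        seq = seq + seq[: len(pattern) - 1]  # catch origin-spanning hits
    L = genome.length
    targets = [(pattern, "+")]
    if strand_policy == "both":
        rc = reverse_complement(pattern)
        if rc != pattern:
            targets.append((rc, "-"))
    hits = []
    for pat, strand in targets:
        i = seq.find(pat)
        while i != -1:
            s0 = (offset0 + i) % L
            e0 = (s0 + len(pat) - 1) % L
            hits.append(MotifHit(
                motif_id=motif_id or pattern, pattern=pattern,
                region=label, strand=strand, start=s0 + 1, end=e0 + 1,
                context=context))
            i = seq.find(pat, i + 1)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# --- perfect repeat runs ----------------------------------------------------

def _is_primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def find_runs(seq: str, kind: str = "homopolymer", *,
              min_copies: int | None = None,
              min_length: int | None = None) -> list[RepeatRun]:
    """Maximal non-extendable perfect repeat runs in a sequence.

    ``kind='homopolymer'``: unit length 1, >= 2 copies by default.
    ``kind='microsatellite'``: primitive units of 2-6 bp, >= 3 copies and
    >= 8 bp total by default. Overlapping candidate runs are resolved to the
    longest run, ties to the smallest unit. Coordinates are 1-based within
    ``seq``.
    """
    seq = seq.upper()
    if kind == "homopolymer":
        min_copies = HOMOPOLYMER_MIN_COPIES if min_copies is None else min_copies
        runs = []
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            n = j - i
            if n >= min_copies and seq[i] in "ACGT":
                runs.append(RepeatRun(unit=seq[i], copies=n, start=i + 1, end=j))
            i = j
        return runs
    if kind != "microsatellite":
        raise ValueError("kind must be 'homopolymer' or 'microsatellite'")
    min_copies = MICROSAT_MIN_COPIES if min_copies is None else min_copies
    min_length = MICROSAT_MIN_LENGTH if min_length is None else min_length
    candidates = []
    lo, hi = MICROSAT_UNITS
    for u in range(lo, hi + 1):
        i = 0
        while i + u <= len(seq):
            unit = seq[i : i + u]
            if not (set(unit) <= set("ACGT") and _is_primitive(unit)):
                i += 1
                continue
            # count whole-unit copies
            k = 1
            while seq[i + k * u : i + (k + 1) * u] == unit:
                k += 1
            if k >= min_copies and k * u >= min_length:
                # maximality to the left: previous unit must differ
                if i < u or seq[i - u : i] != unit:
                    candidates.append(RepeatRun(unit=unit, copies=k,
                                                start=i + 1, end=i + k * u))
                i += 1
            else:
                i += 1
    # resolve overlaps: longest first, then smallest unit, then leftmost
    candidates.sort(key=lambda r: (-r.total_length, len(r.unit), r.start))
    chosen: list[RepeatRun] = []
    for r in candidates:
        if all(r.end < c.start or r.start > c.end for c in chosen):
            chosen.append(r)
    chosen.sort(key=lambda r: r.start)
    return chosen


def find_runs_in_genome(genome: CircularGenome, kind: str = "homopolymer",
                        table: AnnotationTable | None = None,
                        **kwargs) -> list[RepeatRun]:
    """Genome-coordinate repeat scan; origin-crossing runs handled on a
    circular genome, and regions assigned when a table is given."""
    seq = genome.sequence
    if genome.circular:
        pad = min(len(seq), 6 * 64)  # generous wrap window
        runs = find_runs(seq + seq[:pad], kind, **kwargs)
        out = []
        for r in runs:
            if r.start > len(seq):
                continue
            if r.total_length >= len(seq):  # degenerate: whole-genome run
                r = RepeatRun(r.unit, len(seq) // len(r.unit), 1,
                              len(seq) // len(r.unit) * len(r.unit))
            end = (r.end - 1) % len(seq) + 1
            out.append(RepeatRun(r.unit, r.copies, r.start, end, r.region))
        # a run fully inside the pad duplicates one starting in the first copy
        runs = out
    else:
        runs = find_runs(seq, kind, **kwargs)
    if table is not None:
        runs = [RepeatRun(r.unit, r.copies, r.start, r.end,
                          region=table.region_of(r.start)[0]) for r in runs]
    return runs


# --- the conserved-element report ------------------------------------------

@dataclass
class MotifCheck:
    name: str
    found: bool
    hits: list[MotifHit] = field(default_factory=list)
    run_length: int | None = None
    reason: str = ""


@dataclass
class MotifReport:
    checks: dict[str, MotifCheck]

    @property
    def n_found(self) -> int:
        return sum(c.found for c in self.checks.values())

    def __str__(self) -> str:
        lines = [f"conserved motifs: {self.n_found}/{len(self.checks)} found"]
        for c in self.checks.values():
            state = "found" if c.found else f"absent ({c.reason})" if c.reason else "absent"
            where = f" at {c.hits[0].start}-{c.hits[0].end}" if c.hits else ""
            run = f", run length {c.run_length}" if c.run_length else ""
            lines.append(f"  {c.name}: {state}{where}{run}")
        return "\n".join(lines)


def conserved_motif_report(genome: CircularGenome, table: AnnotationTable,
                           *, poly_a_window: int = 25,
                           poly_t_window: int = 30) -> MotifReport:
    """Check the four diagnostic lepidopteran elements (see module docstring).

    Missing prerequisite features produce a partial report with reasons,
    never an exception.
    """
    checks: dict[str, MotifCheck] = {}

    cr = table.feature_by_name("CR")

    # 1. ATAGA + downstream poly-T inside the CR (upstream of rrnS)
    name = "ATAGA+polyT"
    if cr is None:
        checks[name] = MotifCheck(name, False, reason="no control region annotated")
    else:
        hits = scan_motif(genome, "ATAGA", region=(cr.start, cr.end),
                          motif_id=name, context="upstream-of-rrnS")
        if not hits:
            checks[name] = MotifCheck(name, False, reason="ATAGA not found in CR")
        else:
            h = hits[0]
            window = genome.slice(h.end % genome.length + 1,
                                  (h.end + poly_t_window - 1) % genome.length + 1)
            t_runs = [r for r in find_runs(window, "homopolymer") if r.unit == "T"]
            if t_runs:
                checks[name] = MotifCheck(name, True, hits=[h],
                                          run_length=max(r.copies for r in t_runs))
            else:
                checks[name] = MotifCheck(name, False, hits=[h],
                                          reason="no poly-T run downstream of ATAGA")

    # 2. poly-A at the CR end adjacent to trnM
    name = "CR-terminal-polyA"
    if cr is None:
        checks[name] = MotifCheck(name, False, reason="no control region annotated")
    else:
        w0 = cr.end - poly_a_window + 1
        tail = genome.slice((w0 - 1) % genome.length + 1, cr.end)
        a_runs = [r for r in find_runs(tail, "homopolymer") if r.unit == "A"]
        if a_runs:
            best = max(a_runs, key=lambda r: r.copies)
            checks[name] = MotifCheck(name, True, run_length=best.copies)
        else:
            checks[name] = MotifCheck(name, False,
                                      reason=f"no poly-A in last {poly_a_window} bp of CR")

    # 3. ATACTAA in the trnS2-nad1 spacer
    name = "ATACTAA-spacer"
    try:
        span = table.spacer_span("trnS2", "nad1")
        hits = scan_motif(genome, "ATACTAA", region=span, motif_id=name,
                          context="trnS2-nad1 spacer")
        checks[name] = MotifCheck(name, bool(hits), hits=hits,
                                  reason="" if hits else "motif absent from spacer")
    except GenomeError as exc:
        checks[name] = MotifCheck(name, False, reason=str(exc))

    # 4. ATGATAA spanning the atp8/atp6 overlap
    name = "ATGATAA-overlap"
    atp8, atp6 = table.feature_by_name("atp8"), table.feature_by_name("atp6")
    if atp8 is None or atp6 is None:
        checks[name] = MotifCheck(name, False, reason="atp8/atp6 not annotated")
    elif atp6.start > atp8.end:
        checks[name] = MotifCheck(name, False, reason="atp8 and atp6 do not overlap")
    else:
        pad = 7
        window = (max(1, atp6.start - pad), min(genome.length, atp8.end + pad))
        hits = [h for h in scan_motif(genome, "ATGATAA", region=window,
                                      motif_id=name, context="atp8/atp6 overlap")
                if h.start <= atp8.end and h.end >= atp6.start]
        checks[name] = MotifCheck(name, bool(hits), hits=hits,
                                  reason="" if hits else "heptamer absent from overlap")

    return MotifReport(checks)
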