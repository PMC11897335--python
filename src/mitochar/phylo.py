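"""Supermatrix preparation for mitogenome phylogenetics.

Extracts the 13 protein-coding genes, aligns them codon-aware (translate
under the invertebrate mitochondrial code, align amino acids, back-thread
codons), concatenates into a partitioned supermatrix and writes the files
downstream ML software consumes (relaxed PHYLIP, NEXUS with a sets block,
RAxML-style partition text, JSON coordinate map).

Partition schemes:

* ``I``   one partition per gene;
* ``II``  two partitions: codon positions {1,2} vs {3}, across all genes;
* ``III`` codon positions {1,2} only (third positions dropped from the
  exported matrix), single partition by default or per-gene via config;
* ``IV``  a single partition over all sites, flagged for codon models.

Tree inference itself (ML search, model selection, bootstrap) is out of
scope; the bundled aligner is a deliberately simple star alignment that
makes the preparation self-contained on synthetic data, not a replacement
for a production codon aligner. Support-threshold constants commonly used
to read the resulting trees (SH-aLRT >= 80, UFBoot >= 95) are emitted as
documentation alongside the partition files.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment, PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotationTable
from .codes import STOP_CODONS, translate_codon
from .genome import PCG_SYMBOLS, CircularGenome, GenomeError, extract_subsequence

SCHEMES = ("I", "II", "III", "IV")
SUPPORT_THRESHOLDS = {"SH_aLRT_min": 80, "UFBoot_min": 95}
GAP = "-"


# --- PCG extraction ---------------------------------------------------------

def extract_pcgs(genome: CircularGenome, table: AnnotationTable, *,
                 partial: bool = False) -> tuple[dict[str, str], list[str]]:
    """Oriented 5'->3' CDS of every protein-coding gene, in genome order.

    Returns ``(records, absent)``. Truncated stops are retained as-is.
    Missing genes raise unless ``partial=True`` (fragmentary assemblies,
    e.g. GenBank records carrying only a handful of genes, are then
    recorded in the absence list).
    """
    records: dict[str, str] = {}
    absent: list[str] = []
    for name in PCG_SYMBOLS:
        feat = table.feature_by_name(name)
        if feat is None:
            absent.append(name)
        else:
            records[name] = extract_subsequence(genome, feat)
    if absent and not partial:
        raise GenomeError(f"missing PCGs {absent}; pass partial=True to allow")
    if not records:
        raise GenomeError("no protein-coding genes to extract")
    return records, absent


# --- naive codon-aware alignment -------------------------------------------

def _codons_of(cds: str, *, strip_stops: bool = True) -> list[str]:
    cds = cds.upper()
    codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    if strip_stops and codons and codons[-1] in STOP_CODONS:
        codons.pop()
    return codons


def _aa_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -0.5
    return aligner


def align_codon_block(cds_by_taxon: dict[str, str], *,
                      strip_stops: bool = True) -> dict[str, str]:
    """Codon-aware multiple alignment of one gene across taxa.

    Star alignment against the first taxon: translate each CDS, align the
    amino-acid sequences pairwise to the reference, merge on reference
    positions, and back-thread nucleotide codons ('---' per amino-acid gap).
    """
    taxa = list(cds_by_taxon)
    codons = {t: _codons_of(cds_by_taxon[t], strip_stops=strip_stops) for t in taxa}
    aas = {t: "".join("X" if translate_codon(c) == "*" else translate_codon(c)
                      for c in codons[t]) for t in taxa}
    ref = taxa[0]
    if all(len(a) == len(aas[ref]) for a in aas.values()):
        aligned_aa = {t: aas[t] for t in taxa}  # equal length: no gaps needed
    else:
        aligner = _aa_aligner()
        n_ref = len(aas[ref])
        rows = {}  # taxon -> (list of residues per ref position, insertions after pos)
        max_ins = [0] * (n_ref + 1)
        for t in taxa[1:]:
            aln = aligner.align(aas[ref], aas[t])[0]
            ra, ta = str(aln[0]), str(aln[1])
            per_pos: list[str] = []
            ins: list[str] = [""] * (n_ref + 1)
            rp = 0
            for rc, tc in zip(ra, ta):
                if rc == GAP:
                    ins[rp] += tc
                else:
                    per_pos.append(tc)
                    rp += 1
            rows[t] = (per_pos, ins)
            for p, s in enumerate(ins):
                max_ins[p] = max(max_ins[p], len(s))
        aligned_aa = {}
        ref_row = []
        for p in range(n_ref + 1):
            ref_row.append(GAP * max_ins[p])
            if p < n_ref:
                ref_row.append(aas[ref][p])
        aligned_aa[ref] = "".join(ref_row)
        for t in taxa[1:]:
            per_pos, ins = rows[t]
            out = []
            for p in range(n_ref + 1):
                out.append(ins[p].ljust(max_ins[p], GAP))
                if p < n_ref:
                    out.append(per_pos[p])
            aligned_aa[t] = "".join(out)
    # back-thread codons
    out: dict[str, str] = {}
    for t in taxa:
        it = iter(codons[t])
        parts = []
        for aa in aligned_aa[t]:
            parts.append("---" if aa == GAP else next(it))
        out[t] = "".join(parts)
    widths = {len(s) for s in out.values()}
    assert len(widths) == 1, "aligned block rows must share one width"
    return out


# --- the supermatrix --------------------------------------------------------

@dataclass
class PartitionDefinition:
    scheme: str
    sets: dict[str, tuple[int, ...]]  # name -> sorted 1-based site indices
    metadata: dict = field(default_factory=dict)


@dataclass
class PartitionedSupermatrix:
    """Concatenated codon-aware PCG alignment with per-gene coordinates."""

    taxa: list[str]
    gene_order: list[str]
    matrix: dict[str, str]  # taxon -> concatenated row
    coords: dict[str, tuple[int, int]]  # gene -> 1-based inclusive columns

    @property
    def width(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0

    def validate(self) -> None:
        widths = {len(s) for s in self.matrix.values()}
        if len(widths) > 1:
            raise GenomeError(f"unequal row lengths {sorted(widths)}")
        for g, (s, e) in self.coords.items():
            if (e - s + 1) % 3:
                raise GenomeError(f"{g}: block width {e - s + 1} not a codon multiple")


def concatenate(blocks: dict[str, dict[str, str]],
                taxa: list[str] | None = None, *,
                order: str = "genome") -> PartitionedSupermatrix:
    """Concatenate per-gene aligned blocks into one matrix.

    ``order='genome'`` keeps the mitogenome gene order (default, documented);
    ``order='alphabetical'`` matches the convention of common concatenation
    tools. A taxon missing from a block is filled with gaps; a taxon listed
    twice with conflicting sequence raises.
    """
    if not blocks:
        raise GenomeError("no blocks to concatenate")
    if order == "genome":
        genes = [g for g in PCG_SYMBOLS if g in blocks]
        genes += sorted(g for g in blocks if g not in set(PCG_SYMBOLS))
    elif order == "alphabetical":
        genes = sorted(blocks)
    else:
        raise ValueError("order must be 'genome' or 'alphabetical'")
    if taxa is None:
        seen: list[str] = []
        for g in genes:
            for t in blocks[g]:
                if t not in seen:
                    seen.append(t)
        taxa = seen
    rows = {t: [] for t in taxa}
    coords: dict[str, tuple[int, int]] = {}
    col = 0
    for g in genes:
        block = blocks[g]
        widths = {len(s) for s in block.values()}
        if len(widths) != 1:
            raise GenomeError(f"{g}: unaligned block (row widths {sorted(widths)})")
        w = widths.pop()
        for t in taxa:
            rows[t].append(block.get(t, GAP * w))
        coords[g] = (col + 1, col + w)
        col += w
    sm = PartitionedSupermatrix(
        taxa=list(taxa), gene_order=genes,
        matrix={t: "".join(parts) for t, parts in rows.items()}, coords=coords)
    sm.validate()
    return sm


def make_partitions(sm: PartitionedSupermatrix, scheme: str, *,
                    per_gene_iii: bool = False
                    ) -> tuple[PartitionDefinition, PartitionedSupermatrix]:
    """Build a partition definition (and, for scheme III, the subset matrix).

    Returns ``(definition, matrix)``; the matrix is ``sm`` itself except for
    scheme III, where third codon positions are dropped.
    """
    if scheme not in SCHEMES:
        raise GenomeError(f"unknown scheme {scheme!r}; pick from {SCHEMES}")
    width = sm.width
    if scheme == "I":
        sets = {g: tuple(range(s, e + 1)) for g, (s, e) in sm.coords.items()}
        return PartitionDefinition("I", sets), sm
    if scheme == "II":
        pos12, pos3 = [], []
        for g, (s, e) in sm.coords.items():
            for c in range(s, e + 1):
                (pos3 if (c - s) % 3 == 2 else pos12).append(c)
        sets = {"pos12": tuple(sorted(pos12)), "pos3": tuple(sorted(pos3))}
        return PartitionDefinition("II", sets), sm
    if scheme == "IV":
        return PartitionDefinition(
            "IV", {"all": tuple(range(1, width + 1))},
            metadata={"codon_model": True,
                      "genetic_code": "invertebrate mitochondrial (table 5)"}), sm
    # scheme III: subset the matrix to codon positions 1+2
    keep: list[int] = []
    new_coords: dict[str, tuple[int, int]] = {}
    col = 0
    for g in sm.gene_order:
        s, e = sm.coords[g]
        cols = [c for c in range(s, e + 1) if (c - s) % 3 != 2]
        keep.extend(cols)
        new_coords[g] = (col + 1, col + len(cols))
        col += len(cols)
    keep0 = [c - 1 for c in keep]
    sub = PartitionedSupermatrix(
        taxa=list(sm.taxa), gene_order=list(sm.gene_order),
        matrix={t: "".join(row[i] for i in keep0) for t, row in sm.matrix.items()},
        coords=new_coords)
    if per_gene_iii:
        sets = {g: tuple(range(s, e + 1)) for g, (s, e) in new_coords.items()}
    else:
        sets = {"pos12": tuple(range(1, len(keep) + 1))}
    return PartitionDefinition("III", sets, metadata={"positions": "1+2 only"}), sub


# --- site-set <-> range text -----------------------------------------------

def _compress_sites(sites: tuple[int, ...]) -> list[tuple[int, int, int]]:
    """Sorted sites -> arithmetic-progression runs (start, end, stride)."""
    runs: list[tuple[int, int, int]] = []
    i, n = 0, len(sites)
    while i < n:
        if i + 1 == n:
            runs.append((sites[i], sites[i], 1))
            break
        stride = sites[i + 1] - sites[i]
        j = i + 1
        while j + 1 < n and sites[j + 1] - sites[j] == stride:
            j += 1
        runs.append((sites[i], sites[j], stride))
        i = j + 1
    return runs


def _format_ranges(sites: tuple[int, ...], sep: str = ", ") -> str:
    """RAxML joins ranges with commas; NEXUS charsets use whitespace."""
    parts = []
    for s, e, stride in _compress_sites(sites):
        if s == e:
            parts.append(str(s))
        elif stride == 1:
            parts.append(f"{s}-{e}")
        else:
            parts.append(f"{s}-{e}\\{stride}")
    return sep.join(parts)


def _parse_ranges(text: str) -> tuple[int, ...]:
    sites: list[int] = []
    for part in re.split(r"[,\s]+", text):
        part = part.strip()
        if not part:
            continue
        stride = 1
        if "\\" in part:
            part, s = part.split("\\")
            stride = int(s)
        if "-" in part:
            a, b = part.split("-")
            sites.extend(range(int(a), int(b) + 1, stride))
        else:
            sites.append(int(part))
    return tuple(sorted(sites))


def write_raxml_partitions(definition: PartitionDefinition) -> str:
    lines = [f"DNA, {name} = {_format_ranges(sites)}"
             for name, sites in definition.sets.items()]
    return "\n".join(lines) + "\n"


def read_raxml_partitions(text: str) -> dict[str, tuple[int, ...]]:
    sets: dict[str, tuple[int, ...]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        head, ranges = line.split("=", 1)
        name = head.split(",", 1)[1].strip()
        sets[name] = _parse_ranges(ranges)
    return sets


def _sets_block(definition: PartitionDefinition) -> str:
    lines = ["begin sets;"]
    for name, sites in definition.sets.items():
        lines.append(f"    charset {name} = {_format_ranges(sites, sep=' ')};")
    lines.append("end;")
    return "\n".join(lines) + "\n"


def read_nexus_charsets(text: str) -> dict[str, tuple[int, ...]]:
    sets: dict[str, tuple[int, ...]] = {}
    for line in text.splitlines():
        line = line.strip()
        if line.lower().startswith("charset"):
            body = line[len("charset"):].strip().rstrip(";")
            name, ranges = body.split("=", 1)
            sets[name.strip()] = _parse_ranges(ranges)
    return sets


# --- matrix I/O -------------------------------------------------------------

def _to_biopython(sm: PartitionedSupermatrix) -> MultipleSeqAlignment:
    records = [SeqRecord(Seq(sm.matrix[t]), id=t, description="",
                         annotations={"molecule_type": "DNA"}) for t in sm.taxa]
    return MultipleSeqAlignment(records)


def write_phylip(sm: PartitionedSupermatrix, path: str | Path) -> None:
    AlignIO.write(_to_biopython(sm), str(path), "phylip-relaxed")


def read_phylip(path: str | Path) -> dict[str, str]:
    aln = AlignIO.read(str(path), "phylip-relaxed")
    return {rec.id: str(rec.seq) for rec in aln}


def write_nexus(sm: PartitionedSupermatrix, path: str | Path,
                definition: PartitionDefinition | None = None) -> None:
    path = Path(path)
    AlignIO.write(_to_biopython(sm), str(path), "nexus")
    if definition is not None:
        with path.open("a") as fh:
            fh.write("\n" + _sets_block(definition))


def read_nexus(path: str | Path) -> dict[str, str]:
    aln = AlignIO.read(str(path), "nexus")
    return {rec.id: str(rec.seq) for rec in aln}


def write_phylo_files(sm: PartitionedSupermatrix,
                      definition: PartitionDefinition,
                      outdir: str | Path, prefix: str = "supermatrix") -> dict[str, Path]:
    """Write the full export bundle; returns the paths written."""
    if not definition.sets:
        raise GenomeError("refusing to write an empty partition set")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phylip": outdir / f"{prefix}.phy",
        "nexus": outdir / f"{prefix}.nex",
        "raxml": outdir / f"{prefix}.partitions.txt",
        "coords": outdir / f"{prefix}.coords.json",
        "support": outdir / f"{prefix}.support_thresholds.txt",
    }
    write_phylip(sm, paths["phylip"])
    write_nexus(sm, paths["nexus"], definition)
    paths["raxml"].write_text(write_raxml_partitions(definition))
    paths["coords"].write_text(json.dumps(
        {"gene_order": sm.gene_order, "coords": sm.coords,
         "scheme": definition.scheme, "metadata": definition.metadata}, indent=2))
    paths["support"].write_text(
        "# Branch-support reading thresholds for downstream ML trees\n"
        + "".join(f"{k} = {v}\n" for k, v in SUPPORT_THRESHOLDS.items()))
    return paths
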