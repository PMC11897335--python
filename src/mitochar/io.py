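"""Readers and writers for the standard formats the pipeline touches.

Supported feature dialects:

* ``table1_tsv`` — tab-separated annotation table with header
  ``gene  class  strand  start  end  anticodon`` ('.' for missing),
  1-based inclusive coordinates.
* ``gff3`` — via gffutils (in-memory db); feature types CDS/tRNA/rRNA/D_loop.
* ``genbank`` — Biopython flat-file parsing, features only.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    CONTROL_REGION,
    PCG,
    RRNA,
    TRNA,
    CircularGenome,
    FeatureAnnotation,
    GenomeError,
    canonical_gene_name,
)

logger = logging.getLogger("mitochar")

_GFF_TYPE_BY_CLASS = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA", CONTROL_REGION: "D_loop"}
_CLASS_BY_GFF_TYPE = {v: k for k, v in _GFF_TYPE_BY_CLASS.items()}
_CLASS_BY_GFF_TYPE.update({"D-loop": CONTROL_REGION, "misc_feature": CONTROL_REGION})

_TSV_HEADER = ["gene", "class", "strand", "start", "end", "anticodon"]
_TSV_CLASS = {"PCG": PCG, "tRNA": TRNA, "rRNA": RRNA, "control_region": CONTROL_REGION,
              "CR": CONTROL_REGION}


def read_fasta(path: str | Path, *, circular: bool | None = None,
               multi: bool = False) -> CircularGenome | list[CircularGenome]:
    """Read genome(s) from FASTA; sequence upper-cased.

    Circularity is taken from the word ``circular`` in the header unless
    overridden. With ``multi=False`` (mitogenome mode) exactly one record
    is required.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeError(f"{path}: no FASTA records")
    genomes = []
    for rec in records:
        circ = circular if circular is not None else "circular" in rec.description.lower()
        genomes.append(CircularGenome(id=rec.id, sequence=str(rec.seq), circular=circ))
    if multi:
        return genomes
    if len(genomes) > 1:
        raise GenomeError(f"{path}: {len(genomes)} records; pass multi=True to allow")
    return genomes[0]


def write_fasta(genome: CircularGenome, path: str | Path, *, width: int = 70) -> None:
    desc = "circular" if genome.circular else "linear"
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description=desc)
    SeqIO.write([rec], str(path), "fasta")


# --- feature tables ---------------------------------------------------------

def read_feature_table(path: str | Path, dialect: str = "table1_tsv",
                       genome: CircularGenome | None = None) -> list[FeatureAnnotation]:
    """Read an annotation into canonical features, sorted by start coordinate.

    Gene labels are canonicalized; an unmapped label raises rather than
    guessing. If a genome is supplied, coordinates are checked against it.
    """
    readers = {"table1_tsv": _read_tsv, "gff3": _read_gff3, "genbank": _read_genbank}
    try:
        reader = readers[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; pick from {sorted(readers)}") from None
    features = reader(Path(path))
    if not features:
        logger.warning("%s: no features parsed", path)
    if genome is not None:
        for f in features:
            f.validate_against(genome)
    features.sort(key=lambda f: f.start)
    logger.info("%s: %d features", path, len(features))
    return features


def _read_tsv(path: Path) -> list[FeatureAnnotation]:
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        return []
    header = lines[0].split("\t")
    if header != _TSV_HEADER:
        raise GenomeError(f"{path}: expected header {_TSV_HEADER}, got {header}")
    feats = []
    for ln in lines[1:]:
        gene, cls, strand, start, end, anticodon = ln.split("\t")
        anticodon = None if anticodon == "." else anticodon
        name = canonical_gene_name(gene, anticodon)
        feats.append(FeatureAnnotation(
            name=name, feature_class=_TSV_CLASS[cls], strand=strand,
            start=int(start.replace(",", "")), end=int(end.replace(",", "")),
            wraps_origin=int(start.replace(",", "")) > int(end.replace(",", "")),
            anticodon=anticodon))
    return feats


def write_table1_tsv(features: list[FeatureAnnotation], path: str | Path) -> None:
    rows = ["\t".join(_TSV_HEADER)]
    for f in features:
        cls = "CR" if f.feature_class == CONTROL_REGION else f.feature_class
        rows.append("\t".join([f.name, cls, f.strand, str(f.start), str(f.end),
                               f.anticodon or "."]))
    Path(path).write_text("\n".join(rows) + "\n")


def _read_gff3(path: Path) -> list[FeatureAnnotation]:
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    feats = []
    for rec in db.all_features():
        cls = _CLASS_BY_GFF_TYPE.get(rec.featuretype)
        if cls is None:
            continue  # gene/exon scaffolding lines duplicate the typed rows
        label = (rec.attributes.get("Name") or rec.attributes.get("gene")
                 or rec.attributes.get("ID") or [None])[0]
        if label is None:
            raise GenomeError(f"{path}: feature without Name/gene/ID at {rec.start}")
        anticodon = (rec.attributes.get("anticodon") or [None])[0]
        name = canonical_gene_name(label, anticodon)
        feats.append(FeatureAnnotation(
            name=name, feature_class=cls, strand=rec.strand,
            start=rec.start, end=rec.end, anticodon=anticodon))
    return feats


def write_gff3(features: list[FeatureAnnotation], genome_id: str, path: str | Path,
               genome_length: int | None = None) -> None:
    """GFF3 export (1-based inclusive, as the format requires)."""
    lines = ["##gff-version 3"]
    if genome_length:
        lines.append(f"##sequence-region {genome_id} 1 {genome_length}")
    for f in features:
        if f.wraps_origin:
            raise GenomeError(f"{f.name}: GFF3 cannot represent an origin-wrapping feature")
        attrs = f"ID={f.name};Name={f.name}"
        if f.anticodon:
            attrs += f";anticodon={f.anticodon}"
        lines.append("\t".join([
            genome_id, "mitochar", _GFF_TYPE_BY_CLASS[f.feature_class],
            str(f.start), str(f.end), ".", f.strand, ".", attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_genbank(path: Path) -> list[FeatureAnnotation]:
    record = SeqIO.read(str(path), "genbank")
    feats = []
    for ft in record.features:
        cls = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA,
               "D-loop": CONTROL_REGION}.get(ft.type)
        if cls is None:
            continue
        label = (ft.qualifiers.get("gene") or ft.qualifiers.get("product") or [None])[0]
        if label is None:
            raise GenomeError(f"{path}: {ft.type} feature without gene/product qualifier")
        anticodon = None
        q = ft.qualifiers.get("anticodon")
        if q:  # e.g. "(pos:33..35,aa:Met,seq:cat)"
            import re
            m = re.search(r"seq:([acgut]{3})", q[0])
            if m:
                anticodon = m.group(1).upper().replace("T", "U")
        parts = ft.location.parts
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        feats.append(FeatureAnnotation(
            name=canonical_gene_name(label, anticodon), feature_class=cls,
            strand="+" if ft.location.strand != -1 else "-",
            start=start, end=end, wraps_origin=start > end, anticodon=anticodon))
    return feats


def to_bed(features: list[FeatureAnnotation], genome_id: str) -> str:
    """BED (0-based half-open) text for genome-browser use; wrap features split."""
    lines = []
    for f in features:
        if f.wraps_origin:
            raise GenomeError(f"{f.name}: split wrapping features before BED export")
        lines.append(f"{genome_id}\t{f.start - 1}\t{f.end}\t{f.name}\t0\t{f.strand}")
    return "\n".join(lines) + "\n"
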