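"""Bundled reference data.

The package ships the published annotation coordinates of the two
*Paracossulus thrips* mitogenome assemblies (male specimen CAT07, GenBank
PQ668644, 15,395 bp; female specimen CAT08, GenBank PQ668645, 15,385 bp)
transcribed from the assemblies' annotation table, together with the
published per-gene lengths, overlap/spacer values and start/stop codons.
Coordinates are 1-based inclusive; gaps in the published table are signed
(positive = intergenic spacer, negative = overlap with the next feature).

Only the printed annotation values are bundled — no sequence data. The
sequences live under their GenBank accessions and are never required by
the test suite; synthetic genomes stand in for them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genome import FeatureAnnotation

_GENOME_LENGTH = {"cat07": 15_395, "cat08": 15_385}


def _data_path(name: str):
    return resources.files("mitochar.data").joinpath(name)


def load_published_annotation(assembly: str = "cat07") -> list[FeatureAnnotation]:
    """Feature annotations of one published assembly ('cat07' or 'cat08')."""
    from .io import _read_tsv  # local import to avoid a cycle

    key = assembly.lower()
    if key not in _GENOME_LENGTH:
        raise ValueError(f"assembly must be 'cat07' or 'cat08', got {assembly!r}")
    feats = _read_tsv(_data_path(f"{key}_annotation.tsv"))
    feats.sort(key=lambda f: f.start)
    return feats


def published_genome_length(assembly: str = "cat07") -> int:
    """Published total assembly length in bp."""
    return _GENOME_LENGTH[assembly.lower()]


def load_published_values() -> pd.DataFrame:
    """Published per-gene lengths, signed gaps and codons, indexed by gene symbol.

    Columns: length_cat07, length_cat08, gap_cat07, gap_cat08 (pandas
    nullable Int64; the control region's gap is printed as missing),
    start_codon, stop_codon (NaN for non-PCG rows).
    """
    df = pd.read_csv(_data_path("published_annotation_values.tsv"), sep="\t",
                     na_values=["."])
    for col in ("length_cat07", "length_cat08", "gap_cat07", "gap_cat08"):
        df[col] = df[col].astype("Int64")
    return df.set_index("gene")
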