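"""Readers and writers for the standard formats the pipeline touches.

FASTA (genome), GFF3 (annotation, 1-based inclusive), bedGraph (per-strand
coverage, 0-based half-open, converted to 1-based dense tracks at this
boundary), and TSV tables with a header row for every record type.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence, Type

import numpy as np
import pandas as pd
from Bio import SeqIO

from .models import (
    CountMatrix,
    CoverageTrack,
    DEGResult,
    GeneModel,
    GenomeSequence,
    TEPRecord,
    TEResult,
    TranscriptionUnit,
    TSSRecord,
    UEDRecord,
)

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> GenomeSequence:
    """Read a single-contig genome FASTA; multi-contig files are rejected."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FormatError(f"{path}: multiple contigs unsupported ({len(records)} records)")
    rec = records[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        # locate the first offending line for the error message
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(">"):
                    continue
                if set(line.strip().upper()) - set("ACGTN"):
                    raise FormatError(
                        f"{path}:{lineno}: invalid sequence characters {sorted(bad)}"
                    )
        raise FormatError(f"{path}: invalid sequence characters {sorted(bad)}")
    return GenomeSequence(contig_id=rec.id, sequence=seq)


def write_genome_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.contig_id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GENE_ID_KEYS = ("locus_tag", "gene_id", "ID", "Name", "Parent")


def read_annotation_gff(path: str | Path) -> list[GeneModel]:
    """Read CDS features from a GFF3 file into GeneModels.

    Genes whose CDS length is not a multiple of 3 are skipped with a warning;
    a missing strand is an error.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("CDS", order_by="start"):
        gene_id = None
        for key in _GENE_ID_KEYS:
            if key in feat.attributes:
                gene_id = feat.attributes[key][0]
                break
        if gene_id is None:
            raise FormatError(f"{path}: CDS at {feat.start}..{feat.end} has no gene identifier")
        if feat.strand not in ("+", "-"):
            raise FormatError(f"{path}: CDS {gene_id} has no strand")
        length = feat.end - feat.start + 1
        if length % 3 != 0:
            warnings.warn(
                f"{gene_id}: CDS length {length} not a multiple of 3; gene skipped",
                stacklevel=2,
            )
            continue
        genes.append(
            GeneModel(
                gene_id=gene_id, contig_id=feat.seqid, strand=feat.strand,
                cds_start=feat.start, cds_end=feat.end,
            )
        )
    return genes


def write_annotation_gff(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID=cds-{g.gene_id};locus_tag={g.gene_id}"
            fh.write(
                f"{g.contig_id}\ttuarch\tCDS\t{g.cds_start}\t{g.cds_end}\t.\t{g.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_coverage_bedgraph(
    path: str | Path,
    strand: str,
    assay: str,
    condition: str,
    replicate: int,
    genome_length: int,
) -> CoverageTrack:
    """Expand a bedGraph (0-based half-open intervals) into a dense 1-based track.

    Positions absent from the file get depth 0.  Intervals beyond
    ``genome_length`` or overlapping each other are errors.
    """
    path = Path(path)
    depth = np.zeros(genome_length, dtype=float)
    covered = np.zeros(genome_length, dtype=bool)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"start": int, "end": int, "value": float},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.start < 0 or row.end > genome_length:
            raise FormatError(
                f"{path}: interval {row.start}..{row.end} outside genome of length {genome_length}"
            )
        if row.end <= row.start:
            raise FormatError(f"{path}: empty or inverted interval {row.start}..{row.end}")
        if covered[row.start : row.end].any():
            raise FormatError(f"{path}: overlapping interval {row.start}..{row.end}")
        covered[row.start : row.end] = True
        depth[row.start : row.end] = row.value
    return CoverageTrack(
        assay=assay, condition=condition, replicate=replicate, strand=strand, depth=depth
    )


def write_coverage_bedgraph(track: CoverageTrack, contig_id: str, path: str | Path) -> None:
    """Write a dense track as run-length-encoded bedGraph; zero runs are omitted."""
    d = track.depth
    with open(path, "w") as fh:
        if d.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [d.size]))
        for s, e in zip(starts, ends):
            v = float(d[s])
            if v != 0:
                text = str(int(v)) if v.is_integer() else repr(v)
                fh.write(f"{contig_id}\t{s}\t{e}\t{text}\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_TABLE_TYPES: dict[type, list[str]] = {
    TSSRecord: ["gene_id", "position", "strand"],
    TEPRecord: ["position", "strand", "category", "gene_id", "counts"],
    TranscriptionUnit: [
        "gene_id", "strand", "tss_pos", "tep_pos", "start_codon_pos",
        "stop_codon_end_pos", "l_5utr", "l_3utr", "l_tu",
    ],
    UEDRecord: ["gene_id", "assay", "condition", "ued5", "ued3"],
    DEGResult: ["gene_id", "log2fc", "p_value", "is_deg", "direction"],
    TEResult: ["gene_id", "condition", "te", "torso_te"],
    GeneModel: ["gene_id", "contig_id", "strand", "cds_start", "cds_end"],
}


def _encode(value):
    if isinstance(value, tuple):
        return ",".join(str(v) for v in value)
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(value)
    return value


def write_table(records: Sequence, path: str | Path, metadata: dict | None = None) -> None:
    """Write homogeneous records as a TSV with a header row.

    Optional ``metadata`` is serialized as ``# key: value`` comment lines
    above the header.  Mixed record types are an error; an empty list with an
    explicit record type is written via :func:`write_empty_table`.
    """
    records = list(records)
    if not records:
        raise ValueError("write_table needs at least one record; use write_empty_table")
    types = {type(r) for r in records}
    if len(types) > 1:
        raise ValueError(f"mixed record types: {sorted(t.__name__ for t in types)}")
    rtype = types.pop()
    if rtype not in _TABLE_TYPES:
        raise ValueError(f"no table schema for {rtype.__name__}")
    _write_rows(rtype, records, path, metadata)


def write_empty_table(record_type: type, path: str | Path, metadata: dict | None = None) -> None:
    _write_rows(record_type, [], path, metadata)


def _write_rows(rtype, records, path, metadata) -> None:
    columns = _TABLE_TYPES[rtype]
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            values = [_encode(getattr(rec, c)) for c in columns]
            fh.write("\t".join(str(v) for v in values) + "\n")


def read_table(path: str | Path, record_type: Type) -> list:
    """Read back a TSV written by :func:`write_table` into records."""
    if record_type not in _TABLE_TYPES:
        raise ValueError(f"no table schema for {record_type.__name__}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    expected = _TABLE_TYPES[record_type]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: columns {list(df.columns)} do not match {expected}")
    hints = {f.name: f.type for f in dataclasses.fields(record_type)}
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for col in expected:
            raw = getattr(row, col)
            hint = str(hints[col])
            if raw == "NA":
                kwargs[col] = None
            elif col == "counts":
                kwargs[col] = tuple(int(x) for x in raw.split(",")) if raw else ()
            elif "bool" in hint:
                kwargs[col] = raw == "True"
            elif "int" in hint:
                kwargs[col] = int(raw)
            elif "float" in hint:
                kwargs[col] = float(raw)
            else:
                kwargs[col] = raw
        out.append(record_type(**kwargs))
    return out


# ---------------------------------------------------------------------------
# Count matrices and designs
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=df.to_numpy(dtype=np.int64),
    )


def write_count_matrix(cm: CountMatrix, path: str | Path, metadata: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        cm.to_frame().to_csv(fh, sep="\t", index_label="gene_id")


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column sample->condition design TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "condition"]:
        raise FormatError(f"{path}: design must have columns sample_id, condition")
    return dict(zip(df["sample_id"], df["condition"]))


def write_design(design: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tcondition\n")
        for sample, cond in design.items():
            fh.write(f"{sample}\t{cond}\n")
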