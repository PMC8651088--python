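"""Domain types shared across the pipeline.

Coordinate contract
-------------------
All internal genomic coordinates are 1-based and inclusive, matching GFF3.
bedGraph's 0-based half-open intervals are converted at I/O time only.

Codon-relative coordinates (used by :class:`ExtremityPartition`) follow the
bacterial-genomics convention with no zero position: relative to the start
codon, +1 is the first base of the start codon and -1 the last base of the
5'-UTR; relative to the stop codon, -1 is the last base of the stop codon and
+1 the first base of the 3'-UTR.  Metagene profiles instead use a dense
``-W..+W`` axis whose offset 0 sits on the anchor base itself (first base of
the start codon, or last base of the stop codon); see :mod:`tuarch.metagene`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

VALID_STRANDS = ("+", "-")
ASSAYS = ("RNA", "RPF", "TERM")


def shift_downstream(pos: int, k: int, strand: str) -> int:
    """Genomic position ``k`` bases downstream of ``pos`` in transcript direction."""
    return pos + k if strand == "+" else pos - k


def strand_distance(a: int, b: int, strand: str) -> int:
    """Signed transcript-direction distance from ``a`` to ``b``."""
    return b - a if strand == "+" else a - b


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: uppercase A/C/G/T/N."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid characters in genome sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive slice; reverse-complemented for the minus strand."""
        if start < 1 or end > self.length or start > end:
            raise ValueError(f"subseq [{start}, {end}] outside contig of length {self.length}")
        s = self.sequence[start - 1 : end]
        return s if strand == "+" else revcomp(s)


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware CDS on a genome.

    ``cds_start <= cds_end`` in genomic order; on the minus strand the start
    codon therefore sits at ``cds_end``.
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.cds_start > self.cds_end:
            raise ValueError(f"{self.gene_id}: cds_start > cds_end")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length} not a multiple of 3")

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def start_codon_pos(self) -> int:
        """First transcribed base of the start codon."""
        return self.cds_start if self.strand == "+" else self.cds_end

    @property
    def stop_codon_end_pos(self) -> int:
        """Last transcribed base of the stop codon."""
        return self.cds_end if self.strand == "+" else self.cds_start

    def cds_index_to_genomic(self, i: int) -> int:
        """Genomic position of the i-th CDS base (1-based, transcript order)."""
        if not 1 <= i <= self.cds_length:
            raise ValueError(f"CDS index {i} outside 1..{self.cds_length}")
        return shift_downstream(self.start_codon_pos, i - 1, self.strand)


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"TSS {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class CoverageTrack:
    """Dense per-base depth for one assay/condition/replicate/strand.

    ``depth[p - 1]`` is the depth at 1-based genomic position ``p``.  TERM
    tracks hold transcript 3'-end counts (the track producer has already
    mapped Term-seq read 5' ends to the transcript strand), not read-body
    coverage.
    """

    assay: str
    condition: str
    replicate: int
    strand: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if np.any(self.depth < 0):
            raise ValueError("coverage depth must be non-negative")

    @property
    def genome_length(self) -> int:
        return int(self.depth.size)

    def at(self, pos: int) -> float:
        return float(self.depth[pos - 1])

    def region_sum(self, positions: Sequence[int]) -> float:
        idx = np.asarray(positions, dtype=int) - 1
        return float(self.depth[idx].sum())


class TrackSet:
    """Keyed collection of CoverageTracks with replicate averaging.

    Keys are (assay, condition, replicate, strand).
    """

    def __init__(self, tracks: Sequence["CoverageTrack"] = ()):
        self._tracks: dict[tuple[str, str, int, str], CoverageTrack] = {}
        for t in tracks:
            self.add(t)

    def add(self, track: "CoverageTrack") -> None:
        key = (track.assay, track.condition, track.replicate, track.strand)
        if key in self._tracks:
            raise ValueError(f"duplicate track {key}")
        self._tracks[key] = track

    def __iter__(self):
        return iter(self._tracks.values())

    def __len__(self) -> int:
        return len(self._tracks)

    def get(self, assay: str, condition: str, replicate: int, strand: str) -> "CoverageTrack":
        return self._tracks[(assay, condition, replicate, strand)]

    def conditions(self, assay: str) -> list[str]:
        seen: dict[str, None] = {}
        for a, c, _, _ in self._tracks:
            if a == assay:
                seen.setdefault(c)
        return list(seen)

    def replicates(self, assay: str, condition: str) -> list[int]:
        reps = sorted({r for a, c, r, _ in self._tracks if a == assay and c == condition})
        return reps

    def averaged(self, assay: str, condition: str, strand: str) -> "CoverageTrack":
        """Position-wise mean over replicates."""
        reps = self.replicates(assay, condition)
        if not reps:
            raise KeyError(f"no tracks for {assay}/{condition}")
        depth = np.mean(
            [self.get(assay, condition, r, strand).depth for r in reps], axis=0
        )
        return CoverageTrack(
            assay=assay, condition=condition, replicate=0, strand=strand, depth=depth
        )

    def by_strand(self, assay: str, condition: str, replicate: int | None = None):
        """{strand: track} pair; replicate None means replicate-averaged."""
        if replicate is None:
            return {s: self.averaged(assay, condition, s) for s in VALID_STRANDS}
        return {s: self.get(assay, condition, replicate, s) for s in VALID_STRANDS}


TEP_CATEGORIES = ("P", "S", "I", "A", "U")


@dataclass(frozen=True)
class TEPRecord:
    """A transcript 3'-end position with its category and per-replicate counts.

    Categories: P (primary, highest count within the downstream window of a
    stop codon), S (secondary, same window), I (intragenic, sense CDS),
    A (antisense to a gene), U (sense-upstream of a start codon).
    """

    position: int
    strand: str
    category: str
    gene_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.category not in TEP_CATEGORIES:
            raise ValueError(f"bad TEP category {self.category!r}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def total_count(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class TranscriptionUnit:
    """Gene + TSS + primary TEP, with derived UTR and TU lengths.

    Fields follow the TSS-to-TEP span: ``tss_pos`` (t), ``tep_pos`` (p),
    ``start_codon_pos`` (s), ``stop_codon_end_pos`` (e).
    """

    gene_id: str
    strand: str
    tss_pos: int
    tep_pos: int
    start_codon_pos: int
    stop_codon_end_pos: int
    l_5utr: int
    l_3utr: int
    l_tu: int

    @classmethod
    def from_parts(cls, gene: GeneModel, tss_pos: int, tep_pos: int) -> "TranscriptionUnit":
        s, e, st = gene.start_codon_pos, gene.stop_codon_end_pos, gene.strand
        l5 = strand_distance(tss_pos, s, st)  # t..s-1 has s - t bases on +
        l3 = strand_distance(e, tep_pos, st)
        l_tu = strand_distance(tss_pos, tep_pos, st) + 1
        tu = cls(
            gene_id=gene.gene_id, strand=st, tss_pos=tss_pos, tep_pos=tep_pos,
            start_codon_pos=s, stop_codon_end_pos=e,
            l_5utr=l5, l_3utr=l3, l_tu=l_tu,
        )
        if l5 < 0:
            raise ValueError(f"{gene.gene_id}: TSS downstream of start codon (l_5utr={l5})")
        if l3 < 1:
            raise ValueError(f"{gene.gene_id}: TEP not downstream of stop codon (l_3utr={l3})")
        if l_tu != l5 + gene.cds_length + l3:
            raise AssertionError("TU length bookkeeping violated")
        return tu

    @property
    def cds_length(self) -> int:
        return self.l_tu - self.l_5utr - self.l_3utr

    def tu_positions(self) -> np.ndarray:
        """All genomic positions t..p in transcript order."""
        step = 1 if self.strand == "+" else -1
        return np.arange(self.tss_pos, self.tep_pos + step, step)

    def utr5_positions(self) -> np.ndarray:
        return self.tu_positions()[: self.l_5utr]

    def utr3_positions(self) -> np.ndarray:
        return self.tu_positions()[self.l_5utr + self.cds_length :]


@dataclass(frozen=True)
class UEDRecord:
    """UTR enrichment degree for one gene x assay x condition.

    ``ued5``/``ued3`` are mean depth over the UTR divided by mean depth over
    the whole TU; ``None`` marks an undefined value (zero-depth TU, or a
    leaderless gene for ued5).
    """

    gene_id: str
    assay: str
    condition: str
    ued5: float | None
    ued3: float | None


@dataclass(frozen=True)
class DEGResult:
    gene_id: str
    log2fc: float
    p_value: float
    is_deg: bool
    direction: str  # up / down / none


@dataclass(frozen=True)
class TEResult:
    gene_id: str
    condition: str
    te: float
    torso_te: float | None = None


@dataclass
class CountMatrix:
    """Raw integer counts, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class ExtremityPartition:
    """Extremity/torso partition of a CDS, in codon-relative (no-zero) coordinates.

    ``start_window = (a1, b1)`` straddles the start codon (a1 < 0 < b1): bases
    a1..-1 are 5' of the CDS and +1..b1 are the first b1 CDS bases.
    ``stop_window = (a2, b2)`` straddles the stop codon: a2..-1 are the last
    |a2| CDS bases and +1..b2 lie 3' of the CDS.  The torso is the CDS interior
    left over: CDS base indices b1+1 .. L+a2 (transcript order).
    """

    start_window: tuple[int, int] = (-30, 60)
    stop_window: tuple[int, int] = (-33, 15)

    def __post_init__(self) -> None:
        a1, b1 = self.start_window
        a2, b2 = self.stop_window
        if not (a1 < 0 < b1):
            raise ValueError(f"start window {self.start_window} must straddle the start codon")
        if not (a2 < 0 < b2):
            raise ValueError(f"stop window {self.stop_window} must straddle the stop codon")

    # -- codon-relative -> genomic ------------------------------------------
    @staticmethod
    def _start_rel_to_genomic(gene: GeneModel, c: int) -> int:
        if c == 0:
            raise ValueError("codon-relative coordinate 0 is undefined")
        k = c - 1 if c > 0 else c
        return shift_downstream(gene.start_codon_pos, k, gene.strand)

    @staticmethod
    def _stop_rel_to_genomic(gene: GeneModel, c: int) -> int:
        if c == 0:
            raise ValueError("codon-relative coordinate 0 is undefined")
        k = c if c > 0 else c + 1
        return shift_downstream(gene.stop_codon_end_pos, k, gene.strand)

    def start_extremity_positions(self, gene: GeneModel) -> list[int]:
        a1, b1 = self.start_window
        return [self._start_rel_to_genomic(gene, c) for c in range(a1, b1 + 1) if c != 0]

    def stop_extremity_positions(self, gene: GeneModel) -> list[int]:
        a2, b2 = self.stop_window
        return [self._stop_rel_to_genomic(gene, c) for c in range(a2, b2 + 1) if c != 0]

    def torso_cds_indices(self, gene: GeneModel) -> range:
        """1-based CDS base indices of the torso; empty range if none."""
        b1 = self.start_window[1]
        a2 = self.stop_window[0]
        lo, hi = b1 + 1, gene.cds_length + a2
        return range(lo, hi + 1) if hi >= lo else range(0)

    def torso_positions(self, gene: GeneModel) -> list[int]:
        return [gene.cds_index_to_genomic(i) for i in self.torso_cds_indices(gene)]


@dataclass(frozen=True)
class MetageneProfile:
    """Mean depth at fixed offsets from a shared anchor over many genes.

    Offsets run ``-W..+W`` (2W+1 values, including 0); offset 0 is the anchor
    base: the first base of the start codon, or the last base of the stop codon.
    """

    anchor: str  # start_codon | stop_codon
    offsets: np.ndarray
    mean_depth: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        if self.anchor not in ("start_codon", "stop_codon"):
            raise ValueError(f"bad anchor {self.anchor!r}")
        offs = np.asarray(self.offsets, dtype=int)
        if not np.array_equal(np.diff(offs), np.ones(offs.size - 1, dtype=int)):
            raise ValueError("offsets must be contiguous")
        if offs.size != len(self.mean_depth):
            raise ValueError("offsets and mean_depth length mismatch")

    @property
    def half_width(self) -> int:
        return int(self.offsets[-1])
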