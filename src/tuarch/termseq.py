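"""Transcript 3'-end position (TEP) detection and characterization.

Candidate TEPs are per-replicate local maxima of the Term-seq 3'-end count
track; only positions detected in every replicate (within a configurable
tolerance) are kept.  Candidates are then classified relative to the
annotation: primary (P, highest count within the downstream window of a stop
codon), secondary (S, same window), intragenic (I), antisense (A), upstream
(U).  The module also extracts terminator sequence context (positional
nucleotide composition, transcript-sense upstream sequences) and compares
terminator folding free energies against randomly sampled intergenic
sequences.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .models import (
    CoverageTrack,
    GeneModel,
    GenomeSequence,
    TEPRecord,
    shift_downstream,
    strand_distance,
)

log = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass(frozen=True)
class TEPCandidate:
    position: int
    strand: str
    counts: tuple[int, ...]  # one per replicate

    @property
    def total_count(self) -> int:
        return int(sum(self.counts))


def _local_maxima(depth: np.ndarray, min_count: float, radius: int = 3) -> dict[int, float]:
    """1-based positions whose count >= min_count and >= all counts within +/-radius."""
    out: dict[int, float] = {}
    hot = np.flatnonzero(depth >= min_count)
    for i in hot:
        lo = max(0, i - radius)
        hi = min(depth.size, i + radius + 1)
        if depth[i] >= depth[lo:hi].max():
            out[int(i) + 1] = float(depth[i])
    return out


def detect_teps(
    term_tracks: Sequence[Mapping[str, CoverageTrack]],
    min_count: int = 5,
    match_tolerance: int = 0,
    allow_single_replicate: bool = False,
) -> list[TEPCandidate]:
    """Replicate-consistent TEP candidates from Term-seq 3'-end count tracks.

    ``term_tracks`` is one {strand: track} mapping per replicate.  A candidate
    is a position with count >= min_count that is a local maximum within
    +/-3 nt; it is kept iff every replicate has a candidate within
    ``match_tolerance`` nt.  The reported position is replicate 1's candidate.
    """
    if len(term_tracks) < 2 and not allow_single_replicate:
        raise ValueError("need >= 2 Term-seq replicates (or allow_single_replicate=True)")
    out: list[TEPCandidate] = []
    for strand in ("+", "-"):
        per_rep = [_local_maxima(rep[strand].depth, min_count) for rep in term_tracks]
        for pos in sorted(per_rep[0]):
            counts = [per_rep[0][pos]]
            ok = True
            for other in per_rep[1:]:
                matches = [q for q in other if abs(q - pos) <= match_tolerance]
                if not matches:
                    ok = False
                    break
                nearest = min(matches, key=lambda q: (abs(q - pos), q))
                counts.append(other[nearest])
            if ok:
                out.append(
                    TEPCandidate(position=pos, strand=strand, counts=tuple(int(c) for c in counts))
                )
    return out


def classify_teps(
    candidates: Sequence[TEPCandidate],
    genes: Sequence[GeneModel],
    downstream_window: int = 250,
    upstream_window: int = 150,
) -> list[TEPRecord]:
    """Five-way classification of TEP candidates against the annotation.

    Precedence per candidate: sense downstream window of a stop codon (P if
    it holds the window's maximal total count, else S) > sense CDS (I) >
    antisense overlap of a CDS (A) > sense-upstream of a start codon (U);
    anything else is dropped with a log entry.  A candidate inside the
    downstream windows of two same-strand genes goes to the nearer stop
    codon.  Count ties for P break toward the position nearest the stop.
    """
    by_gene: dict[str, list[TEPCandidate]] = {}
    others: list[tuple[TEPCandidate, str, str]] = []  # candidate, category, gene_id

    gene_list = list(genes)

    def downstream_gene(cand: TEPCandidate) -> GeneModel | None:
        hits = []
        for g in gene_list:
            if g.strand != cand.strand:
                continue
            d = strand_distance(g.stop_codon_end_pos, cand.position, g.strand)
            if 1 <= d <= downstream_window:
                hits.append((d, g))
        if not hits:
            return None
        hits.sort(key=lambda t: (t[0], t[1].gene_id))
        if len(hits) > 1:
            warnings.warn(
                f"TEP at {cand.position}{cand.strand} falls in downstream windows of "
                f"{len(hits)} genes; assigned to {hits[0][1].gene_id}",
                stacklevel=2,
            )
        return hits[0][1]

    for cand in candidates:
        g = downstream_gene(cand)
        if g is not None:
            by_gene.setdefault(g.gene_id, []).append(cand)
            continue
        sense_cds = next(
            (
                g for g in gene_list
                if g.strand == cand.strand and g.cds_start <= cand.position <= g.cds_end
            ),
            None,
        )
        if sense_cds is not None:
            others.append((cand, "I", sense_cds.gene_id))
            continue
        antisense = next(
            (
                g for g in gene_list
                if g.strand != cand.strand and g.cds_start <= cand.position <= g.cds_end
            ),
            None,
        )
        if antisense is not None:
            others.append((cand, "A", antisense.gene_id))
            continue
        upstream = None
        for g in gene_list:
            if g.strand != cand.strand:
                continue
            d = strand_distance(cand.position, g.start_codon_pos, g.strand)
            if 1 <= d <= upstream_window:
                upstream = g
                break
        if upstream is not None:
            others.append((cand, "U", upstream.gene_id))
            continue
        log.info("TEP candidate at %d%s unassignable; dropped", cand.position, cand.strand)

    stop_by_gene = {g.gene_id: (g.stop_codon_end_pos, g.strand) for g in gene_list}
    records: list[TEPRecord] = []
    for gene_id, cands in by_gene.items():
        stop, strand = stop_by_gene[gene_id]
        cands = sorted(
            cands,
            key=lambda c: (-c.total_count, strand_distance(stop, c.position, strand)),
        )
        primary = cands[0]
        records.append(
            TEPRecord(
                position=primary.position, strand=primary.strand, category="P",
                gene_id=gene_id, counts=primary.counts,
            )
        )
        for c in cands[1:]:
            records.append(
                TEPRecord(
                    position=c.position, strand=c.strand, category="S",
                    gene_id=gene_id, counts=c.counts,
                )
            )
    for cand, cat, gene_id in others:
        records.append(
            TEPRecord(
                position=cand.position, strand=cand.strand, category=cat,
                gene_id=gene_id, counts=cand.counts,
            )
        )
    records.sort(key=lambda r: (r.position, r.strand))
    return records


def assign_3utr(teps: Sequence[TEPRecord], genes: Sequence[GeneModel]) -> dict[str, int]:
    """3'-UTR length per gene from its primary TEP (stop_codon_end+1 .. TEP)."""
    stop_by_gene = {g.gene_id: (g.stop_codon_end_pos, g.strand) for g in genes}
    out: dict[str, int] = {}
    for rec in teps:
        if rec.category != "P":
            continue
        stop, strand = stop_by_gene[rec.gene_id]
        out[rec.gene_id] = strand_distance(stop, rec.position, strand)
    return out


def nucleotide_composition(
    teps: Sequence[TEPRecord], genome: GenomeSequence, flank: int = 50
) -> np.ndarray:
    """Base fractions at offsets -flank..+flank around TEPs, transcript-sense.

    Returns a (2*flank+1) x 4 matrix (columns A, C, G, T); offset 0 is the
    TEP.  TEPs too near the contig edge are skipped for the out-of-range
    offsets only; each row is normalized over the TEPs contributing to it.
    """
    if not teps:
        raise ValueError("no TEPs")
    n_off = 2 * flank + 1
    counts = np.zeros((n_off, 4))
    totals = np.zeros(n_off)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for rec in teps:
        for oi, off in enumerate(range(-flank, flank + 1)):
            pos = shift_downstream(rec.position, off, rec.strand)
            if not 1 <= pos <= genome.length:
                continue
            base = genome.subseq(pos, pos, rec.strand)
            if base in base_idx:
                counts[oi, base_idx[base]] += 1
                totals[oi] += 1
    if np.any(totals == 0):
        raise ValueError("some offsets have no contributing TEPs")
    return counts / totals[:, None]


def upstream_sequences(
    teps: Sequence[TEPRecord], genome: GenomeSequence, length: int = 40
) -> list[tuple[TEPRecord, str]]:
    """Transcript-sense sequences of ``length`` nt ending at each TEP.

    Sequences truncated by the contig edge are flagged by their shorter
    length; callers may filter on ``len(seq) == length``.
    """
    out = []
    for rec in teps:
        start = shift_downstream(rec.position, -(length - 1), rec.strand)
        lo, hi = min(start, rec.position), max(start, rec.position)
        lo = max(1, lo)
        hi = min(genome.length, hi)
        out.append((rec, genome.subseq(lo, hi, rec.strand)))
    return out


def write_fasta_sequences(seqs: Sequence[tuple[TEPRecord, str]], path) -> None:
    """Upstream sequences as FASTA, suitable for an external motif tool."""
    with open(path, "w") as fh:
        for rec, seq in seqs:
            fh.write(f">tep_{rec.position}{'_plus' if rec.strand == '+' else '_minus'}\n{seq}\n")


def sample_intergenic(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    n: int = 10000,
    length: int = 40,
    seed: int = 0,
) -> list[str]:
    """n random intergenic windows (both strands), none overlapping a CDS."""
    mask = np.zeros(genome.length, dtype=bool)
    for g in genes:
        mask[g.cds_start - 1 : g.cds_end] = True
    # window starting at 0-based i is valid iff mask[i:i+length] is all clear
    cum = np.concatenate(([0], np.cumsum(mask)))
    starts0 = np.arange(0, genome.length - length + 1)
    valid = starts0[(cum[starts0 + length] - cum[starts0]) == 0]
    if valid.size == 0:
        raise ValueError(f"insufficient intergenic space for windows of {length} nt")
    rng = np.random.default_rng(seed)
    picks = rng.choice(valid, size=n, replace=True)
    strands = rng.choice(["+", "-"], size=n)
    out = []
    for i, strand in zip(picks, strands):
        out.append(genome.subseq(int(i) + 1, int(i) + length, str(strand)))
    return out


# ---------------------------------------------------------------------------
# Folding adapters
# ---------------------------------------------------------------------------

def gc_stub_fold(seq: str) -> float:
    """Fast stand-in folding score: -(#G + #C).  For tests and smoke runs."""
    return -float(seq.count("G") + seq.count("C"))


def rnafold_fold(seq: str) -> float:
    """Minimum free energy (kcal/mol) from the RNAfold command-line tool."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold not found on PATH")
    res = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    )
    last = res.stdout.strip().splitlines()[-1]
    return float(last.rsplit("(", 1)[1].rstrip(")").strip())


def mfe_background_test(
    tep_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    fold: Callable[[str], float],
) -> tuple[float, float, float, float]:
    """One-sided rank-sum test that terminator sequences fold more stably.

    Returns (median_tep, median_bg, statistic, p) where p tests
    dG(tep) < dG(background).  Sequences the adapter fails on are skipped
    with a warning.
    """

    def fold_all(seqs):
        vals, failed = [], 0
        for s in seqs:
            try:
                vals.append(fold(s))
            except Exception:  # adapter failure: skip, count
                failed += 1
        if failed:
            warnings.warn(f"folding adapter failed on {failed} sequences; skipped", stacklevel=3)
        return np.asarray(vals)

    tep_dg = fold_all(tep_seqs)
    bg_dg = fold_all(bg_seqs)
    if tep_dg.size == 0 or bg_dg.size == 0:
        raise ValueError("no foldable sequences in one of the groups")
    stat, p = stats.mannwhitneyu(tep_dg, bg_dg, alternative="less")
    return float(np.median(tep_dg)), float(np.median(bg_dg)), float(stat), float(p)
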