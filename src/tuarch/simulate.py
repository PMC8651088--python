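"""Synthetic-data generator.

Builds a toy single-contig bacterial genome with single-gene transcription
units, plants intrinsic terminators (GC-rich hairpin + U-tract) at known
transcript 3'-end positions, and emulates the three sequencing tracks the
analysis consumes: negative-binomial RNA/RPF count matrices with planted
condition effects, piecewise-constant RNA depth over each TU, RPF depth
confined to the CDS +/- extremity margins with a condition-specific stall
multiplier near the start and stop codons, and Term-seq 3'-end counts peaked
at the planted terminators.

Everything is deterministic under ``SimConfig.seed``; each operation derives
its own generator stream so the three stages can be re-run independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GenomeSequence,
    TrackSet,
    TSSRecord,
    revcomp,
    shift_downstream,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    UTR lengths are log-normal with target medians matching the measured
    bacterial medians (53 nt for 5'-UTRs, 92 nt for 3'-UTRs); conditions
    default to a control, a high-light-like stress with expression changes
    only, and a low-temperature-like stress that additionally stalls
    ribosomes at gene extremities (``stall_factor`` applied inside the
    [-30,+60] start / [-33,+15] stop windows).
    """

    seed: int = 0
    n_genes: int = 120
    genome_length: int = 320_000
    utr5_median: float = 53.0
    utr5_sigma: float = 1.0
    utr3_median: float = 92.0
    utr3_sigma: float = 0.55
    cds_len_range: tuple[int, int] = (300, 3000)
    conditions: tuple[str, ...] = ("CTRL", "HL", "LT")
    reference_condition: str = "CTRL"
    stress_condition: str = "LT"  # condition receiving the stall multiplier
    n_replicates: int = 2
    nb_dispersion: float = 0.05
    deg_fraction: float = 0.1
    deg_log2fc_range: tuple[float, float] = (1.0, 3.0)
    stall_factor: float = 3.0
    stall_start_window: tuple[int, int] = (-30, 60)
    stall_stop_window: tuple[int, int] = (-33, 15)
    term_peak_prob: float = 0.9
    term_depth_mean: float = 30.0
    baseline_mean_range: tuple[float, float] = (100.0, 2000.0)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    depth_scale: float = 100.0  # track depth summed over a TU per unit count
    noise_sigma_frac: float = 0.05
    min_spacer: int = 50

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.genome_length < 1:
            raise ValueError("n_genes and genome_length must be positive")
        if self.stall_factor < 1:
            raise ValueError("stall_factor must be >= 1")
        if not 0 <= self.term_peak_prob <= 1:
            raise ValueError("term_peak_prob must be in [0, 1]")
        if self.reference_condition not in self.conditions:
            raise ValueError("reference_condition must be one of conditions")
        if self.stress_condition not in self.conditions:
            raise ValueError("stress_condition must be one of conditions")
        if self.cds_len_range[0] < 9 or self.cds_len_range[0] > self.cds_len_range[1]:
            raise ValueError("bad cds_len_range")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TruthManifest:
    """Planted ground truth: one row per gene.

    Columns: gene_id, strand, cds_start, cds_end, tss, tep, l_5utr, l_3utr,
    baseline_mean, stalled, stem_len, utract_len, and
    rna_log2fc_<cond> / rpf_log2fc_<cond> per non-reference condition.
    """

    genes: pd.DataFrame
    conditions: tuple[str, ...]
    reference_condition: str
    stress_condition: str

    def write(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, config: "SimConfig") -> "TruthManifest":
        return cls(
            genes=pd.read_csv(path, sep="\t"),
            conditions=config.conditions,
            reference_condition=config.reference_condition,
            stress_condition=config.stress_condition,
        )


def _lognormal_length(rng: np.random.Generator, median: float, sigma: float, minimum: int) -> int:
    return max(minimum, int(round(rng.lognormal(mean=np.log(median), sigma=sigma))))


def _terminator(rng: np.random.Generator) -> tuple[str, int, int]:
    """A 40-nt transcript-sense terminator ending at the TEP.

    Layout: random pad, GC stem, loop, reverse-complement stem, U-tract (as
    T on the coding strand) whose last base is the TEP.
    """
    stem_len = int(rng.integers(8, 13))
    loop_len = int(rng.integers(4, 9))
    u_max = 40 - 2 * stem_len - loop_len
    u_len = int(rng.integers(6, min(8, u_max) + 1))
    pad_len = 40 - 2 * stem_len - loop_len - u_len
    pad = "".join(rng.choice(list("ACGT"), size=pad_len)) if pad_len else ""
    stem = "".join(rng.choice(list("GC"), size=stem_len))
    loop = "".join(rng.choice(list("ACGT"), size=loop_len))
    seq = pad + stem + loop + revcomp(stem) + "T" * u_len
    assert len(seq) == 40
    return seq, stem_len, u_len


def _cds_sequence(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


def simulate_genome(
    config: SimConfig,
) -> tuple[GenomeSequence, list[GeneModel], list[TSSRecord], TruthManifest]:
    """Place non-overlapping single-gene TUs on both strands of a toy contig.

    Each gene gets a planted TSS at ``start_codon - l_5utr`` and a planted
    TEP at ``stop_codon_end + l_3utr`` (strand-aware); the 40 nt of transcript
    sequence ending at the TEP form an intrinsic terminator.  ``l_3utr`` is
    floored at 40 so the terminator fits inside the 3'-UTR.
    """
    rng = config.rng(0)
    cds_lo, cds_hi = config.cds_len_range

    rows = []
    pieces: list[str] = []
    cursor = 0  # 0-based build position

    strands = rng.choice(["+", "-"], size=config.n_genes)
    for i in range(config.n_genes):
        gene_id = f"g{i + 1:04d}"
        strand = str(strands[i])
        l5 = _lognormal_length(rng, config.utr5_median, config.utr5_sigma, minimum=2)
        l3 = _lognormal_length(rng, config.utr3_median, config.utr3_sigma, minimum=40)
        cds_len = int(rng.integers(cds_lo // 3, cds_hi // 3 + 1)) * 3

        spacer_len = config.min_spacer + int(rng.integers(0, config.min_spacer + 1))
        spacer = "".join(rng.choice(list("ACGT"), size=spacer_len))

        utr5 = "".join(rng.choice(list("ACGT"), size=l5))
        cds = _cds_sequence(rng, cds_len)
        term, stem_len, u_len = _terminator(rng)
        utr3_pad = "".join(rng.choice(list("ACGT"), size=l3 - 40))
        tu_sense = utr5 + cds + utr3_pad + term  # transcript 5'->3'

        tu_len = len(tu_sense)
        tu_start = cursor + spacer_len + 1  # 1-based genomic
        tu_end = tu_start + tu_len - 1
        if strand == "+":
            genomic = tu_sense
            tss = tu_start
            tep = tu_end
            cds_start = tu_start + l5
            cds_end = cds_start + cds_len - 1
        else:
            genomic = revcomp(tu_sense)
            tss = tu_end
            tep = tu_start
            cds_end = tu_end - l5
            cds_start = cds_end - cds_len + 1

        pieces.append(spacer + genomic)
        cursor = tu_end

        rows.append(
            dict(
                gene_id=gene_id, strand=strand, cds_start=cds_start, cds_end=cds_end,
                tss=tss, tep=tep, l_5utr=l5, l_3utr=l3,
                stem_len=stem_len, utract_len=u_len,
            )
        )

    required = cursor + config.min_spacer
    if required > config.genome_length:
        raise ValueError(
            f"genes do not fit: need genome_length >= {required}, got {config.genome_length}"
        )
    tail = "".join(rng.choice(list("ACGT"), size=config.genome_length - cursor))
    sequence = "".join(pieces) + tail
    assert len(sequence) == config.genome_length

    # expression truth
    n = config.n_genes
    baseline = np.exp(
        rng.uniform(np.log(config.baseline_mean_range[0]), np.log(config.baseline_mean_range[1]), n)
    )
    n_deg = int(round(config.deg_fraction * n))
    deg_idx = rng.choice(n, size=n_deg, replace=False)
    truth = pd.DataFrame(rows)
    truth["baseline_mean"] = baseline
    truth["stalled"] = config.stall_factor > 1
    lo, hi = config.deg_log2fc_range
    for cond in config.conditions:
        if cond == config.reference_condition:
            continue
        lfc = np.zeros(n)
        lfc[deg_idx] = rng.uniform(lo, hi, n_deg) * rng.choice([-1.0, 1.0], n_deg)
        truth[f"rna_log2fc_{cond}"] = lfc
        truth[f"rpf_log2fc_{cond}"] = lfc  # co-regulated by default

    genome = GenomeSequence(contig_id="synthetic_chr", sequence=sequence)
    genes = [
        GeneModel(
            gene_id=r["gene_id"], contig_id="synthetic_chr", strand=r["strand"],
            cds_start=r["cds_start"], cds_end=r["cds_end"],
        )
        for r in rows
    ]
    tss_records = [
        TSSRecord(gene_id=r["gene_id"], position=r["tss"], strand=r["strand"]) for r in rows
    ]
    manifest = TruthManifest(
        genes=truth, conditions=config.conditions,
        reference_condition=config.reference_condition,
        stress_condition=config.stress_condition,
    )
    return genome, genes, tss_records, manifest


def sample_ids(config: SimConfig) -> list[str]:
    return [
        f"{cond}_{rep}" for cond in config.conditions for rep in range(1, config.n_replicates + 1)
    ]


def design_map(config: SimConfig) -> dict[str, str]:
    return {s: s.rsplit("_", 1)[0] for s in sample_ids(config)}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson negative binomial with Var = m + dispersion * m^2."""
    if dispersion < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    truth: TruthManifest, config: SimConfig
) -> tuple[CountMatrix, CountMatrix]:
    """Negative-binomial RNA and RPF count matrices with planted effects.

    mean = baseline x 2^(planted log2FC) x library size factor; size factors
    are drawn log-uniform over ``size_factor_range`` per sample and assay.
    """
    rng = config.rng(1)
    samples = sample_ids(config)
    genes = truth.genes
    matrices = {}
    for assay in ("rna", "rpf"):
        counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
        lo, hi = config.size_factor_range
        sfs = np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples)))
        for j, sample in enumerate(samples):
            cond = sample.rsplit("_", 1)[0]
            lfc = (
                np.zeros(len(genes))
                if cond == config.reference_condition
                else genes[f"{assay}_log2fc_{cond}"].to_numpy()
            )
            mean = genes["baseline_mean"].to_numpy() * np.power(2.0, lfc) * sfs[j]
            counts[:, j] = _nb_draw(rng, mean, config.nb_dispersion)
        matrices[assay] = CountMatrix(
            gene_ids=list(genes["gene_id"]), sample_ids=list(samples), counts=counts
        )
    return matrices["rna"], matrices["rpf"]


def _stall_positions(row, config: SimConfig) -> list[int]:
    """Genomic positions of the extremity windows, codon-relative no-zero coords."""
    strand = row.strand
    s = row.cds_start if strand == "+" else row.cds_end
    e = row.cds_end if strand == "+" else row.cds_start
    out = []
    a1, b1 = config.stall_start_window
    for c in range(a1, b1 + 1):
        if c != 0:
            out.append(shift_downstream(s, c - 1 if c > 0 else c, strand))
    a2, b2 = config.stall_stop_window
    for c in range(a2, b2 + 1):
        if c != 0:
            out.append(shift_downstream(e, c if c > 0 else c + 1, strand))
    return out


def simulate_tracks(
    truth: TruthManifest,
    config: SimConfig,
    rna_counts: CountMatrix | None = None,
    rpf_counts: CountMatrix | None = None,
) -> TrackSet:
    """Per-base coverage tracks for every assay x condition x replicate x strand.

    RNA: piecewise-constant over each TU, total depth proportional to the
    gene's RNA count.  RPF: uniform over the CDS extended by the extremity
    margins, multiplied by ``stall_factor`` inside the extremity windows for
    the stress condition.  TERM: per terminator, Poisson-many 3'-end reads at
    the planted TEP with probability ``term_peak_prob``, otherwise offset
    upstream by a Geometric(0.5) tail.  Gaussian depth noise (sigma =
    ``noise_sigma_frac`` x local mean) is added to RNA/RPF and clipped at 0;
    TERM tracks stay integer counts.
    """
    if rna_counts is None or rpf_counts is None:
        rna_counts, rpf_counts = simulate_counts(truth, config)
    rng = config.rng(2)
    genes = truth.genes
    L = config.genome_length
    tracks = TrackSet()
    samples = sample_ids(config)
    sample_col = {s: j for j, s in enumerate(samples)}

    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            j = sample_col[f"{cond}_{rep}"]
            depth = {"+": np.zeros(L), "-": np.zeros(L)}
            rpf_depth = {"+": np.zeros(L), "-": np.zeros(L)}
            for i, row in enumerate(genes.itertuples(index=False)):
                strand = row.strand
                tu_lo = min(row.tss, row.tep)
                tu_hi = max(row.tss, row.tep)
                l_tu = tu_hi - tu_lo + 1
                rna_c = rna_counts.counts[i, j]
                depth[strand][tu_lo - 1 : tu_hi] += rna_c * config.depth_scale / l_tu

                # RPF support: CDS extended by the extremity margins
                a1 = config.stall_start_window[0]
                b2 = config.stall_stop_window[1]
                s_pos = row.cds_start if strand == "+" else row.cds_end
                e_pos = row.cds_end if strand == "+" else row.cds_start
                up = shift_downstream(s_pos, a1, strand)
                down = shift_downstream(e_pos, b2, strand)
                lo, hi = min(up, down), max(up, down)
                lo, hi = max(1, lo), min(L, hi)
                n_support = hi - lo + 1
                rpf_c = rpf_counts.counts[i, j]
                base = rpf_c * config.depth_scale / n_support
                rpf_depth[strand][lo - 1 : hi] += base
                if cond == config.stress_condition and config.stall_factor > 1 and row.stalled:
                    extra = (config.stall_factor - 1) * base
                    for pos in _stall_positions(row, config):
                        if 1 <= pos <= L:
                            rpf_depth[strand][pos - 1] += extra

            for strand in ("+", "-"):
                for assay, d in (("RNA", depth[strand]), ("RPF", rpf_depth[strand])):
                    if config.noise_sigma_frac > 0:
                        noise = rng.normal(0.0, config.noise_sigma_frac, L) * d
                        d = np.clip(d + noise, 0.0, None)
                    tracks.add(
                        CoverageTrack(
                            assay=assay, condition=cond, replicate=rep,
                            strand=strand, depth=d,
                        )
                    )

    # TERM tracks: one per replicate, shared across conditions
    for rep in range(1, config.n_replicates + 1):
        counts = {"+": np.zeros(L), "-": np.zeros(L)}
        for row in genes.itertuples(index=False):
            n_reads = rng.poisson(config.term_depth_mean)
            if n_reads == 0:
                continue
            at_peak = rng.random(n_reads) < config.term_peak_prob
            n_tail = int(n_reads - at_peak.sum())
            counts[row.strand][row.tep - 1] += int(at_peak.sum())
            if n_tail:
                offsets = rng.geometric(0.5, n_tail)
                for off in offsets:
                    pos = shift_downstream(row.tep, -int(off), row.strand)
                    if 1 <= pos <= L:
                        counts[row.strand][pos - 1] += 1
        for strand in ("+", "-"):
            tracks.add(
                CoverageTrack(
                    assay="TERM", condition="pooled", replicate=rep,
                    strand=strand, depth=counts[strand],
                )
            )
    return tracks


def write_simulation(
    outdir: str | Path,
    config: SimConfig,
    genome: GenomeSequence,
    genes: list[GeneModel],
    tss: list[TSSRecord],
    truth: TruthManifest,
    rna_counts: CountMatrix,
    rpf_counts: CountMatrix,
    tracks: TrackSet,
) -> None:
    """Write all simulator outputs through the standard formats."""
    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_genome_fasta(genome, outdir / "genome.fasta")
    tio.write_annotation_gff(genes, outdir / "annotation.gff3")
    tio.write_table(tss, outdir / "tss.tsv")
    truth.write(outdir / "truth.tsv")
    tio.write_count_matrix(rna_counts, outdir / "counts_rna.tsv")
    tio.write_count_matrix(rpf_counts, outdir / "counts_rpf.tsv")
    tio.write_design(design_map(config), outdir / "design.tsv")
    trackdir = outdir / "tracks"
    trackdir.mkdir(exist_ok=True)
    for t in tracks:
        tag = "plus" if t.strand == "+" else "minus"
        name = f"{t.assay}_{t.condition}_rep{t.replicate}_{tag}.bedgraph"
        tio.write_coverage_bedgraph(t, genome.contig_id, trackdir / name)
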