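"""End-to-end orchestration: simulate (or load) -> normalize -> DEG/TE ->
metagene partition -> TEP calling -> TU assembly -> UED -> clustering.

Every output TSV carries a metadata header (config hash, seed, version) and
reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, expression, io as tio, metagene, termseq, tu_ued
from .models import ExtremityPartition, TEPRecord, TrackSet, TSSRecord
from .simulate import SimConfig, design_map, sample_ids, simulate_counts, simulate_genome, simulate_tracks, write_simulation

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the field's printed constants as defaults."""

    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    expression_floor: float = 10.0
    pseudocount: float = 1.0
    min_count: int = 5
    match_tolerance: int = 0
    downstream_window: int = 250
    upstream_window: int = 150
    metagene_w: int = 200
    boundary: str = "auto"  # auto | default
    default_start_window: tuple[int, int] = (-30, 60)
    default_stop_window: tuple[int, int] = (-33, 15)
    flank: int = 50
    upstream_seq_len: int = 40
    n_background: int = 10000
    k_extremity: int = 7
    k_ued: int = 9
    fold_adapter: str = "gc_stub"  # gc_stub | rnafold | none

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        for name in (
            "expression_floor", "min_count", "downstream_window", "upstream_window",
            "metagene_w", "flank", "upstream_seq_len", "n_background",
            "k_extremity", "k_ued", "fc_threshold", "p_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # the seed propagates into the simulator
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if seed is not None:
            raw["seed"] = seed
        if "sim" in raw and isinstance(raw["sim"], dict):
            for key in ("cds_len_range", "conditions", "deg_log2fc_range",
                        "baseline_mean_range", "size_factor_range",
                        "stall_start_window", "stall_stop_window"):
                if key in raw["sim"] and isinstance(raw["sim"][key], list):
                    raw["sim"][key] = tuple(raw["sim"][key])
        for key in ("default_start_window", "default_stop_window"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_tracks_dir(trackdir: str | Path, genome_length: int) -> TrackSet:
    """Load every ``<assay>_<condition>_rep<k>_<plus|minus>.bedgraph`` file."""
    trackdir = Path(trackdir)
    tracks = TrackSet()
    for path in sorted(trackdir.glob("*.bedgraph")):
        stem = path.stem
        parts = stem.rsplit("_", 2)
        if len(parts) != 3 or not parts[1].startswith("rep"):
            raise tio.FormatError(f"unrecognized track filename {path.name}")
        assay_cond, rep_tag, strand_tag = parts
        assay, condition = assay_cond.split("_", 1)
        strand = "+" if strand_tag == "plus" else "-"
        tracks.add(
            tio.read_coverage_bedgraph(
                path, strand=strand, assay=assay, condition=condition,
                replicate=int(rep_tag[3:]), genome_length=genome_length,
            )
        )
    return tracks


def _load_inputs(config: PipelineConfig):
    from .simulate import TruthManifest

    if config.simulate:
        genome, genes, tss, truth = simulate_genome(config.sim)
        rna_cm, rpf_cm = simulate_counts(truth, config.sim)
        tracks = simulate_tracks(truth, config.sim, rna_cm, rpf_cm)
        design = design_map(config.sim)
        return genome, genes, tss, truth, rna_cm, rpf_cm, tracks, design
    if config.input_dir is None:
        raise ValueError("simulate=false requires input_dir")
    d = Path(config.input_dir)
    for name in ("genome.fasta", "annotation.gff3", "tss.tsv", "counts_rna.tsv",
                 "counts_rpf.tsv", "design.tsv", "tracks"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing input: {d / name}")
    genome = tio.read_genome_fasta(d / "genome.fasta")
    genes = tio.read_annotation_gff(d / "annotation.gff3")
    tss = tio.read_table(d / "tss.tsv", TSSRecord)
    rna_cm = tio.read_count_matrix(d / "counts_rna.tsv")
    rpf_cm = tio.read_count_matrix(d / "counts_rpf.tsv")
    design = tio.read_design(d / "design.tsv")
    tracks = read_tracks_dir(d / "tracks", genome.length)
    truth = None
    if (d / "truth.tsv").exists():
        truth = TruthManifest.read(d / "truth.tsv", config.sim)
    return genome, genes, tss, truth, rna_cm, rpf_cm, tracks, design


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; returns the in-memory results.

    Writes TSV outputs (with a metadata header) plus a JSON run summary under
    ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed, "version": __version__}

    genome, genes, tss, truth, rna_cm, rpf_cm, tracks, design = _load_inputs(config)
    conditions = sorted(set(design.values()))
    ref = config.sim.reference_condition
    stress = config.sim.stress_condition
    log.info("inputs: %d genes, %d tracks, %d samples", len(genes), len(tracks), len(design))

    if config.simulate:
        write_simulation(outdir / "inputs", config.sim, genome, genes, tss, truth,
                         rna_cm, rpf_cm, tracks)

    # --- expression -------------------------------------------------------
    rna_sf = expression.size_factors(rna_cm)
    rpf_sf = expression.size_factors(rpf_cm)
    rna_norm = expression.normalize(rna_cm, rna_sf)
    rpf_norm = expression.normalize(rpf_cm, rpf_sf)
    expressed = expression.expressed_genes(rna_norm, design, floor=config.expression_floor)
    degs = {}
    for cond in conditions:
        if cond == ref:
            continue
        degs[cond] = expression.call_degs(
            rna_norm, design, condition=cond, reference=ref,
            fc_threshold=config.fc_threshold, p_threshold=config.p_threshold,
            pseudocount=config.pseudocount,
        )
        tio.write_table(degs[cond], outdir / f"deg_{cond}_vs_{ref}.tsv", metadata=meta)
    te = expression.translation_efficiency(
        rna_norm, rpf_norm, design, pseudocount=config.pseudocount,
        floor=config.expression_floor,
    )
    tio.write_table(te, outdir / "translation_efficiency.tsv", metadata=meta)
    log.info("expression: %d expressed genes, %s DEGs",
             len(expressed), {c: sum(r.is_deg for r in v) for c, v in degs.items()})

    # --- metagene ---------------------------------------------------------
    profiles = {
        cond: {
            anchor: metagene.profile_from_trackset(
                tracks, genes, cond, anchor, W=config.metagene_w
            )
            for anchor in metagene.ANCHORS
        }
        for cond in conditions
    }
    prof_rows = []
    for cond, by_anchor in profiles.items():
        for anchor, prof in by_anchor.items():
            for off, depth in zip(prof.offsets, prof.mean_depth):
                prof_rows.append((anchor, cond, int(off), float(depth)))
    pd.DataFrame(prof_rows, columns=["anchor", "condition", "offset", "mean_depth"]).to_csv(
        outdir / "metagene_profiles.tsv", sep="\t", index=False
    )

    if config.boundary == "default":
        partition = ExtremityPartition(config.default_start_window, config.default_stop_window)
    else:
        partition = metagene.determine_boundary(
            profiles[stress], [profiles[c] for c in conditions if c != stress]
        )
    log.info("partition: start %s stop %s", partition.start_window, partition.stop_window)
    with open(outdir / "partition.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "start_window": list(partition.start_window),
                "stop_window": list(partition.stop_window),
                "linkage": "ward", "metric": "euclidean", **meta,
            },
            fh, sort_keys=True,
        )

    sf_by_sample = {s: f for s, f in zip(rpf_cm.sample_ids, rpf_sf)}
    region_fc = metagene.region_fold_changes(
        tracks, genes, partition, sf_by_sample, reference_condition=ref,
        pseudocount=config.pseudocount,
    )
    region_fc.to_csv(outdir / "region_fold_changes.tsv", sep="\t", index=False)
    ext = region_fc[(region_fc.region == "extremity") & ~region_fc.excluded]
    ext_matrix = ext.pivot(index="gene_id", columns="condition", values="log2fc").dropna()
    k_ext = min(config.k_extremity, len(ext_matrix))
    ext_clusters = metagene.cluster_rows(ext_matrix, k=k_ext, seed=config.seed)
    ext_clusters.to_frame().to_csv(outdir / "extremity_clusters.tsv", sep="\t")

    # --- termseq ----------------------------------------------------------
    term_reps = [
        {s: tracks.get("TERM", cond, rep, s) for s in ("+", "-")}
        for cond in tracks.conditions("TERM")
        for rep in tracks.replicates("TERM", cond)
    ]
    candidates = termseq.detect_teps(
        term_reps, min_count=config.min_count, match_tolerance=config.match_tolerance
    )
    teps = termseq.classify_teps(
        candidates, genes, downstream_window=config.downstream_window,
        upstream_window=config.upstream_window,
    )
    if teps:
        tio.write_table(teps, outdir / "teps.tsv", metadata=meta)
    else:
        tio.write_empty_table(TEPRecord, outdir / "teps.tsv", metadata=meta)
    log.info("termseq: %d candidates -> %d classified TEPs (%d P)",
             len(candidates), len(teps), sum(1 for t in teps if t.category == "P"))

    composition = termseq.nucleotide_composition(teps, genome, flank=config.flank)
    comp_df = pd.DataFrame(
        composition, columns=list(termseq.BASES),
        index=pd.Index(range(-config.flank, config.flank + 1), name="offset"),
    )
    comp_df.to_csv(outdir / "tep_composition.tsv", sep="\t")

    p_teps = [t for t in teps if t.category == "P"]
    upstream = termseq.upstream_sequences(p_teps, genome, length=config.upstream_seq_len)
    termseq.write_fasta_sequences(upstream, outdir / "tep_upstream.fasta")
    background = termseq.sample_intergenic(
        genome, genes, n=config.n_background, length=config.upstream_seq_len,
        seed=config.seed,
    )
    mfe = None
    if config.fold_adapter != "none":
        fold = termseq.gc_stub_fold if config.fold_adapter == "gc_stub" else termseq.rnafold_fold
        full = [s for _, s in upstream if len(s) == config.upstream_seq_len]
        mfe = termseq.mfe_background_test(full, background, fold)
        log.info("terminator dG: median %.2f vs background %.2f (p=%.3g)", *mfe[:2], mfe[3])

    # --- TU + UED ---------------------------------------------------------
    tus = tu_ued.build_tus(tss, teps, genes)
    tio.write_table(tus, outdir / "transcription_units.tsv", metadata=meta)
    utr5_summary = tu_ued.utr_length_summary(tus, "utr5")
    utr3_summary = tu_ued.utr_length_summary(tus, "utr3")
    ued_records = tu_ued.ued_table(tracks, tus, conditions=conditions)
    tio.write_table(ued_records, outdir / "ued.tsv", metadata=meta)
    rpf5 = (
        tu_ued.ued_frame(ued_records)
        .query("assay == 'RPF'")
        .pivot(index="gene_id", columns="condition", values="ued5")
    )
    n_defined = int((~(rpf5.isna().any(axis=1) | (rpf5 <= 0).any(axis=1))).sum())
    ued_clusters, ued_features, excluded = tu_ued.ued_compare_and_cluster(
        ued_records, ref_condition=ref, assay="RPF", region="ued5",
        k=min(config.k_ued, max(1, n_defined)), seed=config.seed,
    )
    ued_clusters.to_frame().to_csv(outdir / "ued_clusters.tsv", sep="\t")
    shift = {}
    for assay in ("RNA", "RPF"):
        for region in ("ued5", "ued3"):
            try:
                p, n = tu_ued.ued_condition_shift_test(ued_records, stress, ref, assay, region)
            except ValueError:
                p, n = float("nan"), 0
            shift[f"{assay}_{region}"] = {"p": p, "n": n}
    log.info("TU/UED: %d TUs, 5'UTR median %d, 3'UTR median %d",
             len(tus), utr5_summary[0], utr3_summary[0])

    summary = {
        **meta,
        "n_genes": len(genes),
        "n_expressed": len(expressed),
        "n_degs": {c: sum(r.is_deg for r in v) for c, v in degs.items()},
        "n_tep_candidates": len(candidates),
        "n_teps": len(teps),
        "tep_categories": {c: sum(1 for t in teps if t.category == c) for c in "PSIAU"},
        "partition": {"start_window": list(partition.start_window),
                      "stop_window": list(partition.stop_window)},
        "n_tus": len(tus),
        "utr5_summary": dict(zip(("median", "min", "max", "n"), utr5_summary)),
        "utr3_summary": dict(zip(("median", "min", "max", "n"), utr3_summary)),
        "ued_shift_tests": shift,
        "mfe_test": None if mfe is None else dict(
            zip(("median_tep", "median_bg", "statistic", "p"), mfe)
        ),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    return {
        "genome": genome, "genes": genes, "tss": tss, "truth": truth,
        "rna_counts": rna_cm, "rpf_counts": rpf_cm, "tracks": tracks,
        "design": design, "rna_norm": rna_norm, "rpf_norm": rpf_norm,
        "rna_size_factors": rna_sf, "rpf_size_factors": rpf_sf,
        "degs": degs, "te": te, "profiles": profiles, "partition": partition,
        "region_fc": region_fc, "extremity_clusters": ext_clusters,
        "tep_candidates": candidates, "teps": teps, "tus": tus,
        "ued_records": ued_records, "ued_clusters": ued_clusters,
        "summary": summary,
    }
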