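"""Transcription-unit assembly and the UTR enrichment degree (UED).

A transcription unit spans a gene's TSS (t) through its primary TEP (p) and
decomposes into 5'-UTR, CDS, and 3'-UTR.  The UED is the mean depth over a
UTR divided by the mean depth over the whole TU:

    R_5utr = (sum_{i=t..s-1} d_i / l_5utr) / (sum_{i=t..p} d_i / l_tu)
    R_3utr = (sum_{i=e+1..p} d_i / l_3utr) / (sum_{i=t..p} d_i / l_tu)

where s is the first base of the start codon and e the last base of the stop
codon (strand-aware).  R > 1 means depth (e.g. ribosome occupancy) is
enriched in the UTR relative to the TU.  R_5utr is undefined for leaderless
genes (l_5utr = 0) and both are undefined on a zero-depth TU.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import metagene
from .models import (
    CoverageTrack,
    GeneModel,
    TEPRecord,
    TrackSet,
    TranscriptionUnit,
    TSSRecord,
    UEDRecord,
    strand_distance,
)

log = logging.getLogger(__name__)


def build_tus(
    tss: Sequence[TSSRecord],
    teps: Sequence[TEPRecord],
    genes: Sequence[GeneModel],
) -> list[TranscriptionUnit]:
    """One TU per gene that has both a TSS and a primary TEP.

    With multiple TSSs per gene the one nearest the start codon (with
    l_5utr >= 0) is used; a TSS strictly inside the CDS is ignored with a
    warning.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    tss_by_gene: dict[str, list[TSSRecord]] = {}
    for t in tss:
        gene = gene_by_id.get(t.gene_id)
        if gene is None:
            warnings.warn(f"TSS for unknown gene {t.gene_id}; ignored", stacklevel=2)
            continue
        if t.strand != gene.strand:
            raise ValueError(f"TSS strand {t.strand} != gene {t.gene_id} strand {gene.strand}")
        l5 = strand_distance(t.position, gene.start_codon_pos, gene.strand)
        if l5 < 0:
            warnings.warn(
                f"TSS at {t.position} inside CDS of {t.gene_id}; ignored", stacklevel=2
            )
            continue
        tss_by_gene.setdefault(t.gene_id, []).append(t)
    tep_by_gene = {r.gene_id: r for r in teps if r.category == "P"}
    tus = []
    for gene_id, candidates in tss_by_gene.items():
        if gene_id not in tep_by_gene:
            continue
        gene = gene_by_id[gene_id]
        best = min(
            candidates,
            key=lambda t: strand_distance(t.position, gene.start_codon_pos, gene.strand),
        )
        tus.append(
            TranscriptionUnit.from_parts(gene, best.position, tep_by_gene[gene_id].position)
        )
    tus.sort(key=lambda tu: tu.gene_id)
    return tus


def utr_length_summary(
    tus: Sequence[TranscriptionUnit],
    which: str = "utr5",
    gene_subset: Sequence[str] | None = None,
) -> tuple[int, int, int, int]:
    """(median, min, max, n) of UTR lengths; median = lower middle for even n."""
    if which not in ("utr5", "utr3"):
        raise ValueError("which must be utr5 or utr3")
    if gene_subset is not None:
        subset = set(gene_subset)
        tus = [tu for tu in tus if tu.gene_id in subset]
    if not tus:
        raise ValueError("no TUs in the requested subset")
    lengths = sorted(tu.l_5utr if which == "utr5" else tu.l_3utr for tu in tus)
    n = len(lengths)
    return lengths[(n - 1) // 2], lengths[0], lengths[-1], n


def ued(track: CoverageTrack, tu: TranscriptionUnit, region: str) -> float | None:
    """UTR enrichment degree for one track and TU; None when undefined."""
    if region not in ("utr5", "utr3"):
        raise ValueError("region must be utr5 or utr3")
    if track.strand != tu.strand:
        raise ValueError(f"{tu.gene_id}: track strand does not match TU strand")
    tu_depth = track.depth[tu.tu_positions() - 1]
    tu_mean = tu_depth.mean()
    if tu_mean <= 0:
        return None
    if region == "utr5":
        if tu.l_5utr < 1:
            return None
        region_mean = tu_depth[: tu.l_5utr].mean()
    else:
        region_mean = tu_depth[tu.l_5utr + tu.cds_length :].mean()
    return float(region_mean / tu_mean)


def ued_table(
    tracks: TrackSet,
    tus: Sequence[TranscriptionUnit],
    assays: Sequence[str] = ("RNA", "RPF"),
    conditions: Sequence[str] | None = None,
) -> list[UEDRecord]:
    """One UEDRecord per TU x assay x condition, replicates averaged
    position-wise before the ratio; undefined entries carry None."""
    records = []
    for assay in assays:
        conds = list(conditions) if conditions is not None else tracks.conditions(assay)
        for cond in conds:
            if cond not in tracks.conditions(assay):
                raise ValueError(f"no {assay} tracks for condition {cond!r}")
            pair = tracks.by_strand(assay, cond, replicate=None)
            for tu in tus:
                track = pair[tu.strand]
                records.append(
                    UEDRecord(
                        gene_id=tu.gene_id, assay=assay, condition=cond,
                        ued5=ued(track, tu, "utr5"), ued3=ued(track, tu, "utr3"),
                    )
                )
    return records


def ued_frame(records: Sequence[UEDRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(gene_id=r.gene_id, assay=r.assay, condition=r.condition, ued5=r.ued5, ued3=r.ued3)
            for r in records
        ]
    )


def ued_compare_and_cluster(
    records: Sequence[UEDRecord],
    ref_condition: str,
    assay: str = "RPF",
    region: str = "ued5",
    k: int = 9,
    seed: int | None = None,
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Cluster genes by their UED change across conditions.

    Features are log2(UED_condition / UED_ref) per non-reference condition;
    genes with any undefined UED for the chosen assay/region are excluded and
    listed.  Returns (labels, feature matrix, excluded gene ids).
    """
    if region not in ("ued5", "ued3"):
        raise ValueError("region must be ued5 or ued3")
    df = ued_frame(records)
    df = df[df["assay"] == assay]
    wide = df.pivot(index="gene_id", columns="condition", values=region)
    if ref_condition not in wide.columns:
        raise ValueError(f"no UED records for reference condition {ref_condition!r}")
    excluded = list(wide.index[wide.isna().any(axis=1) | (wide <= 0).any(axis=1)])
    wide = wide.drop(index=excluded)
    if excluded:
        log.info("excluded %d genes with undefined UED", len(excluded))
    features = pd.DataFrame(index=wide.index)
    for cond in wide.columns:
        if cond == ref_condition:
            continue
        features[f"log2_{cond}_vs_{ref_condition}"] = np.log2(
            wide[cond] / wide[ref_condition]
        )
    labels = metagene.cluster_rows(features, k=k, seed=seed)
    return labels, features, excluded


def ued_condition_shift_test(
    records: Sequence[UEDRecord],
    condition: str,
    ref_condition: str,
    assay: str,
    region: str = "ued5",
) -> tuple[float, int]:
    """Paired one-sided Wilcoxon signed-rank test that UED increased in
    ``condition`` vs ``ref_condition``; returns (p, n genes paired)."""
    df = ued_frame(records)
    df = df[df["assay"] == assay]
    wide = df.pivot(index="gene_id", columns="condition", values=region)
    paired = wide[[condition, ref_condition]].dropna()
    diffs = paired[condition] - paired[ref_condition]
    diffs = diffs[diffs != 0]
    if len(diffs) < 5:
        raise ValueError("too few paired genes for a signed-rank test")
    stat, p = stats.wilcoxon(diffs, alternative="greater")
    return float(p), int(len(paired))
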