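"""Metagene ribosome-occupancy profiles, the extremity/torso boundary rule,
per-gene region fold changes, and hierarchical clustering.

A metagene profile averages depth over genes at fixed offsets from a shared
anchor.  Offsets run ``-W..+W`` with offset 0 on the anchor base (first base
of the start codon; last base of the stop codon).  The extremity/torso
boundary is the last offset, scanning from the anchor, at which the stress
profile still exceeds the reference (the offset-wise mean of the non-stress
profiles); an offset where stress has decreased to (or below) the reference
belongs to the torso.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .models import (
    CoverageTrack,
    ExtremityPartition,
    GeneModel,
    MetageneProfile,
    TrackSet,
    shift_downstream,
)

ANCHORS = ("start_codon", "stop_codon")


def _anchor_pos(gene: GeneModel, anchor: str) -> int:
    return gene.start_codon_pos if anchor == "start_codon" else gene.stop_codon_end_pos


def metagene_profile(
    tracks_by_strand: dict[str, CoverageTrack],
    genes: list[GeneModel],
    anchor: str,
    W: int = 200,
    per_gene_norm: bool = True,
    condition: str = "",
) -> MetageneProfile:
    """Mean depth at offsets -W..+W from the anchor, averaged over genes.

    With ``per_gene_norm`` each gene's depths are divided by its mean CDS
    depth before averaging (genes with zero CDS depth are skipped); offsets
    that fall off the contig are dropped for that gene only.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}")
    if not genes:
        raise ValueError("empty gene list")
    offsets = np.arange(-W, W + 1)
    total = np.zeros(offsets.size)
    count = np.zeros(offsets.size)
    for gene in genes:
        track = tracks_by_strand[gene.strand]
        L = track.genome_length
        a = _anchor_pos(gene, anchor)
        scale = 1.0
        if per_gene_norm:
            cds_pos = np.arange(gene.cds_start, gene.cds_end + 1) - 1
            mean_cds = float(track.depth[cds_pos].mean())
            if mean_cds <= 0:
                continue
            scale = 1.0 / mean_cds
        step = 1 if gene.strand == "+" else -1
        positions = a + step * offsets
        valid = (positions >= 1) & (positions <= L)
        total[valid] += track.depth[positions[valid] - 1] * scale
        count[valid] += 1
    mean_depth = np.divide(total, count, out=np.zeros_like(total), where=count > 0)
    if not condition:
        condition = next(iter(tracks_by_strand.values())).condition
    return MetageneProfile(anchor=anchor, offsets=offsets, mean_depth=mean_depth, condition=condition)


def profile_from_trackset(
    tracks: TrackSet,
    genes: list[GeneModel],
    condition: str,
    anchor: str,
    assay: str = "RPF",
    W: int = 200,
    per_gene_norm: bool = True,
) -> MetageneProfile:
    """Replicate-averaged metagene profile for one condition."""
    pair = tracks.by_strand(assay, condition, replicate=None)
    return metagene_profile(pair, genes, anchor, W=W, per_gene_norm=per_gene_norm, condition=condition)


def smooth_profile(profile: MetageneProfile, width: int) -> MetageneProfile:
    """Centered moving average; width must be odd."""
    if width <= 1:
        return profile
    if width % 2 == 0:
        raise ValueError("smoothing width must be odd")
    kernel = np.ones(width) / width
    padded = np.pad(profile.mean_depth, width // 2, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return MetageneProfile(
        anchor=profile.anchor, offsets=profile.offsets, mean_depth=smoothed,
        condition=profile.condition,
    )


class BoundaryError(ValueError):
    """The stress profile never crosses the reference within the window."""


def _scan(stress: np.ndarray, ref: np.ndarray, offsets: np.ndarray, order: list[int]) -> int:
    """Profile offset of the last position before stress first drops to <= ref."""
    idx = {int(o): i for i, o in enumerate(offsets)}
    prev = None
    for k in order:
        if stress[idx[k]] <= ref[idx[k]]:
            if prev is None:
                raise BoundaryError(
                    f"stress profile at or below reference already at offset {k}; "
                    "window must straddle the codon (set windows manually)"
                )
            return prev
        prev = k
    raise BoundaryError(
        "stress profile never decreased to the reference within +/-W; set windows manually"
    )


def determine_boundary(
    stress_profiles: dict[str, MetageneProfile],
    ctrl_profile_lists: list[dict[str, MetageneProfile]],
) -> ExtremityPartition:
    """Locate the extremity/torso boundaries from metagene profiles.

    ``stress_profiles`` maps anchor -> stress-condition profile;
    ``ctrl_profile_lists`` is a list of the same mapping for each reference
    condition.  The reference is their offset-wise mean.  Returns the two
    windows in codon-relative (no-zero) coordinates.
    """
    for key in ANCHORS:
        if key not in stress_profiles:
            raise ValueError(f"missing stress profile for anchor {key!r}")
    windows: dict[str, tuple[int, int]] = {}
    for anchor in ANCHORS:
        sp = stress_profiles[anchor]
        refs = []
        for ctrl in ctrl_profile_lists:
            cp = ctrl[anchor]
            if not np.array_equal(cp.offsets, sp.offsets):
                raise ValueError("profiles do not share an offset axis")
            refs.append(cp.mean_depth)
        ref = np.mean(refs, axis=0)
        offs = sp.offsets
        W = int(offs[-1])
        if anchor == "start_codon":
            # into the CDS: increasing offsets from the anchor base
            b_in = _scan(sp.mean_depth, ref, offs, list(range(0, W + 1)))
            # away from the CDS: decreasing offsets
            b_out = _scan(sp.mean_depth, ref, offs, list(range(-1, -W - 1, -1)))
            windows[anchor] = (b_out, b_in + 1)  # profile -> codon-relative
        else:
            b_in = _scan(sp.mean_depth, ref, offs, list(range(0, -W - 1, -1)))
            b_out = _scan(sp.mean_depth, ref, offs, list(range(1, W + 1)))
            windows[anchor] = (b_in - 1, b_out)
    return ExtremityPartition(
        start_window=windows["start_codon"], stop_window=windows["stop_codon"]
    )


def region_fold_changes(
    rpf_tracks: TrackSet,
    genes: list[GeneModel],
    partition: ExtremityPartition,
    size_factors_per_sample: dict[str, float],
    reference_condition: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2 change of extremity and torso RPF per gene, stress vs reference.

    Region sums are size-factor normalized per sample, averaged over
    replicates within each condition.  Genes whose torso is empty are flagged
    ``excluded`` rather than dropped.
    Returns a long DataFrame: gene_id, condition, region, log2fc, excluded.
    """
    conditions = rpf_tracks.conditions("RPF")
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} has no RPF tracks")

    def region_mean(gene: GeneModel, condition: str, positions: list[int]) -> float:
        reps = rpf_tracks.replicates("RPF", condition)
        vals = []
        for rep in reps:
            track = rpf_tracks.get("RPF", condition, rep, gene.strand)
            sf = size_factors_per_sample[f"{condition}_{rep}"]
            vals.append(track.region_sum(positions) / sf)
        return float(np.mean(vals))

    rows = []
    for gene in genes:
        ext_pos = partition.start_extremity_positions(gene) + partition.stop_extremity_positions(gene)
        torso_pos = partition.torso_positions(gene)
        excluded = len(torso_pos) == 0
        for cond in conditions:
            if cond == reference_condition:
                continue
            for region, positions in (("extremity", ext_pos), ("torso", torso_pos)):
                if region == "torso" and excluded:
                    rows.append((gene.gene_id, cond, region, np.nan, True))
                    continue
                num = region_mean(gene, cond, positions) + pseudocount
                den = region_mean(gene, reference_condition, positions) + pseudocount
                rows.append((gene.gene_id, cond, region, float(np.log2(num / den)), excluded))
    return pd.DataFrame(rows, columns=["gene_id", "condition", "region", "log2fc", "excluded"])


def cluster_rows(
    matrix: pd.DataFrame,
    k: int,
    linkage: str = "ward",
    metric: str = "euclidean",
    seed: int | None = None,
) -> pd.Series:
    """Deterministic agglomerative clustering of rows into k groups.

    Labels are 1..k, relabeled so cluster 1 has the largest mean of the first
    feature.  ``seed`` is accepted for interface symmetry; the algorithm is
    deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of rows ({len(matrix)})")
    bad = matrix.index[matrix.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"rows with missing values: {list(bad)}")
    if k == 1 or len(matrix) == 1:
        return pd.Series(1, index=matrix.index, name="cluster")
    Z = scipy_linkage(matrix.to_numpy(dtype=float), method=linkage, metric=metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=matrix.index, name="cluster")
    # stable relabeling: decreasing cluster mean of the first feature
    first = matrix.iloc[:, 0]
    order = (
        first.groupby(labels).mean().sort_values(ascending=False, kind="stable").index
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    return labels.map(remap).rename("cluster")
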