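"""Count normalization, differential expression, translation efficiency, and
hypergeometric functional enrichment.

Normalization is the median-of-ratios estimator: each sample's size factor is
the median, over genes with a positive geometric-mean count, of that sample's
count divided by the gene's across-sample geometric mean.  Differential calls
apply the conjunction |log2FC| > fc_threshold AND p < p_threshold; the test
is pluggable (default: two-sided Welch t on log2(normalized + 1)).
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import (
    CountMatrix,
    CoverageTrack,
    DEGResult,
    ExtremityPartition,
    GeneModel,
    TEResult,
)


def size_factors(counts: CountMatrix | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors, one per sample.

    Factors are rescaled to geometric mean 1 so that re-estimating factors on
    an already-normalized matrix returns all ones (the raw median-of-ratios
    estimator is only idempotent up to a common constant).
    """
    if isinstance(counts, CountMatrix):
        mat = counts.counts.astype(float)
    elif isinstance(counts, pd.DataFrame):
        mat = counts.to_numpy(dtype=float)
    else:
        mat = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    log_geomeans = logs.mean(axis=1)
    valid = np.isfinite(log_geomeans)
    if not valid.any():
        raise ValueError("no gene has a nonzero count in every sample")
    log_factors = np.median(logs[valid] - log_geomeans[valid, None], axis=0)
    return np.exp(log_factors - log_factors.mean())


def normalize(counts: CountMatrix, factors: np.ndarray) -> pd.DataFrame:
    """counts[g, j] / factors[j] as a genes x samples DataFrame."""
    factors = np.asarray(factors, dtype=float)
    if factors.ndim != 1 or factors.size != len(counts.sample_ids):
        raise ValueError(
            f"expected {len(counts.sample_ids)} size factors, got shape {factors.shape}"
        )
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    return pd.DataFrame(
        counts.counts / factors[None, :], index=counts.gene_ids, columns=counts.sample_ids
    )


def condition_means(normalized: pd.DataFrame, design: Mapping[str, str]) -> pd.DataFrame:
    """Mean normalized value per gene x condition (replicates averaged)."""
    conds = pd.Series({s: design[s] for s in normalized.columns})
    return normalized.T.groupby(conds).mean().T


def expressed_genes(
    normalized: pd.DataFrame, design: Mapping[str, str], floor: float = 10.0
) -> list[str]:
    """Genes whose mean normalized expression is >= floor in every condition."""
    means = condition_means(normalized, design)
    keep = (means >= floor).all(axis=1)
    if floor <= 0:
        keep = (means > 0).any(axis=1)
    return list(means.index[keep])


def welch_log_t(stress: np.ndarray, ctrl: np.ndarray) -> float:
    """Two-sided Welch t-test on log2(x + 1); the default differential test."""
    a = np.log2(np.asarray(stress, dtype=float) + 1.0)
    b = np.log2(np.asarray(ctrl, dtype=float) + 1.0)
    if np.allclose(a.var(ddof=1), 0) and np.allclose(b.var(ddof=1), 0):
        return 0.0 if not np.isclose(a.mean(), b.mean()) else 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return p if np.isfinite(p) else 1.0


def call_degs(
    normalized: pd.DataFrame,
    design: Mapping[str, str],
    condition: str,
    reference: str,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    pseudocount: float = 1.0,
    test: Callable[[np.ndarray, np.ndarray], float] = welch_log_t,
) -> list[DEGResult]:
    """Per-gene differential call of ``condition`` vs ``reference``.

    log2FC is computed from condition means of normalized counts with a
    pseudocount; a gene is a DEG iff |log2FC| > fc_threshold and
    p < p_threshold.
    """
    stress_samples = [s for s in normalized.columns if design[s] == condition]
    ctrl_samples = [s for s in normalized.columns if design[s] == reference]
    if not stress_samples or not ctrl_samples:
        raise ValueError(f"no samples for {condition!r} or {reference!r} in design")
    if (len(stress_samples) < 2 or len(ctrl_samples) < 2) and not getattr(
        test, "allows_single_replicate", False
    ):
        raise ValueError("need >= 2 replicates per condition for the differential test")
    out = []
    stress_mat = normalized[stress_samples].to_numpy()
    ctrl_mat = normalized[ctrl_samples].to_numpy()
    for gi, gene in enumerate(normalized.index):
        m_s = stress_mat[gi].mean()
        m_c = ctrl_mat[gi].mean()
        log2fc = float(np.log2((m_s + pseudocount) / (m_c + pseudocount)))
        p = float(test(stress_mat[gi], ctrl_mat[gi]))
        is_deg = abs(log2fc) > fc_threshold and p < p_threshold
        direction = "none" if not is_deg else ("up" if log2fc > 0 else "down")
        out.append(DEGResult(gene_id=gene, log2fc=log2fc, p_value=p, is_deg=is_deg, direction=direction))
    return out


def translation_efficiency(
    rna_norm: pd.DataFrame,
    rpf_norm: pd.DataFrame,
    design: Mapping[str, str],
    pseudocount: float = 1.0,
    floor: float = 10.0,
    torso_rpf: pd.DataFrame | None = None,
) -> list[TEResult]:
    """Translation-to-transcription ratio per gene x condition.

    te = (mean normalized RPF + pseudocount) / (mean normalized RNA +
    pseudocount), over genes passing the RNA expression floor in every
    condition.  ``torso_rpf`` optionally supplies torso-restricted normalized
    RPF values (same layout) for the extremity-excluded variant.
    """
    eligible = expressed_genes(rna_norm, design, floor=floor)
    rna_means = condition_means(rna_norm, design)
    rpf_means = condition_means(rpf_norm, design)
    torso_means = condition_means(torso_rpf, design) if torso_rpf is not None else None
    out = []
    for gene in eligible:
        if gene not in rpf_means.index:
            warnings.warn(f"{gene}: absent from RPF matrix; skipped", stacklevel=2)
            continue
        for cond in rna_means.columns:
            te = (rpf_means.at[gene, cond] + pseudocount) / (rna_means.at[gene, cond] + pseudocount)
            torso_te = None
            if torso_means is not None and gene in torso_means.index:
                torso_te = float(
                    (torso_means.at[gene, cond] + pseudocount)
                    / (rna_means.at[gene, cond] + pseudocount)
                )
            out.append(TEResult(gene_id=gene, condition=cond, te=float(te), torso_te=torso_te))
    return out


def torso_counts(
    rpf_track: CoverageTrack, gene: GeneModel, partition: ExtremityPartition
) -> float:
    """Sum of RPF depth over the torso (CDS interior excluding the extremities)."""
    if rpf_track.strand != gene.strand:
        raise ValueError(f"{gene.gene_id}: track strand {rpf_track.strand} != gene strand")
    positions = partition.torso_positions(gene)
    if not positions:
        raise ValueError(
            f"{gene.gene_id}: torso empty for CDS of {gene.cds_length} bp with "
            f"windows {partition.start_window}/{partition.stop_window}"
        )
    return rpf_track.region_sum(positions)


def hypergeom_enrichment(
    query: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with Benjamini-Hochberg adjustment.

    Returns a DataFrame (term, k, term_size, p, p_adjusted, enriched) sorted
    by p; ``enriched`` iff p_adjusted < alpha.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    if not query <= background:
        raise ValueError("query must be a subset of background")
    N, n = len(background), len(query)
    rows = []
    for term in sorted(term_map):
        term_genes = set(term_map[term]) & background
        K = len(term_genes)
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "k", "term_size", "p"])
    if len(df):
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = []
    df["enriched"] = df["p_adjusted"] < alpha
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
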