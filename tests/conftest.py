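import numpy as np
import pandas as pd
import pytest

from tuarch.models import CoverageTrack, GeneModel
from tuarch.simulate import (
    SimConfig,
    simulate_counts,
    simulate_genome,
    simulate_tracks,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, n_genes=40, genome_length=120_000)


@pytest.fixture(scope="session")
def small_world(small_config):
    """One simulated dataset shared across read-only tests."""
    genome, genes, tss, truth = simulate_genome(small_config)
    rna, rpf = simulate_counts(truth, small_config)
    tracks = simulate_tracks(truth, small_config, rna, rpf)
    return dict(
        config=small_config, genome=genome, genes=genes, tss=tss, truth=truth,
        rna=rna, rpf=rpf, tracks=tracks,
    )


def make_gene(gene_id="g1", strand="+", cds_start=101, cds_end=400) -> GeneModel:
    return GeneModel(
        gene_id=gene_id, contig_id="chr", strand=strand,
        cds_start=cds_start, cds_end=cds_end,
    )


def make_track(depth, assay="RPF", condition="CTRL", replicate=1, strand="+") -> CoverageTrack:
    return CoverageTrack(
        assay=assay, condition=condition, replicate=replicate, strand=strand,
        depth=np.asarray(depth, dtype=float),
    )
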