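"""TEP detection, classification, UTR assignment, sequence context, and the
free-energy background comparison."""

import numpy as np
import pytest

from tuarch import termseq
from tuarch.models import GeneModel, GenomeSequence, TEPRecord, revcomp

from conftest import make_gene, make_track


def term_replicates(*rep_counts, length=1000, strand="+"):
    """Build replicate {strand: track} mappings from {pos: count} dicts."""
    reps = []
    for counts in rep_counts:
        depth = {"+": np.zeros(length), "-": np.zeros(length)}
        for pos, c in counts.items():
            depth[strand][pos - 1] = c
        reps.append(
            {
                s: make_track(depth[s], assay="TERM", condition="pooled", strand=s)
                for s in "+-"
            }
        )
    return reps


class TestDetectTeps:
    def test_replicate_consistency_rule(self):
        reps = term_replicates({560: 15, 520: 8, 300: 6}, {560: 12, 520: 1, 300: 5})
        cands = termseq.detect_teps(reps, min_count=5)
        assert {(c.position, c.counts) for c in cands} == {(300, (6, 5)), (560, (15, 12))}

    def test_match_tolerance_contract(self):
        reps_shifted = term_replicates({560: 15, 300: 6}, {561: 12, 301: 5})
        assert termseq.detect_teps(reps_shifted, min_count=5, match_tolerance=0) == []
        kept = termseq.detect_teps(reps_shifted, min_count=5, match_tolerance=1)
        assert {c.position for c in kept} == {300, 560}

    def test_empty_tracks(self):
        assert termseq.detect_teps(term_replicates({}, {})) == []

    def test_single_replicate_needs_override(self):
        reps = term_replicates({560: 15})
        with pytest.raises(ValueError, match="replicates"):
            termseq.detect_teps(reps)
        assert len(termseq.detect_teps(reps, allow_single_replicate=True)) == 1

    def test_local_maximum_suppresses_shoulders(self):
        reps = term_replicates({560: 15, 559: 7, 300: 6}, {560: 12, 559: 6, 300: 5})
        cands = termseq.detect_teps(reps, min_count=5)
        assert {c.position for c in cands} == {300, 560}


def cand(position, strand="+", counts=(10, 10)):
    return termseq.TEPCandidate(position=position, strand=strand, counts=counts)


class TestClassifyTeps:
    GENES = [make_gene("gA", cds_start=102, cds_end=500)]

    def test_primary_and_secondary_in_downstream_window(self):
        cands = [cand(520, counts=(4, 4)), cand(560, counts=(8, 7)), cand(740, counts=(2, 1))]
        recs = termseq.classify_teps(cands, self.GENES, downstream_window=250)
        by_cat = {r.category: r for r in recs}
        assert by_cat["P"].position == 560
        assert {r.position for r in recs if r.category == "S"} == {520, 740}
        assert all(r.gene_id == "gA" for r in recs)

    def test_beyond_window_is_not_primary(self):
        recs = termseq.classify_teps([cand(751)], self.GENES, downstream_window=250)
        assert all(r.category != "P" for r in recs)

    def test_intragenic_sense(self):
        (rec,) = termseq.classify_teps([cand(300)], self.GENES)
        assert rec.category == "I" and rec.gene_id == "gA"

    def test_antisense(self):
        (rec,) = termseq.classify_teps([cand(300, strand="-")], self.GENES)
        assert rec.category == "A" and rec.gene_id == "gA"

    def test_upstream_of_start_codon(self):
        (rec,) = termseq.classify_teps([cand(60)], self.GENES, upstream_window=150)
        assert rec.category == "U"

    def test_unassignable_dropped(self):
        genes = [make_gene("gA", cds_start=5001, cds_end=5300)]
        assert termseq.classify_teps([cand(100)], genes, upstream_window=150) == []

    def test_at_most_one_primary_per_gene(self, small_world):
        tracks = small_world["tracks"]
        reps = [
            {s: tracks.get("TERM", "pooled", rep, s) for s in "+-"} for rep in (1, 2)
        ]
        cands = termseq.detect_teps(reps, min_count=5)
        recs = termseq.classify_teps(cands, small_world["genes"])
        p_by_gene = [r.gene_id for r in recs if r.category == "P"]
        assert len(p_by_gene) == len(set(p_by_gene))
        assert all(sum(1 for c in r.category) == 1 for r in recs)


class TestAssign3utr:
    def test_plus_strand_distance(self):
        genes = [make_gene("gA", cds_start=102, cds_end=500)]
        teps = [TEPRecord(position=560, strand="+", category="P", gene_id="gA", counts=(5,))]
        assert termseq.assign_3utr(teps, genes) == {"gA": 60}

    def test_minimum_length_one(self):
        genes = [make_gene("gA", cds_start=102, cds_end=500)]
        teps = [TEPRecord(position=501, strand="+", category="P", gene_id="gA", counts=(5,))]
        assert termseq.assign_3utr(teps, genes) == {"gA": 1}

    def test_minus_strand_mirror(self):
        genes = [make_gene("gA", strand="-", cds_start=500, cds_end=799)]
        teps = [TEPRecord(position=440, strand="-", category="P", gene_id="gA", counts=(5,))]
        assert termseq.assign_3utr(teps, genes) == {"gA": 60}


class TestComposition:
    def test_planted_t_run(self):
        seq = "A" * 45 + "TTTTTT" + "A" * 49  # T at 1-based 46..51
        genome = GenomeSequence("c", seq)
        teps = [
            TEPRecord(position=51, strand="+", category="P", gene_id=f"g{i}", counts=(5,))
            for i in range(3)
        ]
        comp = termseq.nucleotide_composition(teps, genome, flank=10)
        t_col = comp[:, 3]
        offsets = list(range(-10, 11))
        for off in range(-5, 1):
            assert t_col[offsets.index(off)] == 1.0
        assert comp.sum(axis=1) == pytest.approx(np.ones(21))

    def test_single_tep_rows_are_unit_vectors(self):
        genome = GenomeSequence("c", "ACGTACGTACGTACGTACGT")
        teps = [TEPRecord(position=10, strand="+", category="P", gene_id="g", counts=(5,))]
        comp = termseq.nucleotide_composition(teps, genome, flank=3)
        assert ((comp == 0) | (comp == 1)).all()
        assert comp.sum(axis=1) == pytest.approx(np.ones(7))

    def test_u_tract_enriched_on_synthetic_terminators(self, small_world):
        """Mean T fraction just upstream of planted TEPs exceeds the genomic
        T frequency by a wide margin."""
        truth, genome = small_world["truth"], small_world["genome"]
        teps = [
            TEPRecord(position=row.tep, strand=row.strand, category="P",
                      gene_id=row.gene_id, counts=(5,))
            for row in truth.genes.itertuples(index=False)
        ]
        comp = termseq.nucleotide_composition(teps, genome, flank=10)
        offsets = list(range(-10, 11))
        t_near = np.mean([comp[offsets.index(o), 3] for o in range(-6, 0)])
        genomic_t = genome.sequence.count("T") / genome.length
        assert t_near - genomic_t >= 0.3


class TestIntergenicSampling:
    def test_windows_avoid_cds_and_are_deterministic(self, small_world):
        genome, genes = small_world["genome"], small_world["genes"]
        seqs = termseq.sample_intergenic(genome, genes, n=200, length=40, seed=5)
        assert len(seqs) == 200 and all(len(s) == 40 for s in seqs)
        assert seqs == termseq.sample_intergenic(genome, genes, n=200, length=40, seed=5)

    def test_cds_overlap_excluded_exhaustively(self):
        genome = GenomeSequence("c", "ACGT" * 25)
        genes = [make_gene("g", cds_start=21, cds_end=80)]
        rng_hits = termseq.sample_intergenic(genome, genes, n=500, length=10, seed=0)
        mask = np.zeros(100, dtype=bool)
        mask[20:80] = True
        for seq in rng_hits:
            assert len(seq) == 10
        # verify positions by reconstruction: every sampled window must match
        # a CDS-free stretch of the genome on either strand
        valid = set()
        for start in range(1, 92):
            if not mask[start - 1 : start + 9].any():
                valid.add(genome.subseq(start, start + 9, "+"))
                valid.add(genome.subseq(start, start + 9, "-"))
        assert set(rng_hits) <= valid

    def test_zero_samples(self, small_world):
        assert termseq.sample_intergenic(
            small_world["genome"], small_world["genes"], n=0, seed=1
        ) == []

    def test_insufficient_space(self):
        genome = GenomeSequence("c", "A" * 50)
        genes = [make_gene("g", cds_start=1, cds_end=48)]
        with pytest.raises(ValueError, match="intergenic"):
            termseq.sample_intergenic(genome, genes, n=5, length=40, seed=0)


class TestMfeBackground:
    def test_fully_separated_groups(self):
        med_t, med_b, _, p = termseq.mfe_background_test(
            ["GGGGCCCC"] * 10, ["AAAATTTT"] * 10, termseq.gc_stub_fold
        )
        assert (med_t, med_b) == (-8.0, 0.0)
        assert p < 0.01

    def test_identical_groups_are_null(self):
        seqs = ["GGCC", "AATT", "ACGT", "GCGC"] * 3
        med_t, med_b, _, p = termseq.mfe_background_test(seqs, seqs, termseq.gc_stub_fold)
        assert med_t == med_b
        assert 0.3 < p < 0.8

    def test_planted_terminators_fold_below_intergenic_background(self, small_world):
        """Real folding engine: hairpin+U-tract terminator sequences have
        lower minimum free energy than random intergenic windows."""
        genome, genes, truth = small_world["genome"], small_world["genes"], small_world["truth"]
        teps = [
            TEPRecord(position=row.tep, strand=row.strand, category="P",
                      gene_id=row.gene_id, counts=(5,))
            for row in truth.genes.itertuples(index=False)
        ][:25]
        tep_seqs = [s for _, s in termseq.upstream_sequences(teps, genome, length=40)]
        bg = termseq.sample_intergenic(genome, genes, n=25, length=40, seed=2)
        med_t, med_b, _, p = termseq.mfe_background_test(tep_seqs, bg, termseq.rnafold_fold)
        assert med_t < med_b
        assert p < 0.001


def _mirror_world(small_world):
    genome = small_world["genome"]
    L = genome.length
    rc = GenomeSequence(genome.contig_id, revcomp(genome.sequence))
    genes = [
        GeneModel(
            gene_id=g.gene_id, contig_id=g.contig_id,
            strand="-" if g.strand == "+" else "+",
            cds_start=L - g.cds_end + 1, cds_end=L - g.cds_start + 1,
        )
        for g in small_world["genes"]
    ]
    tracks = small_world["tracks"]
    reps = []
    for rep in (1, 2):
        pair = {}
        for s in "+-":
            flipped = "-" if s == "+" else "+"
            pair[s] = make_track(
                tracks.get("TERM", "pooled", rep, flipped).depth[::-1],
                assay="TERM", condition="pooled", replicate=rep, strand=s,
            )
        reps.append(pair)
    return rc, genes, reps


def test_strand_symmetry_of_detection_and_classification(small_world):
    """Reverse-complementing the genome and flipping every strand mirrors TEP
    positions and preserves the category census."""
    tracks = small_world["tracks"]
    reps = [{s: tracks.get("TERM", "pooled", rep, s) for s in "+-"} for rep in (1, 2)]
    cands = termseq.detect_teps(reps, min_count=5)
    recs = termseq.classify_teps(cands, small_world["genes"])

    rc, rc_genes, rc_reps = _mirror_world(small_world)
    L = small_world["genome"].length
    rc_cands = termseq.detect_teps(rc_reps, min_count=5)
    rc_recs = termseq.classify_teps(rc_cands, rc_genes)

    assert {L - c.position + 1 for c in rc_cands} == {c.position for c in cands}
    census = lambda rs: sorted((r.category, r.gene_id) for r in rs)
    assert census(rc_recs) == census(recs)
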