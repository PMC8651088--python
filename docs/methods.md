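# Methods

`tuarch` analyzes bacterial transcription-unit (TU) architecture from four
strand-specific data layers: RNA-seq coverage, ribosome-profiling (RPF)
coverage, Term-seq transcript 3′-end counts, and a table of transcription
start sites (TSSs).  This note describes the models and procedures, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Coordinate conventions

All internal coordinates are 1-based and inclusive, matching GFF3; bedGraph's
0-based half-open intervals are converted only at I/O.  Two codon-relative
systems coexist, both strand-aware:

* **Metagene profiles** use a dense offset axis −W..+W (2W+1 offsets,
  including 0).  Offset 0 sits on the anchor base: the first base of the
  start codon, or the last base of the stop codon.  Offset +k is k bases
  downstream in transcript direction.
* **Extremity/torso partitions** use the field's codon-relative numbering
  with no zero: relative to the start codon, +1 is the first CDS base and −1
  the last 5′-UTR base; relative to the stop codon, −1 is the last stop-codon
  base and +1 the first 3′-UTR base.  With the default windows [−30, +60]
  (start) and [−33, +15] (stop), the extremities claim the first 60 and the
  last 33 CDS bases, so a 300-bp CDS has a 207-bp torso.

`determine_boundary` converts between the two (start: b1 = profile crossing
offset + 1; stop: a2 = profile crossing offset − 1).

## Transcript 3′-end calling (Term-seq)

TERM tracks hold per-position transcript 3′-end counts: the producer has
already mapped each Term-seq read's 5′ end to the opposite strand, i.e. onto
the transcript's own strand.  A **candidate** 3′-end position (TEP) is a
position with count ≥ `min_count` (default 5) that is a local maximum within
±3 nt; candidates are kept only if every replicate has one within
`match_tolerance` nt (default 0, exact agreement), and the reported
coordinate is replicate 1's.  The automated threshold-plus-local-maximum rule
replaces manual curation against RNA-seq profiles; both parameters are
exposed.

Classification precedence, per candidate: (1) inside the sense window 1..250
nt downstream of a stop codon → **P** (primary) if it carries the window's
maximal summed count, otherwise **S** (secondary); ties break toward the
position nearest the stop codon, favoring conservative (shorter) 3′-UTRs;
(2) inside a sense CDS → **I**; (3) overlapping a CDS on the opposite
strand → **A**; (4) within 150 nt sense-upstream of a start codon → **U**;
otherwise the candidate is dropped with a log entry.  A candidate falling in
two same-strand downstream windows goes to the nearer stop codon.  Each gene
gets at most one P-TEP, and its 3′-UTR length is the distance from the base
after the stop codon through the P-TEP inclusive (minimum 1).

Terminator sequence context: positional nucleotide composition over
−50..+50 around TEPs (transcript sense, offset 0 = TEP), and the 40-nt
transcript-sense sequence ending at the TEP for folding and motif export.
Folding free energy is computed through a pluggable adapter: `rnafold_fold`
wraps the RNAfold command-line program; `gc_stub_fold` (−(#G + #C)) is a fast
monotone stand-in for tests.  The one-sided Mann–Whitney rank-sum test asks
whether terminator sequences fold more stably than `n_background` (default
10,000) random intergenic windows sampled uniformly from CDS-free space on
both strands.

## Transcription units and the UTR enrichment degree

A TU is assembled for every gene with both a TSS and a P-TEP; with several
TSSs the one nearest the start codon (not inside the CDS) is used.  Writing
t, s, e, p for TSS, first start-codon base, last stop-codon base, and P-TEP:

    R_5utr = ( Σ_{i=t..s−1} d_i / l_5utr ) / ( Σ_{i=t..p} d_i / l_tu )
    R_3utr = ( Σ_{i=e+1..p} d_i / l_3utr ) / ( Σ_{i=t..p} d_i / l_tu )

i.e. mean depth over the UTR divided by mean depth over the whole TU; values
above 1 indicate enrichment (for RPF depth, ribosome accumulation) in the
UTR.  The statistic is invariant to rescaling the track.  Numerical choices:

* **Leaderless genes** (l_5utr = 0): R_5utr divides by the UTR length, so it
  is undefined; the TU is kept, the value flagged undefined and excluded
  from downstream tables.
* **Zero-depth TUs**: undefined rather than pseudocounted — the statistic is
  a ratio of means and a pseudocount distorts short UTRs most.
* **Replicates** are averaged position-wise before the ratio (per-replicate
  values are available by computing on individual tracks).
* Cross-condition shifts are tested with a paired one-sided Wilcoxon
  signed-rank test across genes (zero differences dropped); the choice of a
  paired rank test reflects the strongly skewed, gene-paired nature of the
  ratios.

UED-change clustering uses features log2(UED_cond / UED_ref) per
non-reference condition, Ward linkage on Euclidean distance, default k = 9,
with labels renumbered by decreasing mean of the first feature so cluster 1
is the strongest riser.

## Metagene occupancy and the extremity/torso rule

Profiles average depth over genes at fixed offsets from the start- or
stop-codon anchor (W = 200 by default).  By default each gene is first
normalized by its mean CDS depth so highly expressed genes do not dominate;
raw averaging is available.  No smoothing is applied by default; a centered
moving average of odd width is available because single-base noise can
produce spurious early crossings.

The boundary between extremity and torso is found by comparing the stress
profile against the offset-wise mean of the non-stress profiles: scanning
from the anchor outward, the boundary is the last offset before the stress
profile first falls to or below the reference (an exact tie belongs to the
torso).  If the profiles never cross within ±W, or cross immediately so the
window cannot straddle the codon, the procedure raises and the analyst falls
back to explicit windows.  Per-gene region fold changes divide size-factor-
normalized region sums (extremity = both windows; torso as above), average
replicates within condition, and take log2 with a pseudocount (default 1).
Genes whose CDS is too short to have a torso are flagged, not dropped.
Extremity fold-change clustering defaults to k = 7, Ward/Euclidean.

## Expression, differential calls, translation efficiency

Size factors are median-of-ratios: s_j = median over genes (with positive
geometric-mean count across samples) of count_gj / geomean_g, then rescaled
to geometric mean 1.  The rescaling makes normalization exactly idempotent
(re-estimating factors on a normalized matrix returns ones) and changes
nothing when the raw factors already have geometric mean 1; without it the
estimator is idempotent only up to a common constant.  A consequence worth
knowing: multiplying every library of one assay by the same constant passes
through to normalized values, so absolute translation efficiency inherits
the arbitrary RPF-to-RNA sequencing-depth ratio — relative TE (across genes
or conditions) is the meaningful quantity, and that is what the analyses
compare.

A gene is **expressed** if its mean normalized value is ≥ 10 in every
condition (replicates averaged before thresholding).  A **DEG** satisfies
|log2FC| > 1 AND p < 0.05, with log2FC from condition means of normalized
counts plus a pseudocount (default 1) and p from a pluggable test — default
two-sided Welch t on log2(normalized + 1); any gene-wise (stress, control) →
p function can be substituted, including an exact negative-binomial test.
The p threshold applies to raw p-values; adjusted values are available from
the enrichment utilities if desired.

**TE** = (normalized RPF + pseudocount) / (normalized RNA + pseudocount) per
gene × condition over the expressed set; a torso-restricted variant uses RPF
counts excluding the extremity windows, isolating elongation-phase occupancy
from stalled initiation/termination peaks.

Functional enrichment is an upper-tail hypergeometric test per term with
Benjamini–Hochberg adjustment across terms; a term is enriched when the
adjusted p < 0.05.  Term-to-gene maps are inputs.

## The synthetic-data generator

The generator builds a single-contig genome of non-overlapping, single-gene
TUs on both strands and emulates the statistical structure the analysis
assumes:

* **Architecture**: 5′/3′-UTR lengths are log-normal with medians 53 and
  92 nt, matching the medians measured for the cyanobacterium the pipeline
  targets.  The shape parameters (σ = 1.0 and 0.55) were calibrated to the
  printed length ranges (maxima near 1.9 kb and 0.5 kb at the measured
  sample sizes); the 3′-UTR floor of 40 nt leaves room for the terminator.
  With σ = 0.55 about 3–4 % of 3′-UTRs still exceed the 250-nt primary-TEP
  window — those planted ends are unrecoverable by the classification rule,
  exactly as overly long 3′-UTRs are in real data, which bounds attainable
  recovery near 96 %.
* **Terminators**: the 40 transcript-sense nt ending at each TEP hold a
  random pure-GC stem (8–12 bp), a 4–8-nt loop, the reverse-complement stem,
  and a U-tract of ≥ 6 T ending at the TEP — an idealized intrinsic
  terminator that folds far more stably than intergenic background.
* **Counts**: gene baselines are log-uniform (100–2,000); counts are
  gamma-Poisson (negative binomial, Var = m + α m², default α = 0.05) with
  mean baseline × 2^(planted log2FC) × library size factor; size factors are
  log-uniform in [0.5, 2].  A configurable fraction of genes (default 10 %)
  carries planted |log2FC| ∈ [1, 3] in each stress condition; RNA and RPF
  effects are co-regulated by default.
* **Tracks**: RNA depth is piecewise-constant over each TU with total mass
  proportional to the gene's count; RPF depth covers the CDS extended by the
  extremity margins and is multiplied by `stall_factor` (default 3) inside
  the [−30, +60]/[−33, +15] windows for the designated stress condition
  only; Gaussian depth noise (σ = 5 % of the local mean, clipped at zero) is
  added to RNA/RPF.  TERM tracks place Poisson-many reads per terminator
  (mean 30) at the planted TEP with probability 0.9, the rest offset
  upstream by a Geometric(0.5) tail, and stay integer-valued (their
  shot-noise is already the noise model, so the Gaussian perturbation is not
  applied to them).
* **Conditions**: CTRL (reference), HL (expression changes only), LT
  (expression changes plus ribosome stalling), two replicates each —
  mirroring a control/high-light/low-temperature design with biological
  duplicates.

What the generator does **not** emulate: operonic multi-gene TUs, condition-
dependent TSS/TEP switching, read-level artifacts (sequencing error, mapping
bias, rRNA contamination), codon-resolution ribosome dynamics, and Rho-
dependent termination.  Passing tests therefore demonstrate that the
pipeline recovers planted architecture and occupancy structure under an
idealized noise model, not that it is robust to every artifact of real
libraries.

## Problem sizes and determinism

Default simulations use 120 genes on a 320-kb contig (three conditions × two
replicates); the verification harness uses 30–200 genes per run and ten
seeds for the seed-sweep properties, sizes at which every stage completes in
seconds while leaving enough genes for stable rank tests.  All randomness
flows from a single integer seed through named substreams, so every output
(including run directories) is byte-identical under a fixed configuration;
clustering and boundary determination are deterministic algorithms.

## Known limitations

* Single-contig genomes only; plasmids and multi-chromosome assemblies are
  out of scope.
* The primary/secondary TEP rule depends on the 250-nt downstream window;
  genuinely long 3′-UTRs are classified U or dropped.
* The default Welch-on-log differential test is anticonservative for very
  low counts; substitute an exact NB test through the pluggable interface
  when analyzing shallow libraries.
* Absolute TE depends on the RPF/RNA depth ratio (see above).
* The boundary rule assumes a single contiguous stalling window per codon;
  multimodal stalling would be truncated at the first crossing.
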