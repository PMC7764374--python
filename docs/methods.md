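# Methods

## Coordinate system and gene models

All coordinates are 1-based and inclusive (GFF3 convention); half-open
intervals appear only at file boundaries.  A `GeneModel` stores exons
ordered 5'→3' along the transcript (genomically decreasing for
minus-strand genes), labelled introns strictly between consecutive
exons, and the transcript offset of the first CDS base.  The CDS is
assumed to run in complete codons from that offset to the end of the
transcript; positions ahead of it, or in a trailing partial codon, are
noncoding.  For a minus-strand single-exon gene the transform reduces to
`tpos = G₀ − g + 1` with `G₀` the genome coordinate of the first
transcript base, so `g + tpos` is constant along the gene — the property
used to anchor the maturase model from a single published coordinate
pair.

## Codon-effect annotation

A C-to-U event is always described on the sense strand; on a
minus-strand gene it appears as G→A in the plus-strand pileup, and all
codon arithmetic happens after reverse-complementing to the sense
strand.  The edited codon applies C→T at the focal site *and* at every
supplied co-edited transcript position within the same codon: plant
mitochondrial codons are frequently edited at two positions, and
ignoring the partner would mis-report both the codon and the amino-acid
change (TCC→TTT instead of TCC→TTC).  By default the pipeline uses all
called sites of a gene as the co-edited set.  Note that a fully edited
molecule can carry a partner edit whose population-level degree is below
the calling threshold; the published maturase table contains two such
codons, which is why `classify_effect` accepts an explicit co-edit set.
Synonymy is decided by translating reference and edited codons with the
gene's genetic-code table (default: standard code, which plant
mitochondria use for these genes; configurable by NCBI table id).

## Editing degrees and site calling

The editing degree of one replicate at one site is
`100 · e/(e + u)` where `e`, `u` are the edited/unedited counts of the
two informative bases (C/T on the plus strand, G/A for minus-strand
genes).  Counts of the other two bases are treated as sequencing noise
and ignored.  A replicate with fewer than `min_depth = 10` informative
reads yields a null degree: the threshold is a package decision (the
editing fraction of a handful of reads is dominated by sampling noise),
and a null replicate fails the retention clause below.  Only C-to-U
candidates are evaluated; positions outside gene models or with a
non-cytidine sense reference are tallied as diagnostics.

Germline filtering removes any candidate whose (chrom, pos) carries a
DNA-level variant with the same alternate allele (T for plus-strand
genes, A for minus-strand genes, both expressed on the reference plus
strand).  Filtering is a pure set difference: output ⊆ input.

A site is called when **some tissue has all of its biological replicates
at or above `min_degree` (default 15 %)**.  Called sites carry
per-tissue means and sample SDs (ddof = 1) over replicates; degrees are
kept as floats and rounded to whole percent only in report output.

## Differential editing

Pairwise tissue differences are computed on unrounded means; a site is
differential when any |difference| ≥ 15 percentage points (boundary
inclusive).  Significance letters come from pairwise two-sample Student
t-tests (equal variance, two-sided, n = 3 per tissue); no
multiple-testing correction is applied — the screen is the plain
per-site rule usually printed alongside such tables, and that choice is
deliberate and documented rather than hidden.  Zero-variance degenerate
input is handled explicitly: equal means give p = 1, distinct means with
zero pooled variance give p = 0.

The compact letter display labels the maximal cliques of the
not-significantly-different graph.  Cliques are ordered by the *input
tissue order* (the column-order convention of per-site tables, so three
mutually distinct tissues N, SR, UR read a, b, c in column order even
when their means are not monotone); a tissue in several cliques carries
several letters.  With three groups the maximal-clique construction is
exact, not heuristic.

## Expression screen

`FPKM = count/(L/10³)/(N/10⁶)` with `L` the transcript length and `N`
the library's properly mapped read pairs (configurable to
mitochondria-only totals; ratios are invariant to the choice as long as
it is consistent).  Fold changes are ratios of per-tissue mean FPKMs;
significance is a per-gene Student t-test on replicate FPKMs.  The DE
flag requires ratio > 1.5 or ratio < 1/1.5 **and** p < 0.05.  The lower
bound is 1/1.5 ≈ 0.67 — a symmetric fold screen; a threshold of 0.067
would be a 15-fold asymmetry and is inconsistent with flagged ratios
near 0.5.  No dispersion modelling or shrinkage is used: with three
replicates of a small organellar gene panel, the ratio + t-test screen
is the intended instrument, not an approximation of one.

## Splicing efficiency

Relative abundance per replicate is `2^-(Ct_target − Ct_reference)`
(amplification efficiency fixed at 2; per-primer calibration is out of
scope).  Splicing efficiency is spliced/unspliced relative abundance;
the housekeeping Ct cancels algebraically, so the statistic is invariant
to any per-replicate additive shift of all Ct values — a property the
tests assert exactly.  Replicates are aggregated by geometric mean
(arithmetic mean in log2, where Ct noise is additive and approximately
Gaussian), and spread is the log2-domain SD over biological replicates,
reported back-transformed as a multiplicative factor.  Cross-tissue
ratios divide each tissue's efficiency by the baseline tissue's
(default UR), so the baseline is exactly 1.  Error bars are SDs over
biological replicates, not propagated analytical errors.

## Synthetic data generator

The generator emulates a 3-tissue × 3-replicate nodulation design on a
small synthetic organellar genome: a minus-strand single-exon
maturase-like gene whose transcript carries the published codon contexts
at the published codon indices (filler codon GCA elsewhere, so the gene
has a realistic density of editable cytidines), a plus-strand four-exon
gene with three labelled group-II introns, and ten single-exon genes for
the expression panel.

Default study conditions: 50 editing sites on sense-strand cytidines
with true degrees drawn from {0, 0.2, 0.5, 0.8, 0.95} (30 % of sites
re-draw per tissue to create differential sites); informative depth
NB-distributed with mean 200 and size 10 (overdispersed, to exercise the
min-depth rule); sequencing error 0.005 moved to a uniform random other
base; 8 homozygous germline SNPs planted on separate sense-C positions
so that, unfiltered, they mimic perfect editing candidates — matching
the DNA-based germline filter concept without simulating DNA reads (a
ready-made VCF is emitted).  Expression counts are NB with mean 2000 and
size 100 per gene and tissue (a planted 2× change in N for one gene);
library totals are fixed at 2 × 10⁶ read pairs.  Ct values follow
`Ct = base − log₂(quantity) + N(0, 0.2)` cycles with per-intron spliced
fractions planted per tissue, including an N > UR > SR ordering for the
first intron.

All randomness flows through NumPy's PCG64 `default_rng`, seeded per
stage from the study seed, so outputs are byte-identical across runs and
platforms for a fixed seed.

What the generator does *not* emulate: alignment and mapping artefacts,
strand bias, base-quality structure, PCR duplicates, RNA degradation,
partial editing haplotypes, or primer-efficiency differences.  Passing
the recovery tests therefore demonstrates that the estimators and rules
are implemented correctly and are well calibrated under sampling noise —
not that the pipeline is robust to upstream artefacts, which are
consumed as already-resolved inputs (aligned counts, a finished germline
VCF).

## Problem sizes and numerical choices

The test suite and examples run the default panel (50 sites × 9 samples,
12 genes, 3 introns), 100 repeated qPCR simulations for the
rank-ordering property and 20 seeds for DE recovery; these sizes give
stable pass/fail behaviour for the properties asserted while keeping the
suite quick, and are package choices.  Ties and degenerate inputs are
resolved deterministically (documented in the relevant docstrings):
zero-variance t-tests as above, sites below informative depth are null,
cliques and output tables are sorted stably, and report rounding is
half-even via NumPy/pandas defaults.

## Known limitations

* The caller starts from base counts; varScan-style read-level filters
  (strand bias, base quality) are upstream concerns.
* Letter displays depend on the significance pattern of rounded-input
  replicates near α; with published whole-percent tables, one marginal
  pairwise test (p within ~0.02 of 0.05) can flip a letter.
* The splicing model assumes one housekeeping Ct per tissue × replicate
  (technical replicates pre-averaged) and perfect doubling efficiency.
* No FDR control anywhere by design; interpret flags as screens.
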