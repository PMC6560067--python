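# Methods

## The measurement model

RNA bisulfite sequencing converts unmethylated cytosine to uracil (read
as T) and leaves 5-methylcytosine intact. For a cytosine with true
methylation level m and per-molecule conversion efficiency e, a read
covering the site shows C with probability

    p = m + (1 − m)(1 − e)

and T otherwise (assuming no sequencing error). The per-site level
estimate is the binomial proportion k/n over informative (C-or-T) reads,
so its sampling error is √(p(1−p)/n). Everything downstream — coverage
gates, Welch tests, FDR — operates on these proportions per bisulfite
replicate.

Two failure modes specific to this assay shape the pipeline:

1. **Wholesale non-conversion.** Highly structured RNAs can escape
   conversion entirely, producing reads in which *every* C survives and
   which mimic dense methylation. Because genuine m⁵C in these RNAs is
   sparse, a read whose informative cytosines are more than 1/3
   methylated is discarded (strictly greater; exactly 1/3 is kept). The
   denominator is the number of informative reference-C calls in the
   read, not the read length: that makes the rule scale-free and ties it
   directly to the artifact mechanism. Reads with zero informative
   cytosines carry no evidence either way and are kept.
2. **Reference-absent sequence.** tRNAs acquire a post-transcriptional
   3' CCA absent from the genome, and reads can span splice junctions.
   Both defeat contiguous end-to-end genomic alignment and get dedicated
   rescue passes (below).

## Alignment

Alignment is an exhaustive end-to-end scan over every offset of every
contig, on both genome strands but in a single conversion space
(reference C matched by read T is free; read C over reference T is a
mismatch; N never matches), with a ceiling of 2 mismatches and no
indels. Ties at the best score are classed `ambiguous`; reads with no
window within the ceiling are `unaligned`. The scan is vectorised over
reads (numpy sliding windows) but remains O(reads × reference) by
design: the intended references are mini-transcriptomes of at most a few
hundred kb, where correctness and auditability beat index structures.

The cascade is:

- **Pass 1** — end-to-end genomic alignment.
- **Pass 2** — pass-1 unaligned *and* ambiguous reads are retried after
  removing their last 3 bases (the potential CCA tail); reads falling
  below 20 nt are `discarded_short`.
- **Pass 3** — pass-2 unaligned reads (only; ambiguous reads stop at
  pass 2) are aligned to a splice-junction library (default flank 50 nt,
  clamped to the adjacent exon lengths) and unique hits that straddle
  the junction by ≥1 nt are converted back to genomic coordinates. The
  spanned intron becomes a cigar `D` operation so the methylation
  extractor can walk the alignment; abutting exon blocks merge into a
  single `M`. Junction hits lying entirely within one flank are treated
  as unaligned — a contiguous placement was already available to the
  genomic passes.

A consequence worth knowing: a junction-spanning read whose overhang
into the second exon is only 1–3 nt can tolerate a contiguous genomic
placement running into the intron within the 2-mismatch budget, and is
then absorbed by pass 1 with a slightly wrong 3' placement. This is
inherent to the mismatch-ceiling contract, affects only a band of a few
nt around each junction, and is shared by the aligner family this module
re-specifies. The back-conversion arithmetic itself is exact, and the
test suite verifies it read-by-read against simulation truth.

Alignment is sense-strand directional in conversion space (the assay
converts the RNA molecule itself, and small-RNA libraries are stranded),
so only the C→T space is searched — no G→A space exists here.

## Statistics

- **Testable sites**: coverage strictly greater than 10 in every
  replicate of every tested condition (a site missing from a replicate
  counts as zero coverage).
- **Dependence**: per site, Welch's unequal-variance t-test of the
  rescue condition against each comparator (empty vector; dead enzyme)
  on per-replicate levels, untransformed — the proportions at issue live
  mostly in 0–0.5 where the variance-stabilising transforms change
  nothing material. Benjamini–Hochberg step-up FDR is applied across
  sites within each contrast. A site is `dependent` iff padj < 0.05 in
  both contrasts *and* the rescue mean exceeds both comparator means.
- **Degenerate inputs**: two constant, equal groups give p = 1 by
  convention; constant, unequal groups are evaluated with the variance
  replaced by machine epsilon, which yields an extreme t — callers can
  recognise such sites by their zero within-group range.
- **Two-condition comparisons**: pooled (summed across replicates)
  counts per condition; keep sites with pooled coverage > 100 and level
  ≥ 0.20 in at least one condition. Pooling is the natural reading of a
  depth threshold; the per-replicate alternative would be stricter.
  Global level shifts between conditions use a two-sided Mann–Whitney U
  (exact for tie-free samples of ≤8, otherwise normal approximation with
  tie correction).
- Both strictness choices (> 10, > 100 rather than ≥) are exposed as
  parameters.

## The simulator

`simulate_replicate` draws reads uniformly along each transcript
(per-site depth ~Poisson around `mean_coverage`, the standard shotgun
assumption), applies the conversion model per cytosine independently
(methylated with the profiled m, else converted with probability
`conversion_efficiency`), and emits a fraction `artifact_rate` of reads
as fully unconverted — the correlated failure mode the >1/3 filter
exists for. tRNA sequences carry their CCA; fragments running off the 3'
end are padded with the sequencing adapter and then random bases, so
trimming is exercised with known insert lengths. Quality strings are
constant (the pipeline does no quality trimming). Every read is logged
with its source interval, replicate, artifact flag and per-site emitted
states.

Defaults mirror the emulated study design: 5 bisulfite replicates per
condition, conversion efficiency 0.99 (a convention — observed
efficiencies are rarely published), artifact rate 0.01, 30-nt reads,
300× coverage, site levels 0–0.5.

What the simulator does **not** model: PCR duplicates, GC or ligation
bias, quality decay, molecule-level methylation correlation beyond the
artifact class, and expression differences between conditions. Passing
tests therefore demonstrate correctness of the pipeline's logic under
the stated statistical structure, not robustness to every bias of real
libraries.

`simulate_site_counts` is a count-level fast path that draws the same
post-filter per-site binomials the read-level pipeline produces
(coverage ~Poisson(mean_coverage·(1−artifact_rate)), methylated count
~Binomial(coverage, m + (1−m)(1−e))). The replication-heavy calibration
experiments (null FDR over 50 studies × 500 sites; power over 100
studies) use it; the equivalence of the two routes is itself validated
by the read-level recovery tests, which run simulate → align → extract
end-to-end and land within binomial error of the same p.

## The bundled references

`demo_reference()` builds a three-transcript mini-genome: a 98-nt vault
RNA placeholder with annotated C69/C88 (the true VTRNA1.1 isoform
sequence is not bundled; users can substitute it — labels are 1-based
from the 5' end), a 72+CCA tRNA whose three post-gene genomic bases are
chosen to mismatch the CCA tail in conversion space too (otherwise the
tail would not be genuinely genome-absent for converted reads), and a
two-exon transcript with a 50-nt intron. `single_site_reference()`
builds a one-site transcript for recovery experiments, with an enforced
minimum cytosine density in every read-length window covering the site:
the >1/3 filter needs surrounding informative Cs for its denominator,
mirroring the C-richness of real structured ncRNAs. In C-poor windows
the filter mildly deflates high site levels (a read showing only the
methylated site as informative is discarded), which is visible as a
~1–2 point dip of the demo C69 estimate below its expectation; this
trade-off is inherited from the filter's design.

## Problem sizes and numerical choices

The test and demonstration runs use a ~1.3-kb reference, coverage 60–80
for end-to-end runs, 1000× single-replicate coverage for level-recovery
checks (100 seeds × 3 levels), 500 sites × 50 studies for null-FDR
calibration, and 100 studies for power — sizes chosen so the entire
analysis replays on a laptop in minutes while keeping binomial standard
errors small enough for 3-SE assertions to discriminate. All randomness
flows from explicit seeds through independent, condition-tagged numpy
`SeedSequence` streams; reruns with the same seed are byte-identical.
Floating-point conventions: BH adjusted values are capped at 1 and
restored to input order; Welch p-values use the t survival function
directly (no 1−CDF cancellation); constant groups are detected by value
range rather than computed variance, which picks up mean-roundoff noise.

## Known limitations

- The exhaustive aligner is not meant for genome-scale references.
- Indels, soft-clipping and opposite-strand conversion space are out of
  contract.
- The junction band effect described above.
- The >1/3 filter's deflation of genuinely high methylation (m > 1/3
  with few surrounding cytosines); the filter threshold and minimum
  informative count are parameters for exactly this reason.
- Simulated coverage is uniform along transcripts except for 3'-end
  shortening; no positional (M-bias style) effects are modelled or
  corrected.
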