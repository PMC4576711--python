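# Methods

This note records the scientific and numerical choices behind `ecosplice`:
what the model assumes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Coordinates and formats

All coordinates are 0-based, half-open internally; GFF3's 1-based inclusive
convention is converted at read/write time only. Boundary matching
throughout the pipeline (template boundaries, junction confirmation) is
exact integer equality, which is only safe under a single convention —
hence the hard rule that conversion never happens downstream of I/O.

Spliced alignments are consumed as BED12 (blocks = exons). Inter-block
gaps shorter than `min_intron` are merged into a single block at read
time: such gaps are overwhelmingly alignment indels, not introns.
`min_intron` defaults to 40 bp — below the shortest credible arthropod
intron — and is configurable. Junctions arrive as a four-column TSV
(`chrom  intron_start  intron_end  strand`, 0-based half-open); junction
callers' output dialects vary too much for any one of them to be a stable
contract, so this file format is the package's own. Junction strand may be
unknown (`?`) and is ignored in matching: the confirmation rule is
coordinate-only.

Group labels ("ecotypes") are free strings with `head`/`body` as
defaults; no logic depends on the particular labels.

## Gene templates

A gene's template is built from the transcripts assigned to it, not from
the annotation's exon models — the annotation contributes only gene
extents and strand for assignment. Template construction merges all
transcript blocks and then tiles the template span with alternating
exon/intron pieces, cutting at block-union edges and at every observed
transcript intron boundary. A piece is a template intron when it is a gap
in the block union **or** exactly equals an intron spliced by at least one
transcript. The second clause matters: under a pure block union, a single
intron-retaining isoform would fill the gap and erase the intron from the
template, making retention undetectable in principle. Keeping an intron
that any transcript splices — even when another reads through it — is
what makes the IR definition (a block covering a template intron plus ≥1
base of each flanking exon) operative.

Assignment requires a transcript's span to overlap exactly one same-strand
gene; transcripts overlapping none (`no_gene`) or several (`ambiguous`)
are discarded with counted reasons. Intronless transcripts inside one
template exon emit no events but stay in the AS-index denominator: they
are legitimate sampled sequences.

## Event classification

For each transcript intron the classifier computes, against the template:
the set of wholly contained template exons, and side-specific boundary
sharing with template introns (donor = the intron end abutting the
transcript-5′ exon, so on the minus strand the donor is the right-hand
genomic coordinate). An intron exactly matching a template intron emits
nothing. The five definitions are applied literally; one ES event is
emitted per skipped exon, so an intron skipping two exons yields two ES
events with well-defined identity tuples. An intron that both skips a full
exon and has one moved boundary satisfies the ES definition and a
boundary-type definition simultaneously; by default both events are
emitted (`emit_combined=True`), which keeps the per-boundary rules
exhaustive. With `emit_combined=False` only the ES events are kept. An
intron nested strictly inside one template exon matches no category in
this taxonomy and is ignored (mutually exclusive exons and alternative
first/last exons are likewise out of scope).

The test suite holds the sweep implementation to a brute-force oracle that
enumerates every (intron, template-feature) and (block, template-intron)
pair and applies the definitions independently, over exhaustive
boundary-edit transcripts on small templates, both strands. Two symmetry
properties are asserted: flipping strand at fixed coordinates swaps
5S↔3S and fixes ES/IR/3S5S; mirroring coordinates *and* flipping strand
(the reverse-complement view) preserves every type.

## Junction confirmation and specificity

An event is confirmed iff some junction end equals the event's start or
end on the same chromosome. Confirmation is monotone in the junction set.
Unconfirmed events are retained in outputs (`confirmed=false`) but
excluded from partitioning and every downstream enrichment, mirroring the
design in which only confirmed events are interpreted. Specificity is
presence/absence of per-group support — a deliberate choice: with one
pooled sample per group there is no replication to support a quantitative
differential-splicing test, so none is offered. The junction set is pooled
across groups by default (a per-group option exists): requiring same-group
confirmation would conflate confirmation with specificity.

## Coverage-corrected AS index

For each gene with at least `k` assigned transcripts: draw `k` transcripts
without replacement, rebuild the template *from the drawn transcripts
only*, detect and deduplicate events within the draw, count distinct
events; the index is the mean over `n_samples` draws (defaults k=10,
n_samples=100). Genes below `k` are ineligible and reported as missing,
never 0. Rebuilding the template per subsample is essential — reusing the
full-coverage template would leak coverage information into every draw and
defeat the correction. Sampling is per gene rather than global: only a
per-gene index yields a prevalence comparable across datasets. Each gene
gets its own RNG stream derived from (run seed, crc32 of the gene id), so
results are bit-reproducible and independent of gene iteration order.
Prevalence counts a gene as alternatively spliced when its index is
positive — the threshold-free reading.

## Randomization enrichment

Null draws sample `|test set|` items from the pool without replacement
(vectorized: per-draw uniform keys, argpartition of the k smallest), so
the exact null for a single boolean feature is hypergeometric. The
empirical z against simulated moments is the primary statistic, with the
exact hypergeometric two-sided p (minimum-likelihood summation) reported
alongside as a closed-form cross-check, plus an add-one-smoothed empirical
tail proportion. All p values are two-sided; direction is reported
separately, since both enrichments and depletions are of interest. When
the null sd is zero the z is undefined and the empirical p is used, with a
warning.

Event-type tests are Bonferroni corrected with family = groups × types
(10 by default; the family size is explicit config, since subsetting a
family silently would change the correction). Gene-set and GO tests are
BH corrected across categories. GO terms annotating fewer than `min_term`
background genes are pooled into one composite category before testing
(default 100, matching the convention for a catalog of ~10⁴ genes; for
the 1,000-gene synthetic catalog the scaled cutoff 30 is used in tests
and the acceptance script). The enrichment background defaults to all
genes with ≥1 confirmed event in either group; both this and the
per-group alternative are accepted arguments, as the choice is a genuine
analysis decision.

The two-proportion comparison between the two specific sets uses the
pooled-variance Z with a two-sided normal p; a pooled proportion of 0 or
1 returns z=0, p=1 with a warning rather than dividing by zero.

## Synthetic data

The generator emulates the statistical structure the analysis assumes: a
shared gene catalog (default 1,000 genes, 3–8 exons of 80–300 bp, introns
60–400 bp, both strands), two transcript pools (12–25 transcripts per gene
per group), a junction file, a GO map and curated lists, all in the exact
formats the readers consume, plus a truth manifest. Default proportions
follow the observed louse analysis: 36% of genes carry an event, planted
events split 57/17/26% shared/A-specific/B-specific, and a planted event
boundary is covered by a junction with probability 0.7649 (the published
confirmation rate). The event-type mixture defaults to an ES-heavy
metazoan-like vector (0.35/0.15/0.20/0.10/0.20 over ES/5S/3S/3S5S/IR).

Each selected gene carries exactly one planted event, realised as a
geometric edit of the gene's reference isoform (exon deleted, intron
retained, boundary shifted 2–50 bp *into* a flanking exon). One event per
gene keeps truth labels exact and avoids edit interactions within one
isoform. A carrying group expresses the edited isoform in ~40% of its
transcripts. Confirmation junctions are emitted per event (the upstream
constitutive intron for ES; the event interval itself otherwise); noise
junctions are placed ≥2 bp away from every true boundary so they can
never accidentally confirm. Constitutive junctions are deliberately not
emitted — the junction file exists only to drive confirmation, and
omitting them keeps the manifest's `confirmable` flag exact.

What the simulator does *not* emulate: sequence content, read errors,
aligner behaviour, partial/truncated alignments, expression levels,
overlapping genes, or multiple interacting events per gene. Passing tests
therefore demonstrate the correctness of the coordinate logic and the
statistics under clean geometry, not robustness to alignment artifacts in
real data.

For planted-bias recovery the configuration is chosen by power analysis:
only body-ES (up) and body-IR (down) deviate — 5S/3S/3S5S shares are
identical across categories and the head-specific mixture equals the pool
mixture, so all head tests and the remaining body tests are true nulls —
with effect sizes giving expected |z| ≈ 6–7 at ~150 body-specific events.
Note an unavoidable residual: with 8 true-null Bonferroni tests the
familywise false-flag rate is ~4%, and BH across ~13 GO categories with
one strong hit passes a rank-2 null with probability of a few percent;
over many seeds roughly one run in ten shows one spurious flag. That is a
property of the corrections, not a defect of the pipeline.

## Problem sizes

Test-suite and acceptance runs use a 1,000-gene catalog (~35,000
transcripts per run), 10,000 randomization draws for enrichment, 100
subsamples of 10 for the index, and a calibration experiment of 1,000
replicate tests at 1,000 draws each; the full suite runs in well under a
minute per module on one CPU.

## Known limitations

* Template construction is evidence-union based; an intron is only
  recoverable as IR if at least one transcript splices it exactly. Introns
  whose interior contains foreign splice boundaries from other isoforms
  are conservatively treated as exonic.
* A transcript overlapping two annotated genes is always discarded as
  ambiguous; read-through transcripts are not modelled.
* Specificity is presence/absence: an event seen once in one group and
  dozens of times in the other is "shared".
* The index's eligibility rule (≥ k transcripts) means lowly covered
  genes contribute nothing to prevalence; this is by design (the index
  exists to compare unequal coverages, not to rescue missing data).
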