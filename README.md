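# ecosplice

Comparative alternative-splicing (AS) analysis for two-sample transcript
pools — detection and classification of AS events from spliced transcript
alignments, short-read junction confirmation, partitioning of events into
shared and group-specific sets, a coverage-corrected AS index, and
randomization-based enrichment tests.

## The problem

Two populations of the same species (the motivating case: human head and
body lice, con-specific ecotypes with nearly identical genomes but distinct
niches) can differ in their *transcript pools* even when they do not differ
in gene content or expression. Given one pool of spliced transcript
alignments per group against a shared genome and annotation, `ecosplice`
asks: which splicing events are seen in both groups, which in only one, and
are the group-specific events biased in kind (event type) or in function
(gene sets, GO terms) relative to the background of all spliced events?

## Method

**Detection.** All transcripts assigned to a gene (span overlapping exactly
one same-strand annotated gene; others are discarded) are merged into an
exon–intron *template*. Each transcript is compared back to the template
and deviations are classified into the five canonical event types:

| type | definition | event interval |
|------|-----------|----------------|
| ES   | transcript intron splices out ≥1 whole template exon, ends on template exon boundaries | each skipped exon |
| IR   | transcript block reads through a template intron, ≥1 bp into both flanking exons | the retained intron |
| 5S   | alternative 5′-donor site: intron shares its acceptor-side boundary with a template intron, donor moved | the transcript intron |
| 3S   | alternative 3′-acceptor site: donor shared, acceptor moved | the transcript intron |
| 3S5S | both splice sites moved (no boundary shared, no whole exon skipped) | the transcript intron |

Donor and acceptor are strand-aware: the same genomic geometry is a 5S on
the plus strand and a 3S on the minus strand. Events are deduplicated on
(gene, type, start, end), summing per-group transcript support.

**Confirmation.** An event is confirmed when a short-read splice-junction
end matches one of its boundaries *exactly* (coordinate equality, strand
ignored). Only confirmed events enter the partition and enrichment stages.

**Specificity.** With O_A events observed in group A, O_B in B, and T
confirmed in total: shared = O_A + O_B − T, A-specific = T − O_B,
B-specific = T − O_A. Genes are classed by whether they carry ≥1
A-specific and/or B-specific event.

**Coverage-corrected AS index.** The raw event count of a gene grows with
transcript coverage. For each gene with ≥ k assigned transcripts, the index
is the mean number of distinct events over n repeated subsamples of k
transcripts drawn without replacement (defaults k = 10, n = 100), with the
template rebuilt inside each subsample. AS prevalence is the proportion of
eligible genes with index > 0.

**Enrichment.** A feature's count in a test set (e.g. ES events among
B-specific events) is compared with its distribution over 10,000
equal-sized random draws from the pool, summarized as
z = (observed − null mean)/null sd with a two-sided normal p; the exact
hypergeometric p is reported alongside. Event-type tests are Bonferroni
corrected (family = groups × types), gene-set/GO tests BH corrected, with
GO terms under a size cutoff pooled into one composite category. A pooled
two-proportion Z test compares feature shares between the two specific
sets.

## Worked example

Simulate a two-group dataset with planted events and run the full
pipeline:

```bash
ecosplice simulate --outdir demo --seed 11 --n-genes 200
# -> wrote 72 planted events to demo

cat > demo/config.json <<'JSON'
{
 "annotation": "demo/genes.gff3",
 "alignments_a": "demo/transcripts_head.bed",
 "alignments_b": "demo/transcripts_body.bed",
 "junctions": "demo/junctions.tsv",
 "go_map": "demo/go_map.tsv",
 "min_term": 30
}
JSON

ecosplice run-all --config demo/config.json --outdir demo/out
```

which prints the stage counts:

```json
{
 "confirmation_rate_pct": 72.22,
 "confirmed_events": 52,
 "distinct_events": 72,
 "gene_specificity": {
  "genes_both": 0,
  "genes_specific_A": 15,
  "genes_specific_B": 12,
  "genes_union": 27
 },
 "genes_with_transcripts": 200,
 "partition": {
  "observed_A": 40,
  "observed_B": 37,
  "shared": 25,
  "specific_A": 15,
  "specific_B": 12,
  "total_confirmed": 52
 },
 "transcripts_assigned": 7454,
 "transcripts_discarded": {},
 "transcripts_read": 7454
}
```

All 72 planted events are detected as distinct events; 52 carry a
boundary-matching junction (the generator's default confirmation
probability is 0.7649) and are partitioned: 25 shared, 15 head-only,
12 body-only, and the identities `shared = observed_A + observed_B −
total` hold by construction. `demo/out/` additionally contains the
per-event table, the partition labels, the per-gene AS index,
and the enrichment tables.

Stage-wise subcommands (`simulate | detect | confirm | partition | index |
enrich`) compose to the same outputs; see `ecosplice --help`.

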