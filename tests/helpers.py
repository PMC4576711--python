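"""Shared builders for test objects."""

from ecosplice.as_detection import GeneTemplate
from ecosplice.io_formats import ASEvent, SplicedAlignment

_COUNTER = [0]


def aln(blocks, strand="+", ecotype="head", chrom="chr1", tid=None):
    if tid is None:
        _COUNTER[0] += 1
        tid = f"t{_COUNTER[0]}"
    return SplicedAlignment(
        transcript_id=tid, ecotype=ecotype, chrom=chrom, strand=strand,
        blocks=tuple(tuple(b) for b in blocks),
    )


def template(exons, strand="+", gene_id="g1", chrom="chr1"):
    """Template whose introns are the gaps between the given exons."""
    return GeneTemplate.from_exons(gene_id, chrom, strand, exons)


def event(gene_id="g1", event_type="ES", start=200, end=300, chrom="chr1",
          support=None, confirmed=False):
    return ASEvent(
        gene_id=gene_id, event_type=event_type, chrom=chrom, start=start, end=end,
        support=dict(support or {"head": 1}), confirmed=confirmed,
    )
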