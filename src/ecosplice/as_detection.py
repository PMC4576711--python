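"""Transcript assignment, gene-template construction and AS event detection.

The detection model: all transcripts assigned to a gene are merged into an
exon–intron *template* (the union of their exon blocks). Each transcript is
then compared against the template and deviations are classified into the
five canonical alternative-splicing event types:

``ES``
    exon skipping — a transcript intron splices out one or more whole
    template exons, with both intron ends on template exon boundaries.
    One event per skipped exon; the event interval is the skipped exon.
``IR``
    intron retention — a transcript block reads through a template intron,
    extending at least one base into both flanking template exons. The
    event interval is the retained template intron.
``5S`` / ``3S``
    alternative 5′-donor (resp. 3′-acceptor) site — a transcript intron
    shares its acceptor-side (resp. donor-side) boundary with a template
    intron while the other boundary has moved. Donor/acceptor are defined
    relative to transcript orientation, so the same genomic geometry is a
    5S on the plus strand and a 3S on the minus strand. The event interval
    is the transcript intron.
``3S5S``
    both splice sites alternative — the intron overlaps template intron
    territory but shares neither boundary and skips no complete exon.

A transcript intron identical to a template intron, or a block lying within
a single template exon, is consistent with the template and emits nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ASEvent, GeneCatalog, SplicedAlignment


@dataclass(frozen=True)
class GeneTemplate:
    """Merged exon–intron structure of one gene, built from its transcripts.

    ``template_exons`` and ``template_introns`` alternate and tile the
    template span. An intron spliced by at least one transcript stays an
    intron even when another transcript's block reads through it — without
    this, a single retention isoform would erase the intron from the
    template and intron retention could never be observed.
    """

    gene_id: str
    chrom: str
    strand: str
    template_exons: tuple[tuple[int, int], ...]
    template_introns: tuple[tuple[int, int], ...]

    @classmethod
    def from_exons(cls, gene_id: str, chrom: str, strand: str,
                   exons: list[tuple[int, int]]) -> "GeneTemplate":
        """Template whose introns are exactly the gaps between the exons."""
        ex = tuple(tuple(e) for e in sorted(exons))
        introns = tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))
        return cls(gene_id, chrom, strand, ex, introns)

    @property
    def span(self) -> tuple[int, int]:
        return (self.template_exons[0][0], self.template_exons[-1][1])


@dataclass(frozen=True)
class DiscardedTranscript:
    transcript_id: str
    ecotype: str
    reason: str  # no_gene | ambiguous


def assign_transcripts(
    alignments: list[SplicedAlignment], catalog: GeneCatalog
) -> tuple[dict[str, list[SplicedAlignment]], list[DiscardedTranscript]]:
    """Assign each transcript to the unique same-strand gene its span overlaps.

    Transcripts overlapping no gene are discarded with reason ``no_gene``,
    transcripts overlapping two or more genes with reason ``ambiguous``.
    """
    if len(catalog) == 0:
        raise ValueError("gene catalog is empty")
    assigned: dict[str, list[SplicedAlignment]] = {}
    discarded: list[DiscardedTranscript] = []
    for aln in alignments:
        start, end = aln.span
        hits = catalog.overlapping(aln.chrom, start, end, strand=aln.strand)
        if len(hits) == 1:
            assigned.setdefault(hits[0].gene_id, []).append(aln)
        else:
            reason = "no_gene" if not hits else "ambiguous"
            discarded.append(DiscardedTranscript(aln.transcript_id, aln.ecotype, reason))
    return assigned, discarded


def merge_intervals(intervals: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of intervals, merging overlapping and bookended neighbours."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def build_gene_template(transcripts: list[SplicedAlignment], gene_id: str | None = None) -> GeneTemplate:
    """Merge all transcript blocks into the gene's exon–intron template.

    The template span is tiled by pieces cut at every union-block edge and
    every observed intron boundary. A piece is a template intron when it is
    a gap in the block union *or* exactly matches an intron spliced by some
    transcript (so a retention isoform cannot erase an intron that other
    transcripts splice); adjacent pieces of equal kind are re-merged.
    """
    if not transcripts:
        raise ValueError("at least one transcript required to build a template")
    chroms = {t.chrom for t in transcripts}
    strands = {t.strand for t in transcripts}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("transcripts for one gene must share chrom and strand")
    union = merge_intervals([b for t in transcripts for b in t.blocks])
    observed_introns = {iv for t in transcripts for iv in t.introns}

    span = (union[0][0], union[-1][1])
    cuts = {span[0], span[1]}
    for s, e in union:
        cuts.update((s, e))
    for s, e in observed_introns:
        if span[0] < s < span[1]:
            cuts.add(s)
        if span[0] < e < span[1]:
            cuts.add(e)
    edges = sorted(cuts)

    def covered(s: int, e: int) -> bool:
        return any(us <= s and e <= ue for us, ue in union)

    exons: list[list[int]] = []
    introns: list[list[int]] = []
    for s, e in zip(edges, edges[1:]):
        is_intron = (s, e) in observed_introns or not covered(s, e)
        target = introns if is_intron else exons
        if target and target[-1][1] == s:
            target[-1][1] = e
        else:
            target.append([s, e])

    return GeneTemplate(
        gene_id=gene_id if gene_id is not None else transcripts[0].transcript_id,
        chrom=chroms.pop(),
        strand=strands.pop(),
        template_exons=tuple((s, e) for s, e in exons),
        template_introns=tuple((s, e) for s, e in introns),
    )


def _intron_sides(intron: tuple[int, int], strand: str) -> tuple[int, int]:
    """(donor, acceptor) genomic positions of an intron, strand-aware.

    On '+' the donor is the left (start) coordinate; on '-' the right.
    """
    s, e = intron
    return (s, e) if strand == "+" else (e, s)


def detect_events(
    transcript: SplicedAlignment,
    template: GeneTemplate,
    emit_combined: bool = True,
) -> list[ASEvent]:
    """Classify one transcript's deviations from its gene template.

    ``emit_combined`` controls whether an intron that skips a full template
    exon *and* has one moved boundary emits both the ES event(s) and the
    5S/3S boundary event; turning it off keeps only the boundary event for
    such introns unless both boundaries sit on template exon boundaries.
    """
    strand = template.strand
    exons = template.template_exons
    introns = set(template.template_introns)
    exon_starts = {s for s, _ in exons}
    exon_ends = {e for _, e in exons}
    donor_positions = {_intron_sides(j, strand)[0] for j in introns}
    acceptor_positions = {_intron_sides(j, strand)[1] for j in introns}

    events: list[ASEvent] = []

    def emit(event_type: str, start: int, end: int) -> None:
        events.append(
            ASEvent(
                gene_id=template.gene_id, event_type=event_type, chrom=template.chrom,
                start=start, end=end, support={transcript.ecotype: 1},
            )
        )

    exon_boundaries = exon_starts | exon_ends

    for intron in transcript.introns:
        s, e = intron
        if intron in introns:
            continue  # constitutive splice, consistent with template
        donor, acceptor = _intron_sides(intron, strand)
        donor_shared = donor in donor_positions
        acceptor_shared = acceptor in acceptor_positions
        skipped = [(xs, xe) for xs, xe in exons if s <= xs and xe <= e]
        es_def = bool(skipped) and s in exon_boundaries and e in exon_boundaries

        boundary_event: tuple[str, int, int] | None = None
        if donor_shared and not acceptor_shared:
            boundary_event = ("3S", s, e)
        elif acceptor_shared and not donor_shared:
            boundary_event = ("5S", s, e)
        elif not donor_shared and not acceptor_shared and not skipped:
            # both splice sites moved; only meaningful over intron territory
            # (an intron nested inside one template exon matches no category)
            if any(s < je and js < e for js, je in introns):
                boundary_event = ("3S5S", s, e)

        if es_def:
            for xs, xe in skipped:
                emit("ES", xs, xe)
            if boundary_event is not None and emit_combined:
                emit(*boundary_event)
        elif boundary_event is not None:
            emit(*boundary_event)

    template_introns = template.template_introns
    for bs, be in transcript.blocks:
        for js, je in template_introns:
            if bs < js and je < be:
                emit("IR", js, je)

    return events


def deduplicate_events(all_events: list[ASEvent]) -> list[ASEvent]:
    """Merge events on identity (gene, type, start, end), summing support."""
    merged: dict[tuple, ASEvent] = {}
    for ev in all_events:
        key = ev.identity
        if key in merged:
            tgt = merged[key]
            for eco, n in ev.support.items():
                tgt.support[eco] = tgt.support.get(eco, 0) + n
            tgt.confirmed = tgt.confirmed or ev.confirmed
        else:
            merged[key] = ASEvent(
                gene_id=ev.gene_id, event_type=ev.event_type, chrom=ev.chrom,
                start=ev.start, end=ev.end, support=dict(ev.support), confirmed=ev.confirmed,
            )
    return sorted(merged.values(), key=lambda e: (e.chrom, e.start, e.end, e.event_type, e.gene_id))


def detect_all(
    assigned: dict[str, list[SplicedAlignment]],
    emit_combined: bool = True,
) -> tuple[dict[str, GeneTemplate], list[ASEvent]]:
    """Build a template per gene, detect events for every transcript, deduplicate."""
    templates: dict[str, GeneTemplate] = {}
    raw: list[ASEvent] = []
    for gene_id in sorted(assigned):
        transcripts = assigned[gene_id]
        tpl = build_gene_template(transcripts, gene_id=gene_id)
        templates[gene_id] = tpl
        for t in transcripts:
            raw.extend(detect_events(t, tpl, emit_combined=emit_combined))
    return templates, deduplicate_events(raw)
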