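"""Detection: assignment, templates, classification vs. a definitional oracle."""

import itertools

import numpy as np
import pytest

from ecosplice import as_detection as det
from ecosplice.io_formats import GeneCatalog, GeneModel
from helpers import aln, template


# ---------------------------------------------------------------------------
# brute-force definitional oracle: enumerates every (intron, template feature)
# and (block, template intron) pair and applies the five event definitions
# literally; independent of the sweep logic in as_detection


def oracle_classify(transcript, tpl, emit_combined=True):
    out = []
    strand = tpl.strand
    tex = list(tpl.template_exons)
    tin = list(tpl.template_introns)
    boundary_set = set()
    for xs, xe in tex:
        boundary_set.update((xs, xe))

    def sides(iv):
        return (iv[0], iv[1]) if strand == "+" else (iv[1], iv[0])

    for intron in transcript.introns:
        if intron in tin:
            continue
        s, e = intron
        skipped = [x for x in tex if s <= x[0] and x[1] <= e]
        es_holds = bool(skipped) and s in boundary_set and e in boundary_set
        donor_shared = any(sides(intron)[0] == sides(j)[0] for j in tin)
        acceptor_shared = any(sides(intron)[1] == sides(j)[1] for j in tin)
        boundary = None
        if donor_shared and not acceptor_shared:
            boundary = ("3S", s, e)
        if acceptor_shared and not donor_shared:
            boundary = ("5S", s, e)
        if (not donor_shared and not acceptor_shared and not skipped
                and any(max(s, js) < min(e, je) for js, je in tin)):
            boundary = ("3S5S", s, e)
        if es_holds:
            out.extend(("ES", xs, xe) for xs, xe in skipped)
            if boundary and emit_combined:
                out.append(boundary)
        elif boundary:
            out.append(boundary)

    for bs, be in transcript.blocks:
        for js, je in tin:
            if bs < js and je < be:
                out.append(("IR", js, je))
    return sorted(out)


def classify(transcript, tpl, emit_combined=True):
    return sorted(
        (ev.event_type, ev.start, ev.end)
        for ev in det.detect_events(transcript, tpl, emit_combined=emit_combined)
    )


# ---------------------------------------------------------------------------


class TestAssignment:
    @pytest.fixture
    def catalog(self):
        return GeneCatalog([
            GeneModel("gA", "chr1", "+", 0, 1000),
            GeneModel("gB", "chr1", "+", 2000, 3000),
            GeneModel("gOv1", "chr2", "+", 0, 1000),
            GeneModel("gOv2", "chr2", "+", 500, 1500),
        ])

    def test_transcript_inside_single_gene_assigned(self, catalog):
        assigned, discarded = det.assign_transcripts([aln([(100, 400)])], catalog)
        assert set(assigned) == {"gA"} and not discarded

    def test_intergenic_transcript_discarded_no_gene(self, catalog):
        _, discarded = det.assign_transcripts([aln([(1200, 1600)])], catalog)
        assert discarded[0].reason == "no_gene"

    def test_wrong_strand_counts_as_no_gene(self, catalog):
        _, discarded = det.assign_transcripts([aln([(100, 400)], strand="-")], catalog)
        assert discarded[0].reason == "no_gene"

    def test_two_overlapping_genes_ambiguous(self, catalog):
        _, discarded = det.assign_transcripts([aln([(600, 900)], chrom="chr2")], catalog)
        assert discarded[0].reason == "ambiguous"

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            det.assign_transcripts([aln([(0, 10)])], GeneCatalog())


class TestTemplate:
    def test_single_transcript_template_identical(self):
        tpl = det.build_gene_template([aln([(0, 100), (200, 300)])])
        assert tpl.template_exons == ((0, 100), (200, 300))
        assert tpl.template_introns == ((100, 200),)

    def test_union_with_alternative_acceptor(self):
        tpl = det.build_gene_template([
            aln([(0, 100), (200, 300)]),
            aln([(0, 100), (150, 300)]),
        ])
        assert tpl.template_exons == ((0, 100), (150, 300))
        assert tpl.template_introns == ((100, 150),)

    def test_full_joint_coverage_single_exon(self):
        # intronless overlapping transcripts covering [0,300) jointly
        tpl = det.build_gene_template([aln([(0, 180)]), aln([(150, 300)])])
        assert tpl.template_exons == ((0, 300),) and tpl.template_introns == ()

    def test_spliced_intron_survives_a_readthrough_block(self):
        """A retention isoform must not erase an intron others splice."""
        tpl = det.build_gene_template([
            aln([(0, 100), (200, 300)]),
            aln([(0, 300)]),
        ])
        assert tpl.template_exons == ((0, 100), (200, 300))
        assert tpl.template_introns == ((100, 200),)

    def test_mixed_strands_rejected(self):
        with pytest.raises(ValueError):
            det.build_gene_template([aln([(0, 100)]), aln([(0, 100)], strand="-")])


TPL3 = [(0, 100), (200, 300), (400, 500)]


class TestClassification:
    def test_exon_skipping(self):
        tpl = template(TPL3)
        assert classify(aln([(0, 100), (400, 500)]), tpl) == [("ES", 200, 300)]

    def test_intron_retention(self):
        tpl = template(TPL3)
        assert classify(aln([(0, 300)]), tpl) == [("IR", 100, 200)]

    def test_donor_shift_strand_mapping(self):
        """Same geometry: 5S on + (donor moved), 3S on - (acceptor moved)."""
        # template intron (120,200); transcript intron (100,200)
        tpl = template([(0, 120), (200, 300)])
        tr = aln([(0, 100), (200, 300)])
        assert classify(tr, tpl) == [("5S", 100, 200)]
        tpl_m = template([(0, 120), (200, 300)], strand="-")
        tr_m = aln([(0, 100), (200, 300)], strand="-")
        assert classify(tr_m, tpl_m) == [("3S", 100, 200)]

    def test_both_boundaries_moved(self):
        tpl = template(TPL3)
        assert classify(aln([(0, 90), (210, 300), (400, 500)]), tpl) == [("3S5S", 90, 210)]

    def test_exact_intron_and_contained_block_emit_nothing(self):
        tpl = template(TPL3)
        assert classify(aln([(0, 100), (200, 300)]), tpl) == []
        assert classify(aln([(220, 280)]), tpl) == []

    def test_combined_skip_with_shifted_boundary(self):
        # intron (100,300): skips exon 2's territory up to its end boundary;
        # donor matches template intron 1, acceptor does not
        tpl = template([(0, 100), (200, 250), (300, 400)])
        # intron (100,250): contains exon (200,250), both ends on exon
        # boundaries; donor matches template intron 1, acceptor matches none
        got = classify(aln([(0, 100), (250, 400)]), tpl)
        assert got == sorted([("ES", 200, 250), ("3S", 100, 250)])
        off = classify(aln([(0, 100), (250, 400)]), tpl, emit_combined=False)
        assert off == [("ES", 200, 250)]

    def test_intron_skipping_two_exons_yields_two_events(self):
        tpl = template([(0, 100), (200, 300), (400, 500), (600, 700)])
        got = classify(aln([(0, 100), (600, 700)]), tpl)
        assert got == [("ES", 200, 300), ("ES", 400, 500)]


class TestDeduplication:
    def test_identity_merge_sums_support(self):
        evs = [det.detect_events(aln([(0, 100), (400, 500)], ecotype=e), template(TPL3))[0]
               for e in ["head"] * 3 + ["body"] * 2]
        (merged,) = det.deduplicate_events(evs)
        assert merged.support == {"head": 3, "body": 2}

    def test_one_bp_difference_stays_distinct(self):
        from helpers import event
        assert len(det.deduplicate_events([event(start=200), event(start=201, end=301)])) == 2

    def test_fixture_with_identity_duplicates(self):
        from helpers import event
        raw = [event(start=10 * i, end=10 * i + 5) for i in range(6)]
        raw += [event(start=0, end=5), event(start=0, end=5),
                event(start=10, end=15), event(start=20, end=25)]
        assert len(det.deduplicate_events(raw)) == 6

    def test_duplicate_transcript_adds_support_not_events(self):
        tpl = template(TPL3)
        t1 = aln([(0, 100), (400, 500)])
        single = det.deduplicate_events(det.detect_events(t1, tpl))
        double = det.deduplicate_events(
            det.detect_events(t1, tpl) + det.detect_events(aln([(0, 100), (400, 500)]), tpl))
        assert [e.identity for e in single] == [e.identity for e in double]
        assert double[0].total_support() == 2


# ---------------------------------------------------------------------------
# oracle equivalence and strand antisymmetry on generated instances


def _boundary_edit_transcripts(tpl, grid=600):
    """Transcripts formed from exon subsets and boundary edits of a template."""
    exons = tpl.template_exons
    n = len(exons)
    out = []
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            blocks = [list(exons[i]) for i in subset]
            candidates = [blocks]
            for bi in range(len(blocks)):
                for side in (0, 1):
                    for delta in (-60, -30, -10, 10, 30):
                        edited = [list(b) for b in blocks]
                        edited[bi][side] += delta
                        candidates.append(edited)
            for c in candidates:
                c = [b for b in c if b[0] < b[1] and 0 <= b[0] and b[1] <= grid]
                if not c or any(c[i][0] <= c[i - 1][1] for i in range(1, len(c))):
                    continue
                out.append(tuple(tuple(b) for b in c))
    return sorted(set(out))


def _mirror(blocks, grid=600):
    return tuple(sorted((grid - e, grid - s) for s, e in blocks))


EXON_SETS = [
    [(0, 100)],
    [(0, 100), (150, 250)],
    [(0, 100), (150, 250), (320, 400)],
    [(0, 100), (150, 250), (320, 400), (470, 560)],
    [(40, 130), (170, 260), (300, 420), (480, 590)],
]


@pytest.mark.parametrize("exons", EXON_SETS, ids=lambda x: f"{len(x)}exons")
@pytest.mark.parametrize("strand", ["+", "-"])
def test_classifier_matches_definitional_oracle(exons, strand):
    """Exhaustive boundary-edit sweep: detector == literal definitions."""
    tpl = template(exons, strand=strand)
    for blocks in _boundary_edit_transcripts(tpl):
        tr = aln(blocks, strand=strand)
        assert classify(tr, tpl) == oracle_classify(tr, tpl), (blocks, exons, strand)


@pytest.mark.parametrize("exons", EXON_SETS[1:], ids=lambda x: f"{len(x)}exons")
def test_strand_flip_swaps_donor_acceptor_types(exons):
    """Identical geometry on the opposite strand swaps 5S<->3S, fixes ES/IR/3S5S."""
    swap = {"5S": "3S", "3S": "5S", "ES": "ES", "IR": "IR", "3S5S": "3S5S"}
    tpl = template(exons, strand="+")
    tpl_f = template(exons, strand="-")
    for blocks in _boundary_edit_transcripts(tpl):
        fwd = classify(aln(blocks), tpl)
        flipped = classify(aln(blocks, strand="-"), tpl_f)
        assert sorted((swap[t], s, e) for t, s, e in fwd) == flipped, blocks


@pytest.mark.parametrize("exons", EXON_SETS[1:], ids=lambda x: f"{len(x)}exons")
def test_reverse_complement_invariance(exons):
    """Mirroring coordinates and flipping strand preserves every event type."""
    tpl = template(exons, strand="+")
    tpl_m = template([tuple(iv) for iv in _mirror(exons)], strand="-")
    for blocks in _boundary_edit_transcripts(tpl):
        fwd = classify(aln(blocks), tpl)
        rev = classify(aln(_mirror(blocks), strand="-"), tpl_m)
        assert sorted(t for t, _, _ in fwd) == sorted(t for t, _, _ in rev), blocks


def test_exclusivity_of_boundary_types():
    """No intron ever yields two of {5S, 3S, 3S5S}; ES co-occurs only with one."""
    rng = np.random.default_rng(7)
    for _ in range(300):
        n = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(10, 590, 10), size=2 * n, replace=False))
        exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n)]
        tpl = template(exons, strand="+" if rng.random() < 0.5 else "-")
        edits = _boundary_edit_transcripts(tpl)
        for blocks in [edits[i] for i in rng.choice(len(edits), size=min(20, len(edits)), replace=False)]:
            tr = aln(blocks, strand=tpl.strand)
            events = det.detect_events(tr, tpl)
            per_intron = {}
            for ev in events:
                if ev.event_type in ("5S", "3S", "3S5S"):
                    per_intron.setdefault((ev.start, ev.end), []).append(ev.event_type)
            for types in per_intron.values():
                assert len(types) == 1
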