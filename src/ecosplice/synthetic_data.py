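"""Seed-reproducible synthetic datasets with an exact ground-truth manifest.

The simulator emulates the two-pool comparative design the pipeline
analyses: a shared gene catalog, one spliced-transcript pool per ecotype
(default labels ``head`` and ``body``), a short-read splice-junction file,
a GO annotation map and curated gene lists — all in exactly the formats
:mod:`ecosplice.io_formats` reads.

Each gene gets a multi-exon reference isoform; a configurable fraction of
genes carries one planted AS event, realised as a concrete geometric edit
of the reference isoform matching one of the five event definitions (exon
skipped, intron retained, donor/acceptor shifted). Truth labels are
therefore exact, not probabilistic. Event categories (shared /
A-specific / B-specific) decide which ecotype's pool contains transcripts
exhibiting the edit.

Junctions are emitted per planted event: with probability
``junction_confirm_prob`` a junction matching one event boundary is
written (the event is *confirmable*); noise junctions are placed at least
2 bp away from every true event boundary so they can never accidentally
confirm anything. Constitutive junctions are deliberately not emitted —
the junction file exists only to drive confirmation, and omitting them
keeps the confirmable label exact.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    GeneModel,
    Junction,
    SplicedAlignment,
    write_bed12,
    write_gff3,
    write_junctions,
)

EVENT_TYPES = ("ES", "5S", "3S", "3S5S", "IR")
CATEGORIES = ("shared", "A_specific", "B_specific")


@dataclass
class SimulationConfig:
    """All knobs of the simulator; same seed -> byte-identical output files."""

    n_genes: int = 1000
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (60, 400)
    intergenic_len: tuple[int, int] = (500, 2000)
    transcripts_per_gene: tuple[int, int] = (12, 25)  # per ecotype
    frac_genes_with_events: float = 0.36
    #: probability vector over (ES, 5S, 3S, 3S5S, IR) per event category;
    #: ES most prevalent, as in metazoan transcriptomes generally
    event_mixture: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "shared": (0.35, 0.15, 0.2, 0.1, 0.2),
            "A_specific": (0.35, 0.15, 0.2, 0.1, 0.2),
            "B_specific": (0.35, 0.15, 0.2, 0.1, 0.2),
        }
    )
    #: category split of planted events, matching the observed louse
    #: partition (4,771 shared / 1,415 head- / 2,183 body-specific of 8,369)
    frac_shared: float = 0.57
    frac_A_specific: float = 0.17
    frac_B_specific: float = 0.26
    #: fraction of transcripts of a carrying ecotype that exhibit the event
    alt_isoform_frac: float = 0.4
    #: short reads confirmed 76.49% of detected events in the source data
    junction_confirm_prob: float = 0.7649
    noise_junction_rate: float = 0.0  # spurious junctions per kb of genome
    n_go_terms: int = 12
    go_term_gene_frac: float = 0.15  # baseline membership probability per (gene, term)
    #: (term_id, category, fold): multiply membership prob for genes whose
    #: planted event belongs to the category
    planted_go_bias: tuple[str, str, float] | None = None
    ecotypes: tuple[str, str] = ("head", "body")
    seed: int = 0

    def validate(self) -> None:
        fr = (self.frac_shared, self.frac_A_specific, self.frac_B_specific)
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        for cat, mix in self.event_mixture.items():
            if len(mix) != 5 or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"event mixture for {cat} must be 5 probabilities summing to 1")
        for lo, hi in (self.exons_per_gene, self.exon_len, self.intron_len,
                       self.transcripts_per_gene, self.intergenic_len):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be (lo, hi) with 1 <= lo <= hi")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need >= 3 exons so every event type has room")
        if not 0 <= self.frac_genes_with_events <= 1:
            raise ValueError("frac_genes_with_events must be a proportion")


@dataclass
class PlantedEvent:
    gene_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    category: str  # shared | A_specific | B_specific
    confirmable: bool


@dataclass
class TruthManifest:
    """Exact bookkeeping of everything the simulator planted."""

    events: list[PlantedEvent]
    gene_go: dict[str, list[str]]
    gene_lists: dict[str, list[str]]
    expected_partition: dict[str, int]

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "events": [dataclasses.asdict(e) for e in self.events],
            "gene_go": self.gene_go,
            "gene_lists": self.gene_lists,
            "expected_partition": self.expected_partition,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            events=[PlantedEvent(**e) for e in payload["events"]],
            gene_go=payload["gene_go"],
            gene_lists=payload["gene_lists"],
            expected_partition=payload["expected_partition"],
        )


@dataclass
class _SimGene:
    model: GeneModel
    exons: list[tuple[int, int]]  # reference isoform

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]


def _make_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[_SimGene]:
    genes = []
    pos = 0
    chrom_idx = 0
    genes_per_chrom = max(1, cfg.n_genes // 8)
    for i in range(cfg.n_genes):
        if i % genes_per_chrom == 0 and i > 0:
            chrom_idx += 1
            pos = 0
        pos += int(rng.integers(cfg.intergenic_len[0], cfg.intergenic_len[1] + 1))
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exons = []
        cursor = pos
        for j in range(n_ex):
            ex_len = int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
            exons.append((cursor, cursor + ex_len))
            cursor += ex_len
            if j < n_ex - 1:
                cursor += int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"GENE{i:05d}"
        genes.append(
            _SimGene(
                model=GeneModel(gene_id, f"chr{chrom_idx + 1}", strand, exons[0][0], exons[-1][1]),
                exons=exons,
            )
        )
        pos = exons[-1][1]
    return genes


def _plant_edit(
    gene: _SimGene, event_type: str, rng: np.random.Generator, min_intron: int = 40
) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Edit the reference isoform to exhibit one event; return (blocks, interval).

    The returned interval is the event interval the detector should report:
    the skipped exon for ES, the retained template intron for IR, and the
    modified transcript intron for the boundary types. Donor/acceptor sides
    are strand-aware, so a 5S on a minus-strand gene shifts the intron's
    right-hand genomic boundary.
    """
    exons = [list(e) for e in gene.exons]
    n = len(exons)
    strand = gene.model.strand
    # internal exon / intron the edit applies to
    ex_i = int(rng.integers(1, n - 1))         # internal exon index
    iv_i = int(rng.integers(0, n - 1))         # intron index

    if event_type == "ES":
        interval = tuple(exons[ex_i])
        blocks = exons[:ex_i] + exons[ex_i + 1:]
        return [tuple(b) for b in blocks], interval

    if event_type == "IR":
        js, je = gene.introns[iv_i]
        blocks = exons[:iv_i] + [[exons[iv_i][0], exons[iv_i + 1][1]]] + exons[iv_i + 2:]
        return [tuple(b) for b in blocks], (js, je)

    js, je = gene.introns[iv_i]
    left_len = exons[iv_i][1] - exons[iv_i][0]
    right_len = exons[iv_i + 1][1] - exons[iv_i + 1][0]
    # shift a boundary into the flanking exon, keeping >=1 bp of exon and
    # an intron still >= min_intron; shifting outward (into the intron)
    # would create boundaries inside intron territory — inward only
    max_left = min(left_len - 1, 50)
    max_right = min(right_len - 1, 50)
    shift_l = int(rng.integers(2, max_left + 1))
    shift_r = int(rng.integers(2, max_right + 1))
    move_start = (event_type == "5S") == (strand == "+")  # which genomic side is the donor
    if event_type in ("5S", "3S"):
        if move_start:
            exons[iv_i][1] = js - shift_l
            interval = (js - shift_l, je)
        else:
            exons[iv_i + 1][0] = je + shift_r
            interval = (js, je + shift_r)
    else:  # 3S5S: both boundaries move
        exons[iv_i][1] = js - shift_l
        exons[iv_i + 1][0] = je + shift_r
        interval = (js - shift_l, je + shift_r)
    return [tuple(b) for b in exons], interval


def simulate_dataset(cfg: SimulationConfig, outdir: str | os.PathLike) -> TruthManifest:
    """Write the full synthetic file set into ``outdir``; return the manifest.

    Files: ``genes.gff3``, ``transcripts_<ecotype>.bed`` (x2),
    ``junctions.tsv``, ``go_map.tsv``, ``genes_<list>.txt``,
    ``manifest.json``.
    """
    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genes = _make_genes(cfg, rng)
    eco_a, eco_b = cfg.ecotypes

    n_events = int(round(cfg.frac_genes_with_events * cfg.n_genes))
    event_gene_idx = rng.choice(cfg.n_genes, size=n_events, replace=False)
    categories = rng.choice(
        CATEGORIES, size=n_events,
        p=[cfg.frac_shared, cfg.frac_A_specific, cfg.frac_B_specific],
    )

    planted: list[PlantedEvent] = []
    alignments: dict[str, list[SplicedAlignment]] = {eco_a: [], eco_b: []}
    junctions: list[Junction] = []
    protected: set[tuple[str, int]] = set()  # true boundaries noise must avoid

    edits: dict[str, tuple[list[tuple[int, int]], PlantedEvent]] = {}
    for gi, cat in zip(event_gene_idx, categories):
        gene = genes[gi]
        etype = str(rng.choice(EVENT_TYPES, p=cfg.event_mixture[cat]))
        blocks, interval = _plant_edit(gene, etype, rng)
        confirmable = bool(rng.random() < cfg.junction_confirm_prob)
        ev = PlantedEvent(
            gene_id=gene.model.gene_id, event_type=etype, chrom=gene.model.chrom,
            start=interval[0], end=interval[1], category=cat, confirmable=confirmable,
        )
        planted.append(ev)
        edits[gene.model.gene_id] = (blocks, ev)
        protected.add((ev.chrom, ev.start))
        protected.add((ev.chrom, ev.end))
        if confirmable:
            junctions.append(_confirming_junction(gene, ev))

    # transcript pools: reference isoform plus, on carrier genes, the edited
    # isoform in the carrying ecotype(s)
    t_counter = 0
    for gene in genes:
        edit = edits.get(gene.model.gene_id)
        for eco in (eco_a, eco_b):
            n_tr = int(rng.integers(cfg.transcripts_per_gene[0], cfg.transcripts_per_gene[1] + 1))
            carries = edit is not None and (
                edit[1].category == "shared"
                or (edit[1].category == "A_specific" and eco == eco_a)
                or (edit[1].category == "B_specific" and eco == eco_b)
            )
            n_alt = max(1, int(round(cfg.alt_isoform_frac * n_tr))) if carries else 0
            for k in range(n_tr):
                blocks = edit[0] if k < n_alt else tuple(gene.exons)
                alignments[eco].append(
                    SplicedAlignment(
                        transcript_id=f"T{t_counter:07d}", ecotype=eco,
                        chrom=gene.model.chrom, strand=gene.model.strand,
                        blocks=tuple(tuple(b) for b in blocks),
                    )
                )
                t_counter += 1

    junctions.extend(_noise_junctions(cfg, genes, protected, rng))

    gene_go, gene_lists = _annotations(cfg, genes, edits, rng)
    manifest = TruthManifest(
        events=planted, gene_go=gene_go, gene_lists=gene_lists,
        expected_partition=_expected_partition(planted),
    )

    write_gff3([g.model for g in genes], os.path.join(outdir, "genes.gff3"))
    for eco in (eco_a, eco_b):
        alignments[eco].sort(key=lambda a: (a.chrom, a.span[0], a.transcript_id))
        write_bed12(alignments[eco], os.path.join(outdir, f"transcripts_{eco}.bed"))
    write_junctions(junctions, os.path.join(outdir, "junctions.tsv"))
    _write_annotations(cfg, gene_go, gene_lists, outdir)
    manifest.to_json(os.path.join(outdir, "manifest.json"))
    return manifest


def _confirming_junction(gene: _SimGene, ev: PlantedEvent) -> Junction:
    """A genuinely attainable junction matching >=1 boundary of the event."""
    if ev.event_type == "ES":
        # the constitutive intron upstream of the skipped exon ends exactly
        # at the exon start: its acceptor confirms the event
        for js, je in gene.introns:
            if je == ev.start:
                return Junction(ev.chrom, js, je, gene.model.strand)
        raise AssertionError("skipped exon must have an upstream intron")
    # IR: the spliced isoform's intron is the event interval itself;
    # boundary types: the modified intron is the event interval
    return Junction(ev.chrom, ev.start, ev.end, gene.model.strand)


def _noise_junctions(
    cfg: SimulationConfig,
    genes: list[_SimGene],
    protected: set[tuple[str, int]],
    rng: np.random.Generator,
) -> list[Junction]:
    if cfg.noise_junction_rate <= 0:
        return []
    out = []
    by_chrom: dict[str, int] = {}
    for g in genes:
        by_chrom[g.model.chrom] = max(by_chrom.get(g.model.chrom, 0), g.model.end)
    forbidden = {(c, p + d) for c, p in protected for d in (-2, -1, 0, 1, 2)}
    for chrom, length in sorted(by_chrom.items()):
        n = rng.poisson(cfg.noise_junction_rate * length / 1000.0)
        for _ in range(n):
            s = int(rng.integers(0, max(1, length - 200)))
            e = s + int(rng.integers(60, 200))
            if (chrom, s) in forbidden or (chrom, e) in forbidden:
                continue
            out.append(Junction(chrom, s, e, "?"))
    return out


def _annotations(cfg, genes, edits, rng):
    terms = [f"GO:{i:07d}" for i in range(cfg.n_go_terms)]
    gene_go: dict[str, list[str]] = {}
    for g in genes:
        gid = g.model.gene_id
        ev = edits.get(gid, (None, None))[1]
        assigned = []
        for t in terms:
            p = cfg.go_term_gene_frac
            if (
                cfg.planted_go_bias is not None
                and t == cfg.planted_go_bias[0]
                and ev is not None
                and ev.category == cfg.planted_go_bias[1]
            ):
                p = min(1.0, p * cfg.planted_go_bias[2])
            if rng.random() < p:
                assigned.append(t)
        if assigned:
            gene_go[gid] = assigned
    # two curated lists: one random, one built from a random term's members
    all_ids = [g.model.gene_id for g in genes]
    random_list = sorted(rng.choice(all_ids, size=max(5, cfg.n_genes // 20), replace=False))
    term0_members = sorted(g for g, ts in gene_go.items() if terms[0] in ts)
    gene_lists = {"random": list(random_list), "term0_members": term0_members}
    return gene_go, gene_lists


def _write_annotations(cfg, gene_go, gene_lists, outdir) -> None:
    with open(os.path.join(outdir, "go_map.tsv"), "w") as fh:
        fh.write("gene_id\tterm_id\tterm_name\n")
        for gid in sorted(gene_go):
            for t in sorted(gene_go[gid]):
                fh.write(f"{gid}\t{t}\tterm {t}\n")
    for name, members in gene_lists.items():
        with open(os.path.join(outdir, f"genes_{name}.txt"), "w") as fh:
            fh.write("\n".join(members) + "\n")


def _expected_partition(planted: list[PlantedEvent]) -> dict[str, int]:
    """Partition counts the pipeline should recover among confirmable events."""
    conf = [e for e in planted if e.confirmable]
    shared = sum(1 for e in conf if e.category == "shared")
    spec_a = sum(1 for e in conf if e.category == "A_specific")
    spec_b = sum(1 for e in conf if e.category == "B_specific")
    return {
        "total_confirmed": len(conf),
        "observed_A": shared + spec_a,
        "observed_B": shared + spec_b,
        "shared": shared,
        "specific_A": spec_a,
        "specific_B": spec_b,
    }


def end_to_end_recovery_report(
    manifest: TruthManifest,
    detected_events: list,
    partition_counts: dict[str, int] | None = None,
) -> dict:
    """Recall/precision of detected-and-confirmed events against the manifest.

    Detected events are compared on (gene, type, start, end); only
    confirmable planted events count toward recall (the others cannot be
    confirmed by construction). Precision is computed over confirmed
    detected events.
    """
    truth = {(e.gene_id, e.event_type, e.start, e.end): e for e in manifest.events}
    truth_confirmable = {k for k, e in truth.items() if e.confirmable}
    detected_confirmed = {ev.identity for ev in detected_events if ev.confirmed}
    if truth_confirmable and detected_confirmed and not (truth_confirmable & detected_confirmed):
        raise ValueError(
            "pipeline outputs share no events with the manifest; "
            "were they produced from a different simulation run?"
        )

    by_type: dict[str, dict[str, float]] = {}
    for etype in EVENT_TYPES:
        t = {k for k in truth_confirmable if k[1] == etype}
        d = {k for k in detected_confirmed if k[1] == etype}
        by_type[etype] = {
            "recall": len(t & d) / len(t) if t else float("nan"),
            "precision": len(t & d) / len(d) if d else float("nan"),
            "n_truth": len(t), "n_detected": len(d),
        }
    report = {
        "recall_overall": len(truth_confirmable & detected_confirmed) / len(truth_confirmable)
        if truth_confirmable else float("nan"),
        "precision_overall": len(truth_confirmable & detected_confirmed) / len(detected_confirmed)
        if detected_confirmed else float("nan"),
        "by_type": by_type,
    }
    if partition_counts is not None:
        report["partition_delta"] = {
            k: partition_counts.get(k, 0) - v for k, v in manifest.expected_partition.items()
        }
    return report
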