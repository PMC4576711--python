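"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are 0-based, half-open internally; conversion to and
from 1-based inclusive conventions (GFF3) happens only here, at the I/O
boundary. Everything downstream can therefore compare boundaries by exact
integer equality.

Formats handled:

* GFF3 gene annotation -> :class:`GeneCatalog`
* BED12 spliced transcript alignments -> :class:`SplicedAlignment`
* splice-junction TSV (``chrom  intron_start  intron_end  strand``,
  0-based half-open) -> :class:`JunctionSet`
* GO map TSV (``gene_id  term_id  term_name``) and flat gene lists
* distinct-event and partition tables as TSV
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: alignment gaps shorter than this are treated as indels and merged,
#: not as introns; below the shortest credible arthropod intron
DEFAULT_MIN_INTRON = 40

EVENT_TYPES = ("ES", "5S", "3S", "3S5S", "IR")

EVENTS_COLUMNS = [
    "gene_id", "event_type", "chrom", "start", "end",
    "support_head", "support_body", "confirmed",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene locus: the anchor for transcript assignment."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end ({self.start} >= {self.end})")


class GeneCatalog:
    """Set of gene models with O(log n) interval lookup per chromosome."""

    def __init__(self, genes: list[GeneModel] | None = None):
        self._genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes or []:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise FormatError(f"duplicate gene_id {gene.gene_id!r}")
        self._genes[gene.gene_id] = gene
        self._trees.setdefault(gene.chrom, IntervalTree()).addi(gene.start, gene.end, gene)

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __iter__(self):
        return iter(self._genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> set[str]:
        return set(self._genes)

    def overlapping(self, chrom: str, start: int, end: int, strand: str | None = None) -> list[GeneModel]:
        """Genes whose extent overlaps [start, end), optionally strand-matched."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))


@dataclass(frozen=True)
class SplicedAlignment:
    """One transcript's exon blocks on the genome, labeled with its ecotype.

    ``blocks`` are sorted, non-overlapping, 0-based half-open exon intervals;
    ``introns`` are the gaps between consecutive blocks. Blocks and introns
    tile ``[span[0], span[1])`` exactly.
    """

    transcript_id: str
    ecotype: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.blocks:
            raise ValueError(f"{self.transcript_id}: at least one block required")
        prev_end = None
        for s, e in self.blocks:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty block ({s},{e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.transcript_id}: blocks overlap or out of order")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0]) for i in range(len(self.blocks) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return (self.blocks[0][0], self.blocks[-1][1])


def merge_small_gaps(blocks: list[tuple[int, int]], min_intron: int) -> tuple[tuple[int, int], ...]:
    """Merge consecutive blocks whose gap is < ``min_intron`` (indels, not introns)."""
    merged: list[list[int]] = [list(blocks[0])]
    for s, e in blocks[1:]:
        if s - merged[-1][1] < min_intron:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class Junction:
    """One short-read-supported intron; donor < acceptor, 0-based half-open."""

    chrom: str
    donor: int
    acceptor: int
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise FormatError(f"junction {self.chrom}:{self.donor}-{self.acceptor}: donor must be < acceptor")


class JunctionSet:
    """Deduplicated junctions with exact (chrom, position) end lookup."""

    def __init__(self, junctions: list[Junction] | None = None):
        self._junctions: set[tuple[str, int, int]] = set()
        self._ends: set[tuple[str, int]] = set()
        for j in junctions or []:
            self.add(j)

    def add(self, junction: Junction) -> None:
        key = (junction.chrom, junction.donor, junction.acceptor)
        if key in self._junctions:
            return
        self._junctions.add(key)
        self._ends.add((junction.chrom, junction.donor))
        self._ends.add((junction.chrom, junction.acceptor))

    def __len__(self) -> int:
        return len(self._junctions)

    def has_end(self, chrom: str, position: int) -> bool:
        """True iff some junction's donor or acceptor sits exactly here."""
        return (chrom, position) in self._ends

    def union(self, other: "JunctionSet") -> "JunctionSet":
        out = JunctionSet()
        for chrom, d, a in self._junctions | other._junctions:
            out.add(Junction(chrom, d, a))
        return out


@dataclass
class ASEvent:
    """A distinct alternative-splicing event on a gene.

    Identity is the tuple ``(gene_id, event_type, start, end)``; ``support``
    counts transcripts exhibiting the event per ecotype.
    """

    gene_id: str
    event_type: str
    chrom: str
    start: int
    end: int
    support: dict[str, int] = field(default_factory=dict)
    confirmed: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.start < self.end:
            raise ValueError(f"event {self.gene_id}:{self.start}-{self.end}: start must be < end")

    @property
    def identity(self) -> tuple[str, str, int, int]:
        return (self.gene_id, self.event_type, self.start, self.end)

    def total_support(self) -> int:
        return sum(self.support.values())


# ---------------------------------------------------------------------------
# readers


def read_gene_annotation(path: str | os.PathLike) -> GeneCatalog:
    """Read gene features from a GFF3 file into a :class:`GeneCatalog`.

    GFF3 1-based inclusive [start, end] becomes 0-based half-open
    [start-1, end). Only features of type ``gene`` are used.
    """
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
    except gffutils.exceptions.EmptyInputError:
        return GeneCatalog()  # header-only annotation: a valid empty catalog
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise FormatError(f"malformed GFF3 {path}: {exc}") from exc
    catalog = GeneCatalog()
    for feat in db.features_of_type("gene"):
        gene_id = feat.id
        catalog.add(GeneModel(gene_id=gene_id, chrom=feat.seqid, strand=feat.strand,
                              start=feat.start - 1, end=feat.end))
    return catalog


def read_spliced_alignments(
    path: str | os.PathLike,
    ecotype: str,
    min_intron: int = DEFAULT_MIN_INTRON,
) -> list[SplicedAlignment]:
    """Read BED12 transcript alignments, one :class:`SplicedAlignment` per record.

    Blocks are rebuilt from blockStarts/blockSizes; inter-block gaps shorter
    than ``min_intron`` are merged into one block.
    """
    alignments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(fields)}")
            chrom, chrom_start, _, name, _, strand = fields[0], int(fields[1]), fields[2], fields[3], fields[4], fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(
                    f"{path}:{lineno}: blockCount={n_blocks} disagrees with "
                    f"blockSizes ({len(sizes)}) / blockStarts ({len(starts)})"
                )
            blocks = [(chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)]
            for i in range(1, len(blocks)):
                if blocks[i][0] < blocks[i - 1][1]:
                    raise FormatError(f"{path}:{lineno}: blocks out of order or overlapping")
            alignments.append(
                SplicedAlignment(
                    transcript_id=name, ecotype=ecotype, chrom=chrom, strand=strand,
                    blocks=merge_small_gaps(blocks, min_intron),
                )
            )
    return alignments


def read_junctions(path: str | os.PathLike) -> JunctionSet:
    """Read a junction TSV (chrom, intron_start, intron_end, strand; 0-based half-open)."""
    out = JunctionSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[3] if len(fields) > 3 else "?"
            if start >= end:
                raise FormatError(f"{path}:{lineno}: intron_start {start} >= intron_end {end}")
            out.add(Junction(chrom, start, end, strand))
    return out


def read_gene_list(path: str | os.PathLike, catalog: GeneCatalog) -> tuple[set[str], int]:
    """Read a one-ID-per-line gene list restricted to catalog genes.

    Returns ``(gene_set, n_dropped)``; unresolvable IDs are logged and dropped.
    An empty file is an error (misconfiguration, not an empty set).
    """
    ids = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                ids.append(token)
    if not ids:
        raise FormatError(f"{path}: gene list is empty")
    kept = {g for g in ids if g in catalog}
    dropped = len(set(ids)) - len(kept)
    if dropped:
        logger.warning("%s: dropped %d gene IDs not in catalog", path, dropped)
    return kept, dropped


def read_go_map(path: str | os.PathLike, catalog: GeneCatalog) -> tuple[dict[str, set[str]], int]:
    """Read a GO map TSV (gene_id, term_id[, term_name]) -> gene -> {terms}.

    Rows for genes absent from the catalog are dropped (count returned).
    """
    mapping: dict[str, set[str]] = {}
    dropped_genes: set[str] = set()
    n_rows = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: expected >=2 columns per row")
            gene_id, term_id = fields[0], fields[1]
            n_rows += 1
            if gene_id not in catalog:
                dropped_genes.add(gene_id)
                continue
            mapping.setdefault(gene_id, set()).add(term_id)
    if n_rows == 0:
        raise FormatError(f"{path}: GO map is empty")
    if dropped_genes:
        logger.warning("%s: dropped %d gene IDs not in catalog", path, len(dropped_genes))
    return mapping, len(dropped_genes)


def invert_gene_sets(gene_to_terms: dict[str, set[str]]) -> dict[str, set[str]]:
    """Invert a gene -> terms map into term -> genes."""
    inv: dict[str, set[str]] = {}
    for gene, terms in gene_to_terms.items():
        for t in terms:
            inv.setdefault(t, set()).add(gene)
    return inv


# ---------------------------------------------------------------------------
# event-table round trip


def events_to_frame(events: list[ASEvent], ecotypes: tuple[str, str] = ("head", "body")) -> pd.DataFrame:
    a, b = ecotypes
    rows = [
        {
            "gene_id": ev.gene_id, "event_type": ev.event_type, "chrom": ev.chrom,
            "start": ev.start, "end": ev.end,
            "support_head": ev.support.get(a, 0), "support_body": ev.support.get(b, 0),
            "confirmed": ev.confirmed,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def write_events(events: list[ASEvent], path: str | os.PathLike,
                 ecotypes: tuple[str, str] = ("head", "body")) -> None:
    events_to_frame(events, ecotypes).to_csv(path, sep="\t", index=False)


def read_events(path: str | os.PathLike,
                ecotypes: tuple[str, str] = ("head", "body")) -> list[ASEvent]:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENTS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    a, b = ecotypes
    events = []
    for row in df.itertuples(index=False):
        support = {}
        if row.support_head:
            support[a] = int(row.support_head)
        if row.support_body:
            support[b] = int(row.support_body)
        events.append(
            ASEvent(gene_id=row.gene_id, event_type=row.event_type, chrom=row.chrom,
                    start=int(row.start), end=int(row.end), support=support,
                    confirmed=bool(row.confirmed))
        )
    return events


# ---------------------------------------------------------------------------
# writers used by the simulator and pipeline


def write_gff3(genes: list[GeneModel], path: str | os.PathLike) -> None:
    """Write gene features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tecosplice\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_bed12(alignments: list[SplicedAlignment], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            start, end = aln.span
            sizes = ",".join(str(e - s) for s, e in aln.blocks)
            starts = ",".join(str(s - start) for s, e in aln.blocks)
            fh.write(
                f"{aln.chrom}\t{start}\t{end}\t{aln.transcript_id}\t0\t{aln.strand}\t"
                f"{start}\t{end}\t0\t{len(aln.blocks)}\t{sizes}\t{starts}\n"
            )


def write_junctions(junctions: list[Junction], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tintron_start\tintron_end\tstrand\n")
        for j in sorted(junctions, key=lambda j: (j.chrom, j.donor, j.acceptor)):
            fh.write(f"{j.chrom}\t{j.donor}\t{j.acceptor}\t{j.strand}\n")
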