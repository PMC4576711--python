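"""Junction confirmation of AS events and ecotype-specificity partitioning.

An event is *confirmed* when a short-read splice junction end (donor or
acceptor) exactly matches at least one of the event's genomic boundaries on
the same chromosome — a coordinate-only rule; junction strand is ignored.
Only confirmed events enter the shared / ecotype-specific partition and all
downstream enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ASEvent, GeneCatalog, JunctionSet

SHARED = "shared"


@dataclass(frozen=True)
class PartitionCounts:
    """Set arithmetic over confirmed events observed in two ecotypes.

    With O_A events observed in ecotype A, O_B in B and T confirmed in total:
    shared = O_A + O_B - T, specific_A = T - O_B, specific_B = T - O_A.
    """

    total_confirmed: int
    observed_a: int
    observed_b: int

    @property
    def shared(self) -> int:
        return self.observed_a + self.observed_b - self.total_confirmed

    @property
    def specific_a(self) -> int:
        return self.total_confirmed - self.observed_b

    @property
    def specific_b(self) -> int:
        return self.total_confirmed - self.observed_a

    def validate(self) -> None:
        if self.shared < 0 or self.specific_a < 0 or self.specific_b < 0:
            raise ValueError(f"inconsistent partition counts: {self}")
        assert self.specific_a + self.specific_b + self.shared == self.total_confirmed

    def as_dict(self) -> dict[str, int]:
        return {
            "total_confirmed": self.total_confirmed,
            "observed_A": self.observed_a,
            "observed_B": self.observed_b,
            "shared": self.shared,
            "specific_A": self.specific_a,
            "specific_B": self.specific_b,
        }


@dataclass(frozen=True)
class GeneSpecificitySets:
    """Genes carrying at least one ecotype-specific event, per ecotype."""

    genes_specific_a: frozenset[str]
    genes_specific_b: frozenset[str]

    @property
    def genes_both(self) -> frozenset[str]:
        return self.genes_specific_a & self.genes_specific_b

    @property
    def genes_union(self) -> frozenset[str]:
        return self.genes_specific_a | self.genes_specific_b

    def counts(self) -> dict[str, int]:
        return {
            "genes_specific_A": len(self.genes_specific_a),
            "genes_specific_B": len(self.genes_specific_b),
            "genes_both": len(self.genes_both),
            "genes_union": len(self.genes_union),
        }


def confirm_events(events: list[ASEvent], junctions: JunctionSet) -> list[ASEvent]:
    """Set ``confirmed`` on each event; all events are returned, flag set.

    Confirmation requires a junction end equal to the event start or end.
    """
    for ev in events:
        ev.confirmed = junctions.has_end(ev.chrom, ev.start) or junctions.has_end(ev.chrom, ev.end)
    return events


def specificity_label(event: ASEvent, ecotypes: tuple[str, str]) -> str:
    """``shared`` / ``A_only`` / ``B_only`` from the event's support counts."""
    a, b = ecotypes
    in_a = event.support.get(a, 0) > 0
    in_b = event.support.get(b, 0) > 0
    if not (in_a or in_b):
        raise ValueError(f"event {event.identity} has zero total support")
    if in_a and in_b:
        return SHARED
    return "A_only" if in_a else "B_only"


def partition_specificity(
    confirmed_events: list[ASEvent], ecotypes: tuple[str, str] = ("head", "body")
) -> tuple[PartitionCounts, list[str]]:
    """Partition confirmed events into shared / A-only / B-only.

    Returns the counts and the per-event label list (parallel to input).
    """
    labels = [specificity_label(ev, ecotypes) for ev in confirmed_events]
    a, b = ecotypes
    observed_a = sum(1 for ev in confirmed_events if ev.support.get(a, 0) > 0)
    observed_b = sum(1 for ev in confirmed_events if ev.support.get(b, 0) > 0)
    counts = PartitionCounts(
        total_confirmed=len(confirmed_events), observed_a=observed_a, observed_b=observed_b
    )
    counts.validate()
    return counts, labels


def gene_specificity_sets(
    labeled_events: list[tuple[ASEvent, str]], catalog: GeneCatalog | None = None
) -> GeneSpecificitySets:
    """Genes with >=1 A-only event (resp. B-only), from labeled confirmed events."""
    genes_a, genes_b = set(), set()
    for ev, label in labeled_events:
        if catalog is not None and ev.gene_id not in catalog:
            raise ValueError(f"event gene {ev.gene_id!r} not in catalog")
        if label == "A_only":
            genes_a.add(ev.gene_id)
        elif label == "B_only":
            genes_b.add(ev.gene_id)
    return GeneSpecificitySets(frozenset(genes_a), frozenset(genes_b))


def confirmation_rate(n_confirmed: int, n_total: int) -> float:
    """Percentage of detected events confirmed by junctions (e.g. 76.49)."""
    if n_total <= 0:
        raise ValueError("no events detected")
    return 100.0 * n_confirmed / n_total
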