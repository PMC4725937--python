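"""Shared record types for SAG assemblies.

A single-cell amplified genome (SAG) arrives as a set of assembled contigs
plus a per-gene annotation table.  Everything downstream — GC/size/taxonomy
filtering, tetranucleotide ordination, marker-based completeness — consumes
the three containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Contig", "GeneCall", "SAGAssembly", "MarkerSet"]

_DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class Contig:
    """One assembled contig: the unit on which every QC filter decides."""

    id: str
    sequence: str
    source_sag: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneCall:
    """An annotated gene on a contig.

    Coordinates are 1-based inclusive (GFF convention).  ``taxon_domain`` /
    ``taxon_phylum`` carry the best-hit classification used by the gene-content
    filter; ``marker_id`` is set when the gene is a single-copy marker.
    Strand is carried for completeness but no filter consults it.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    taxon_domain: str = "unclassified"
    taxon_phylum: str = "unclassified"
    marker_id: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid coordinates "
                f"start={self.start} end={self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")


@dataclass
class SAGAssembly:
    """One SAG: contigs, gene calls and free-form sample metadata."""

    sag_id: str
    contigs: list[Contig] = field(default_factory=list)
    genes: list[GeneCall] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"assembly {self.sag_id!r}: duplicate contig IDs {dup}")
        known = set(ids)
        for g in self.genes:
            if g.contig_id not in known:
                raise ValueError(
                    f"assembly {self.sag_id!r}: gene {g.gene_id!r} references "
                    f"unknown contig {g.contig_id!r}"
                )
            contig = self.contig(g.contig_id)
            if g.end > contig.length:
                raise ValueError(
                    f"gene {g.gene_id!r}: end={g.end} exceeds contig "
                    f"{g.contig_id!r} length {contig.length}"
                )

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    def genes_on(self, contig_id: str) -> list[GeneCall]:
        return [g for g in self.genes if g.contig_id == contig_id]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def marker_hits(self) -> dict[str, list[str]]:
        """Map marker_id -> contig IDs carrying it (contig listed once per copy)."""
        hits: dict[str, list[str]] = {}
        for g in self.genes:
            if g.marker_id:
                hits.setdefault(g.marker_id, []).append(g.contig_id)
        return hits

    def subset(self, contig_ids: set[str], sag_id: str | None = None) -> "SAGAssembly":
        """New assembly restricted to the given contigs (genes follow)."""
        return SAGAssembly(
            sag_id=sag_id or self.sag_id,
            contigs=[c for c in self.contigs if c.id in contig_ids],
            genes=[g for g in self.genes if g.contig_id in contig_ids],
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class MarkerSet:
    """An ordered list of unique single-copy marker gene IDs."""

    name: str
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.marker_ids) < 1:
            raise ValueError(f"marker set {self.name!r}: empty")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            dup = sorted(
                {m for m in self.marker_ids if self.marker_ids.count(m) > 1}
            )
            raise ValueError(f"marker set {self.name!r}: duplicate IDs {dup}")

    @property
    def size(self) -> int:
        return len(self.marker_ids)

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in set(self.marker_ids)
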