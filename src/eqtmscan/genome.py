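"""Core genomic domain types shared across the pipeline.

Coordinates are 0-based, half-open internally (BED native on I/O). A CpG is a
point coordinate at the C of the CpG dinucleotide. TSS/TES are strand-aware
point coordinates: for a ``+`` strand gene TSS = span start and TES = span end;
for a ``-`` strand gene the roles are swapped, so ``tss > tes`` when stored
strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class AnnotationError(ValueError):
    """Raised for malformed gene models or unresolvable annotations."""


@dataclass(frozen=True)
class CpGSite:
    cpg_id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise AnnotationError(f"{self.cpg_id}: negative position {self.pos}")


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES and ordered exons.

    ``exons`` are half-open ``[start, end)`` intervals in genome order
    (ascending coordinate), independent of strand; transcription order is
    derived from ``strand`` where needed.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int  # span start (leftmost coordinate)
    end: int    # span end (rightmost, exclusive)
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.start >= self.end:
            raise AnnotationError(f"{self.gene_id}: empty span (tss=tes)")
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        exs = tuple(tuple(e) for e in self.exons)
        if any(e[0] >= e[1] for e in exs):
            raise AnnotationError(f"{self.gene_id}: empty exon")
        if any(e[0] < self.start or e[1] > self.end for e in exs):
            raise AnnotationError(f"{self.gene_id}: exon outside gene span")
        object.__setattr__(self, "exons", tuple(sorted(exs)))

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    def exons_transcription_order(self) -> tuple:
        """Exons ordered first → last in the direction of transcription."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def distance_to(self, pos: int) -> int:
        """Unsigned distance from a point to the gene span (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class ToyGenome:
    chromosomes: list  # list of (name, length)
    genes: list = field(default_factory=list)
    cpgs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for g in self.genes:
            if g.chrom not in lengths:
                raise AnnotationError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.start < 0 or g.end > lengths[g.chrom]:
                raise AnnotationError(f"{g.gene_id}: span outside chromosome bounds")
        seen = set()
        for c in self.cpgs:
            if c.chrom not in lengths:
                raise AnnotationError(f"{c.cpg_id}: unknown chromosome {c.chrom}")
            if c.pos >= lengths[c.chrom]:
                raise AnnotationError(f"{c.cpg_id}: position past chromosome end")
            key = (c.chrom, c.pos)
            if key in seen:
                raise AnnotationError(f"duplicate CpG position {key}")
            seen.add(key)

    def chrom_length(self, name: str) -> int:
        return dict(self.chromosomes)[name]

    def mirrored(self) -> "ToyGenome":
        """Reflect every chromosome (flip coordinates and strands).

        Classification must be invariant under this transformation; it is used
        by the strand-symmetry tests.
        """
        lengths = dict(self.chromosomes)
        genes = [
            GeneModel(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand="-" if g.strand == "+" else "+",
                start=lengths[g.chrom] - g.end,
                end=lengths[g.chrom] - g.start,
                exons=tuple(
                    (lengths[g.chrom] - e, lengths[g.chrom] - s) for s, e in g.exons
                ),
            )
            for g in self.genes
        ]
        cpgs = [
            CpGSite(c.cpg_id, c.chrom, lengths[c.chrom] - c.pos) for c in self.cpgs
        ]
        return ToyGenome(list(self.chromosomes), genes, cpgs)
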