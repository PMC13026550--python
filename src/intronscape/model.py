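"""Core genome/intron data model.

Coordinates are 1-based inclusive throughout (GFF3 convention). An insertion
site ``s`` means the intron lies between reference-gene positions ``s`` and
``s+1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .naming import name_intron

__all__ = ["Genome", "GeneModel", "IntronRecord", "Interval"]

#: (start, end), 1-based inclusive
Interval = tuple[int, int]


@dataclass
class GeneModel:
    """A gene with exon intervals on its genome; introns are the gaps."""

    name: str
    strand: str  # '+' or '-'
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in gene {self.name}")

    @property
    def introns(self) -> list[Interval]:
        """Intervals between consecutive exons (genome coordinates)."""
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]


@dataclass
class Genome:
    id: str
    organelle: str  # 'mt' | 'cp'
    species: str
    sequence: str  # DNA
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self):
        if self.organelle not in ("mt", "cp"):
            raise ValueError(f"organelle must be 'mt' or 'cp', got {self.organelle!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: non-DNA characters {sorted(bad)}")


@dataclass
class IntronRecord:
    """One intron occurrence: RNA sequence plus its exon context."""

    id: str  # instance id, unique within a cohort
    genome_id: str
    host_gene: str
    site: int | None  # reference-gene coordinate; intron between site and site+1
    sequence: str  # RNA
    structure: str | None = None  # dot-bracket, same length as sequence
    upstream_flank: str = ""  # RNA, from the annotated upstream exon
    downstream_flank: str = ""  # RNA, from the annotated downstream exon

    def __post_init__(self):
        if self.site is not None and self.site <= 0:
            raise ValueError("insertion site must be positive")
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise ValueError(f"intron {self.id}: structure/sequence length mismatch")

    @property
    def family_name(self) -> str:
        if self.site is None:
            raise ValueError(f"intron {self.id}: insertion site not yet mapped")
        return name_intron(self.host_gene, self.site)
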