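"""Domain records: annotated plastomes, quadripartite boundaries, CDSs.

Coordinates are 0-based half-open throughout. Plastomes are circular, so
region intervals may wrap past the origin; :class:`Interval` carries the
genome length needed to resolve modular arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Interval",
    "GeneAnnotation",
    "RegionBoundaries",
    "PlastomeRecord",
    "GeneSequence",
]


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a circle of a given length.

    ``end < start`` is legal and means the interval wraps through the
    origin. A zero-length interval has ``start == end``.
    """

    start: int
    end: int
    circle: int

    def __len__(self) -> int:
        if self.end >= self.start:
            return self.end - self.start
        return self.circle - self.start + self.end

    def extract(self, sequence: str) -> str:
        if self.end >= self.start:
            return sequence[self.start : self.end]
        return sequence[self.start :] + sequence[: self.end]

    def contains(self, pos: int) -> bool:
        pos %= self.circle
        if self.end >= self.start:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene: name, feature class, strand and exon structure.

    ``exons`` are 0-based half-open intervals on the genome, ordered in
    transcription direction (descending start coordinates for minus-strand
    genes). Introns are the gaps between consecutive exons.
    """

    name: str
    feature_class: str  # CDS | tRNA | rRNA
    strand: str  # '+' | '-'
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if self.feature_class not in ("CDS", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene must have at least one exon")

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between adjacent exons, as genome-coordinate intervals."""
        spans = sorted((min(s, e), max(s, e)) for s, e in self.exons)
        return tuple(
            (spans[i][1], spans[i + 1][0])
            for i in range(len(spans) - 1)
            if spans[i + 1][0] > spans[i][1]
        )

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    def total_exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class RegionBoundaries:
    """Quadripartite partition of a circular plastome.

    The four intervals partition the circle in the canonical orientation
    LSC -> IRb -> SSC -> IRa; IRa is the exact reverse complement of IRb.
    """

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval

    @property
    def genome_length(self) -> int:
        return self.lsc.circle

    def lengths(self) -> dict[str, int]:
        return {
            "lsc": len(self.lsc),
            "irb": len(self.irb),
            "ssc": len(self.ssc),
            "ira": len(self.ira),
        }

    def validate(self, sequence: str | None = None) -> None:
        from .genetics import revcomp

        if len(self.irb) != len(self.ira):
            raise ValueError("IR copies differ in length")
        total = sum(self.lengths().values())
        if total != self.genome_length:
            raise ValueError(
                f"regions sum to {total}, genome is {self.genome_length}"
            )
        if len(self.lsc) < len(self.ssc):
            raise ValueError("LSC shorter than SSC")
        if sequence is not None:
            if revcomp(self.ira.extract(sequence)) != self.irb.extract(sequence):
                raise ValueError("IRa is not the reverse complement of IRb")


@dataclass
class PlastomeRecord:
    """A circular plastome: sequence, gene annotations, optional boundaries."""

    species_id: str
    sequence: str
    genes: list[GeneAnnotation] = field(default_factory=list)
    boundaries: RegionBoundaries | None = None

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        n = len(self.sequence)
        for g in self.genes:
            for s, e in g.exons:
                if not (0 <= s < n and 0 < e <= n):
                    raise ValueError(
                        f"exon {s}-{e} of {g.name} outside [0,{n})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_boundaries(self, boundaries: RegionBoundaries) -> "PlastomeRecord":
        return replace_boundaries(self, boundaries)

    def canonical(self) -> dict:
        """Canonical serialization used for round-trip comparison."""
        return {
            "species_id": self.species_id,
            "sequence": self.sequence,
            "genes": [
                {
                    "name": g.name,
                    "class": g.feature_class,
                    "strand": g.strand,
                    "exons": [list(x) for x in g.exons],
                }
                for g in sorted(
                    self.genes, key=lambda g: (g.start, g.name, g.feature_class)
                )
            ],
        }


def replace_boundaries(
    record: PlastomeRecord, boundaries: RegionBoundaries
) -> PlastomeRecord:
    out = PlastomeRecord(record.species_id, record.sequence, list(record.genes))
    out.boundaries = boundaries
    return out


@dataclass(frozen=True)
class GeneSequence:
    """One spliced, strand-corrected, in-frame coding sequence."""

    species_id: str
    gene_name: str
    cds: str
    category: str = "other"

    def __post_init__(self):
        if len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.gene_name}: CDS length {len(self.cds)} not a multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.cds)

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3
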