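"""Domain types for circular genomes and gene annotations.

Coordinates are 1-based inclusive throughout, matching GenBank flat files
and the feature-table dialect read by :mod:`mitochar.io`.  Strand labels
follow the gene-centric convention used for plant mitogenomes: ``J`` means
the gene reads 5'->3' on the stored sequence, ``N`` means it reads on the
reverse complement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

__all__ = [
    "CircularGenome",
    "Segment",
    "GeneFeature",
    "AnnotationSet",
    "CATEGORIES",
    "STRANDS",
    "revcomp",
    "summarize_annotation",
]

CATEGORIES = ("PCG", "tRNA", "rRNA", "other")
STRANDS = ("J", "N")

# IUPAC nucleotide one-letter codes (unambiguous + ambiguity + gap-free)
IUPAC_NT = set("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return sequence.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class Segment:
    """A contiguous 1-based inclusive interval on a genome circle."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"segment start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"segment end {self.end} precedes start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "Segment") -> int:
        """Number of shared base pairs with another segment (0 if disjoint)."""
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)


@dataclass
class GeneFeature:
    """A named gene with strand, category, and one or more coordinate segments.

    Multi-segment features model both cis-spliced (multi-exon) and
    trans-spliced genes; segment order is the order the annotation lists
    them, which is also the order the coding sequence is assembled in
    (see :func:`mitochar.codons.extract_cds`).
    """

    gene: str
    category: str
    strand: str
    segments: list[Segment]
    declared_length: Optional[int] = None
    declared_gc: Optional[float] = None
    declared_init_codon: Optional[str] = None
    declared_term_codon: Optional[str] = None
    declared_spacer: Optional[int] = None
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"{self.gene}: category {self.category!r} not in {CATEGORIES}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"{self.gene}: strand {self.strand!r} must be 'J' or 'N'"
            )
        if not self.segments:
            raise ValidationError(f"{self.gene}: feature needs >= 1 segment")

    @property
    def length(self) -> int:
        """Exon-sum length in bp."""
        return sum(s.length for s in self.segments)

    @property
    def first_start(self) -> int:
        return self.segments[0].start

    @property
    def max_end(self) -> int:
        return max(s.end for s in self.segments)

    def length_matches_declaration(self) -> bool:
        return self.declared_length is None or self.length == self.declared_length

    def copy(self) -> "GeneFeature":
        return replace(self, segments=list(self.segments))


@dataclass
class AnnotationSet:
    """Ordered collection of gene features for one genome circle.

    Input order is preserved and duplicate gene names are allowed (large
    plant mitogenome circles routinely carry two copies of rRNA and ccm
    genes).
    """

    genome_name: str
    features: list[GeneFeature] = field(default_factory=list)
    genome_length: Optional[int] = None

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    def category_counts(self) -> dict[str, int]:
        counts = Counter(f.category for f in self.features)
        out = {c: counts.get(c, 0) for c in CATEGORIES}
        out["total"] = len(self.features)
        return out

    def validate_lengths(self) -> list[str]:
        """Return warnings for features whose declared length disagrees
        with the segment sum."""
        warnings = []
        for f in self.features:
            if not f.length_matches_declaration():
                warnings.append(
                    f"{self.genome_name}/{f.gene}: declared length "
                    f"{f.declared_length} != segment sum {f.length}"
                )
        return warnings


@dataclass
class CircularGenome:
    """A named nucleotide sequence with declared topology.

    The sequence is case-normalized to upper case on construction and
    must contain only IUPAC nucleotide codes; the primary alphabet is
    {A, C, G, T, N}.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_NT
        if bad:
            offset = next(
                i for i, c in enumerate(self.sequence) if c in bad
            )
            raise ValidationError(
                f"{self.name}: non-IUPAC character {self.sequence[offset]!r} "
                f"at offset {offset}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, segment: Segment) -> str:
        """Forward-strand sequence of a segment (1-based inclusive).

        Segments must lie within the genome; origin-spanning features are
        represented as two segments by the readers.
        """
        if segment.end > self.length:
            raise ValidationError(
                f"{self.name}: segment {segment.start}-{segment.end} exceeds "
                f"genome length {self.length}"
            )
        return self.sequence[segment.start - 1 : segment.end]

    def rotated(self, offset: int) -> "CircularGenome":
        """Genome rotated so old position ``offset+1`` becomes position 1."""
        offset %= self.length
        return CircularGenome(
            self.name, self.sequence[offset:] + self.sequence[:offset], self.circular
        )


def summarize_annotation(*annotation_sets: AnnotationSet) -> dict[str, int]:
    """Category counts pooled over one or more annotation sets.

    Counting is per record: duplicated genes each count once, matching how
    published mitogenome tables tally their gene content.
    """
    total: Counter = Counter()
    for ann in annotation_sets:
        for f in ann:
            total[f.category] += 1
    out = {c: total.get(c, 0) for c in CATEGORIES}
    out["total"] = sum(out.values())
    return out
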