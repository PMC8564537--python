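"""Gene geometry on circular genomes: exon-sum lengths, intergenic
spacers (negative for overlaps), overlap pairs, and coding fraction.

Spacer convention: genes are ordered by the start of their first segment;
the spacer between consecutive genes is ``start(next) - end(prev) - 1``
where ``end(prev)`` is the maximum end over the previous gene's segments.
On a circular genome one additional wrap spacer connects the last gene
back to the first, adding the genome length to the downstream start.
Negative spacers indicate overlap, zero means abutting genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .model import AnnotationSet, GeneFeature

__all__ = [
    "SpacerRecord",
    "gene_length",
    "intergenic_spacers",
    "overlap_pairs",
    "coding_fraction",
    "validate_declared_spacers",
]


@dataclass(frozen=True)
class SpacerRecord:
    upstream_gene: str
    downstream_gene: str
    spacer_bp: int
    wraps_origin: bool = False


def gene_length(feature: GeneFeature) -> int:
    """Exon-sum length: sum over segments of (end - start + 1)."""
    return feature.length


def _sorted_features(annotations: AnnotationSet) -> list[GeneFeature]:
    return sorted(annotations.features, key=lambda f: (f.first_start, f.max_end))


def intergenic_spacers(
    annotations: AnnotationSet,
    genome_length: Optional[int] = None,
    circular: bool = True,
) -> list[SpacerRecord]:
    """One spacer per consecutive gene pair, plus the wrap spacer.

    Input row order is irrelevant: features are re-sorted by first-segment
    start.  The wrap spacer (last gene back to the first across the
    origin) is emitted only for circular genomes with a known length.
    """
    feats = _sorted_features(annotations)
    if not feats:
        return []
    records = []
    for prev, nxt in zip(feats, feats[1:]):
        records.append(
            SpacerRecord(prev.gene, nxt.gene, nxt.first_start - prev.max_end - 1)
        )
    if circular and len(feats) >= 1:
        length = genome_length or annotations.genome_length
        if length is None:
            raise ValueError("circular spacer computation needs genome_length")
        last, first = feats[-1], feats[0]
        records.append(
            SpacerRecord(
                last.gene,
                first.gene,
                first.first_start + length - last.max_end - 1,
                wraps_origin=True,
            )
        )
    return records


def _shared_bp(a: GeneFeature, b: GeneFeature) -> int:
    """True sequence-level overlap: summed intersection of the two
    features' segments (65 bp for a tRNA nested inside a longer gene even
    when the spacer convention prints a larger negative value)."""
    return sum(sa.overlap(sb) for sa in a.segments for sb in b.segments)


def overlap_pairs(annotations: AnnotationSet) -> list[dict]:
    """Consecutive gene pairs that overlap.

    A pair is reported when its spacer is negative *and* the two features
    physically share bases; a negative spacer alone can be an artifact of
    a trans-spliced upstream gene whose distant segment reaches past the
    next gene's start without touching it.  Each entry reports both
    ``overlap_bp`` (= -spacer, the published convention) and
    ``shared_bp`` (bases the two features actually share; smaller for a
    short gene nested inside a longer one).
    """
    feats = _sorted_features(annotations)
    out = []
    for prev, nxt in zip(feats, feats[1:]):
        spacer = nxt.first_start - prev.max_end - 1
        shared = _shared_bp(prev, nxt)
        if spacer < 0 and shared > 0:
            out.append(
                {
                    "pair": (prev.gene, nxt.gene),
                    "overlap_bp": -spacer,
                    "shared_bp": shared,
                }
            )
    return out


def coding_fraction(
    annotations: Iterable[AnnotationSet] | AnnotationSet,
    genome_length_total: int,
) -> dict[str, float]:
    """Additive coding content: sum of exon-sum gene lengths over all
    features (overlapping bases counted once per gene, matching the
    additive accounting of published gene-content totals)."""
    if genome_length_total <= 0:
        raise ValueError("genome length must be positive")
    if isinstance(annotations, AnnotationSet):
        annotations = [annotations]
    coding_bp = sum(f.length for ann in annotations for f in ann)
    return {
        "coding_bp": coding_bp,
        "percent": 100.0 * coding_bp / genome_length_total,
    }


def validate_declared_spacers(
    annotations: AnnotationSet,
    genome_length: Optional[int] = None,
    circular: bool = True,
) -> list[str]:
    """Warnings where a declared intergenic value disagrees with the
    computed spacer.

    Published tables are not always consistent about which end of a
    multi-segment upstream gene they measured from, so disagreements are
    reported, never raised.
    """
    feats = _sorted_features(annotations)
    # duplicate gene names are common; match computed spacers to features
    # by identity, not by name
    computed: dict[int, tuple[str, int]] = {}
    for prev, nxt in zip(feats, feats[1:]):
        computed[id(nxt)] = (prev.gene, nxt.first_start - prev.max_end - 1)
    warnings = []
    for f in annotations:
        if f.declared_spacer is None or id(f) not in computed:
            continue
        upstream, spacer = computed[id(f)]
        if spacer != f.declared_spacer:
            warnings.append(
                f"{annotations.genome_name}/{f.gene}: declared intergenic "
                f"{f.declared_spacer} != computed {spacer} "
                f"(upstream {upstream})"
            )
    return warnings
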