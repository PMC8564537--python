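"""Readers and writers: feature-table TSV, GenBank flat files, FASTA.

The feature-table dialect mirrors published mitogenome annotation tables:
one row per gene with columns ``gene category strand segments length gc
init_codon term_codon intergenic`` (an optional leading ``genome`` column
separates circles in a multi-genome file).  ``segments`` is a
semicolon-joined list of ``start-end`` ranges; on read, en-dashes and
thousands separators are tolerated, and a row with an empty gene cell
continues the previous gene with additional segments.  The canonical
writer emits plain hyphens and no separators.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

from .model import (
    AnnotationSet,
    CircularGenome,
    GeneFeature,
    Segment,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_feature_table",
    "read_feature_tables",
    "write_feature_table",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
]

PathLike = Union[str, Path]

TABLE_COLUMNS = [
    "gene",
    "category",
    "strand",
    "segments",
    "length",
    "gc",
    "init_codon",
    "term_codon",
    "intergenic",
]


class ParseError(ValueError):
    """Malformed input; the message names the offending line."""


_DASHES = "–—−"  # en dash, em dash, minus sign


def _parse_position(token: str, lineno: int) -> Segment:
    text = token.strip().replace(",", "")
    for d in _DASHES:
        text = text.replace(d, "-")
    # a leading '-' would be a malformed negative start, not a delimiter
    parts = text.split("-")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ParseError(f"line {lineno}: malformed position {token!r}")
    try:
        start, end = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed position {token!r}") from exc
    try:
        return Segment(start, end)
    except ValidationError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def _parse_segments(cell: str, lineno: int) -> list[Segment]:
    return [_parse_position(tok, lineno) for tok in cell.split(";") if tok.strip()]


def _opt_int(cell: str) -> Optional[int]:
    cell = cell.strip().replace(",", "")
    for d in _DASHES:
        cell = cell.replace(d, "-")
    return int(cell) if cell else None


def _opt_float(cell: str) -> Optional[float]:
    cell = cell.strip()
    return float(cell) if cell else None


def read_feature_tables(path: PathLike) -> dict[str, AnnotationSet]:
    """Read a (possibly multi-genome) feature table.

    Returns one :class:`AnnotationSet` per distinct value of the
    ``genome`` column, keyed by genome name and in first-seen order.
    Files without a ``genome`` column yield a single set named after the
    file stem.
    """
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        header = [h.strip().lower() for h in header]
        idx = {name: header.index(name) for name in header}
        if "gene" not in idx or "strand" not in idx or "segments" not in idx:
            raise ParseError(
                f"{path}: header must contain gene/strand/segments columns"
            )
        has_genome_col = "genome" in idx

        def cell(row: list[str], name: str) -> str:
            i = idx.get(name)
            return row[i].strip() if i is not None and i < len(row) else ""

        sets: dict[str, AnnotationSet] = {}
        last_feature: Optional[GeneFeature] = None
        for lineno, row in enumerate(reader, start=2):
            if not any(c.strip() for c in row):
                continue
            gene = cell(row, "gene")
            segs = _parse_segments(cell(row, "segments"), lineno)
            if not gene:
                # continuation row: extra segments for the previous gene
                if last_feature is None:
                    raise ParseError(
                        f"line {lineno}: continuation row before any gene"
                    )
                last_feature.segments.extend(segs)
                continue
            strand = cell(row, "strand")
            if strand not in ("J", "N"):
                raise ParseError(
                    f"line {lineno}: strand must be J or N, got {strand!r}"
                )
            genome = cell(row, "genome") if has_genome_col else path.stem
            if genome not in sets:
                sets[genome] = AnnotationSet(genome_name=genome)
            try:
                feature = GeneFeature(
                    gene=gene,
                    category=cell(row, "category") or "other",
                    strand=strand,
                    segments=segs,
                    declared_length=_opt_int(cell(row, "length")),
                    declared_gc=_opt_float(cell(row, "gc")),
                    declared_init_codon=cell(row, "init_codon") or None,
                    declared_term_codon=cell(row, "term_codon") or None,
                    declared_spacer=_opt_int(cell(row, "intergenic")),
                )
            except ValidationError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            sets[genome].features.append(feature)
            last_feature = feature
    return sets


def read_feature_table(
    path: PathLike,
    genome_length: Optional[int] = None,
    genome: Optional[str] = None,
) -> AnnotationSet:
    """Read the feature table for a single genome circle.

    ``genome`` selects a circle from a multi-genome file; omitted, the
    file must describe exactly one circle.
    """
    sets = read_feature_tables(path)
    if genome is not None:
        if genome not in sets:
            raise ParseError(f"{path}: no rows for genome {genome!r}")
        ann = sets[genome]
    elif len(sets) == 1:
        ann = next(iter(sets.values()))
    elif not sets:
        ann = AnnotationSet(genome_name=Path(path).stem)
    else:
        raise ParseError(
            f"{path}: contains {len(sets)} genomes; pass genome= to choose one"
        )
    ann.genome_length = genome_length
    if genome_length is not None:
        for f in ann:
            if f.max_end > genome_length:
                raise ValidationError(
                    f"{ann.genome_name}/{f.gene}: segment end {f.max_end} "
                    f"exceeds genome length {genome_length}"
                )
    return ann


def write_feature_table(path: PathLike, *annotation_sets: AnnotationSet) -> None:
    """Write one or more annotation sets in the canonical dialect."""
    with Path(path).open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["genome"] + TABLE_COLUMNS)
        for ann in annotation_sets:
            for f in ann:
                writer.writerow(
                    [
                        ann.genome_name,
                        f.gene,
                        f.category,
                        f.strand,
                        ";".join(f"{s.start}-{s.end}" for s in f.segments),
                        "" if f.declared_length is None else f.declared_length,
                        "" if f.declared_gc is None else f"{f.declared_gc:.2f}",
                        f.declared_init_codon or "",
                        f.declared_term_codon or "",
                        "" if f.declared_spacer is None else f.declared_spacer,
                    ]
                )


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_KEY_TO_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}
_CATEGORY_TO_KEY = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "other": "CDS"}


def read_genbank(path: PathLike) -> tuple[CircularGenome, AnnotationSet]:
    """Read a single-LOCUS GenBank flat file.

    Joined locations become ordered segments; complemented locations map
    to strand ``N``; a location spanning the origin of a circular record
    is split into two segments and flagged ``wraps_origin``.  Categories
    are inferred from the feature key unless a ``/note="category:..."``
    qualifier (as emitted by :func:`write_genbank`) overrides it.
    """
    record = SeqIO.read(str(path), "genbank")
    if len(record.seq) == 0:
        raise ParseError(f"{path}: record has no sequence")
    circular = record.annotations.get("topology", "linear") == "circular"
    genome = CircularGenome(record.id or record.name, str(record.seq), circular)
    ann = AnnotationSet(genome_name=genome.name, genome_length=genome.length)
    for feat in record.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "misc_feature", "gene"):
            continue
        if feat.type == "gene" and any(
            f.type in ("CDS", "tRNA", "rRNA")
            and f.qualifiers.get("gene") == feat.qualifiers.get("gene")
            for f in record.features
        ):
            continue  # gene wrapper duplicating a typed feature
        category = _KEY_TO_CATEGORY.get(feat.type, "other")
        for note in feat.qualifiers.get("note", []):
            if note.startswith("category:"):
                category = note.split(":", 1)[1]
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("product", [None])[0]
            or feat.type
        )
        parts = feat.location.parts
        strand = "N" if feat.location.strand == -1 else "J"
        if strand == "N":
            # Biopython lists complement(join(...)) parts in transcription
            # order; store segments in ascending genomic order as the
            # tables do, unless this is a trans-spliced layout where order
            # is meaningful (kept as annotated).
            parts = list(parts)
        segments = [Segment(int(p.start) + 1, int(p.end)) for p in parts]
        wraps = False
        if (
            circular
            and len(segments) == 2
            and segments[0].end == genome.length
            and segments[1].start == 1
        ):
            wraps = True
        ann.features.append(
            GeneFeature(
                gene=name,
                category=category,
                strand=strand,
                segments=segments,
                wraps_origin=wraps,
            )
        )
    return genome, ann


def write_genbank(
    path: PathLike, genome: CircularGenome, annotations: AnnotationSet
) -> None:
    """Write a genome circle and its annotations as a GenBank flat file."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.name[:16],
        name=genome.name[:16],
        description=f"{genome.name} mitochondrial genome circle",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    for f in annotations:
        strand = 1 if f.strand == "J" else -1
        locs = [
            SimpleLocation(s.start - 1, s.end, strand=strand) for s in f.segments
        ]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        qualifiers = {"gene": [f.gene], "note": [f"category:{f.category}"]}
        record.features.append(
            SeqFeature(
                location, type=_CATEGORY_TO_KEY[f.category], qualifiers=qualifiers
            )
        )
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike, circular: bool = True) -> list[CircularGenome]:
    return [
        CircularGenome(rec.id, str(rec.seq), circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: PathLike, *genomes: CircularGenome) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.name, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")
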