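"""Perfect tandem-repeat census on circular sequences.

``find_ssrs`` applies MISA-style semantics: maximal *perfect* runs of a
1-6 bp unit, reported once at maximal extent when the copy number meets
the per-unit-length threshold (defaults 1:10, 2:6, 3:5, 4:5, 5:5, 6:5).
No mismatch tolerance: a mononucleotide run interrupted by a single
substitution is two runs.  ``find_tandem_repeats`` extends the same
exact-period detection to minisatellite units (7-100 bp); it is a
deliberate simplification of alignment-based tools and finds perfect
duplications only.

Motifs are canonicalized to the lexicographically least rotation of the
unit, so (AT)n and (TA)n report the same ``motif`` while the observed
phase is retained in ``unit``.  Circular genomes are scanned with an
origin-spanning window so repeats crossing position 1 are found once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .model import AnnotationSet, CircularGenome

__all__ = [
    "SSRRecord",
    "DEFAULT_SSR_THRESHOLDS",
    "canonical_motif",
    "find_ssrs",
    "find_tandem_repeats",
    "resolve_overlaps",
    "repeat_fraction",
    "annotate_in_gene",
]

DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

COMPOUND_DISTANCE = 100  # bp between adjacent runs reported as a compound group


@dataclass(frozen=True)
class SSRRecord:
    """A detected perfect repeat: span = unit_len * copies."""

    motif: str
    unit: str
    unit_len: int
    copies: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive; < start only for origin-wrapping records
    wraps_origin: bool = False
    in_gene: Optional[str] = None
    compound_group: Optional[int] = None
    kind: str = "ssr"

    @property
    def span(self) -> int:
        return self.unit_len * self.copies


def canonical_motif(unit: str) -> str:
    """Lexicographically least rotation of the repeat unit."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _min_dividing_period(unit: str) -> int:
    """Smallest period p dividing len(unit) with unit == unit[:p] repeated."""
    k = len(unit)
    for p in range(1, k):
        if k % p == 0 and unit == unit[:p] * (k // p):
            return p
    return k


def _periodic_stretches(seq: str, k: int) -> Iterable[tuple[int, int]]:
    """Yield (start0, stretch_len) of maximal regions where seq[j] ==
    seq[j-k]; stretch_len includes the leading unit."""
    n = len(seq)
    if n <= k:
        return
    j = k
    run_start = None
    while j < n:
        if seq[j] == seq[j - k]:
            if run_start is None:
                run_start = j
            j += 1
        else:
            if run_start is not None:
                yield run_start - k, (j - run_start) + k
                run_start = None
            j += 1
    if run_start is not None:
        yield run_start - k, (n - run_start) + k


def _unrolled(rec: SSRRecord, genome_length: int) -> range:
    """0-based positions covered by a record, unrolled past the origin."""
    start0 = rec.start - 1
    return range(start0, start0 + rec.span)


def _contains(outer: SSRRecord, inner: SSRRecord, length: int) -> bool:
    """Circular containment of inner's span within outer's span."""
    o0 = outer.start - 1
    i0 = inner.start - 1
    if i0 < o0:
        i0 += length
    return i0 + inner.span <= o0 + outer.span


def _scan(
    genome: CircularGenome,
    unit_lengths: Sequence[int],
    min_copies: Mapping[int, int],
    min_total: int,
    window: int,
    kind: str,
) -> list[SSRRecord]:
    seq = genome.sequence
    length = len(seq)
    if length == 0:
        return []
    w = min(window, length - 1) if genome.circular else 0
    ext = seq + seq[:w]
    records: list[SSRRecord] = []
    for k in unit_lengths:
        for start0, stretch in _periodic_stretches(ext, k):
            if start0 >= length:
                continue  # lives entirely in the wrap window; found earlier
            copies = stretch // k
            if copies > length // k:  # repeat longer than the circle itself
                copies = length // k
            if copies < min_copies.get(k, 2) or copies * k < min_total:
                continue
            unit = ext[start0 : start0 + k]
            if _min_dividing_period(unit) != k:
                continue  # reported at its true (smaller) unit length
            end0 = start0 + copies * k - 1
            records.append(
                SSRRecord(
                    motif=canonical_motif(unit),
                    unit=unit,
                    unit_len=k,
                    copies=copies,
                    start=start0 + 1,
                    end=(end0 % length) + 1,
                    wraps_origin=end0 >= length,
                    kind=kind,
                )
            )
    # drop runs that are circular sub-runs of a wrapping record (the tail
    # of an origin-spanning repeat is re-detected at the sequence start)
    wrappers = [r for r in records if r.wraps_origin]
    if wrappers:
        records = [
            r
            for r in records
            if r in wrappers
            or not any(
                w.motif == r.motif and _contains(w, r, length) for w in wrappers
            )
        ]
    records.sort(key=lambda r: (r.start, r.unit_len))
    return records


def find_ssrs(
    genome: CircularGenome,
    thresholds: Optional[Mapping[int, int]] = None,
    annotations: Optional[AnnotationSet] = None,
) -> list[SSRRecord]:
    """MISA-style perfect microsatellites on a (circular) genome.

    Adjacent runs within 100 bp share a ``compound_group`` tag; when an
    annotation set is given, each record is labelled with the first gene
    it overlaps (any-overlap rule).
    """
    thresholds = dict(thresholds or DEFAULT_SSR_THRESHOLDS)
    window = max(k * c for k, c in thresholds.items())
    records = _scan(
        genome,
        sorted(thresholds),
        thresholds,
        min_total=0,
        window=window,
        kind="ssr",
    )
    records = _tag_compound_groups(records, genome.length)
    if annotations is not None:
        records = annotate_in_gene(records, annotations, genome.length)
    return records


def find_tandem_repeats(
    genome: CircularGenome,
    min_unit: int = 7,
    max_unit: int = 100,
    min_total: int = 24,
) -> list[SSRRecord]:
    """Perfect minisatellites: exact-period tandem duplications with unit
    length above the SSR range, at least two full copies and ``min_total``
    bp of repeated sequence.  Overlapping calls are resolved longest
    first."""
    if min_unit <= 6:
        raise ValueError("min_unit must exceed the SSR unit range (> 6)")
    records = _scan(
        genome,
        list(range(min_unit, max_unit + 1)),
        {},
        min_total=min_total,
        window=max_unit * 2 + min_total,
        kind="minisatellite",
    )
    return resolve_overlaps(records, genome.length)


def resolve_overlaps(
    records: Sequence[SSRRecord], genome_length: int
) -> list[SSRRecord]:
    """Greedy longest-first selection of mutually non-overlapping records."""
    chosen: list[SSRRecord] = []
    covered: set[int] = set()
    for rec in sorted(records, key=lambda r: (-r.span, r.start)):
        positions = {p % genome_length for p in _unrolled(rec, genome_length)}
        if positions & covered:
            continue
        covered |= positions
        chosen.append(rec)
    chosen.sort(key=lambda r: r.start)
    return chosen


def repeat_fraction(
    records: Sequence[SSRRecord], genome_length_total: int
) -> dict[str, float]:
    """Total repeat footprint: sum of record spans over the genome length.

    Records must be non-overlapping (apply :func:`resolve_overlaps`
    first when mixing scans).
    """
    if genome_length_total <= 0:
        raise ValueError("genome length must be positive")
    repeat_bp = sum(r.span for r in records)
    return {
        "repeat_bp": repeat_bp,
        "percent": 100.0 * repeat_bp / genome_length_total,
    }


def annotate_in_gene(
    records: Sequence[SSRRecord],
    annotations: AnnotationSet,
    genome_length: int,
) -> list[SSRRecord]:
    """Label each record with the first annotated gene it overlaps."""
    out = []
    for rec in records:
        pieces = (
            [(rec.start, genome_length), (1, rec.end)]
            if rec.wraps_origin
            else [(rec.start, rec.end)]
        )
        hit = None
        for f in annotations:
            for seg in f.segments:
                if any(lo <= seg.end and hi >= seg.start for lo, hi in pieces):
                    hit = f.gene
                    break
            if hit:
                break
        out.append(replace(rec, in_gene=hit))
    return out


def _tag_compound_groups(
    records: list[SSRRecord], genome_length: int
) -> list[SSRRecord]:
    """Adjacent runs within COMPOUND_DISTANCE bp share a group id."""
    out: list[SSRRecord] = []
    group = 0
    current: list[SSRRecord] = []

    def flush() -> None:
        nonlocal group
        if len(current) >= 2:
            group += 1
            out.extend(replace(r, compound_group=group) for r in current)
        else:
            out.extend(current)
        current.clear()

    for rec in records:
        if current and rec.start - (current[-1].start - 1 + current[-1].span) > COMPOUND_DISTANCE:
            flush()
        current.append(rec)
    flush()
    return out
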