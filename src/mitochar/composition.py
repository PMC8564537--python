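"""Base composition, AT/GC content, and strand-skew statistics.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C), computed from
raw counts (the percentage normalizations cancel algebraically).  Both
skews lie in [-1, 1]; a negative AT-skew means the sequence is T-rich.
Reported values are rounded half-away-from-zero to 4 decimal places to
match the print precision of mitogenome literature; raw values are kept
in machine output.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import IUPAC_NT, AnnotationSet, CircularGenome, GeneFeature, revcomp

__all__ = [
    "BaseCounts",
    "UndefinedStatisticError",
    "count_bases",
    "at_skew",
    "gc_skew",
    "at_content",
    "gc_content",
    "round_half_away",
    "composition_report",
]


class UndefinedStatisticError(ArithmeticError):
    """A ratio statistic was requested for an empty denominator."""


@dataclass(frozen=True)
class BaseCounts:
    """Exact per-base tallies; ambiguity codes land in ``other_count``."""

    a_count: int = 0
    t_count: int = 0
    g_count: int = 0
    c_count: int = 0
    other_count: int = 0

    @property
    def total(self) -> int:
        return (
            self.a_count + self.t_count + self.g_count + self.c_count + self.other_count
        )

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(
            self.a_count + other.a_count,
            self.t_count + other.t_count,
            self.g_count + other.g_count,
            self.c_count + other.c_count,
            self.other_count + other.other_count,
        )

    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            raise UndefinedStatisticError("empty sequence has no base percentages")
        return {
            base: 100.0 * count / self.total
            for base, count in (
                ("A", self.a_count),
                ("T", self.t_count),
                ("G", self.g_count),
                ("C", self.c_count),
                ("other", self.other_count),
            )
        }


def count_bases(sequence: str) -> BaseCounts:
    """Tally A/T/G/C; N and IUPAC ambiguity codes count as ``other``.

    Raises ``ValueError`` naming the offset of the first non-IUPAC
    character.
    """
    seq = sequence.upper()
    bad = set(seq) - IUPAC_NT
    if bad:
        offset = next(i for i, ch in enumerate(seq) if ch in bad)
        raise ValueError(f"non-IUPAC character {seq[offset]!r} at offset {offset}")
    a = seq.count("A")
    t = seq.count("T") + seq.count("U")
    g = seq.count("G")
    c = seq.count("C")
    return BaseCounts(a, t, g, c, len(seq) - a - t - g - c)


def at_skew(counts: BaseCounts) -> float:
    """(A - T) / (A + T); negative means T-rich."""
    denom = counts.a_count + counts.t_count
    if denom == 0:
        raise UndefinedStatisticError("AT-skew undefined: no A or T bases")
    return (counts.a_count - counts.t_count) / denom


def gc_skew(counts: BaseCounts) -> float:
    """(G - C) / (G + C); negative means C-rich."""
    denom = counts.g_count + counts.c_count
    if denom == 0:
        raise UndefinedStatisticError("GC-skew undefined: no G or C bases")
    return (counts.g_count - counts.c_count) / denom


def at_content(counts: BaseCounts) -> float:
    """100 * (A + T) / total, in percent."""
    if counts.total == 0:
        raise UndefinedStatisticError("AT content undefined for empty sequence")
    return 100.0 * (counts.a_count + counts.t_count) / counts.total


def gc_content(counts: BaseCounts) -> float:
    if counts.total == 0:
        raise UndefinedStatisticError("GC content undefined for empty sequence")
    return 100.0 * (counts.g_count + counts.c_count) / counts.total


def round_half_away(value: float, ndigits: int) -> float:
    """Round half away from zero (print convention for skews/percentages)."""
    quant = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(value)).quantize(
            quant, rounding=decimal.ROUND_HALF_UP
        )
    )


def _oriented_sequence(genome: CircularGenome, feature: GeneFeature) -> str:
    """Gene-centric sequence: J features as stored, N features reverse
    complemented (per-segment, concatenated in reverse listed order)."""
    if feature.strand == "J":
        return "".join(genome.slice(s) for s in feature.segments)
    return "".join(revcomp(genome.slice(s)) for s in reversed(feature.segments))


DEFAULT_CLASSES = ("whole", "PCG", "tRNA", "rRNA")


def composition_report(
    genomes: Sequence[CircularGenome],
    annotations: Optional[Mapping[str, AnnotationSet]] = None,
    classes: Sequence[str] = DEFAULT_CLASSES,
) -> pd.DataFrame:
    """Per-circle, per-class composition table plus a combined row.

    Class sequences are assembled by concatenating the strand-oriented
    sequence of every member feature (gene-centric convention: N-strand
    genes contribute their reverse complement).  Classes with no members
    or an empty denominator get NaN skews and are flagged ``undefined``.
    """
    annotations = annotations or {}
    rows = []
    combined: dict[str, BaseCounts] = {c: BaseCounts() for c in classes}

    def make_row(genome_name: str, cls: str, counts: BaseCounts) -> dict:
        row: dict = {"genome": genome_name, "class": cls, "length": counts.total}
        row.update(
            {
                "a_count": counts.a_count,
                "t_count": counts.t_count,
                "g_count": counts.g_count,
                "c_count": counts.c_count,
                "other_count": counts.other_count,
            }
        )
        try:
            row["at_content"] = at_content(counts)
            row["gc_content"] = gc_content(counts)
            pct = counts.percentages()
            row["a_pct"], row["t_pct"] = pct["A"], pct["T"]
            row["g_pct"], row["c_pct"] = pct["G"], pct["C"]
        except UndefinedStatisticError:
            row["at_content"] = row["gc_content"] = float("nan")
            row["a_pct"] = row["t_pct"] = row["g_pct"] = row["c_pct"] = float("nan")
        for name, fn in (("at_skew", at_skew), ("gc_skew", gc_skew)):
            try:
                raw = fn(counts)
                row[name] = round_half_away(raw, 4)
                row[name + "_raw"] = raw
            except UndefinedStatisticError:
                row[name] = row[name + "_raw"] = float("nan")
        row["undefined"] = counts.total == 0
        return row

    for genome in genomes:
        ann = annotations.get(genome.name)
        for cls in classes:
            if cls == "whole":
                counts = count_bases(genome.sequence)
            else:
                feats = ann.by_category(cls) if ann is not None else []
                counts = BaseCounts()
                for f in feats:
                    counts = counts + count_bases(_oriented_sequence(genome, f))
            combined[cls] = combined[cls] + counts
            rows.append(make_row(genome.name, cls, counts))
    if len(genomes) > 1:
        for cls in classes:
            rows.append(make_row("combined", cls, combined[cls]))
    return pd.DataFrame(rows)
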