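"""Strand-aware CDS assembly, codon counting, RSCU, and start/stop audit.

Angiosperm mitochondrial genes use the universal genetic code, so all
translation here runs on NCBI translation table 1.  RSCU (relative
synonymous codon usage) for a codon is its count divided by the mean
count over its synonymous family; 1 means no bias, above 1 preferred.
The three stop codons are treated as one synonymous family by default,
mirroring how mitogenome codon tables list TAA among preferred codons;
``include_stops=False`` gives the common alternative.

ACG initiation codons are reported as non-canonical but valid: plant
mitochondria restore ATG by C-to-U RNA editing, which is not modelled
here.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .model import AnnotationSet, CircularGenome, GeneFeature, revcomp

__all__ = [
    "CodonUsageTable",
    "STANDARD_AA_MAP",
    "SYNONYMOUS_FAMILIES",
    "extract_cds",
    "codon_counts",
    "rscu",
    "classify_codons",
    "start_stop_audit",
    "CODING_CATEGORIES",
]

logger = logging.getLogger(__name__)

STOP = "*"
ALL_CODONS = ["".join(p) for p in itertools.product("TCAG", repeat=3)]

_table1 = CodonTable.unambiguous_dna_by_id[1]
STANDARD_AA_MAP: dict[str, str] = {c: _table1.forward_table[c] for c in _table1.forward_table}
STANDARD_AA_MAP.update({c: STOP for c in _table1.stop_codons})

# codon-bearing categories: the "other" class of plant mitogenome tables
# (ccmB/ccmC/ccmFc/ccmFn/mttB) are protein-coding and carry codons
CODING_CATEGORIES = ("PCG", "other")


def _families(include_stops: bool) -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in STANDARD_AA_MAP.items():
        fams.setdefault(aa, []).append(codon)
    if not include_stops:
        fams.pop(STOP, None)
    return fams


SYNONYMOUS_FAMILIES = _families(include_stops=True)


@dataclass
class CodonUsageTable:
    """Per-codon counts with derived RSCU values and classification."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in ALL_CODONS}
    )
    aa_map: dict[str, str] = field(default_factory=lambda: dict(STANDARD_AA_MAP))
    rscu: dict[str, Optional[float]] = field(default_factory=dict)
    classification: dict[str, str] = field(default_factory=dict)
    dropped_nt: int = 0
    ambiguous_codons: int = 0

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def aa_counts(self) -> dict[str, int]:
        out: Counter = Counter()
        for codon, n in self.counts.items():
            out[self.aa_map[codon]] += n
        return dict(out)

    def to_frame(self) -> pd.DataFrame:
        total = self.total_codons
        rows = [
            {
                "codon": c,
                "aa": self.aa_map[c],
                "count": self.counts[c],
                "frequency": self.counts[c] / total if total else float("nan"),
                "rscu": self.rscu.get(c),
                "class": self.classification.get(c, ""),
            }
            for c in ALL_CODONS
        ]
        return pd.DataFrame(rows)


def extract_cds(genome: CircularGenome, feature: GeneFeature) -> str:
    """Assemble the coding sequence of a feature.

    J strand: concatenate segment slices in listed order.  N strand:
    reverse complement each segment and concatenate in reverse listed
    order (equivalently, the reverse complement of the forward
    concatenation).  The result length equals the exon-sum gene length.
    """
    if feature.strand == "J":
        return "".join(genome.slice(s) for s in feature.segments)
    return "".join(revcomp(genome.slice(s)) for s in reversed(feature.segments))


def codon_counts(cds_list: Iterable[str]) -> CodonUsageTable:
    """Count codons over a pool of coding sequences.

    The reading frame starts at position 1 of each CDS.  A trailing
    partial codon is dropped with a warning; codons containing ambiguity
    codes are excluded from the table but tallied in
    ``ambiguous_codons``.
    """
    table = CodonUsageTable()
    for cds in cds_list:
        seq = cds.upper()
        usable = len(seq) - len(seq) % 3
        if usable < len(seq):
            table.dropped_nt += len(seq) - usable
            logger.warning(
                "CDS length %d not divisible by 3; dropped %d trailing nt",
                len(seq),
                len(seq) - usable,
            )
        for i in range(0, usable, 3):
            codon = seq[i : i + 3]
            if codon in table.counts:
                table.counts[codon] += 1
            else:
                table.ambiguous_codons += 1
    return table


def rscu(table: CodonUsageTable, include_stops: bool = True) -> CodonUsageTable:
    """Fill RSCU values in place and return the table.

    For codon c in synonymous family F:
    RSCU(c) = count(c) / mean(count over F).  Families with zero total
    observations get RSCU ``None`` (reported blank, never 0).
    """
    table.rscu = {}
    for fam in _families(include_stops).values():
        fam_total = sum(table.counts[c] for c in fam)
        if fam_total == 0:
            for c in fam:
                table.rscu[c] = None
        else:
            mean = fam_total / len(fam)
            for c in fam:
                table.rscu[c] = table.counts[c] / mean
    return table


def classify_codons(table: CodonUsageTable) -> dict[str, str]:
    """Classify codons by the strict RSCU threshold.

    RSCU > 1 -> optimal, < 1 -> non_optimal, exactly 1 -> no_preference
    (single-codon families ATG/Met and TGG/Trp always land here when
    observed).
    """
    if not table.rscu:
        rscu(table)
    table.classification = {}
    for codon, value in table.rscu.items():
        if value is None:
            continue
        if value > 1:
            table.classification[codon] = "optimal"
        elif value < 1:
            table.classification[codon] = "non_optimal"
        else:
            table.classification[codon] = "no_preference"
    return table.classification


CANONICAL_START = "ATG"


def start_stop_audit(
    genome: CircularGenome,
    annotations: AnnotationSet,
    categories: Sequence[str] = ("PCG",),
) -> pd.DataFrame:
    """First/last codon of every coding feature, checked against any
    declared codons.

    CDS shorter than 6 nt are flagged rather than audited.  Mismatches
    between computed and declared codons are reported in the
    ``init_matches_declared`` / ``term_matches_declared`` columns.
    """
    rows = []
    for f in annotations:
        if f.category not in categories:
            continue
        cds = extract_cds(genome, f)
        if len(cds) < 6:
            rows.append(
                {
                    "gene": f.gene,
                    "init_codon": None,
                    "term_codon": None,
                    "is_canonical_start": None,
                    "flag": "too_short",
                }
            )
            continue
        usable = len(cds) - len(cds) % 3
        init, term = cds[:3], cds[usable - 3 : usable]
        row = {
            "gene": f.gene,
            "init_codon": init,
            "term_codon": term,
            "is_canonical_start": init == CANONICAL_START,
            "flag": "",
        }
        if f.declared_init_codon:
            row["init_matches_declared"] = init == f.declared_init_codon.upper()
        if f.declared_term_codon:
            row["term_matches_declared"] = term == f.declared_term_codon.upper()
        rows.append(row)
    return pd.DataFrame(rows)
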