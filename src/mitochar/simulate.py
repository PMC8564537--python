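"""Seeded generator of circular mitogenome-like fixtures with ground truth.

The generator plants genes (single- or multi-segment, both strands,
optionally overlapping via explicit coordinates) and perfect repeats on a
random background whose base probabilities are solved in closed form from
the requested AT content and strand skews:

    p(A) = AT/2 * (1 + at_skew),   p(T) = AT/2 * (1 - at_skew)
    p(G) = GC/2 * (1 + gc_skew),   p(C) = GC/2 * (1 - gc_skew)

with AT = at_content/100 and GC = 1 - AT, so the whole-genome skews hit
their targets in expectation rather than by post-hoc editing.  Identical
seed and template give byte-identical output.

Ground truth (:class:`GenomeTruth`) records every planted feature as it
stands in the *final* sequence — if an explicitly requested overlap or an
in-gene repeat overwrites part of an earlier gene, the truth holds the
re-extracted coding sequence, which is what any downstream analysis can
recover.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .codons import ALL_CODONS, STANDARD_AA_MAP, STOP, extract_cds
from .model import AnnotationSet, CircularGenome, GeneFeature, Segment, revcomp
from .repeats import SSRRecord, canonical_motif

__all__ = [
    "PlantedGeneSpec",
    "PlantedRepeatSpec",
    "GenomeTemplate",
    "GenomeTruth",
    "PackingError",
    "generate_genome",
    "generate_species_set",
    "load_templates",
    "write_truth",
]

BASES = np.array(["A", "T", "G", "C"])
STOP_CODONS = [c for c, aa in STANDARD_AA_MAP.items() if aa == STOP]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]


class PackingError(RuntimeError):
    """Planted features could not be placed without unintended collisions."""


@dataclass
class PlantedGeneSpec:
    """Request for one planted gene.

    Either explicit ``segments`` (1-based inclusive pairs; may deliberately
    overlap other features) or a ``length`` to be auto-placed in
    ``n_segments`` pieces.  Coding features get a generated CDS
    (init + sense codons from the codon profile + term) unless
    ``coding_sequence`` is supplied.
    """

    name: str
    category: str = "PCG"
    strand: str = "J"
    length: Optional[int] = None
    n_segments: int = 1
    segments: Optional[list[tuple[int, int]]] = None
    coding_sequence: Optional[str] = None
    init_codon: str = "ATG"
    term_codon: str = "TAA"


@dataclass
class PlantedRepeatSpec:
    motif: str
    copies: int
    start: Optional[int] = None
    in_gene: Optional[str] = None


@dataclass
class GenomeTemplate:
    name: str
    length: int
    at_content: float = 54.8  # percent
    at_skew: float = 0.0
    gc_skew: float = 0.0
    genes: list[PlantedGeneSpec] = field(default_factory=list)
    repeats: list[PlantedRepeatSpec] = field(default_factory=list)
    codon_profile: Optional[dict[str, float]] = None

    def base_probs(self) -> dict[str, float]:
        at = self.at_content / 100.0
        gc = 1.0 - at
        return {
            "A": at / 2 * (1 + self.at_skew),
            "T": at / 2 * (1 - self.at_skew),
            "G": gc / 2 * (1 + self.gc_skew),
            "C": gc / 2 * (1 - self.gc_skew),
        }


@dataclass
class PlantedGeneTruth:
    name: str
    category: str
    strand: str
    segments: list[tuple[int, int]]
    coding_sequence: str
    init_codon: Optional[str]
    term_codon: Optional[str]


@dataclass
class GenomeTruth:
    seed: int
    name: str
    length: int
    target_base_freqs: dict[str, float]
    target_at_skew: float
    target_gc_skew: float
    planted_genes: list[PlantedGeneTruth]
    planted_repeats: list[SSRRecord]
    codon_profile: dict[str, float]


def _default_codon_profile(base_probs: dict[str, float]) -> dict[str, float]:
    """Sense-codon sampling weights induced by the background base
    probabilities, so codon composition is consistent with genome
    composition."""
    weights = {
        c: base_probs[c[0]] * base_probs[c[1]] * base_probs[c[2]]
        for c in SENSE_CODONS
    }
    total = sum(weights.values())
    return {c: w / total for c, w in weights.items()}


def _sample_cds(
    spec: PlantedGeneSpec, profile: dict[str, float], rng: np.random.Generator
) -> str:
    if spec.coding_sequence is not None:
        return spec.coding_sequence.upper()
    length = spec.length or 300
    if length % 3:
        raise ValueError(f"{spec.name}: coding length {length} not divisible by 3")
    n_internal = length // 3 - 2
    if n_internal < 0:
        raise ValueError(f"{spec.name}: coding length must be >= 6")
    codons = list(profile)
    probs = np.array([profile[c] for c in codons])
    internal = rng.choice(codons, size=n_internal, p=probs / probs.sum())
    return spec.init_codon + "".join(internal) + spec.term_codon


def _random_seq(length: int, probs: dict[str, float], rng: np.random.Generator) -> str:
    p = np.array([probs[b] for b in "ATGC"])
    return "".join(rng.choice(BASES, size=length, p=p / p.sum()))


class _Packer:
    """Tracks claimed intervals; random placement keeps a 1 bp margin so
    auto-placed features never abut or overlap by accident."""

    def __init__(self, length: int, rng: np.random.Generator) -> None:
        self.length = length
        self.rng = rng
        self.claimed: list[tuple[int, int]] = []

    def claim(self, start: int, end: int) -> None:
        self.claimed.append((start, end))

    def is_free(self, start: int, end: int, margin: int = 1) -> bool:
        return all(
            end + margin < s or start - margin > e for s, e in self.claimed
        )

    def place(self, size: int, owner: str, tries: int = 500) -> tuple[int, int]:
        if size > self.length:
            raise PackingError(f"{owner}: size {size} exceeds genome length")
        for _ in range(tries):
            start = int(self.rng.integers(1, self.length - size + 2))
            end = start + size - 1
            if self.is_free(start, end):
                self.claim(start, end)
                return start, end
        raise PackingError(
            f"could not place {owner} ({size} bp) after {tries} tries; "
            f"colliding with {len(self.claimed)} claimed intervals"
        )


def _split_lengths(total: int, n: int) -> list[int]:
    base, rem = divmod(total, n)
    return [base + (1 if i < rem else 0) for i in range(n)]


def generate_genome(
    template: GenomeTemplate, seed: int
) -> tuple[CircularGenome, AnnotationSet, GenomeTruth]:
    """Generate one genome circle with annotations and ground truth."""
    rng = np.random.default_rng(seed)
    probs = template.base_probs()
    profile = template.codon_profile or _default_codon_profile(probs)
    sequence = np.array(list(_random_seq(template.length, probs, rng)))
    packer = _Packer(template.length, rng)

    # explicit segments claim space first (deliberate overlaps allowed
    # among themselves, and exempt from the margin rule)
    for spec in template.genes:
        if spec.segments:
            for s, e in spec.segments:
                packer.claim(s, e)

    ann = AnnotationSet(genome_name=template.name, genome_length=template.length)
    planted: list[tuple[PlantedGeneSpec, GeneFeature, str]] = []
    for spec in template.genes:
        coding = spec.category in ("PCG", "other")
        if coding:
            gene_seq = _sample_cds(spec, profile, rng)
        else:
            gene_seq = (
                spec.coding_sequence.upper()
                if spec.coding_sequence
                else _random_seq(spec.length or 72, probs, rng)
            )
        if spec.segments:
            segments = [Segment(s, e) for s, e in spec.segments]
        else:
            chunks = _split_lengths(len(gene_seq), spec.n_segments)
            placed = sorted(packer.place(size, spec.name) for size in chunks)
            segments = [Segment(s, e) for s, e in placed]
        if sum(s.length for s in segments) != len(gene_seq):
            raise ValueError(
                f"{spec.name}: segment total {sum(s.length for s in segments)} "
                f"!= sequence length {len(gene_seq)}"
            )
        _write_gene(sequence, segments, spec.strand, gene_seq)
        feature = GeneFeature(
            gene=spec.name,
            category=spec.category,
            strand=spec.strand,
            segments=segments,
        )
        ann.features.append(feature)
        planted.append((spec, feature, gene_seq))

    # repeats are stamped last at reserved loci
    planted_repeats: list[SSRRecord] = []
    gene_by_name = {f.gene: f for _, f, _ in planted}
    for rep in template.repeats:
        span = len(rep.motif) * rep.copies
        if rep.start is not None:
            start, end = rep.start, rep.start + span - 1
            packer.claim(start, end)
        elif rep.in_gene is not None:
            host = gene_by_name[rep.in_gene]
            seg = max(host.segments, key=lambda s: s.length)
            if seg.length < span + 6:
                raise PackingError(
                    f"repeat ({rep.motif}){rep.copies} does not fit inside "
                    f"{rep.in_gene}"
                )
            # keep clear of the start/stop codons of the host CDS
            start = int(rng.integers(seg.start + 3, seg.end - span - 2))
            end = start + span - 1
        else:
            start, end = packer.place(span, f"repeat ({rep.motif}){rep.copies}")
        if end > template.length:
            raise PackingError(f"repeat ({rep.motif}){rep.copies} exceeds genome")
        stamp = (rep.motif * rep.copies).upper()
        sequence[start - 1 : end] = list(stamp)
        # guard the flanks so the perfect run ends exactly at the planted
        # coordinates instead of extending a phase into the background
        unit = rep.motif.upper()
        for pos0, forbidden in (
            ((start - 2) % template.length, unit[-1]),
            (end % template.length, unit[0]),
        ):
            if sequence[pos0] == forbidden:
                choices = [b for b in "ATGC" if b != forbidden]
                sequence[pos0] = choices[int(rng.integers(0, 3))]
        planted_repeats.append(
            SSRRecord(
                motif=canonical_motif(rep.motif.upper()),
                unit=rep.motif.upper(),
                unit_len=len(rep.motif),
                copies=rep.copies,
                start=start,
                end=end,
                in_gene=rep.in_gene,
            )
        )

    genome = CircularGenome(template.name, "".join(sequence))

    # truth reflects the final sequence (explicit overlaps / in-gene
    # repeats may have overwritten earlier plants)
    gene_truth = []
    for spec, feature, _ in planted:
        final_cds = extract_cds(genome, feature)
        coding = spec.category in ("PCG", "other")
        gene_truth.append(
            PlantedGeneTruth(
                name=spec.name,
                category=spec.category,
                strand=spec.strand,
                segments=[(s.start, s.end) for s in feature.segments],
                coding_sequence=final_cds,
                init_codon=final_cds[:3] if coding else None,
                term_codon=final_cds[-3:] if coding else None,
            )
        )
    truth = GenomeTruth(
        seed=seed,
        name=template.name,
        length=template.length,
        target_base_freqs=probs,
        target_at_skew=template.at_skew,
        target_gc_skew=template.gc_skew,
        planted_genes=gene_truth,
        planted_repeats=planted_repeats,
        codon_profile=profile,
    )
    return genome, ann, truth


def _write_gene(
    sequence: np.ndarray, segments: list[Segment], strand: str, gene_seq: str
) -> None:
    """Inverse of CDS extraction: distribute the gene sequence over its
    segments so that extraction recovers it exactly."""
    if strand == "J":
        offset = 0
        for seg in segments:
            chunk = gene_seq[offset : offset + seg.length]
            sequence[seg.start - 1 : seg.end] = list(chunk)
            offset += seg.length
    else:
        offset = 0
        for seg in reversed(segments):
            chunk = gene_seq[offset : offset + seg.length]
            sequence[seg.start - 1 : seg.end] = list(revcomp(chunk))
            offset += seg.length


# ---------------------------------------------------------------------------
# species sets for supermatrix preparation
# ---------------------------------------------------------------------------


def generate_species_set(
    n_species: int,
    gene_list: Union[dict[str, str], dict[str, int]],
    divergence: float,
    seed: int,
) -> dict[str, dict[str, str]]:
    """Evolve a common ancestor into ``n_species`` gene sets.

    ``gene_list`` maps gene name to an ancestor sequence, or to a length
    (an ancestor is then drawn uniformly).  Each site mutates
    independently with probability ``divergence`` to one of the three
    other bases (Jukes-Cantor-style draw); lengths are preserved.
    """
    if not 0 <= divergence < 0.75:
        raise ValueError("divergence must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    ancestors: dict[str, str] = {}
    for gene, value in gene_list.items():
        if isinstance(value, str):
            ancestors[gene] = value.upper()
        else:
            ancestors[gene] = "".join(rng.choice(BASES, size=int(value)))
    out: dict[str, dict[str, str]] = {}
    for i in range(1, n_species + 1):
        species = f"species{i}"
        genes = {}
        for gene, anc in ancestors.items():
            arr = np.array(list(anc))
            mask = rng.random(len(arr)) < divergence
            if mask.any():
                idx = np.flatnonzero(mask)
                for j in idx:
                    others = [b for b in "ATGC" if b != arr[j]]
                    arr[j] = others[int(rng.integers(0, 3))]
            genes[gene] = "".join(arr)
        out[species] = genes
    return out


# ---------------------------------------------------------------------------
# templates and truth serialization
# ---------------------------------------------------------------------------


def load_templates(path: Union[str, Path]) -> list[GenomeTemplate]:
    """Read genome-circle templates from a YAML file (``circles:`` list)."""
    data = yaml.safe_load(Path(path).read_text())
    circles = data["circles"] if isinstance(data, dict) else data
    templates = []
    for circ in circles:
        genes = [PlantedGeneSpec(**g) for g in circ.get("genes", [])]
        for g in genes:
            if g.segments is not None:
                g.segments = [tuple(s) for s in g.segments]
        repeats = [PlantedRepeatSpec(**r) for r in circ.get("repeats", [])]
        templates.append(
            GenomeTemplate(
                name=circ["name"],
                length=int(circ["length"]),
                at_content=float(circ.get("at_content", 54.8)),
                at_skew=float(circ.get("at_skew", 0.0)),
                gc_skew=float(circ.get("gc_skew", 0.0)),
                genes=genes,
                repeats=repeats,
                codon_profile=circ.get("codon_profile"),
            )
        )
    return templates


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_truth(path: Union[str, Path], truth: GenomeTruth) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(asdict(truth)), sort_keys=False))
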