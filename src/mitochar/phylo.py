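"""Supermatrix preparation: ordered concatenation of orthologous genes.

Builds per-species concatenations of named protein-coding genes in a
globally fixed gene order, with a partition map suitable for RAxML-style
partitioned analyses.  Alignment, model selection, and tree search are
external steps this module prepares inputs for; it never calls them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from statistics import mode
from typing import Mapping, Sequence, Union

__all__ = [
    "SupermatrixRecord",
    "DEFAULT_GENE_ORDER",
    "build_supermatrix",
    "split_supermatrix",
    "write_supermatrix_fasta",
    "write_phylip",
    "write_partition_file",
]

logger = logging.getLogger(__name__)

# The 24 mitochondrial PCGs conventionally concatenated for angiosperm
# phylogenomics: 3 ATP synthase, 3 cytochrome c oxidase, cob, 9 NADH
# dehydrogenase, 4 ribosomal protein, 4 cytochrome maturation genes.
DEFAULT_GENE_ORDER = (
    "atp1", "atp6", "atp9",
    "cox1", "cox2", "cox3",
    "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
    "rps12", "rps13", "rps3", "rps4",
    "ccmB", "ccmC", "ccmFc", "ccmFn",
)

# GenBank annotations vary; matching is case-insensitive with synonyms
_SYNONYMS = {
    "cytb": "cob",
    "cob": "cob",
    "mt-cyb": "cob",
    "nad4l": "nad4L",
    "ccmb": "ccmB",
    "ccmc": "ccmC",
    "ccmfc": "ccmFc",
    "ccmfn": "ccmFn",
}


def _canonical_gene(name: str) -> str:
    low = name.strip().lower()
    return _SYNONYMS.get(low, low if low != "nad4l" else "nad4L")


@dataclass
class SupermatrixRecord:
    species: str
    sequence: str
    partition_map: list[tuple[str, int, int]]  # (gene, start, end) 1-based


def build_supermatrix(
    per_species_genes: Mapping[str, Mapping[str, str]],
    gene_order: Sequence[str] = DEFAULT_GENE_ORDER,
    missing_policy: str = "drop_species",
) -> list[SupermatrixRecord]:
    """Concatenate genes in ``gene_order`` for every species.

    ``missing_policy`` is ``drop_species`` (exclude species lacking any
    ordered gene, with a warning) or ``gap_fill`` (insert a '-' block of
    the gene's modal length).  Output is deterministic given
    ``gene_order``: input-map iteration order never matters.
    """
    if not gene_order:
        raise ValueError("gene_order must be non-empty")
    if missing_policy not in ("drop_species", "gap_fill"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    # normalize gene naming per species
    canon: dict[str, dict[str, str]] = {}
    for species in sorted(per_species_genes):
        canon[species] = {
            _canonical_gene(g): seq.upper()
            for g, seq in per_species_genes[species].items()
        }
    order = [_canonical_gene(g) for g in gene_order]

    modal_length: dict[str, int] = {}
    for gene in order:
        lengths = [len(canon[sp][gene]) for sp in canon if gene in canon[sp]]
        if lengths:
            modal_length[gene] = mode(sorted(lengths))

    records = []
    for species in sorted(canon):
        genes = canon[species]
        missing = [g for g in order if g not in genes]
        if missing and missing_policy == "drop_species":
            logger.warning(
                "dropping %s: missing gene(s) %s", species, ", ".join(missing)
            )
            continue
        parts: list[str] = []
        partition_map: list[tuple[str, int, int]] = []
        pos = 0
        for gene in order:
            if gene in genes:
                block = genes[gene]
            else:
                if gene not in modal_length:
                    raise ValueError(
                        f"gene {gene!r} present in no species; cannot gap-fill"
                    )
                block = "-" * modal_length[gene]
            partition_map.append((gene, pos + 1, pos + len(block)))
            parts.append(block)
            pos += len(block)
        records.append(SupermatrixRecord(species, "".join(parts), partition_map))
    return records


def split_supermatrix(record: SupermatrixRecord) -> dict[str, str]:
    """Recover per-gene blocks from a supermatrix record."""
    return {
        gene: record.sequence[start - 1 : end]
        for gene, start, end in record.partition_map
    }


def write_supermatrix_fasta(
    path: Union[str, Path], records: Sequence[SupermatrixRecord]
) -> None:
    with Path(path).open("w") as handle:
        for rec in records:
            handle.write(f">{rec.species}\n")
            for i in range(0, len(rec.sequence), 70):
                handle.write(rec.sequence[i : i + 70] + "\n")


def write_phylip(
    path: Union[str, Path], records: Sequence[SupermatrixRecord]
) -> None:
    """Relaxed sequential PHYLIP (full names, space-separated)."""
    if not records:
        raise ValueError("no records to write")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("supermatrix rows differ in length")
    with Path(path).open("w") as handle:
        handle.write(f"{len(records)} {lengths.pop()}\n")
        for rec in records:
            handle.write(f"{rec.species}  {rec.sequence}\n")


def write_partition_file(
    path: Union[str, Path], records: Sequence[SupermatrixRecord]
) -> None:
    """RAxML-style partition file: ``DNA, gene = start-end`` per block."""
    if not records:
        raise ValueError("no records to write")
    with Path(path).open("w") as handle:
        for gene, start, end in records[0].partition_map:
            handle.write(f"DNA, {gene} = {start}-{end}\n")
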