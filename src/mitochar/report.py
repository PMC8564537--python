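"""Orchestration: run every characterization stage and emit a report
bundle of machine-readable TSV tables.

Sequence-free mode is first-class: given only a feature table, the gene
summary, geometry, and validation sections run from coordinates alone —
a transcription of a published annotation table is a complete input.
Outputs are deterministic (no timestamps), so rerunning on identical
inputs reproduces identical bytes.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import codons, composition, geometry, repeats
from .io import read_fasta, read_feature_tables, read_genbank
from .model import AnnotationSet, CircularGenome, summarize_annotation

__all__ = ["RunConfig", "run_characterization"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for one characterization run.

    ``genome_paths`` may be empty (sequence-free mode), FASTA files whose
    record ids match the feature table's genome names, or GenBank files
    carrying their own annotations.
    """

    out_dir: str
    features_path: Optional[str] = None
    genome_paths: list[str] = field(default_factory=list)
    classes: list[str] = field(default_factory=lambda: ["whole", "PCG", "tRNA", "rRNA"])
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: dict(repeats.DEFAULT_SSR_THRESHOLDS)
    )
    circular: bool = True
    skew_precision: int = 4
    percent_precision: int = 2
    genome_lengths: dict[str, int] = field(default_factory=dict)

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        data["ssr_thresholds"] = {int(k): int(v) for k, v in self.ssr_thresholds.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["ssr_thresholds"] = {
            int(k): int(v) for k, v in data.get("ssr_thresholds", {}).items()
        }
        data["genome_lengths"] = {
            str(k): int(v) for k, v in data.get("genome_lengths", {}).items()
        }
        return cls(**data)


def _load_inputs(
    config: RunConfig,
) -> tuple[dict[str, CircularGenome], dict[str, AnnotationSet]]:
    genomes: dict[str, CircularGenome] = {}
    annotations: dict[str, AnnotationSet] = {}
    for path in config.genome_paths:
        p = Path(path)
        if p.suffix.lower() in (".gb", ".gbk", ".genbank"):
            genome, ann = read_genbank(p)
            genomes[genome.name] = genome
            annotations[genome.name] = ann
        else:
            for genome in read_fasta(p, circular=config.circular):
                genomes[genome.name] = genome
    if config.features_path:
        for name, ann in read_feature_tables(config.features_path).items():
            annotations[name] = ann
    for name, ann in annotations.items():
        if name in genomes:
            ann.genome_length = genomes[name].length
        elif name in config.genome_lengths:
            ann.genome_length = config.genome_lengths[name]
        if ann.genome_length is not None:
            for f in ann:
                if f.max_end > ann.genome_length:
                    raise ValueError(
                        f"{name}/{f.gene}: coordinate {f.max_end} exceeds "
                        f"genome length {ann.genome_length}"
                    )
    if not genomes and not annotations:
        raise ValueError("no inputs: provide genome_paths and/or features_path")
    return genomes, annotations


def run_characterization(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run all applicable stages; write TSVs under ``config.out_dir``.

    Returns the bundle as DataFrames keyed by section name.  Sections
    that need sequence are skipped (with a log line) in sequence-free
    mode.  Every declared-vs-computed mismatch lands in
    ``validation.tsv``.
    """
    genomes, annotations = _load_inputs(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, pd.DataFrame] = {}

    # gene summary (per circle + combined)
    rows = []
    for name, ann in annotations.items():
        rows.append({"genome": name, **ann.category_counts()})
    if annotations:
        rows.append({"genome": "combined", **summarize_annotation(*annotations.values())})
        bundle["summary"] = pd.DataFrame(rows)

    # geometry
    geo_rows = []
    validation: list[str] = []
    for name, ann in annotations.items():
        validation.extend(ann.validate_lengths())
        validation.extend(
            geometry.validate_declared_spacers(
                ann, ann.genome_length, config.circular and ann.genome_length is not None
            )
        )
        spacers = geometry.intergenic_spacers(
            ann,
            ann.genome_length,
            circular=config.circular and ann.genome_length is not None,
        )
        feats = sorted(ann.features, key=lambda f: (f.first_start, f.max_end))
        shared = {
            (p["pair"][0], p["pair"][1]): p["shared_bp"]
            for p in geometry.overlap_pairs(ann)
        }
        # spacers[i] has feats[i] as its upstream gene (last one wraps)
        spacer_by_upstream = {i: r for i, r in enumerate(spacers)}
        for i, f in enumerate(feats):
            rec = spacer_by_upstream.get(i)
            geo_rows.append(
                {
                    "genome": name,
                    "gene": f.gene,
                    "length": f.length,
                    "spacer_to_next": rec.spacer_bp if rec else None,
                    "next_gene": rec.downstream_gene if rec else None,
                    "wraps_origin": rec.wraps_origin if rec else False,
                    "shared_bp": shared.get(
                        (f.gene, rec.downstream_gene) if rec else None
                    ),
                }
            )
    if geo_rows:
        bundle["geometry"] = pd.DataFrame(geo_rows)

    # sequence-dependent sections
    seq_genomes = [g for n, g in genomes.items()]
    if seq_genomes:
        bundle["composition"] = composition.composition_report(
            seq_genomes, annotations, config.classes
        )
        cds_pool = []
        audits = []
        for name, genome in genomes.items():
            ann = annotations.get(name)
            if ann is None:
                continue
            for f in ann:
                if f.category in codons.CODING_CATEGORIES:
                    cds_pool.append(codons.extract_cds(genome, f))
            audit = codons.start_stop_audit(genome, ann, codons.CODING_CATEGORIES)
            if not audit.empty:
                audit.insert(0, "genome", name)
                audits.append(audit)
        if cds_pool:
            table = codons.codon_counts(cds_pool)
            codons.rscu(table)
            codons.classify_codons(table)
            bundle["rscu"] = table.to_frame()
        if audits:
            audit_df = pd.concat(audits, ignore_index=True)
            bundle["start_stop"] = audit_df
            for _, row in audit_df.iterrows():
                for col in ("init_matches_declared", "term_matches_declared"):
                    if col in row and row.get(col) is False:
                        validation.append(
                            f"{row['genome']}/{row['gene']}: computed "
                            f"{row['init_codon']}/{row['term_codon']} does not "
                            f"match declared codons"
                        )
        ssr_rows = []
        for name, genome in genomes.items():
            found = repeats.find_ssrs(
                genome, config.ssr_thresholds, annotations.get(name)
            )
            found += repeats.find_tandem_repeats(genome)
            for r in found:
                ssr_rows.append({"genome": name, **asdict(r)})
        bundle["ssr"] = pd.DataFrame(ssr_rows)
    else:
        logger.info("no sequences given; skipping composition/RSCU/SSR sections")

    bundle["validation"] = pd.DataFrame({"warning": validation})

    for section, frame in bundle.items():
        frame.to_csv(out_dir / f"{section}.tsv", sep="\t", index=False)
    return bundle
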