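"""Bundled reference data.

``ncadamba_tables.tsv`` is a hand transcription of the published
annotation tables for the two mitochondrial genome circles of
*Neolamarckia cadamba* (109,836 bp and 305,144 bp; GenBank MT320890 and
MT364442).  Typographically ambiguous GC-content cells in the source were
left blank rather than guessed.  ``PUBLISHED_BASE_COUNTS`` carries the
per-circle base tallies as printed for those deposited sequences, usable
as inputs where the sequences themselves are not (the toolkit never
downloads the accessions).

``ncadamba_like.yaml`` is a simulation template mirroring the headline
structure of the study system at one-tenth linear scale, for fast
synthetic end-to-end runs.
"""

from importlib import resources
from pathlib import Path

from ..io import read_feature_tables
from ..model import AnnotationSet

__all__ = [
    "reference_table_path",
    "load_reference_annotations",
    "simulation_template_path",
    "GENOME_LENGTHS",
    "PUBLISHED_BASE_COUNTS",
]

# circle lengths as deposited
GENOME_LENGTHS = {"genome1": 109_836, "genome2": 305_144}

# printed per-circle base tallies (bp)
PUBLISHED_BASE_COUNTS = {
    "genome1": {"A": 29_521, "T": 30_287, "G": 24_412, "C": 25_616},
    "genome2": {"A": 83_584, "T": 84_075, "G": 69_089, "C": 68_286},
}


def _data_path(name: str) -> Path:
    return Path(resources.files(__package__) / name)


def reference_table_path() -> Path:
    return _data_path("ncadamba_tables.tsv")


def simulation_template_path() -> Path:
    return _data_path("ncadamba_like.yaml")


def load_reference_annotations() -> dict[str, AnnotationSet]:
    """Both transcribed circles, with genome lengths attached."""
    sets = read_feature_tables(reference_table_path())
    for name, ann in sets.items():
        ann.genome_length = GENOME_LENGTHS.get(name)
    return sets
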