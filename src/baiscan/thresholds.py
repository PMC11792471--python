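"""Numeric thresholds of the bai-operon profiling pipeline.

Every cutoff used anywhere in the pipeline lives in a single frozen
:class:`Thresholds` object so that a run is fully described by one record:
reference-database inclusion rules, translated-read mapping rules, read
trimming parameters, operon-clustering rules and the bile acid phenotype
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

#: Default names for the eight gene families of the bile-acid-inducible
#: (bai) operon.  The names are conventional, not load-bearing: every
#: function accepting a ``families`` argument treats them as opaque labels
#: and only requires that there are exactly eight unique ones.
DEFAULT_FAMILIES: tuple[str, ...] = (
    "baiA", "baiB", "baiCD", "baiE", "baiF", "baiG", "baiH", "baiI",
)

N_FAMILIES = 8


def validate_families(families: tuple[str, ...]) -> tuple[str, ...]:
    families = tuple(families)
    if len(families) != N_FAMILIES:
        raise ValueError(f"expected {N_FAMILIES} gene families, got {len(families)}")
    if len(set(families)) != N_FAMILIES:
        raise ValueError("gene family names must be unique")
    return families


@dataclass(frozen=True)
class Thresholds:
    """All numeric cutoffs of the pipeline, with their standard defaults.

    Attributes
    ----------
    orf_min_identity:
        Minimum amino-acid identity for an ORF to match a seed bai sequence
        during reference-database construction.
    orf_min_length_fraction:
        Minimum alignment length for an ORF match, as a fraction of the
        90th-quantile alignment length recorded for that gene family.
    min_families_for_genome:
        A genome joins the reference database only if ORFs matched at least
        this many distinct bai families (out of eight).
    read_min_identity, read_min_alignment_aa:
        Translated-read mapping cutoffs: a read hit must reach this identity
        over at least this many aligned amino acids.
    pair_min_operon_coverage:
        Genome pairs whose summed per-family alignments cover less than this
        fraction of the operon's total sequence length are excluded from
        clustering.
    cluster_identity:
        Averaged amino-acid identity threshold for single-linkage clustering
        of bai-carrying genomes.
    pseudocount:
        Relative-abundance floor substituted for zero per-gene abundances
        before geometric means and log transforms.
    min_cluster_genes_detected:
        A cluster counts as detected in a sample when at least this many of
        its families recruited at least one read.
    trim_minlen, trim_trailing_q, trim_window, trim_window_q:
        Read QC parameters: minimum kept length, trailing-base quality
        cutoff, sliding-window width and mean-quality cutoff.
    phenotype_ratio_cutoff:
        DCA:CA ion-abundance ratio above which a sample is labelled
        high-secondary-bile-acid.
    """

    orf_min_identity: float = 0.70
    orf_min_length_fraction: float = 0.70
    min_families_for_genome: int = 4
    read_min_identity: float = 0.90
    read_min_alignment_aa: int = 25
    pair_min_operon_coverage: float = 0.80
    cluster_identity: float = 0.90
    pseudocount: float = 1e-9
    min_cluster_genes_detected: int = 4
    trim_minlen: int = 75
    trim_trailing_q: int = 20
    trim_window: int = 4
    trim_window_q: int = 20
    phenotype_ratio_cutoff: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "orf_min_identity",
            "orf_min_length_fraction",
            "read_min_identity",
            "pair_min_operon_coverage",
            "cluster_identity",
        ):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        for name in (
            "min_families_for_genome",
            "read_min_alignment_aa",
            "min_cluster_genes_detected",
            "trim_minlen",
            "trim_window",
        ):
            value = getattr(self, name)
            if not (isinstance(value, int) and value > 0):
                raise ValueError(f"{name} must be a positive integer, got {value}")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


DEFAULT_THRESHOLDS = Thresholds()
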