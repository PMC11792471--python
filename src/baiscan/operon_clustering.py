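"""Clustering of bai-carrying genomes by averaged operon identity.

For every pair of genomes the same-family bai sequences are aligned and the
per-family results pooled: averaged identity = (sum of matching amino acids)
/ (sum of alignment lengths) across the eight families.  Pairs for which
less than 80% of the operon's total sequence length aligned are excluded
(the denominator is the mean of the two genomes' summed bai gene lengths, a
symmetric choice).  Genomes are then clustered by single linkage at 90%
averaged identity: clusters are the connected components of the graph whose
edges are the non-excluded pairs at or above the threshold.  Single linkage
needs no extra parameters and is independent of input order; cluster ids
are canonicalized by each cluster's smallest member genome id.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .align import AlignmentBackend, align_protein
from .profiler import ReadHit
from .reference_db import ReferenceDB
from .thresholds import DEFAULT_THRESHOLDS, Thresholds


@dataclass(frozen=True)
class OperonPair:
    """Pooled alignment summary for one genome pair."""

    genome_a: str
    genome_b: str
    per_family: dict  # family -> (matching_residues, alignment_length)
    total_matching: int
    total_aligned: int
    total_bai_length: float  # mean of the two genomes' summed bai lengths

    @property
    def averaged_identity(self) -> float:
        return self.total_matching / self.total_aligned if self.total_aligned else 0.0

    @property
    def coverage(self) -> float:
        return self.total_aligned / self.total_bai_length if self.total_bai_length else 0.0

    def excluded(self, t: Thresholds = DEFAULT_THRESHOLDS) -> bool:
        return self.coverage < t.pair_min_operon_coverage


@dataclass(frozen=True)
class ClusterAssignment:
    """Genome -> cluster mapping with stable, order-independent ids."""

    genome_to_cluster: dict
    cluster_members: dict  # cluster_id -> sorted tuple of genome ids

    def __getitem__(self, genome_id: str) -> int:
        return self.genome_to_cluster[genome_id]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.genome_to_cluster.items()),
            columns=["genome_id", "cluster_id"],
        )


def pairwise_operon_identity(
    db: ReferenceDB,
    backend: AlignmentBackend | None = None,
) -> list[OperonPair]:
    """Averaged per-family identities for every genome pair in the database.

    Requires one sequence per (genome, family) — the dereplication rule of
    the reference-database builder guarantees this.  Families absent in
    either genome contribute nothing to the pooled alignment length.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    per_genome: dict[str, dict[str, str]] = {}
    for entry in db:
        fams = per_genome.setdefault(entry.genome_id, {})
        if entry.family in fams:
            raise ValueError(
                f"genome {entry.genome_id} has multiple sequences for family {entry.family}"
            )
        fams[entry.family] = entry.residues
    genomes = sorted(per_genome)
    total_length = {g: sum(len(s) for s in per_genome[g].values()) for g in genomes}

    pairs = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            shared = sorted(set(per_genome[ga]) & set(per_genome[gb]))
            per_family = {}
            matching = aligned = 0
            for fam in shared:
                hit = align_protein(per_genome[ga][fam], per_genome[gb][fam], ga, gb, backend)
                if hit is None:
                    continue
                per_family[fam] = (hit.matching_residues, hit.alignment_length)
                matching += hit.matching_residues
                aligned += hit.alignment_length
            pairs.append(
                OperonPair(
                    genome_a=ga,
                    genome_b=gb,
                    per_family=per_family,
                    total_matching=matching,
                    total_aligned=aligned,
                    total_bai_length=(total_length[ga] + total_length[gb]) / 2.0,
                )
            )
    return pairs


def cluster_genomes(
    pairs: Iterable[OperonPair],
    t: Thresholds = DEFAULT_THRESHOLDS,
    genomes: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Single-linkage clustering of genomes at the averaged-identity threshold.

    ``genomes`` may add isolated genomes not covered by any qualifying pair
    (each becomes a singleton cluster).  Cluster ids are consecutive
    integers starting at 1, ordered by each cluster's smallest genome id.
    """
    graph = nx.Graph()
    for g in genomes or []:
        graph.add_node(g)
    for pair in pairs:
        graph.add_node(pair.genome_a)
        graph.add_node(pair.genome_b)
        if not pair.excluded(t) and pair.averaged_identity >= t.cluster_identity:
            graph.add_edge(pair.genome_a, pair.genome_b)
    components = sorted(
        (tuple(sorted(c)) for c in nx.connected_components(graph)),
        key=lambda members: members[0],
    )
    genome_to_cluster = {}
    cluster_members = {}
    for cid, members in enumerate(components, start=1):
        cluster_members[cid] = members
        for g in members:
            genome_to_cluster[g] = cid
    return ClusterAssignment(genome_to_cluster, cluster_members)


def label_reads_with_clusters(
    hits: Iterable[ReadHit],
    assignment: ClusterAssignment,
) -> list[ReadHit]:
    """Attach each hit's best-reference cluster label (idempotent)."""
    labelled = []
    for hit in hits:
        if hit.genome_id not in assignment.genome_to_cluster:
            raise ValueError(f"genome {hit.genome_id} has no cluster assignment")
        labelled.append(replace(hit, cluster_id=assignment[hit.genome_id]))
    return labelled


def pairs_to_frame(pairs: Sequence[OperonPair], t: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome_a": [p.genome_a for p in pairs],
            "genome_b": [p.genome_b for p in pairs],
            "averaged_identity": [p.averaged_identity for p in pairs],
            "coverage": [p.coverage for p in pairs],
            "excluded": [int(p.excluded(t)) for p in pairs],
        }
    )


def write_cluster_outputs(
    pairs: Sequence[OperonPair],
    assignment: ClusterAssignment,
    prefix: str | Path,
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> None:
    """Write the pairs TSV and the clusters TSV under a common prefix."""
    prefix = Path(prefix)
    pairs_to_frame(pairs, t).to_csv(
        prefix.with_suffix(".pairs.tsv"), sep="\t", index=False, float_format="%.10g"
    )
    assignment.to_frame().to_csv(prefix.with_suffix(".clusters.tsv"), sep="\t", index=False)
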