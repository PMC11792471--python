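"""Construction of the dereplicated bai amino-acid reference database.

A reference database is the union of a curated *seed set* of bai gene
sequences (trusted with their family labels as given) and ORFs from
candidate genomes that match a seed sequence well enough.  The inclusion
rules are:

* an ORF matches family *g* when some seed sequence of family *g* aligns
  at >= 70% identity over >= 70% of the 90th-quantile alignment length
  recorded for that family;
* an ORF matching several families keeps only its best-identity family;
* a genome joins the database only when its ORFs matched at least four of
  the eight bai families, and then one representative ORF per
  (genome, family) is kept (highest identity wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentBackend, align_protein, check_protein
from .thresholds import DEFAULT_THRESHOLDS, Thresholds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceSequence:
    """One bai gene amino-acid sequence in the reference database."""

    sequence_id: str
    genome_id: str
    family: str
    residues: str
    origin: str = "seed_set"  # or "orf_match"
    cluster_id: Optional[int] = None

    def __post_init__(self) -> None:
        check_protein(self.residues, f"residues of {self.sequence_id}")
        if self.origin not in ("seed_set", "orf_match"):
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class ReferenceDB:
    """The dereplicated set of bai reference sequences.

    Entries are kept in a stable, sorted order (by sequence_id) so that two
    databases built from the same inputs compare equal and serialise
    byte-identically.
    """

    entries: list[ReferenceSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.sequence_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence_id(s): {dupes}")
        self.entries = sorted(self.entries, key=lambda e: e.sequence_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, ReferenceDB) and self.entries == other.entries

    @property
    def genomes(self) -> list[str]:
        return sorted({e.genome_id for e in self.entries})

    @property
    def families(self) -> list[str]:
        return sorted({e.family for e in self.entries})

    def by_id(self, sequence_id: str) -> ReferenceSequence:
        for e in self.entries:
            if e.sequence_id == sequence_id:
                return e
        raise KeyError(sequence_id)

    def sequences_for_genome(self, genome_id: str) -> list[ReferenceSequence]:
        return [e for e in self.entries if e.genome_id == genome_id]

    def with_clusters(self, genome_to_cluster: Mapping[str, int]) -> "ReferenceDB":
        """Return a copy whose entries carry cluster labels."""
        missing = {e.genome_id for e in self.entries} - set(genome_to_cluster)
        if missing:
            raise ValueError(f"no cluster assignment for genomes: {sorted(missing)}")
        return ReferenceDB(
            [replace(e, cluster_id=int(genome_to_cluster[e.genome_id])) for e in self.entries]
        )

    # ------------------------------------------------------------------ I/O

    def to_fasta(self, path: str | Path) -> None:
        """Write entries as FASTA with ``>sequence_id|genome_id|family`` headers."""
        records = [
            SeqRecord(Seq(e.residues), id=f"{e.sequence_id}|{e.genome_id}|{e.family}", description="")
            for e in self.entries
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, origin: str = "seed_set") -> "ReferenceDB":
        entries = []
        for record in SeqIO.parse(str(path), "fasta"):
            parts = record.id.split("|")
            if len(parts) != 3:
                raise ValueError(
                    f"malformed reference header {record.id!r}; expected seqid|genome|family"
                )
            seq_id, genome_id, fam = parts
            entries.append(
                ReferenceSequence(seq_id, genome_id, fam, str(record.seq).upper(), origin=origin)
            )
        return cls(entries)

    def write_index(self, path: str | Path) -> None:
        """Write the TSV index (sequence_id, genome_id, family, origin, cluster_id)."""
        frame = pd.DataFrame(
            {
                "sequence_id": [e.sequence_id for e in self.entries],
                "genome_id": [e.genome_id for e in self.entries],
                "family": [e.family for e in self.entries],
                "origin": [e.origin for e in self.entries],
                "cluster_id": [e.cluster_id if e.cluster_id is not None else "" for e in self.entries],
            }
        )
        frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class OrfMatch:
    """A qualifying ORF-to-family assignment found during DB construction."""

    orf_id: str
    genome_id: str
    family: str
    identity: float
    alignment_length: int
    residues: str


def family_q90_length(lengths: Sequence[int]) -> float:
    """90th quantile of recorded alignment lengths for one gene family.

    Linear interpolation between order statistics, the common quantile
    default; e.g. lengths 1..10 give 9.1.
    """
    lengths = list(lengths)
    if not lengths:
        raise ValueError("family_q90_length requires at least one alignment length")
    return float(np.quantile(np.asarray(lengths, dtype=float), 0.9))


def match_orfs(
    orf_sets: Mapping[str, Mapping[str, str]],
    seed_refs: Iterable[ReferenceSequence],
    t: Thresholds = DEFAULT_THRESHOLDS,
    backend: AlignmentBackend | None = None,
) -> list[OrfMatch]:
    """Assign ORFs to bai families by alignment against the seed set.

    Parameters
    ----------
    orf_sets:
        Mapping genome_id -> {orf_id -> amino-acid sequence}.
    seed_refs:
        Seed reference sequences carrying family labels.

    Notes
    -----
    The 90th-quantile alignment length for a family is computed over all
    seed-vs-ORF alignments of that family that reach ``orf_min_identity``;
    the length requirement is then applied in a second pass, so the quantile
    population does not depend on input order.
    """
    seed_refs = list(seed_refs)
    # first pass: best identity-qualifying alignment per (genome, orf, family)
    candidates: list[tuple[str, str, str, float, int, str]] = []
    per_family_lengths: dict[str, list[int]] = {}
    for genome_id, orfs in orf_sets.items():
        for orf_id, residues in orfs.items():
            best_per_family: dict[str, tuple[float, int]] = {}
            for ref in seed_refs:
                hit = align_protein(ref.residues, residues, ref.sequence_id, orf_id, backend)
                if hit is None or hit.identity < t.orf_min_identity:
                    continue
                prev = best_per_family.get(ref.family)
                key = (hit.identity, hit.alignment_length)
                if prev is None or key > prev:
                    best_per_family[ref.family] = key
            for fam, (identity, length) in best_per_family.items():
                per_family_lengths.setdefault(fam, []).append(length)
                candidates.append((genome_id, orf_id, fam, identity, length, residues))

    q90 = {fam: family_q90_length(ls) for fam, ls in per_family_lengths.items()}

    # second pass: length rule, then best family per ORF
    best_per_orf: dict[tuple[str, str], OrfMatch] = {}
    for genome_id, orf_id, fam, identity, length, residues in candidates:
        if length < t.orf_min_length_fraction * q90[fam]:
            continue
        match = OrfMatch(orf_id, genome_id, fam, identity, length, residues)
        prev = best_per_orf.get((genome_id, orf_id))
        # best identity wins; ties broken by lexicographic family name
        if (
            prev is None
            or match.identity > prev.identity
            or (match.identity == prev.identity and match.family < prev.family)
        ):
            best_per_orf[(genome_id, orf_id)] = match
    return sorted(best_per_orf.values(), key=lambda m: (m.genome_id, m.orf_id))


def call_bai_genomes(
    matches: Iterable[OrfMatch],
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> set[str]:
    """Genomes whose ORFs matched at least ``min_families_for_genome`` families."""
    families_per_genome: dict[str, set[str]] = {}
    for m in matches:
        families_per_genome.setdefault(m.genome_id, set()).add(m.family)
    return {
        genome
        for genome, fams in families_per_genome.items()
        if len(fams) >= t.min_families_for_genome
    }


def build_reference_db(
    seed_refs: Iterable[ReferenceSequence],
    orf_sets: Mapping[str, Mapping[str, str]],
    t: Thresholds = DEFAULT_THRESHOLDS,
    backend: AlignmentBackend | None = None,
) -> ReferenceDB:
    """Union of the seed set and qualifying ORF matches.

    For each qualifying genome, one ORF per family is kept (highest
    identity; ties broken by orf_id).
    """
    seed_refs = list(seed_refs)
    matches = match_orfs(orf_sets, seed_refs, t, backend)
    kept_genomes = call_bai_genomes(matches, t)
    best: dict[tuple[str, str], OrfMatch] = {}
    for m in matches:
        if m.genome_id not in kept_genomes:
            continue
        key = (m.genome_id, m.family)
        prev = best.get(key)
        if (
            prev is None
            or m.identity > prev.identity
            or (m.identity == prev.identity and m.orf_id < prev.orf_id)
        ):
            best[key] = m
    entries = list(seed_refs)
    for m in best.values():
        entries.append(
            ReferenceSequence(m.orf_id, m.genome_id, m.family, m.residues, origin="orf_match")
        )
    logger.info(
        "reference DB: %d seed + %d ORF-derived sequences from %d genomes",
        len(seed_refs), len(best), len(kept_genomes),
    )
    return ReferenceDB(entries)
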