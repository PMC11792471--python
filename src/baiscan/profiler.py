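"""Translated-read profiling of bai genes.

QC-passed nucleotide reads are translated in all six reading frames (stop
codons split a frame into segments, each handled independently) and each
segment is aligned against the amino-acid reference database.  A read is
assigned its single best hit — highest alignment score, ties broken by
lexicographically smallest reference sequence id — provided the hit reaches
90% identity over at least 25 aligned amino acids.

Per-family read counts divided by the QC-passed read count give per-gene
relative abundances; the operon-level abundance is the geometric mean of
the eight per-gene abundances, with zero abundances floored at the 1e-9
pseudocount.  The same rule applies per operon cluster, and a cluster
counts as *detected* in a sample when at least four of its families
recruited at least one read.

A shared-k-mer prefilter (exact amino-acid 5-mers) selects candidate
reference sequences before any alignment is computed; a read segment that
shares no 5-mer with a reference cannot reach 90% identity over 25
residues, so the filter does not change results, only cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentBackend, align_prepared, prepare
from .preprocess import QualityRead
from .reads import ReadBatch
from .reference_db import ReferenceDB
from .thresholds import DEFAULT_FAMILIES, DEFAULT_THRESHOLDS, N_FAMILIES, Thresholds, validate_families
from .translate import decode_aa, kmer_code_set, kmer_codes, six_frame_translations, translate_batch

KMER_K = 5


@dataclass(frozen=True)
class ReadHit:
    """Best single reference hit of one read."""

    read_id: str
    sequence_id: str
    family: str
    genome_id: str
    identity: float
    alignment_length: int
    score: int
    cluster_id: Optional[int] = None


class ReferenceIndex:
    """Amino-acid 5-mer index over a reference database.

    Maps each exact 5-mer to the reference entries containing it; used to
    shortlist alignment candidates for read segments and whole batches.
    """

    def __init__(self, db: ReferenceDB, k: int = KMER_K):
        from .translate import encode_aa

        self.db = db
        self.k = k
        self.entries = list(db.entries)
        self._aa_codes = [encode_aa(e.residues) for e in self.entries]
        kmer_to_entries: dict[int, list[int]] = {}
        for idx, codes in enumerate(self._aa_codes):
            for code in np.unique(kmer_codes(codes, k)):
                kmer_to_entries.setdefault(int(code), []).append(idx)
        self._kmer_to_entries = {
            code: np.asarray(idxs, dtype=np.int64) for code, idxs in kmer_to_entries.items()
        }
        self.kmer_sorted = np.fromiter(sorted(self._kmer_to_entries), dtype=np.int64)
        self._prepared: list = [None] * len(self.entries)

    def prepared(self, i: int):
        """Pre-encoded protein sequence of entry ``i`` (cached)."""
        if self._prepared[i] is None:
            self._prepared[i] = prepare(self.entries[i].residues)
        return self._prepared[i]

    def candidates(self, segment_codes: np.ndarray) -> list[int]:
        """Indices of reference entries sharing at least one k-mer."""
        found: set[int] = set()
        for code in np.unique(kmer_codes(segment_codes, self.k)):
            hit = self._kmer_to_entries.get(int(code))
            if hit is not None:
                found.update(int(i) for i in hit)
        return sorted(found)


def _segments(aa_codes: np.ndarray, min_len: int) -> list[np.ndarray]:
    """Maximal stop/X-free runs of a translated frame, at least ``min_len`` long."""
    coding = aa_codes < 20
    if not coding.any():
        return []
    boundaries = np.flatnonzero(np.diff(np.concatenate(([0], coding.view(np.int8), [0]))))
    return [
        aa_codes[start:end]
        for start, end in zip(boundaries[::2], boundaries[1::2])
        if end - start >= min_len
    ]


def map_read(
    read: QualityRead | str,
    db: ReferenceDB,
    t: Thresholds = DEFAULT_THRESHOLDS,
    index: ReferenceIndex | None = None,
    backend: AlignmentBackend | None = None,
) -> Optional[ReadHit]:
    """Best single reference hit of one read, or ``None``.

    Best = highest local-alignment score among hits satisfying the identity
    and length thresholds; score ties go to the lexicographically smallest
    reference sequence id.
    """
    if isinstance(read, QualityRead):
        read_id, seq = read.read_id, read.nucleotides
    else:
        read_id, seq = "read", str(read)
    if index is None:
        index = ReferenceIndex(db)
    best: tuple[tuple[int, str], ReadHit] | None = None
    for _frame, aa in six_frame_translations(seq):
        for segment in _segments(aa, t.read_min_alignment_aa):
            candidates = index.candidates(segment)
            if not candidates:
                continue
            peptide = decode_aa(segment)
            peptide_prepared = prepare(peptide) if backend is None else None
            for ei in candidates:
                entry = index.entries[ei]
                if backend is None:
                    result = align_prepared(peptide_prepared, index.prepared(ei))
                else:
                    result = backend(peptide, entry.residues)
                if result is None:
                    continue
                score, matches, length = result
                identity = matches / length
                if length < t.read_min_alignment_aa or identity < t.read_min_identity:
                    continue
                key = (-score, entry.sequence_id)
                if best is None or key < best[0]:
                    best = (
                        key,
                        ReadHit(
                            read_id=read_id,
                            sequence_id=entry.sequence_id,
                            family=entry.family,
                            genome_id=entry.genome_id,
                            identity=identity,
                            alignment_length=length,
                            score=score,
                            cluster_id=entry.cluster_id,
                        ),
                    )
    return best[1] if best else None


def _screen_batch(batch: ReadBatch, index: ReferenceIndex, t: Thresholds) -> np.ndarray:
    """Boolean mask of reads sharing at least one amino-acid k-mer with the DB."""
    n = len(batch)
    k = index.k
    cols = np.arange(batch.seq_codes.shape[1])
    codes = np.where(cols[None, :] < batch.lengths[:, None], batch.seq_codes, 4)
    candidate = np.zeros(n, dtype=bool)
    for frame in range(6):
        aa = translate_batch(codes, frame)
        m = aa.shape[1]
        if m < k:
            continue
        kcode = np.zeros((n, m - k + 1), dtype=np.int64)
        valid = np.ones((n, m - k + 1), dtype=bool)
        for i in range(k):
            window = aa[:, i : m - k + 1 + i]
            kcode = kcode * 20 + np.minimum(window, 19)
            valid &= window < 20
        rows, _ = np.nonzero(valid)
        shared = np.isin(kcode[valid], index.kmer_sorted)
        candidate[rows[shared]] = True
    return candidate


def map_reads(
    reads: ReadBatch | Sequence[QualityRead],
    db: ReferenceDB,
    t: Thresholds = DEFAULT_THRESHOLDS,
    index: ReferenceIndex | None = None,
    backend: AlignmentBackend | None = None,
) -> list[ReadHit]:
    """Map a read set; returns the best hit of every read that maps.

    For uniform-length batches a vectorized k-mer screen shortlists
    candidate reads first; results are identical to calling
    :func:`map_read` on every read.
    """
    if index is None:
        index = ReferenceIndex(db)
    if isinstance(reads, ReadBatch):
        batch = reads
        if len(batch) == 0:
            return []
        candidate_idx = (
            np.flatnonzero(_screen_batch(batch, index, t))
            if batch.uniform_length
            else np.arange(len(batch))
        )
        hits = []
        for i in candidate_idx:
            hit = map_read(
                QualityRead(batch.ids[i], batch.sequence(i), batch.quality(i)),
                db, t, index, backend,
            )
            if hit is not None:
                hits.append(hit)
        return hits
    hits = []
    for read in reads:
        hit = map_read(read, db, t, index, backend)
        if hit is not None:
            hits.append(hit)
    return hits


# ------------------------------------------------------------- abundances

def count_hits_by_family(
    hits: Iterable[ReadHit],
    families: tuple[str, ...] = DEFAULT_FAMILIES,
) -> dict[str, int]:
    families = validate_families(families)
    counts = {fam: 0 for fam in families}
    for hit in hits:
        if hit.family not in counts:
            raise ValueError(f"hit family {hit.family!r} not among configured families")
        counts[hit.family] += 1
    return counts


def gene_relative_abundances(
    counts: Mapping[str, int],
    denominator: int,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
) -> dict[str, float]:
    """Per-family read fraction: count / QC-passed read count."""
    families = validate_families(families)
    if denominator <= 0:
        raise ValueError("denominator (QC-passed read count) must be positive")
    return {fam: counts.get(fam, 0) / denominator for fam in families}


def operon_abundance(
    fractions: Mapping[str, float] | Sequence[float],
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> float:
    """Geometric mean of the eight per-gene abundances, zeros floored at the pseudocount."""
    values = list(fractions.values()) if isinstance(fractions, Mapping) else list(fractions)
    if len(values) != N_FAMILIES:
        raise ValueError(f"expected {N_FAMILIES} per-family fractions, got {len(values)}")
    if any(v < 0 for v in values):
        raise ValueError("fractions must be non-negative")
    floored = [v if v > 0 else t.pseudocount for v in values]
    return float(math.exp(sum(math.log(v) for v in floored) / N_FAMILIES))


@dataclass
class SampleProfile:
    """Per-sample bai profile: counts, fractions and operon abundances.

    ``cluster_counts`` etc. are keyed by cluster id and include every
    cluster passed to :func:`build_sample_profile`, so undetected clusters
    appear with zero counts (needed for prevalence denominators).
    """

    sample_id: str
    denominator: int
    families: tuple[str, ...]
    family_counts: dict[str, int]
    family_fractions: dict[str, float]
    operon_abundance: float
    cluster_counts: dict[int, dict[str, int]] = field(default_factory=dict)
    cluster_abundances: dict[int, float] = field(default_factory=dict)
    cluster_detected: dict[int, bool] = field(default_factory=dict)


def cluster_profiles(
    hits: Iterable[ReadHit],
    denominator: int,
    t: Thresholds = DEFAULT_THRESHOLDS,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    clusters: Sequence[int] | None = None,
) -> tuple[dict[int, dict[str, int]], dict[int, float], dict[int, bool]]:
    """Per-cluster family counts, operon abundances and detected flags.

    Every hit must carry a cluster label (reads are labelled by their
    best-hit reference's cluster).
    """
    families = validate_families(families)
    hits = list(hits)
    for hit in hits:
        if hit.cluster_id is None:
            raise ValueError(f"read {hit.read_id}: best-hit reference has no cluster label")
    cluster_ids = sorted(set(clusters or []) | {h.cluster_id for h in hits})
    counts = {cid: {fam: 0 for fam in families} for cid in cluster_ids}
    for hit in hits:
        counts[hit.cluster_id][hit.family] += 1
    abundances = {}
    detected = {}
    for cid in cluster_ids:
        fracs = gene_relative_abundances(counts[cid], denominator, families)
        abundances[cid] = operon_abundance(fracs, t)
        n_detected = sum(1 for fam in families if counts[cid][fam] > 0)
        detected[cid] = n_detected >= t.min_cluster_genes_detected
    return counts, abundances, detected


def build_sample_profile(
    sample_id: str,
    hits: Iterable[ReadHit],
    denominator: int,
    t: Thresholds = DEFAULT_THRESHOLDS,
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    clusters: Sequence[int] | None = None,
) -> SampleProfile:
    """Assemble the full per-sample profile from mapped hits."""
    families = validate_families(families)
    hits = list(hits)
    fam_counts = count_hits_by_family(hits, families)
    fractions = gene_relative_abundances(fam_counts, denominator, families)
    profile = SampleProfile(
        sample_id=sample_id,
        denominator=denominator,
        families=families,
        family_counts=fam_counts,
        family_fractions=fractions,
        operon_abundance=operon_abundance(fractions, t),
    )
    if (hits and all(h.cluster_id is not None for h in hits)) or clusters:
        counts, abundances, detected = cluster_profiles(hits, denominator, t, families, clusters)
        profile.cluster_counts = counts
        profile.cluster_abundances = abundances
        profile.cluster_detected = detected
    return profile


def profiles_to_frame(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    """Tidy long-format table of per-sample profiles (one row per quantity)."""
    rows = []
    for p in profiles:
        for fam in p.families:
            rows.append(
                (p.sample_id, "family", fam, "", p.family_counts[fam],
                 p.family_fractions[fam], "")
            )
        rows.append((p.sample_id, "operon", "", "", "", p.operon_abundance, ""))
        for cid in sorted(p.cluster_abundances):
            for fam in p.families:
                rows.append(
                    (p.sample_id, "cluster_family", fam, cid,
                     p.cluster_counts[cid][fam], "", "")
                )
            rows.append(
                (p.sample_id, "cluster_operon", "", cid, "",
                 p.cluster_abundances[cid], int(p.cluster_detected[cid]))
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "kind", "family", "cluster_id", "count", "value", "detected"],
    )


def write_profiles_tsv(profiles: Sequence[SampleProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False, float_format="%.10g")


def hits_to_frame(hits: Sequence[ReadHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [h.read_id for h in hits],
            "sequence_id": [h.sequence_id for h in hits],
            "family": [h.family for h in hits],
            "genome_id": [h.genome_id for h in hits],
            "cluster_id": [h.cluster_id if h.cluster_id is not None else "" for h in hits],
            "identity": [h.identity for h in hits],
            "alignment_length": [h.alignment_length for h in hits],
            "score": [h.score for h in hits],
        }
    )
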