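"""Pairwise protein alignment behind a pluggable backend contract.

The pipeline never cares *how* two amino-acid sequences are aligned, only
about three numbers per best local alignment: score, matching residues and
alignment length (gap columns included).  Identity is always
``matching_residues / alignment_length``, the reporting convention of the
translated-search tools this pipeline emulates.

The built-in backend is biotite's affine-gap local Smith-Waterman with
BLOSUM62 scoring (gap open 11, extend 1), the default scoring of standard
protein search tools, so identities are comparable to published values.
An external aligner can be plugged in as any callable with the same
signature as :func:`biotite_backend`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import biotite.sequence as _bseq
import biotite.sequence.align as _balign

#: Amino-acid alphabet accepted by the pipeline.  ``X`` marks an unknown
#: residue and never counts as a match.
VALID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GAP_OPEN = 11
GAP_EXTEND = 1

_MATRIX = _balign.SubstitutionMatrix.std_protein_matrix()  # BLOSUM62

#: A backend maps two residue strings to ``(score, matching_residues,
#: alignment_length)`` for the best local alignment, or ``None`` when no
#: positive-scoring local alignment exists.
AlignmentBackend = Callable[[str, str], Optional[tuple[int, int, int]]]


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    score: int
    matching_residues: int
    alignment_length: int

    @property
    def identity(self) -> float:
        """Matching residues over alignment length, gap columns included."""
        return self.matching_residues / self.alignment_length

    def __post_init__(self) -> None:
        if self.alignment_length <= 0:
            raise ValueError("alignment_length must be positive")
        if not 0 <= self.matching_residues <= self.alignment_length:
            raise ValueError("matching_residues must be within alignment_length")


def check_protein(sequence: str, what: str = "sequence") -> str:
    """Validate an amino-acid string against the accepted alphabet."""
    if not sequence:
        raise ValueError(f"{what} must be non-empty")
    bad = set(sequence) - VALID_ALPHABET
    if bad:
        raise ValueError(f"{what} contains invalid residues: {sorted(bad)!r}")
    return sequence


def _to_protein(sequence: str) -> _bseq.ProteinSequence:
    return _bseq.ProteinSequence(sequence)


def _summarise(alignment: _balign.Alignment) -> Optional[tuple[int, int, int]]:
    trace = alignment.trace
    length = trace.shape[0]
    if length == 0:
        return None
    q, s = alignment.sequences
    qi, si = trace[:, 0], trace[:, 1]
    both = (qi != -1) & (si != -1)
    qcode = np.asarray(q.code)[qi[both]]
    scode = np.asarray(s.code)[si[both]]
    # X never matches, not even X-vs-X
    x_code = q.alphabet.encode("X")
    matches = int(np.count_nonzero((qcode == scode) & (qcode != x_code)))
    return int(alignment.score), matches, length


def prepare(sequence: str) -> _bseq.ProteinSequence:
    """Pre-encode a residue string for repeated alignment calls."""
    return _to_protein(sequence)


def align_prepared(
    query: _bseq.ProteinSequence, subject: _bseq.ProteinSequence
) -> Optional[tuple[int, int, int]]:
    """Backend core on pre-encoded sequences (saves re-encoding in hot loops)."""
    alignments = _balign.align_optimal(
        query,
        subject,
        _MATRIX,
        gap_penalty=(-GAP_OPEN, -GAP_EXTEND),
        local=True,
        max_number=1,
    )
    if not alignments or alignments[0].score <= 0:
        return None
    return _summarise(alignments[0])


def biotite_backend(query: str, subject: str) -> Optional[tuple[int, int, int]]:
    """Affine-gap local Smith-Waterman via biotite (BLOSUM62, 11/1)."""
    return align_prepared(_to_protein(query), _to_protein(subject))


def align_protein(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    backend: AlignmentBackend | None = None,
) -> Optional[AlignmentHit]:
    """Best local alignment of ``query`` against ``subject``.

    Returns ``None`` when no positive-scoring local alignment exists
    (e.g. sequences with no residue pair scoring above zero).
    """
    check_protein(query, "query")
    check_protein(subject, "subject")
    result = (backend or biotite_backend)(query, subject)
    if result is None:
        return None
    score, matches, length = result
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=score,
        matching_residues=matches,
        alignment_length=length,
    )
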