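"""Codon tables, six-frame translation and amino-acid k-mer coding.

Nucleotides are coded A=0, C=1, G=2, T=3, N=4; amino acids are coded by
their index in :data:`AA_ORDER`, with 20 for a stop and 21 for X/unknown.
Translation uses the standard genetic code; any codon containing N
translates to X.  These integer codings let whole read batches be
translated and k-mer-screened with numpy table lookups.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NT_ORDER = "ACGT"
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODE = 20
X_CODE = 21

_NT_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(NT_ORDER):
    _NT_CODE[ord(_c)] = _i
    _NT_CODE[ord(_c.lower())] = _i

_AA_CODE = np.full(256, X_CODE, dtype=np.uint8)
for _i, _c in enumerate(AA_ORDER):
    _AA_CODE[ord(_c)] = _i
_AA_CODE[ord("*")] = STOP_CODE

_AA_CHAR = np.frombuffer((AA_ORDER + "*X").encode(), dtype=np.uint8)

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid lookup over base-5 codon codes (25*a + 5*b + c)
CODON_AA = np.full(125, X_CODE, dtype=np.uint8)
for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    _idx = 25 * NT_ORDER.index(_codon[0]) + 5 * NT_ORDER.index(_codon[1]) + NT_ORDER.index(_codon[2])
    CODON_AA[_idx] = AA_ORDER.index(_aa)
for _codon in _STANDARD_TABLE.stop_codons:
    _idx = 25 * NT_ORDER.index(_codon[0]) + 5 * NT_ORDER.index(_codon[1]) + NT_ORDER.index(_codon[2])
    CODON_AA[_idx] = STOP_CODE

#: amino acid -> tuple of synonymous codons, for seeded reverse translation
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_STANDARD_TABLE.forward_table.items()):
    CODONS_FOR_AA.setdefault(_aa, ())
    CODONS_FOR_AA[_aa] = CODONS_FOR_AA[_aa] + (_codon,)

FRAME_NAMES = ("+0", "+1", "+2", "-0", "-1", "-2")


def encode_nt(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 codes (unknown letters become N)."""
    return _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_nt(codes: np.ndarray) -> str:
    chars = np.frombuffer((NT_ORDER + "N").encode(), dtype=np.uint8)
    return chars[codes].tobytes().decode()


def encode_aa(seq: str) -> np.ndarray:
    return _AA_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def decode_aa(codes: np.ndarray) -> str:
    return _AA_CHAR[codes].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[..., ::-1]]


def translate_codes(codes: np.ndarray) -> np.ndarray:
    """Translate a 1-D nucleotide code array (frame 0, trailing bases ignored)."""
    n = (codes.size // 3) * 3
    c = codes[:n].reshape(-1, 3).astype(np.int64)
    return CODON_AA[25 * c[:, 0] + 5 * c[:, 1] + c[:, 2]]


def six_frame_translations(seq: str) -> list[tuple[str, np.ndarray]]:
    """All six reading-frame translations of ``seq`` as (frame, aa codes)."""
    fwd = encode_nt(seq)
    rev = revcomp_codes(fwd)
    out = []
    for name, strand in (("+", fwd), ("-", rev)):
        for offset in range(3):
            out.append((f"{name}{offset}", translate_codes(strand[offset:])))
    return out


def translate_batch(codes: np.ndarray, frame: int) -> np.ndarray:
    """Translate a (n_reads, length) nucleotide code matrix in one frame.

    ``frame`` indexes :data:`FRAME_NAMES`: 0-2 are forward offsets, 3-5 are
    offsets on the reverse complement.
    """
    if frame >= 3:
        codes = revcomp_codes(codes)
        frame -= 3
    length = codes.shape[1]
    n_codons = (length - frame) // 3
    window = codes[:, frame : frame + 3 * n_codons].reshape(codes.shape[0], n_codons, 3)
    window = window.astype(np.int64)
    return CODON_AA[25 * window[:, :, 0] + 5 * window[:, :, 1] + window[:, :, 2]]


def kmer_codes(aa_codes: np.ndarray, k: int = 5) -> np.ndarray:
    """Valid k-mer codes (base-20) of a peptide; k-mers touching stop/X are dropped.

    Works on 1-D (one peptide) or 2-D (batch) input; returns a flat array of
    the valid codes.
    """
    arr = np.atleast_2d(aa_codes)
    n, length = arr.shape
    if length < k:
        return np.zeros(0, dtype=np.int64)
    code = np.zeros((n, length - k + 1), dtype=np.int64)
    valid = np.ones((n, length - k + 1), dtype=bool)
    for i in range(k):
        window = arr[:, i : length - k + 1 + i]
        code = code * 20 + np.minimum(window, 19)
        valid &= window < 20
    return code[valid]


def kmer_code_set(aa_codes_list: list[np.ndarray], k: int = 5) -> np.ndarray:
    """Sorted unique k-mer codes across several peptides."""
    parts = [kmer_codes(c, k) for c in aa_codes_list]
    if not parts:
        return np.zeros(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))
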