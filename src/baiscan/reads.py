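"""A columnar container for read sets.

:class:`ReadBatch` stores a set of reads as integer-coded matrices so the
QC and mapping stages can work on whole batches with numpy, while
converting to and from per-read :class:`~baiscan.preprocess.QualityRead`
objects on demand.  Reads may have different lengths; matrices are padded
and a ``lengths`` vector records each read's true extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .preprocess import QualityRead
from .translate import decode_nt, encode_nt


@dataclass
class ReadBatch:
    ids: list[str]
    seq_codes: np.ndarray  # (n, max_len) uint8, A=0 C=1 G=2 T=3 N=4
    qualities: np.ndarray  # (n, max_len) uint8 Phred scores
    lengths: np.ndarray  # (n,) int64

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.seq_codes.shape != self.qualities.shape or self.seq_codes.shape[0] != n:
            raise ValueError("inconsistent ReadBatch dimensions")
        if self.lengths.shape != (n,):
            raise ValueError("lengths must have one entry per read")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def uniform_length(self) -> bool:
        return len(self) > 0 and bool((self.lengths == self.lengths[0]).all())

    def sequence(self, i: int) -> str:
        return decode_nt(self.seq_codes[i, : self.lengths[i]])

    def quality(self, i: int) -> tuple[int, ...]:
        return tuple(int(q) for q in self.qualities[i, : self.lengths[i]])

    def __iter__(self) -> Iterator[QualityRead]:
        for i in range(len(self)):
            yield QualityRead(self.ids[i], self.sequence(i), self.quality(i))

    def subset(self, mask_or_indices) -> "ReadBatch":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ReadBatch(
            [self.ids[i] for i in idx],
            self.seq_codes[idx],
            self.qualities[idx],
            self.lengths[idx],
        )

    def truncated(self, new_lengths: np.ndarray) -> "ReadBatch":
        """Batch with per-read lengths reduced to ``new_lengths`` (QC trim)."""
        new_lengths = np.asarray(new_lengths, dtype=np.int64)
        if (new_lengths > self.lengths).any():
            raise ValueError("truncation cannot extend reads")
        return ReadBatch(list(self.ids), self.seq_codes, self.qualities, new_lengths)

    @classmethod
    def from_reads(cls, reads: Iterable[QualityRead]) -> "ReadBatch":
        reads = list(reads)
        n = len(reads)
        width = max((len(r) for r in reads), default=0)
        seq = np.full((n, width), 4, dtype=np.uint8)
        qual = np.zeros((n, width), dtype=np.uint8)
        lengths = np.zeros(n, dtype=np.int64)
        ids = []
        for i, r in enumerate(reads):
            ids.append(r.read_id)
            lengths[i] = len(r)
            seq[i, : len(r)] = encode_nt(r.nucleotides)
            qual[i, : len(r)] = r.qualities
        return cls(ids, seq, qual, lengths)

    @classmethod
    def from_sequences(
        cls,
        ids: Sequence[str],
        sequences: Sequence[str],
        quality: int = 37,
    ) -> "ReadBatch":
        reads = [
            QualityRead(i, s, tuple([quality] * len(s))) for i, s in zip(ids, sequences)
        ]
        return cls.from_reads(reads)

    def write_fastq(self, path: str | Path) -> int:
        """Fast plain-text Phred+33 FASTQ writer for large batches."""
        with open(path, "w") as fh:
            for i in range(len(self)):
                quals = (self.qualities[i, : self.lengths[i]] + 33).tobytes().decode("ascii")
                fh.write(f"@{self.ids[i]}\n{self.sequence(i)}\n+\n{quals}\n")
        return len(self)
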