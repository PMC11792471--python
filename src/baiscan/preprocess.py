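"""Read quality control: trailing trim, sliding-window trim, length filter.

The QC chain is applied in a fixed order — trailing-quality trim, then
sliding-window trim, then a minimum-length filter (defaults 20 / 4:20 / 75)
— and the count of reads that survive is the denominator for every
relative-abundance estimate downstream.

Two equivalent implementations are provided: a per-read reference
implementation (:func:`qc_pipeline`) that states the semantics plainly, and
a vectorized batch path (:func:`qc_batch`) used for large simulated read
sets; the two are cross-checked in the test suite.

Sliding-window semantics: scanning 5'->3', the read is clipped at the start
of the first full window whose mean quality falls below the cutoff; reads
shorter than the window are evaluated as a single window of their full
length.  This is a simplification of the classic trimmer's re-scan inside
the failing window; the declared rule is unambiguous and is what the tests
pin down.

Trimming only ever truncates from the 3' end; bases are never modified.
Phred+33 quality encoding is assumed; scores above 60 are treated as
evidence of Phred+64 input and rejected.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .thresholds import DEFAULT_THRESHOLDS, Thresholds

logger = logging.getLogger(__name__)

MAX_PLAUSIBLE_PHRED = 60
_NT = frozenset("ACGTN")


@dataclass(frozen=True)
class QualityRead:
    """A nucleotide read with per-base Phred quality scores."""

    read_id: str
    nucleotides: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.nucleotides) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: {len(self.nucleotides)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        bad = set(self.nucleotides) - _NT
        if bad:
            raise ValueError(f"read {self.read_id}: invalid bases {sorted(bad)!r}")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.read_id}: negative quality score")
        if any(q > MAX_PLAUSIBLE_PHRED for q in self.qualities):
            raise ValueError(
                f"read {self.read_id}: quality score above {MAX_PLAUSIBLE_PHRED}; "
                "input looks Phred+64 encoded, only Phred+33 is supported"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)

    def truncated(self, length: int) -> "QualityRead":
        return QualityRead(self.read_id, self.nucleotides[:length], self.qualities[:length])


@dataclass(frozen=True)
class QCReport:
    """Accounting of a QC run; ``passed_reads`` is the abundance denominator."""

    input_reads: int
    passed_reads: int
    trimmed_bases: int
    dropped_short: int

    def __post_init__(self) -> None:
        if min(self.input_reads, self.passed_reads, self.trimmed_bases, self.dropped_short) < 0:
            raise ValueError("QC counts must be non-negative")
        if self.passed_reads + self.dropped_short != self.input_reads:
            raise ValueError("passed_reads + dropped_short must equal input_reads")


def trim_trailing(read: QualityRead, q: int) -> QualityRead:
    """Remove 3' bases whose quality is below ``q``, stopping at the first base >= q."""
    keep = len(read)
    while keep > 0 and read.qualities[keep - 1] < q:
        keep -= 1
    return read.truncated(keep)


def sliding_window_trim(read: QualityRead, window: int, q: int) -> QualityRead:
    """Clip at the start of the first window (5'->3') with mean quality < q."""
    n = len(read)
    if n == 0:
        return read
    quals = read.qualities
    if n < window:
        return read if sum(quals) / n >= q else read.truncated(0)
    for start in range(0, n - window + 1):
        if sum(quals[start : start + window]) / window < q:
            return read.truncated(start)
    return read


def qc_pipeline(
    reads: Iterable[QualityRead],
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[QualityRead], QCReport]:
    """Apply trailing trim, sliding-window trim and the length filter.

    Returns the surviving reads (input order preserved) and a
    :class:`QCReport` whose ``passed_reads`` is the relative-abundance
    denominator.
    """
    passed: list[QualityRead] = []
    n_in = trimmed = dropped = 0
    for read in reads:
        n_in += 1
        out = trim_trailing(read, t.trim_trailing_q)
        out = sliding_window_trim(out, t.trim_window, t.trim_window_q)
        trimmed += len(read) - len(out)
        if len(out) >= t.trim_minlen:
            passed.append(out)
        else:
            dropped += 1
    return passed, QCReport(n_in, len(passed), trimmed, dropped)


def qc_kept_lengths(
    qualities: np.ndarray,
    lengths: np.ndarray,
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Vectorized QC: kept length per read (0 when fully trimmed).

    ``qualities`` is a (n_reads, max_len) array; positions at and beyond
    each read's length are ignored.  Semantics identical to the per-read
    functions; the length filter is *not* applied here.
    """
    n, width = qualities.shape
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    cols = np.arange(width)
    valid = cols[None, :] < lengths[:, None]
    q = np.where(valid, qualities.astype(np.int64), -1)

    # trailing trim: last position with quality >= cutoff
    good = q >= t.trim_trailing_q
    any_good = good.any(axis=1)
    last_good = width - 1 - np.argmax(good[:, ::-1], axis=1)
    l1 = np.where(any_good, last_good + 1, 0)

    # sliding-window trim on the trailing-trimmed prefix
    w = t.trim_window
    valid1 = cols[None, :] < l1[:, None]
    qz = np.where(valid1, qualities, 0).astype(np.float64)
    csum = np.concatenate([np.zeros((n, 1)), np.cumsum(qz, axis=1)], axis=1)
    kept = l1.copy()

    if width >= w:
        means = (csum[:, w:] - csum[:, :-w]) / w  # window starting at col j
        starts = cols[: width - w + 1]
        in_range = starts[None, :] <= (l1[:, None] - w)  # full window inside read
        fails = (means[:, : width - w + 1] < t.trim_window_q) & in_range
        any_fail = fails.any(axis=1)
        first_fail = np.argmax(fails, axis=1)
        kept = np.where(any_fail, first_fail, kept)

    # reads shorter than the window: single window of full length
    short = (l1 > 0) & (l1 < w)
    if short.any():
        mean_short = csum[np.arange(n), l1] / np.maximum(l1, 1)
        kept = np.where(short & (mean_short < t.trim_window_q), 0, kept)
    return kept.astype(np.int64)


def qc_batch(
    qualities: np.ndarray,
    lengths: np.ndarray,
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[np.ndarray, QCReport]:
    """Vectorized QC including the length filter.

    Returns ``kept_lengths`` (0 for dropped reads) and the
    :class:`QCReport`.  A read passes when its kept length is at least
    ``trim_minlen``.
    """
    kept = qc_kept_lengths(qualities, lengths, t)
    passed_mask = kept >= t.trim_minlen
    trimmed = int((lengths - kept).sum())
    report = QCReport(
        input_reads=int(lengths.size),
        passed_reads=int(passed_mask.sum()),
        trimmed_bases=trimmed,
        dropped_short=int((~passed_mask).sum()),
    )
    return np.where(passed_mask, kept, 0), report


def remove_host_reads(
    reads: Sequence[QualityRead],
    host_filter: Callable[[QualityRead], bool] | None = None,
) -> list[QualityRead]:
    """Drop reads flagged as host-derived by ``host_filter``.

    The built-in default flags nothing: synthetic communities contain no
    host DNA.  A real screen (e.g. mapping against a human reference) can
    be supplied as any predicate on reads.
    """
    if host_filter is None:
        return list(reads)
    kept = [r for r in reads if not host_filter(r)]
    logger.info("host screen removed %d of %d reads", len(reads) - len(kept), len(reads))
    return kept


# ----------------------------------------------------------------- FASTQ I/O

def _open_text(path: str | Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[QualityRead]:
    """Iterate Phred+33 FASTQ records (optionally gzipped) as :class:`QualityRead`."""
    with _open_text(path, "r") as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield QualityRead(
                record.id,
                str(record.seq).upper(),
                tuple(record.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ (gzipped when the path ends in .gz)."""
    n = 0
    with _open_text(path, "w") as fh:
        for read in reads:
            quals = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.nucleotides}\n+\n{quals}\n")
            n += 1
    return n
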