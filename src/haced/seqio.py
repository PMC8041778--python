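"""FASTQ/FASTA input-output and Phred quality arithmetic.

Reads are the unit flowing through the whole pipeline: a sequence over
``{A, C, G, T, N}`` with one Sanger-encoded (+33) Phred score per base.
Quality scores are clamped at 60 on input; only the +33 dialect is
supported (MiSeq-era data).

The quality arithmetic here is the standard Phred algebra: a base with
quality ``q`` has accuracy ``1 - 10**(-q/10)`` (Q30 = 99.9%), and a read of
``L`` independent bases at per-base accuracy ``a`` contains at least one
error with probability ``1 - a**L`` (for a = 0.999 and L = 300 this is 26%,
which is why exact-match haplotype clustering needs error correction on top
of quality filtering).
"""

from __future__ import annotations

import gzip
import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np
from Bio import SeqIO as _BioSeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
MAX_QUALITY = 60

__all__ = [
    "Read",
    "ReadPair",
    "SeqRecord",
    "RunStats",
    "FastqParseError",
    "PairingError",
    "read_fastq",
    "read_fastq_paired",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "accuracy_from_phred",
    "read_error_probability",
    "compute_run_stats",
    "run_stats_table",
    "revcomp",
]


class FastqParseError(ValueError):
    """Malformed FASTQ record; the message names the offending line."""


class PairingError(ValueError):
    """R1 and R2 files hold unequal record counts."""


@dataclass
class Read:
    """A sequenced read: id, sequence and per-base Phred scores."""

    id: str
    seq: str
    qual: np.ndarray

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.int16)
        if len(self.qual) != len(self.seq):
            raise FastqParseError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        if len(self.qual) and (self.qual.min() < 0 or self.qual.max() > MAX_QUALITY):
            raise FastqParseError(
                f"read {self.id!r}: quality outside 0..{MAX_QUALITY}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Read):
            return NotImplemented
        return (
            self.id == other.id
            and self.seq == other.seq
            and np.array_equal(self.qual, other.qual)
        )


@dataclass(frozen=True)
class ReadPair:
    r1: Read
    r2: Read


@dataclass(frozen=True)
class SeqRecord:
    """A named reference sequence (IUPAC alphabet allowed)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")


@dataclass
class RunStats:
    """Per-sample retention statistics (reads in/out, bases, mean quality)."""

    n_read_pairs: int
    n_retained: int
    retained_pct: float
    n_bases_retained: int
    mean_quality: float
    sample: str = ""


_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: Union[str, Path], mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _decode_qual(qual_str: str, read_id: str) -> np.ndarray:
    q = np.frombuffer(qual_str.encode("ascii"), dtype=np.uint8).astype(np.int16)
    q -= PHRED_OFFSET
    if len(q) and q.min() < 0:
        raise FastqParseError(
            f"read {read_id!r}: quality character below '!' (+33 encoding assumed)"
        )
    np.minimum(q, MAX_QUALITY, out=q)
    return q


def read_fastq(path: Union[str, Path]) -> Iterator[Read]:
    """Stream reads from a (optionally gzipped) 4-line FASTQ file.

    Raises :class:`FastqParseError` naming the approximate line number on a
    malformed record. An empty file yields an empty stream.
    """
    n = 0
    with _open_text(path) as handle:
        it = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:  # Biopython's malformed-record errors
                raise FastqParseError(
                    f"{path}: malformed FASTQ record near line {4 * n + 1}: {exc}"
                ) from exc
            read_id = title.split()[0] if title else f"record{n}"
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: near line {4 * n + 1}: sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )
            yield Read(read_id, seq.upper(), _decode_qual(qual, read_id))
            n += 1


def read_fastq_paired(
    path_r1: Union[str, Path], path_r2: Union[str, Path]
) -> Iterator[ReadPair]:
    """Stream read pairs, paired by position in the R1/R2 files."""
    it1, it2 = read_fastq(path_r1), read_fastq(path_r2)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise PairingError(
                f"unequal record counts: {path_r1} and {path_r2} diverge "
                f"after {n} pairs"
            )
        yield ReadPair(r1, r2)
        n += 1


def write_fastq(reads: Iterable[Read], path: Union[str, Path]) -> int:
    """Write reads as 4-line +33 FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(int(q) + PHRED_OFFSET) for q in read.qual)
            handle.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: Union[str, Path]) -> list[SeqRecord]:
    with _open_text(path) as handle:
        return [
            SeqRecord(rec.id, str(rec.seq).upper())
            for rec in _BioSeqIO.parse(handle, "fasta")
        ]


def write_fasta(records: Iterable[SeqRecord], path: Union[str, Path]) -> int:
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.seq}\n")
            n += 1
    return n


def accuracy_from_phred(q: float) -> float:
    """Per-base accuracy ``1 - 10**(-q/10)`` for a (possibly fractional) Phred score."""
    if q < 0:
        raise ValueError(f"Phred score must be non-negative, got {q}")
    return 1.0 - 10.0 ** (-q / 10.0)


def read_error_probability(per_base_accuracy: float, read_length: int) -> float:
    """Probability of at least one error in a read of the given length."""
    if not 0.0 <= per_base_accuracy <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {per_base_accuracy}")
    if read_length < 0:
        raise ValueError(f"read length must be non-negative, got {read_length}")
    return 1.0 - per_base_accuracy**read_length


def compute_run_stats(
    reads_in: Union[int, Iterable[Read]],
    reads_retained: Iterable[Read],
    sample: str = "",
) -> RunStats:
    """Retention statistics for one sample.

    ``reads_in`` may be the input read count or the input stream itself.
    ``retained_pct`` is 100 * retained / input; ``mean_quality`` is the
    arithmetic mean over all retained base qualities.
    """
    n_in = reads_in if isinstance(reads_in, int) else sum(1 for _ in reads_in)
    n_ret = 0
    n_bases = 0
    qual_sum = 0.0
    for read in reads_retained:
        n_ret += 1
        n_bases += len(read)
        qual_sum += float(read.qual.sum())
    if n_in == 0:
        warnings.warn("no input reads: retained_pct reported as 0", stacklevel=2)
        pct = 0.0
    else:
        pct = 100.0 * n_ret / n_in
    mean_q = qual_sum / n_bases if n_bases else 0.0
    return RunStats(n_in, n_ret, pct, n_bases, mean_q, sample=sample)


def run_stats_table(stats: Sequence[RunStats]):
    """Collect RunStats rows into a DataFrame with table-style headers."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample": [s.sample for s in stats],
            "paired_end_reads": [s.n_read_pairs for s in stats],
            "retained_reads": [s.n_retained for s in stats],
            "remaining_pct": [round(s.retained_pct, 1) for s in stats],
            "retained_bases": [s.n_bases_retained for s in stats],
            "mean_base_quality": [round(s.mean_quality, 2) for s in stats],
        }
    )
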