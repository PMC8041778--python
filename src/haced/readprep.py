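"""Paired-end merging, all-bases quality filtering and fixed-length trimming.

The merger reproduces the behaviour envelope of overlap-based read joiners:
mate 2 is reverse-complemented, every admissible overlap length is scored by
its mismatch ratio, and the best (lowest-ratio, ties broken toward the
longer overlap) wins provided the ratio does not exceed ``max_mismatch_ratio``.
Within the overlap the higher-quality base is kept with its quality;
agreeing bases keep the max of the two qualities; a tie between different
bases keeps the mate-1 base at the min quality.

The non-UMI branch of the pipeline then trims the fixed primer/adapter
lengths (20 nt at 5', 22 nt at 3' by default, leaving the 365-base target
window) and prunes any read containing one or more bases below Q30.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .seqio import Read, ReadPair, revcomp

__all__ = [
    "MergeParams",
    "TrimSpec",
    "MergeStats",
    "merge_pair",
    "merge_pairs",
    "q30_filter",
    "trim_fixed",
    "trim_many",
]

_BASE_TO_U8 = np.zeros(128, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _BASE_TO_U8[ord(_c)] = _i
_U8_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _seq_to_u8(seq: str) -> np.ndarray:
    return _BASE_TO_U8[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _u8_to_seq(arr: np.ndarray) -> str:
    return _U8_TO_BASE[arr].tobytes().decode("ascii")


@dataclass(frozen=True)
class MergeParams:
    """Overlap-search window and mismatch tolerance for pair merging."""

    min_overlap: int = 10
    max_overlap: int = 300
    max_mismatch_ratio: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap <= self.max_overlap:
            raise ValueError("require 0 < min_overlap <= max_overlap")


@dataclass(frozen=True)
class TrimSpec:
    """Fixed-length primer/adapter trim (defaults: 20 nt 5', 22 nt 3')."""

    trim5: int = 20
    trim3: int = 22

    def __post_init__(self) -> None:
        if self.trim5 < 0 or self.trim3 < 0:
            raise ValueError("trim lengths must be non-negative")


@dataclass
class MergeStats:
    n_pairs: int = 0
    n_merged: int = 0
    n_failed: int = 0


def _assemble(r1: Read, b_seq: np.ndarray, b_qual: np.ndarray,
              overlap: int) -> Read:
    """Build the merged read given mate 1, reverse-complemented mate 2 and
    the chosen overlap length."""
    a_seq = _seq_to_u8(r1.seq)
    a_qual = np.asarray(r1.qual, dtype=np.int16)
    la = len(a_seq)
    ov_a_seq = a_seq[la - overlap:]
    ov_a_q = a_qual[la - overlap:]
    ov_b_seq = b_seq[:overlap]
    ov_b_q = b_qual[:overlap]

    take_b = ov_b_q > ov_a_q
    ov_seq = np.where(take_b, ov_b_seq, ov_a_seq)
    ov_q = np.where(take_b, ov_b_q, ov_a_q)
    agree = ov_a_seq == ov_b_seq
    ov_q = np.where(agree, np.maximum(ov_a_q, ov_b_q), ov_q)
    # equal qualities, different bases: mate-1 base at min quality
    tie = (~agree) & (ov_a_q == ov_b_q)
    ov_seq = np.where(tie, ov_a_seq, ov_seq)
    ov_q = np.where(tie, np.minimum(ov_a_q, ov_b_q), ov_q)

    seq = np.concatenate([a_seq[: la - overlap], ov_seq, b_seq[overlap:]])
    qual = np.concatenate([a_qual[: la - overlap], ov_q, b_qual[overlap:]])
    return Read(r1.id, _u8_to_seq(seq), qual)


def merge_pair(pair: ReadPair, params: MergeParams = MergeParams()) -> Optional[Read]:
    """Merge one read pair; returns None on merge failure.

    The overlap length minimising the mismatch ratio wins (ties go to the
    longer overlap); the merge fails when even the best ratio exceeds
    ``max_mismatch_ratio``.
    """
    if not len(pair.r1) or not len(pair.r2):
        raise ValueError("both mates must be non-empty")
    a = _seq_to_u8(pair.r1.seq)
    b = _seq_to_u8(revcomp(pair.r2.seq))
    hi = min(params.max_overlap, len(a), len(b))
    if hi < params.min_overlap:
        return None
    best_o = best_m = -1
    for o in range(params.min_overlap, hi + 1):
        m = int(np.count_nonzero(a[len(a) - o:] != b[:o]))
        # ratio m/o <= best_m/best_o, ties -> longer overlap (later o)
        if best_o < 0 or m * best_o <= best_m * o:
            best_o, best_m = o, m
    if best_m > params.max_mismatch_ratio * best_o:
        return None
    b_qual = np.asarray(pair.r2.qual, dtype=np.int16)[::-1]
    return _assemble(pair.r1, b, b_qual, best_o)


def merge_pairs(
    pairs: Sequence[ReadPair], params: MergeParams = MergeParams()
) -> tuple[list[Read], MergeStats]:
    """Merge many pairs, vectorising the overlap scan over same-length batches.

    Equivalent to calling :func:`merge_pair` per pair, but the mismatch
    counting runs across all pairs of a given (len1, len2) at once.
    """
    pairs = list(pairs)
    stats = MergeStats(n_pairs=len(pairs))
    out: list[Optional[Read]] = [None] * len(pairs)

    groups: dict[tuple[int, int], list[int]] = {}
    for i, p in enumerate(pairs):
        groups.setdefault((len(p.r1), len(p.r2)), []).append(i)

    for (l1, l2), idx in groups.items():
        if l1 == 0 or l2 == 0:
            raise ValueError("both mates must be non-empty")
        hi = min(params.max_overlap, l1, l2)
        if hi < params.min_overlap:
            continue
        if len(idx) < 32:
            for i in idx:
                out[i] = merge_pair(pairs[i], params)
            continue
        A = np.empty((len(idx), l1), dtype=np.uint8)
        B = np.empty((len(idx), l2), dtype=np.uint8)
        BQ = np.empty((len(idx), l2), dtype=np.int16)
        for row, i in enumerate(idx):
            A[row] = _seq_to_u8(pairs[i].r1.seq)
            B[row] = _seq_to_u8(revcomp(pairs[i].r2.seq))
            BQ[row] = np.asarray(pairs[i].r2.qual, dtype=np.int16)[::-1]
        best_o = np.full(len(idx), -1, dtype=np.int64)
        best_m = np.full(len(idx), -1, dtype=np.int64)
        for o in range(params.min_overlap, hi + 1):
            m = np.count_nonzero(A[:, l1 - o:] != B[:, :o], axis=1)
            better = (best_o < 0) | (m * best_o <= best_m * o)
            best_o[better] = o
            best_m[better] = m[better]
        ok = best_m <= params.max_mismatch_ratio * best_o
        for row, i in enumerate(idx):
            if ok[row]:
                out[i] = _assemble(pairs[i].r1, B[row], BQ[row], int(best_o[row]))

    merged = [r for r in out if r is not None]
    stats.n_merged = len(merged)
    stats.n_failed = stats.n_pairs - stats.n_merged
    return merged, stats


def q30_filter(
    reads: Iterable[Read], min_q: int = 30, require_all: bool = True
) -> Iterator[Read]:
    """Retain reads whose bases are all at or above ``min_q``.

    With ``require_all=False`` the criterion relaxes to the mean quality.
    """
    for read in reads:
        if not len(read):
            continue
        if require_all:
            if read.qual.min() >= min_q:
                yield read
        elif read.qual.mean() >= min_q:
            yield read


def trim_fixed(read: Read, spec: TrimSpec = TrimSpec()) -> Optional[Read]:
    """Cut fixed lengths off both ends; None (dropped) if the read is too short."""
    if len(read) <= spec.trim5 + spec.trim3:
        return None
    end = len(read) - spec.trim3
    return Read(read.id, read.seq[spec.trim5:end], read.qual[spec.trim5:end])


def trim_many(
    reads: Iterable[Read], spec: TrimSpec = TrimSpec()
) -> tuple[list[Read], int]:
    """Trim a stream; returns (kept reads, number dropped as too short)."""
    kept: list[Read] = []
    dropped = 0
    for read in reads:
        t = trim_fixed(read, spec)
        if t is None:
            dropped += 1
        else:
            kept.append(t)
    return kept, dropped
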