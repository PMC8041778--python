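"""UMI extraction, family grouping and consensus calling.

A unique molecular identifier (UMI) is a random oligonucleotide attached
once per template molecule before amplification; reads sharing a UMI derive
from the same molecule, so their per-position disagreements are PCR or
sequencing errors and can be voted away. The read structure is described by
a 5'-anchored mask over ``{n, N}``: ``n`` marks a constant position to
discard, ``N`` a UMI position (``nnnNNNNNNNNNNNNN`` = 3 constant bases then
a 13-base UMI).

Consensus calling is a quality-weighted per-position majority vote with an
agreement floor: a family is rejected rather than allowed to emit an
invented base. Members whose length differs from the family's modal length
are excluded from voting (indel-bearing reads on a fixed-length amplicon).
Consensus qualities are capped (default Q40).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .readprep import _seq_to_u8, _u8_to_seq
from .seqio import Read

__all__ = [
    "UmiMask",
    "UmiFamily",
    "ConsensusRead",
    "ConsensusParams",
    "ConsensusResult",
    "UmiTally",
    "extract_umi",
    "group_families",
    "call_consensus",
    "consensus_reads",
]

DEFAULT_MASK = "nnnNNNNNNNNNNNNN"


@dataclass(frozen=True)
class UmiMask:
    """5'-anchored read-structure mask over {n, N}; N positions hold the UMI."""

    mask: str = DEFAULT_MASK

    def __post_init__(self) -> None:
        if set(self.mask) - {"n", "N"}:
            raise ValueError("mask may contain only 'n' and 'N'")
        n_umi = self.mask.count("N")
        if n_umi < 1:
            raise ValueError("mask must contain at least one N (UMI) position")
        first = self.mask.index("N")
        if self.mask[first : first + n_umi] != "N" * n_umi:
            raise ValueError("UMI (N) positions must be contiguous")

    def __len__(self) -> int:
        return len(self.mask)

    @property
    def umi_start(self) -> int:
        return self.mask.index("N")

    @property
    def umi_len(self) -> int:
        return self.mask.count("N")


@dataclass
class UmiFamily:
    """Reads (mask-stripped) sharing one UMI."""

    umi: str
    members: list[Read]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusRead:
    """Error-corrected consensus of a UMI family; qualities capped."""

    umi: str
    seq: str
    qual: np.ndarray
    family_size: int

    @property
    def id(self) -> str:
        return f"umi:{self.umi}"

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ConsensusParams:
    min_family_size: int = 3
    min_agreement: float = 0.7
    quality_cap: int = 40

    def __post_init__(self) -> None:
        if self.min_family_size < 1:
            raise ValueError("min_family_size must be >= 1")
        if not 0.5 < self.min_agreement <= 1.0:
            raise ValueError("min_agreement must be in (0.5, 1]")


@dataclass
class ConsensusResult:
    """Outcome of one family's consensus call; ``consensus`` is None on rejection."""

    consensus: Optional[ConsensusRead]
    reason: str  # "ok" | "family-too-small" | "ambiguous" | "length-excluded"
    n_voters: int = 0


@dataclass
class UmiTally:
    """Read bookkeeping through UMI processing; every input read lands in
    exactly one bucket."""

    n_input: int = 0
    n_too_short: int = 0
    n_umi_invalid: int = 0
    n_grouped: int = 0
    n_family_too_small: int = 0
    n_ambiguous: int = 0
    n_length_excluded: int = 0
    n_consensus_members: int = 0


def extract_umi(read: Read, mask: UmiMask = UmiMask()) -> Optional[tuple[str, Read]]:
    """Split a read into (UMI, payload) under the mask.

    Returns None for reads shorter than the mask or whose UMI contains N.
    """
    ml = len(mask)
    if len(read) <= ml:
        return None
    umi = read.seq[mask.umi_start : mask.umi_start + mask.umi_len]
    if "N" in umi:
        return None
    payload = Read(read.id, read.seq[ml:], read.qual[ml:])
    return umi, payload


def group_families(
    reads: Iterable[Read],
    mask: UmiMask = UmiMask(),
    merge_1mm: bool = False,
    tally: Optional[UmiTally] = None,
) -> list[UmiFamily]:
    """Group reads into UMI families by exact UMI match.

    With ``merge_1mm``, a family whose size is at most 1/10 of a family at
    Hamming distance 1 is absorbed into the larger one (sequencing errors in
    the UMI itself).
    """
    tally = tally if tally is not None else UmiTally()
    buckets: dict[str, list[Read]] = {}
    for read in reads:
        tally.n_input += 1
        if len(read) <= len(mask):
            tally.n_too_short += 1
            continue
        hit = extract_umi(read, mask)
        if hit is None:
            tally.n_umi_invalid += 1
            continue
        umi, payload = hit
        buckets.setdefault(umi, []).append(payload)
        tally.n_grouped += 1

    if merge_1mm:
        _absorb_1mm(buckets)

    families = [UmiFamily(umi, members) for umi, members in buckets.items()]
    families.sort(key=lambda f: (-f.size, f.umi))
    return families


def _absorb_1mm(buckets: dict[str, list[Read]]) -> None:
    """Absorb small families into 10x-larger Hamming-1 neighbours, smallest first."""
    alphabet = "ACGT"
    for umi in sorted(buckets, key=lambda u: (len(buckets[u]), u)):
        members = buckets.get(umi)
        if members is None:
            continue
        best: Optional[str] = None
        for i, c in enumerate(umi):
            for alt in alphabet:
                if alt == c:
                    continue
                neighbour = umi[:i] + alt + umi[i + 1:]
                other = buckets.get(neighbour)
                if other is not None and len(members) * 10 <= len(other):
                    if best is None or len(buckets[best]) < len(other):
                        best = neighbour
        if best is not None:
            buckets[best].extend(members)
            del buckets[umi]


def call_consensus(
    family: UmiFamily, params: ConsensusParams = ConsensusParams()
) -> ConsensusResult:
    """Quality-weighted majority consensus of one family.

    Per position the base with the largest summed quality wins; its quality
    is ``min(cap, sum(support) - sum(dissent))`` floored at 2. The family is
    rejected when smaller than ``min_family_size``, when any position's
    winning base is carried by fewer than ``min_agreement`` of the voting
    reads (or ties at equal weight), or when every member is excluded by the
    modal-length rule.
    """
    if family.size < params.min_family_size:
        return ConsensusResult(None, "family-too-small")

    lengths = Counter(len(m) for m in family.members)
    # modal length; ties broken toward the longer read
    modal_len = max(lengths, key=lambda L: (lengths[L], L))
    voters = [m for m in family.members if len(m) == modal_len]
    if not voters:
        return ConsensusResult(None, "length-excluded")

    k = len(voters)
    seqs = np.empty((k, modal_len), dtype=np.uint8)
    quals = np.empty((k, modal_len), dtype=np.int32)
    for i, m in enumerate(voters):
        seqs[i] = _seq_to_u8(m.seq)
        quals[i] = m.qual
    # weights[b, j]: summed quality supporting base b at position j (N never wins)
    weights = np.zeros((4, modal_len), dtype=np.int64)
    counts = np.zeros((4, modal_len), dtype=np.int64)
    for b in range(4):
        hits = seqs == b
        weights[b] = (quals * hits).sum(axis=0)
        counts[b] = hits.sum(axis=0)

    winner = weights.argmax(axis=0)
    cols = np.arange(modal_len)
    w_win = weights[winner, cols]
    # tie at equal top weight -> ambiguous
    tied = (weights == w_win).sum(axis=0) > 1
    if tied.any():
        return ConsensusResult(None, "ambiguous", n_voters=k)
    if (counts[winner, cols] < params.min_agreement * k).any():
        return ConsensusResult(None, "ambiguous", n_voters=k)

    dissent = weights.sum(axis=0) - w_win
    qual = np.clip(w_win - dissent, 2, params.quality_cap).astype(np.int16)
    seq = _u8_to_seq(winner.astype(np.uint8))
    return ConsensusResult(
        ConsensusRead(family.umi, seq, qual, family.size), "ok", n_voters=k
    )


def consensus_reads(
    families: Iterable[UmiFamily],
    params: ConsensusParams = ConsensusParams(),
    tally: Optional[UmiTally] = None,
) -> list[ConsensusRead]:
    """Call consensus over many families, tallying rejection reasons."""
    tally = tally if tally is not None else UmiTally()
    out: list[ConsensusRead] = []
    for family in families:
        result = call_consensus(family, params)
        if result.consensus is not None:
            out.append(result.consensus)
            tally.n_consensus_members += result.n_voters
            tally.n_length_excluded += family.size - result.n_voters
        elif result.reason == "family-too-small":
            tally.n_family_too_small += family.size
        elif result.reason == "ambiguous":
            tally.n_ambiguous += family.size
        else:
            tally.n_length_excluded += family.size
    return out
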