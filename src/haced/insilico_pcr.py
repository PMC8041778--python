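"""In-silico PCR: locate degenerate primer pairs and predict amplicons.

Primers may contain IUPAC ambiguity codes (Y = C/T, R = A/G, N = any, ...).
The forward primer is searched on the forward strand and the reverse primer
as its reverse complement downstream; a hit spans both primers inclusively.
Circular references (mitogenomes) are scanned on the doubled sequence and
deduplicated, so amplicons wrapping the origin are found.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values as _IUPAC

from .seqio import SeqRecord, revcomp

__all__ = ["Primer", "AmpliconHit", "iupac_match", "find_amplicons", "hits_to_frame"]


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("primer sequence must be non-empty")
        bad = set(self.seq.upper()) - set(_IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letters in primer {self.name}: {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AmpliconHit:
    """0-based half-open span on the reference forward strand, forward
    primer through reverse-complemented reverse primer inclusive."""

    ref_id: str
    start: int
    end: int
    fwd_name: str
    rev_name: str

    @property
    def length(self) -> int:
        return self.end - self.start


def iupac_match(pattern_base: str, target_base: str) -> bool:
    """True iff the concrete target base is in the IUPAC expansion of the
    pattern base."""
    p = pattern_base.upper()
    t = target_base.upper()
    if p not in _IUPAC:
        raise ValueError(f"invalid IUPAC pattern letter {pattern_base!r}")
    if t not in "ACGT":
        raise ValueError(f"target base must be one of ACGT, got {target_base!r}")
    return t in _IUPAC[p]


def _pattern_regex(primer_seq: str) -> re.Pattern:
    body = "".join(
        c if len(_IUPAC[c]) == 1 else f"[{_IUPAC[c]}]" for c in primer_seq.upper()
    )
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def _find_sites(seq: str, primer_seq: str, max_mismatch: int) -> list[int]:
    if max_mismatch == 0:
        return [m.start() for m in _pattern_regex(primer_seq).finditer(seq)]
    # sliding-window mismatch count against the IUPAC expansion table
    L = len(primer_seq)
    if L > len(seq):
        return []
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, L)
    allowed = np.zeros((L, 128), dtype=bool)
    for j, c in enumerate(primer_seq.upper()):
        for t in _IUPAC[c]:
            allowed[j, ord(t)] = True
    ok = allowed[np.arange(L)[None, :], windows]
    mism = L - ok.sum(axis=1)
    return list(np.nonzero(mism <= max_mismatch)[0])


def find_amplicons(
    reference: SeqRecord,
    fwd: Primer,
    rev: Primer,
    max_len: Optional[int] = None,
    circular: bool = False,
    max_mismatch: int = 0,
) -> list[AmpliconHit]:
    """All predicted amplicons for a primer pair on one reference.

    Pairs every forward-primer site with every downstream reverse-primer
    site (reverse complement on the forward strand) whose total span does
    not exceed ``max_len``. Returns an empty list when nothing amplifies.
    """
    if len(fwd) >= len(reference.seq) or len(rev) >= len(reference.seq):
        raise ValueError("primers must be shorter than the reference")
    L = len(reference.seq)
    seq = reference.seq.upper()
    scan = seq + seq[: L - 1] if circular else seq
    rev_rc = revcomp(rev.seq)

    fwd_sites = [p for p in _find_sites(scan, fwd.seq, max_mismatch) if p < L]
    rev_sites = _find_sites(scan, rev_rc, max_mismatch)

    hits = []
    seen = set()
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev)
            if end - f < len(fwd) + len(rev):
                continue
            if max_len is not None and end - f > max_len:
                continue
            if circular and end - f > L:
                continue
            key = (f % L, (end - f))
            if key in seen:
                continue
            seen.add(key)
            hits.append(AmpliconHit(reference.id, f, end, fwd.name, rev.name))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def extract_amplicon(reference: SeqRecord, hit: AmpliconHit) -> str:
    """The amplified subsequence (wraps the origin for circular hits)."""
    doubled = reference.seq + reference.seq
    return doubled[hit.start : hit.end]


def hits_to_frame(hits: list[AmpliconHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ref_id": [h.ref_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "length": [h.length for h in hits],
            "fwd_name": [h.fwd_name for h in hits],
            "rev_name": [h.rev_name for h in hits],
        }
    )
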