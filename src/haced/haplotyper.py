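"""Haplotype dereplication, detection thresholding and threshold calibration.

Reads (or UMI consensus sequences) trimmed to the common target window are
clustered at 100% identity; cluster sizes are the haplotype abundances.
Within a sample, abundances are normalised by the largest cluster, and a
haplotype is *detected* when its relative abundance reaches a threshold
expressed as a percentage of the maximum cluster.

Against a reference haplotype set, sensitivity is the percentage of true
haplotypes that were detected (recall) and specificity the percentage of
detected haplotypes that are true (precision). The operating threshold is
calibrated as the smallest grid value whose mean specificity across
calibration samples reaches a floor (85% by default); with error-corrected
consensus reads the calibrated threshold drops by roughly an order of
magnitude because error haplotypes are scrubbed out.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .seqio import SeqRecord, read_fasta

__all__ = [
    "HaplotypeTable",
    "ReferenceSet",
    "DetectionResult",
    "CalibrationCurve",
    "ThresholdCalibrationError",
    "default_threshold_grid",
    "dereplicate",
    "detect",
    "score_detection",
    "calibrate_threshold",
    "union_haplotypes",
    "UnionReport",
]

# tolerance for >= comparisons of relative abundances against grid values
_REL_TOL = 1e-9


class ThresholdCalibrationError(ValueError):
    """No grid threshold reaches the required specificity."""


@dataclass
class HaplotypeTable:
    """Dereplicated unique sequences with counts and max-normalised abundances.

    Rows are sorted by count descending, ties by sequence; the largest
    cluster sits at ``rel_abundance == 100``.
    """

    sequences: list[str]
    counts: np.ndarray
    rel_abundance: np.ndarray  # % of the maximum cluster

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.sequences)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": self.sequences,
                "count": self.counts,
                "rel_abundance_pct": self.rel_abundance,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t")
        return cls.from_counts(dict(zip(df["sequence"], df["count"])))

    @classmethod
    def from_counts(cls, counter: dict[str, int]) -> "HaplotypeTable":
        items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        seqs = [s for s, _ in items]
        counts = np.array([c for _, c in items], dtype=np.int64)
        rel = 100.0 * counts / counts.max() if len(counts) else np.array([])
        return cls(seqs, counts, rel)


@dataclass
class ReferenceSet:
    """Named reference haplotypes (e.g., Sanger-determined per-individual
    target-window sequences); sequences must be unique."""

    records: list[SeqRecord]

    def __post_init__(self) -> None:
        seqs = [r.seq for r in self.records]
        if len(set(seqs)) != len(seqs):
            raise ValueError("reference haplotype sequences must be unique")

    @property
    def sequences(self) -> set[str]:
        return {r.seq for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSet":
        return cls(read_fasta(path))

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "ReferenceSet":
        return cls([SeqRecord(f"hap{i}", s) for i, s in enumerate(dict.fromkeys(seqs))])


@dataclass
class DetectionResult:
    detected: set[str]
    n_true_detected: int
    n_false_detected: int
    sensitivity: float  # %
    specificity: float  # %


@dataclass
class CalibrationCurve:
    """Per-threshold mean sensitivity/specificity and the chosen cut-off."""

    thresholds: np.ndarray  # % of max cluster, strictly increasing
    sensitivity: np.ndarray  # mean % across samples
    specificity: np.ndarray  # mean % across samples
    chosen_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_pct": self.thresholds,
                "sensitivity_pct": self.sensitivity,
                "specificity_pct": self.specificity,
            }
        )


def default_threshold_grid() -> np.ndarray:
    """0.05% steps from 0.05% to 5% (covers the 0.2% and 1.5% operating points)."""
    return np.round(np.arange(1, 101) * 0.05, 10)


def dereplicate(reads: Iterable) -> HaplotypeTable:
    """Cluster sequences at 100% agreement; cluster sizes are abundances.

    Accepts plain strings or any object with a ``seq`` attribute.
    """
    counter: Counter[str] = Counter()
    for r in reads:
        counter[r if isinstance(r, str) else r.seq] += 1
    return HaplotypeTable.from_counts(counter)


def detect(table: HaplotypeTable, threshold: float) -> set[str]:
    """Haplotypes whose relative abundance reaches ``threshold`` (% of max)."""
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    keep = table.rel_abundance + _REL_TOL >= threshold
    return {s for s, k in zip(table.sequences, keep) if k}


def score_detection(
    detected: set[str], truth: Union[ReferenceSet, set[str], Sequence[str]]
) -> DetectionResult:
    """Sensitivity (% of truth detected) and specificity (% of detections true)."""
    truth_seqs = truth.sequences if isinstance(truth, ReferenceSet) else set(truth)
    if not truth_seqs:
        raise ValueError("reference haplotype set is empty")
    n_true = len(detected & truth_seqs)
    n_false = len(detected) - n_true
    sensitivity = 100.0 * n_true / len(truth_seqs)
    specificity = 100.0 * n_true / len(detected) if detected else 100.0
    return DetectionResult(detected, n_true, n_false, sensitivity, specificity)


def calibrate_threshold(
    samples: Sequence[tuple[HaplotypeTable, Union[ReferenceSet, set[str]]]],
    grid: Optional[Sequence[float]] = None,
    min_specificity: float = 85.0,
    aggregate: str = "mean",
) -> CalibrationCurve:
    """Sweep thresholds over calibration samples and pick the operating point.

    For each grid threshold, per-sample sensitivity/specificity are computed
    and averaged (``aggregate="mean"``, unweighted) or pooled over summed
    true/false counts (``aggregate="pooled"``). The chosen threshold is the
    smallest grid value whose aggregate specificity reaches
    ``min_specificity``; raises :class:`ThresholdCalibrationError` if none does.
    """
    if not samples:
        raise ValueError("at least one calibration sample is required")
    grid_arr = np.asarray(default_threshold_grid() if grid is None else grid, dtype=float)
    if len(grid_arr) == 0 or (np.diff(grid_arr) <= 0).any():
        raise ValueError("grid must be non-empty and strictly increasing")
    if aggregate not in ("mean", "pooled"):
        raise ValueError("aggregate must be 'mean' or 'pooled'")

    sens = np.empty(len(grid_arr))
    spec = np.empty(len(grid_arr))
    for i, t in enumerate(grid_arr):
        per_sample = [score_detection(detect(tab, t), ref) for tab, ref in samples]
        if aggregate == "mean":
            sens[i] = float(np.mean([r.sensitivity for r in per_sample]))
            spec[i] = float(np.mean([r.specificity for r in per_sample]))
        else:
            n_truth = sum(
                len(ref.sequences if isinstance(ref, ReferenceSet) else set(ref))
                for _, ref in samples
            )
            tp = sum(r.n_true_detected for r in per_sample)
            det = sum(r.n_true_detected + r.n_false_detected for r in per_sample)
            sens[i] = 100.0 * tp / n_truth
            spec[i] = 100.0 * tp / det if det else 100.0

    ok = spec >= min_specificity
    if not ok.any():
        raise ThresholdCalibrationError(
            f"no threshold in the grid reaches specificity {min_specificity}%"
        )
    chosen = float(grid_arr[int(np.argmax(ok))])
    return CalibrationCurve(grid_arr, sens, spec, chosen)


@dataclass
class UnionReport:
    n_union: int
    set_sizes: list[int]
    pair_intersections: dict[tuple[int, int], int] = field(default_factory=dict)


def union_haplotypes(sets: Sequence[set[str]]) -> UnionReport:
    """Union cardinality plus the pairwise-sharing accounting across samples."""
    union: set[str] = set()
    for s in sets:
        union |= set(s)
    pairs = {
        (i, j): len(set(sets[i]) & set(sets[j]))
        for i, j in combinations(range(len(sets)), 2)
    }
    return UnionReport(len(union), [len(s) for s in sets], pairs)
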