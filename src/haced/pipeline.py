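"""End-to-end pipelines: merge -> error handling -> haplotype table -> report.

Two branches mirror the two library designs:

* ``umi``  — merge pairs, extract the UMI under the read-structure mask,
  group families, call error-corrected consensus sequences, trim the fixed
  primer regions, dereplicate. Operating threshold 0.2% of the largest
  cluster by default.
* ``q30``  — merge pairs, trim the fixed primer regions, prune every read
  containing a base below Q30, dereplicate. Operating threshold 1.5% by
  default.

Either branch can instead calibrate its threshold against a reference
haplotype FASTA (smallest grid value with specificity >= 85%), score the
detected haplotypes against that reference, and invert a reference
haplotype frequency distribution into an individual-count estimate.
All intermediate artifacts are written as FASTQ/TSV plus one JSON report;
every input read is accounted for in the report's ledger.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .abundance import ReferenceFreqs, estimate_individuals
from .haplotyper import (
    ReferenceSet,
    calibrate_threshold,
    dereplicate,
    detect,
    score_detection,
)
from .readprep import MergeParams, TrimSpec, merge_pairs, q30_filter, trim_many
from .seqio import compute_run_stats, read_fastq_paired, run_stats_table, write_fastq
from .umi import (
    DEFAULT_MASK,
    ConsensusParams,
    UmiMask,
    UmiTally,
    consensus_reads,
    group_families,
)

__all__ = [
    "PipelineConfig",
    "ConfigurationError",
    "run_pipeline",
    "umi_haplotype_table",
    "q30_haplotype_table",
]

logger = logging.getLogger("haced")

DEFAULT_THRESHOLDS = {"umi": 0.2, "q30": 1.5}


class ConfigurationError(ValueError):
    """Invalid pipeline configuration (raised before any compute)."""


@dataclass
class PipelineConfig:
    branch: str  # "umi" | "q30"
    r1: str
    r2: str
    outdir: str
    sample: str = "sample"
    mask: str = DEFAULT_MASK
    trim5: int = 20
    trim3: int = 22
    min_q: int = 30
    min_family_size: int = 3
    merge_1mm: bool = False
    min_overlap: int = 10
    max_overlap: int = 300
    max_mismatch_ratio: float = 0.25
    threshold: Union[float, str, None] = None  # % of max cluster, or "calibrate"
    reference_fasta: Optional[str] = None
    reference_freqs: Optional[str] = None
    n_bootstrap: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        if self.branch not in ("umi", "q30"):
            raise ConfigurationError(f"unknown branch {self.branch!r}")
        if self.threshold == "calibrate" and self.reference_fasta is None:
            raise ConfigurationError(
                "threshold='calibrate' requires a reference FASTA"
            )
        if isinstance(self.threshold, (int, float)) and not 0 < self.threshold <= 100:
            raise ConfigurationError("numeric threshold must be in (0, 100]")
        for p in (self.r1, self.r2):
            if not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute one branch end to end; returns (and writes) the run report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trim = TrimSpec(cfg.trim5, cfg.trim3)
    mp = MergeParams(cfg.min_overlap, cfg.max_overlap, cfg.max_mismatch_ratio)

    pairs = list(read_fastq_paired(cfg.r1, cfg.r2))
    merged, mstats = merge_pairs(pairs, mp)
    logger.info("%s: %d pairs, %d merged, %d merge failures",
                cfg.sample, mstats.n_pairs, mstats.n_merged, mstats.n_failed)
    write_fastq(merged, outdir / "merged.fastq")

    ledger: dict[str, int] = {
        "input_pairs": mstats.n_pairs,
        "merged": mstats.n_merged,
        "merge_failed": mstats.n_failed,
    }

    if cfg.branch == "umi":
        tally = UmiTally()
        families = group_families(
            merged, UmiMask(cfg.mask), merge_1mm=cfg.merge_1mm, tally=tally
        )
        cons = consensus_reads(
            families, ConsensusParams(min_family_size=cfg.min_family_size),
            tally=tally,
        )
        sizes = pd.Series([f.size for f in families], name="family_size")
        sizes.value_counts().sort_index().rename("n_families").to_csv(
            outdir / "family_size_hist.tsv", sep="\t"
        )
        ledger.update(
            umi_too_short=tally.n_too_short,
            umi_invalid=tally.n_umi_invalid,
            family_too_small=tally.n_family_too_small,
            consensus_ambiguous=tally.n_ambiguous,
            length_excluded=tally.n_length_excluded,
            consensus_members=tally.n_consensus_members,
            n_families=len(families),
            n_consensus=len(cons),
        )
        kept, n_short = trim_many(cons, trim)
        ledger["trim_dropped"] = n_short
    else:
        trimmed, n_short = trim_many(merged, trim)
        kept = list(q30_filter(trimmed, cfg.min_q))
        ledger["trim_dropped"] = n_short
        ledger["q30_pruned"] = len(trimmed) - len(kept)
        ledger["q30_retained"] = len(kept)

    write_fastq(kept, outdir / "retained.fastq")
    stats = compute_run_stats(mstats.n_pairs, iter(kept), sample=cfg.sample)
    run_stats_table([stats]).to_csv(outdir / "run_stats.tsv", sep="\t", index=False)

    table = dereplicate(kept)
    table.to_tsv(outdir / "haplotypes.tsv")

    reference = (
        ReferenceSet.from_fasta(cfg.reference_fasta) if cfg.reference_fasta else None
    )
    if cfg.threshold == "calibrate":
        curve = calibrate_threshold([(table, reference)])
        curve.to_frame().to_csv(outdir / "calibration.tsv", sep="\t", index=False)
        threshold = curve.chosen_threshold
    elif cfg.threshold is None:
        threshold = DEFAULT_THRESHOLDS[cfg.branch]
    else:
        threshold = float(cfg.threshold)

    detected = detect(table, threshold) if len(table) else set()
    report: dict = {
        "sample": cfg.sample,
        "branch": cfg.branch,
        "threshold_pct": threshold,
        "n_detected": len(detected),
        "run_stats": asdict(stats),
        "ledger": ledger,
    }

    if reference is not None:
        result = score_detection(detected, reference)
        report["detection"] = {
            "n_true_detected": result.n_true_detected,
            "n_false_detected": result.n_false_detected,
            "sensitivity_pct": result.sensitivity,
            "specificity_pct": result.specificity,
        }
        pd.DataFrame(
            [{"sample": cfg.sample, "TRUE": result.n_true_detected,
              "FALSE": result.n_false_detected}]
        ).to_csv(outdir / "detection.tsv", sep="\t", index=False)

    if cfg.reference_freqs is not None and detected:
        freqs = ReferenceFreqs.from_tsv(cfg.reference_freqs)
        est = estimate_individuals(
            len(detected), freqs, n_bootstrap=cfg.n_bootstrap, seed=cfg.seed
        )
        report["abundance"] = {
            "h_observed": est.h_observed,
            "m_point": est.m_point,
            "m_low": est.m_low,
            "m_high": est.m_high,
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def umi_haplotype_table(
    r1,
    r2,
    mask: str = DEFAULT_MASK,
    trim: TrimSpec = TrimSpec(),
    merge_params: MergeParams = MergeParams(),
    consensus_params: ConsensusParams = ConsensusParams(),
):
    """In-memory UMI branch: merge -> group -> consensus -> trim -> dereplicate."""
    pairs = [_as_pair(t) for t in zip(r1, r2)]
    merged, _ = merge_pairs(pairs, merge_params)
    families = group_families(merged, UmiMask(mask))
    cons = consensus_reads(families, consensus_params)
    kept, _ = trim_many(cons, trim)
    return dereplicate(kept)


def q30_haplotype_table(
    r1,
    r2,
    trim: TrimSpec = TrimSpec(),
    merge_params: MergeParams = MergeParams(),
    min_q: int = 30,
):
    """In-memory non-UMI branch: merge -> trim -> Q30 prune -> dereplicate."""
    pairs = [_as_pair(t) for t in zip(r1, r2)]
    merged, _ = merge_pairs(pairs, merge_params)
    trimmed, _ = trim_many(merged, trim)
    return dereplicate(list(q30_filter(trimmed, min_q)))


def _as_pair(t):
    from .seqio import ReadPair

    return t if isinstance(t, ReadPair) else ReadPair(*t)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
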