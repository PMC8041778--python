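"""Synthetic eDNA amplicon sequencing with full ground truth.

The generator emulates the data-generating process of a haplotype-counting
eDNA experiment on a mitochondrial control-region amplicon:

1. a pool of distinct haplotypes (365-base target window by default) is
   assigned to individuals (sharing structure configurable);
2. each individual sheds template molecules into the water with a lognormal
   yield (sigma 1.5 by default, so per-individual abundances span several
   hundred-fold);
3. each template molecule receives one random UMI (13 nt) and is duplicated
   through the first-PCR cycles (4 by default), polymerase substitutions
   arising at ~5e-5 per base per duplication (99.995% fidelity);
4. later amplification multiplies family sizes (negative-binomial reads per
   molecule) without new tracked template identities, still injecting
   polymerase errors per duplication;
5. paired 300-base reads are emitted with per-base Phred draws, sequencing
   substitutions occurring at probability ``10**(-Q/10)``.

Read layout (mate 1): 3-nt constant + 13-nt UMI + 20-nt forward primer +
insert prefix; mate 2: 3-nt constant + 19-nt reverse primer + insert
reverse-complement prefix. The non-UMI library omits the constant + UMI
block on mate 1. Every read id encodes its individual and molecule of
origin, so pipeline output can be audited against the truth.

Everything is driven by one seeded generator: identical config + seed give
byte-identical reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .readprep import _seq_to_u8, _u8_to_seq
from .seqio import Read, SeqRecord, revcomp, write_fasta, write_fastq

__all__ = [
    "SimConfig",
    "GroundTruth",
    "BranchReads",
    "SimulatedRun",
    "Table3Structure",
    "make_haplotypes",
    "simulate_reads",
    "emulate_table3_structure",
    "FWD_PRIMER",
    "REV_PRIMER",
    "CONSTANT_5P",
    "CONSTANT_3P",
]

# concrete instantiations of the locus primers flanking the 365-base window
FWD_PRIMER = "CTAGTACCCAACCATTCATA"  # 20 nt
REV_PRIMER = "TGACCCTCTAGAAAGAACG"  # 19 nt
CONSTANT_5P = "GTC"  # constant spacer ahead of the UMI on mate 1
CONSTANT_3P = "CAG"  # constant spacer ahead of the reverse primer on mate 2

_READ_CHUNK = 16384


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sequencing run."""

    n_individuals: int = 96
    n_haplotypes: int = 96
    insert_len: int = 365
    yield_sigma: float = 1.5  # lognormal sigma of per-individual eDNA yield
    molecules_per_individual_mean: float = 50.0
    umi_len: int = 13
    first_pcr_cycles: int = 4
    later_pcr_duplications: int = 8
    polymerase_error_rate: float = 5e-5  # per base per duplication
    reads_per_molecule_mean: float = 6.0
    reads_per_molecule_dispersion: float = 3.0
    read_len: int = 300
    mean_quality: float = 38.0
    quality_sd: float = 2.0
    low_quality_tail_fraction: float = 0.003
    sequencing_errors: bool = True
    seed: int = 0
    haplotype_assignment: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.n_haplotypes > self.n_individuals:
            raise ValueError("n_haplotypes must not exceed n_individuals")
        if not 0.0 <= self.polymerase_error_rate <= 1.0:
            raise ValueError("polymerase_error_rate must be in [0, 1]")
        for name in ("n_individuals", "n_haplotypes", "insert_len", "umi_len",
                     "read_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class GroundTruth:
    """Per-haplotype, per-molecule and per-read provenance of a branch."""

    haplotypes: list[SeqRecord]  # the simulated truth pool (insert window)
    assignment: np.ndarray  # individual -> haplotype index
    molecule_individual: np.ndarray
    molecule_haplotype: np.ndarray
    molecule_umi: Optional[list[str]]  # None for the non-UMI branch
    read_molecule: np.ndarray

    @property
    def haplotype_sequences(self) -> set[str]:
        return {h.seq for h in self.haplotypes}

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_individual)


@dataclass
class BranchReads:
    r1: list[Read]
    r2: list[Read]
    truth: GroundTruth


@dataclass
class SimulatedRun:
    umi: BranchReads
    plain: BranchReads
    haplotypes: list[SeqRecord]
    assignment: np.ndarray
    config: SimConfig


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _u8_to_seq(rng.integers(0, 4, length).astype(np.uint8))


def make_haplotypes(
    base_seq,
    n: int,
    min_pairwise_diff: int = 1,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_substitutions: int = 8,
) -> list[SeqRecord]:
    """Derive ``n`` pairwise-distinct haplotypes from a base sequence.

    The base sequence itself is the first haplotype; the rest carry
    ``n_substitutions`` random substitutions each. All pairs are guaranteed
    to differ at ``min_pairwise_diff`` or more positions.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_seq.seq if isinstance(base_seq, SeqRecord) else str(base_seq)
    L = len(base)
    if 4.0**L < n:
        raise ValueError(f"sequence space of length {L} cannot hold {n} haplotypes")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_sub = max(n_substitutions, min_pairwise_diff)

    pool = np.empty((n, L), dtype=np.uint8)
    pool[0] = _seq_to_u8(base)
    made = 1
    attempts = 0
    while made < n:
        attempts += 1
        if attempts > 1000 * n:
            raise ValueError("could not place enough distinct haplotypes")
        cand = pool[0].copy()
        pos = rng.choice(L, size=min(n_sub, L), replace=False)
        cand[pos] = (cand[pos] + rng.integers(1, 4, len(pos))) % 4
        if (np.count_nonzero(pool[:made] != cand[None, :], axis=1)
                >= min_pairwise_diff).all():
            pool[made] = cand
            made += 1
    return [SeqRecord(f"hap{i}", _u8_to_seq(pool[i])) for i in range(n)]


def _default_assignment(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.haplotype_assignment is not None:
        a = np.asarray(cfg.haplotype_assignment, dtype=np.int64)
        if len(a) != cfg.n_individuals:
            raise ValueError("haplotype_assignment length != n_individuals")
        return a
    extra = rng.integers(0, cfg.n_haplotypes, cfg.n_individuals - cfg.n_haplotypes)
    return np.concatenate([np.arange(cfg.n_haplotypes), extra])


def _first_pcr_errors(
    cfg: SimConfig, rng: np.random.Generator, n_molecules: int, template_len: int
) -> dict[int, list[tuple[int, int, float]]]:
    """Sparse per-molecule first-PCR error lists.

    Each error is (position, base-shift 1..3, inherited-fraction). An error
    born at cycle k is carried by 2**-k of the molecule's final copies, so a
    read inherits it with that probability.
    """
    c = cfg.first_pcr_cycles
    if c == 0 or cfg.polymerase_error_rate == 0.0:
        return {}
    n_dups = 2**c - 1
    n_err = rng.binomial(n_dups * template_len, cfg.polymerase_error_rate,
                         size=n_molecules)
    cycle_p = np.array([2.0 ** (k - 1) for k in range(1, c + 1)]) / n_dups
    out: dict[int, list[tuple[int, int, float]]] = {}
    for mol in np.nonzero(n_err)[0]:
        errors = []
        for _ in range(int(n_err[mol])):
            k = int(rng.choice(c, p=cycle_p)) + 1
            pos = int(rng.integers(template_len))
            shift = int(rng.integers(1, 4))
            errors.append((pos, shift, 2.0**-k))
        out[int(mol)] = errors
    return out


def _simulate_branch(
    cfg: SimConfig,
    rng: np.random.Generator,
    haplotypes: list[SeqRecord],
    assignment: np.ndarray,
    yields: np.ndarray,
    with_umi: bool,
) -> BranchReads:
    rest = [  # haplotype-dependent part of the template (407 nt by default)
        FWD_PRIMER + h.seq + revcomp(REV_PRIMER) + revcomp(CONSTANT_3P)
        for h in haplotypes
    ]
    rest_u8 = np.stack([_seq_to_u8(s) for s in rest])
    prefix_len = len(CONSTANT_5P) + cfg.umi_len if with_umi else 0
    template_len = prefix_len + rest_u8.shape[1]

    mols_per_ind = rng.poisson(yields)
    molecule_individual = np.repeat(np.arange(cfg.n_individuals), mols_per_ind)
    n_mol = len(molecule_individual)
    molecule_haplotype = assignment[molecule_individual]
    umi_codes = rng.integers(0, 4, (n_mol, cfg.umi_len)).astype(np.uint8) \
        if with_umi else None

    pcr_errors = _first_pcr_errors(cfg, rng, n_mol, template_len)

    disp = cfg.reads_per_molecule_dispersion
    p_nb = disp / (disp + cfg.reads_per_molecule_mean)
    reads_per_mol = rng.negative_binomial(disp, p_nb, size=n_mol)
    read_molecule = np.repeat(np.arange(n_mol), reads_per_mol)
    n_reads = len(read_molecule)
    mol_read_start = np.concatenate([[0], np.cumsum(reads_per_mol)])

    # assemble per-read templates
    T = np.empty((n_reads, template_len), dtype=np.uint8)
    if with_umi:
        T[:, : len(CONSTANT_5P)] = _seq_to_u8(CONSTANT_5P)[None, :]
        T[:, len(CONSTANT_5P) : prefix_len] = umi_codes[read_molecule]
    T[:, prefix_len:] = rest_u8[molecule_haplotype[read_molecule]]

    # first-PCR errors: each read of the molecule inherits independently
    for mol, errors in pcr_errors.items():
        lo, hi = mol_read_start[mol], mol_read_start[mol + 1]
        if hi == lo:
            continue
        for pos, shift, frac in errors:
            carriers = lo + np.nonzero(rng.random(hi - lo) < frac)[0]
            T[carriers, pos] = (T[carriers, pos] + shift) % 4

    # later-PCR errors: independent per read
    if cfg.polymerase_error_rate > 0 and cfg.later_pcr_duplications > 0:
        n_late = rng.binomial(
            cfg.later_pcr_duplications * template_len,
            cfg.polymerase_error_rate, size=n_reads,
        )
        for r in np.nonzero(n_late)[0]:
            for _ in range(int(n_late[r])):
                pos = int(rng.integers(template_len))
                T[r, pos] = (T[r, pos] + rng.integers(1, 4)) % 4

    mate1 = T[:, : cfg.read_len]
    mate2 = (3 - T[:, ::-1])[:, : cfg.read_len]

    read_individual = molecule_individual[read_molecule]
    tag = "umi" if with_umi else "plain"
    r1: list[Read] = []
    r2: list[Read] = []
    for lo in range(0, n_reads, _READ_CHUNK):
        hi = min(lo + _READ_CHUNK, n_reads)
        for mate_arr, out in ((mate1, r1), (mate2, r2)):
            block = mate_arr[lo:hi].copy()
            q = np.rint(
                rng.normal(cfg.mean_quality, cfg.quality_sd, block.shape)
            ).astype(np.int16)
            np.clip(q, 2, 41, out=q)
            if cfg.low_quality_tail_fraction > 0:
                tail = rng.random(block.shape) < cfg.low_quality_tail_fraction
                q[tail] = rng.integers(8, 30, int(tail.sum()))
            if cfg.sequencing_errors:
                perr = 10.0 ** (-q / 10.0)
                flip = rng.random(block.shape) < perr
                n_flip = int(flip.sum())
                block[flip] = (block[flip] + rng.integers(1, 4, n_flip)) % 4
            for j in range(hi - lo):
                i = lo + j
                rid = f"{tag}_i{read_individual[i]}_m{read_molecule[i]}_r{i}"
                out.append(Read(rid, _u8_to_seq(block[j]), q[j]))

    truth = GroundTruth(
        haplotypes=haplotypes,
        assignment=assignment,
        molecule_individual=molecule_individual,
        molecule_haplotype=molecule_haplotype,
        molecule_umi=[_u8_to_seq(u) for u in umi_codes] if with_umi else None,
        read_molecule=read_molecule,
    )
    return BranchReads(r1, r2, truth)


def simulate_reads(cfg: SimConfig) -> SimulatedRun:
    """Generate UMI-tagged and plain paired-end libraries from one haplotype
    pool, with shared per-individual yields and full ground truth."""
    rng = np.random.default_rng(cfg.seed)
    base = _random_seq(rng, cfg.insert_len)
    haplotypes = make_haplotypes(base, cfg.n_haplotypes, rng=rng)
    assignment = _default_assignment(cfg, rng)
    yields = rng.lognormal(
        np.log(cfg.molecules_per_individual_mean), cfg.yield_sigma,
        cfg.n_individuals,
    )
    umi = _simulate_branch(cfg, rng, haplotypes, assignment, yields, with_umi=True)
    plain = _simulate_branch(cfg, rng, haplotypes, assignment, yields, with_umi=False)
    return SimulatedRun(umi, plain, haplotypes, assignment, cfg)


def write_run(run: SimulatedRun, outdir) -> dict[str, str]:
    """Write both branches' FASTQ, the truth FASTA and truth tables."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, branch in (("umi", run.umi), ("plain", run.plain)):
        for mate, reads in (("R1", branch.r1), ("R2", branch.r2)):
            p = outdir / f"{tag}_{mate}.fastq"
            write_fastq(reads, p)
            paths[f"{tag}_{mate}"] = str(p)
        t = branch.truth
        df = pd.DataFrame(
            {
                "molecule": np.arange(t.n_molecules),
                "individual": t.molecule_individual,
                "haplotype": t.molecule_haplotype,
                "umi": t.molecule_umi if t.molecule_umi is not None else "",
            }
        )
        p = outdir / f"{tag}_molecules.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"{tag}_molecules"] = str(p)
    p = outdir / "haplotypes.fasta"
    write_fasta(run.haplotypes, p)
    paths["haplotypes"] = str(p)
    return paths


@dataclass
class Table3Structure:
    """Two overlapping reference groups with the published sharing pattern:
    36 haplotypes over 38 resident individuals (2 duplicated pairs), 64
    haplotypes over 70 newly added individuals (4 pairs + 1 triplicate),
    4 haplotypes shared between groups; union 96 haplotypes / 108
    individuals."""

    haplotypes_a: list[SeqRecord]
    haplotypes_b: list[SeqRecord]
    individuals_a: list[str]  # 38 per-individual sequences
    individuals_b: list[str]  # 70 per-individual sequences
    shared: set[str]

    @property
    def union(self) -> set[str]:
        return {h.seq for h in self.haplotypes_a} | {h.seq for h in self.haplotypes_b}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals_a) + len(self.individuals_b)


def emulate_table3_structure(
    seed: Optional[int] = None, insert_len: int = 365
) -> Table3Structure:
    """Build the two-group haplotype-sharing structure described above."""
    rng = np.random.default_rng(seed)
    haps = make_haplotypes(_random_seq(rng, insert_len), 96, rng=rng)
    haps_a = haps[:36]
    haps_b = haps[32:]
    # residents: haplotypes 0 and 1 duplicated, the rest singletons
    individuals_a = [haps_a[0].seq, haps_a[1].seq] + [h.seq for h in haps_a]
    # newcomers: 4 duplicated pairs, 1 triplicate, 59 singletons
    individuals_b = (
        [h.seq for h in haps_b[:4]]  # second copies of the 4 pairs
        + [haps_b[4].seq, haps_b[4].seq]  # two extra copies of the triplicate
        + [h.seq for h in haps_b]
    )
    assert len(individuals_a) == 38 and len(individuals_b) == 70
    return Table3Structure(
        haplotypes_a=haps_a,
        haplotypes_b=haps_b,
        individuals_a=individuals_a,
        individuals_b=individuals_b,
        shared={h.seq for h in haps[32:36]},
    )
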