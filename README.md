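# haced — haplotype counting from eDNA

`haced` estimates how many individuals of a species are present in a body
of water from the mitochondrial control-region (D-loop) haplotypes found in
its environmental DNA. In species whose D-loop diversity is close to 1
(tunas, eels, several small pelagic fishes), almost every individual
carries a unique haplotype, so an amplicon-sequencing run on filtered water
can be turned into a census — if sequencing errors can be kept from minting
false haplotypes, and if the haplotype count can be mapped back onto an
individual count. The package is aimed at molecular-ecology groups running
such surveys and at methods developers who want a fully simulatable
test bed.

## What it does

* **Read preparation** — FASTQ I/O (+33, gzip), overlap-based pair merging,
  fixed primer trimming (20 nt 5′ / 22 nt 3′ around a 365-base window), and
  the all-bases ≥ Q30 filter. Phred arithmetic included: accuracy
  `1 − 10^(−q/10)`, per-read error probability `1 − a^L` (Q30 over 300
  bases: 26%).
* **UMI error correction** — a 5′ mask (`nnnNNNNNNNNNNNNN`: 3 constant
  bases, 13-base UMI) splits each merged read into UMI and payload; reads
  sharing a UMI derive from one template molecule and are collapsed to a
  quality-weighted majority consensus (agreement floor 0.7, quality cap
  Q40, ambiguous families rejected rather than guessed).
* **Haplotype counting** — 100%-identity dereplication; detection at a
  threshold expressed as % of the largest cluster; sensitivity/specificity
  scoring against reference haplotypes; threshold calibration (smallest
  grid value with mean specificity ≥ 85%); multi-sample haplotype-sharing
  accounting.
* **Abundance estimation** — Nei haplotype diversity
  `h = n/(n−1)(1 − Σp_i²)`; individual-based rarefaction
  `H(m) = S_obs − Σ C(n−n_i, m)/C(n, m)`; Chao1 extrapolation
  `H(n+m*) = S_obs + f0(1 − (1 − f1/(nf0+f1))^{m*})`; curve inversion with
  a 95% band to estimate individuals from an observed haplotype count.
* **In-silico PCR** — degenerate (IUPAC) primer-pair scanning with
  primer-inclusive amplicon spans, circular-reference support.
* **Simulation** — a generative model of the whole experiment (lognormal
  per-individual eDNA yields, per-molecule UMI tagging, first-PCR and
  later-PCR polymerase errors at 99.995% fidelity, per-base Phred-driven
  sequencing errors) with complete ground truth, so every stage is tested
  closed-loop.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

`examples/01_simulate_and_count.py` simulates a 20-individual sample and
counts haplotypes with and without UMI correction:

```
simulated 10570 UMI read pairs, 11142 plain read pairs, 20 true haplotypes
UMI branch @ 0.2% of max cluster: 20 true + 0 false (sensitivity 100.0%, specificity 100.0%)
Q30 branch @ 1.5% of max cluster: 13 true + 0 false (sensitivity 65.0%, specificity 100.0%)
```

Consensus calling removes the error haplotypes that otherwise flood the
low-abundance range, so the UMI branch operates at a ~7× lower detection
threshold and recovers the rare individuals the Q30 branch misses.

`examples/03_estimate_individuals.py` then maps a haplotype count onto an
individual count using a 507-individual reference drawn from a
near-unique pool (h ≈ 0.9996):

```
reference: n=507 individuals, S_obs=461 haplotypes, f1=417 singletons, diversity h=0.9996
96 observed haplotypes -> 98 individuals [95, 101] (95% band)
```

At diversity this high the accumulation curve hugs the identity line, so
96 distinct haplotypes correspond to only slightly more individuals.

The other examples cover threshold calibration
(`02_calibrate_threshold.py`) and degenerate-primer amplicon prediction
(`04_insilico_pcr.py`, one 1,092-bp product).

## Command line

A thin CLI wraps the library for shell pipelines:

```bash
haced simulate --config sim.yaml --out data/          # synthetic run + truth
haced merge --r1 R1.fastq --r2 R2.fastq --out merged.fastq
haced consensus --in merged.fastq --mask nnnNNNNNNNNNNNNN --min-family 3 --out cons.fastq
haced haplotypes --in cons.fastq --out haplotypes.tsv
haced calibrate --table haplotypes.tsv --ref truth.fasta
haced estimate --h-observed 96 --freqs ref_freqs.tsv
haced run --config pipeline.yaml                      # either branch, end to end
```

`haced run` writes all intermediates (merged FASTQ, consensus FASTQ,
family-size histogram, haplotype table, calibration sweep, detection
report) plus a single `report.json` in which every input read is accounted
for.

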