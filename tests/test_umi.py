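"""UMI extraction, family grouping and consensus error correction."""

import numpy as np
import pytest

from conftest import mk_read, random_dna
from haced.umi import (
    ConsensusParams,
    UmiFamily,
    UmiMask,
    UmiTally,
    call_consensus,
    consensus_reads,
    extract_umi,
    group_families,
)


class TestUmiMask:
    def test_default_mask_structure(self):
        mask = UmiMask()
        assert len(mask) == 16
        assert mask.umi_start == 3
        assert mask.umi_len == 13

    @pytest.mark.parametrize("bad", ["", "nnn", "nXN", "NnN"])
    def test_invalid_masks_rejected(self, bad):
        with pytest.raises(ValueError):
            UmiMask(bad)


class TestExtractUmi:
    def test_constant_umi_payload_split(self):
        umi = "ACGTACGTACGTA"
        payload = "TTTTGGGGCCCCAAAA"
        read = mk_read("GTC" + umi + payload)
        got_umi, got_payload = extract_umi(read, UmiMask())
        assert got_umi == umi
        assert got_payload.seq == payload
        assert len(got_payload.qual) == len(payload)

    def test_single_n_mask(self):
        got_umi, payload = extract_umi(mk_read("ACGTACGT"), UmiMask("N"))
        assert got_umi == "A"
        assert payload.seq == "CGTACGT"

    def test_short_read_discarded(self):
        assert extract_umi(mk_read("ACGTACGTAC"), UmiMask()) is None

    def test_umi_containing_n_discarded(self):
        read = mk_read("GTC" + "ACGTACNTACGTA" + "TTTT")
        assert extract_umi(read, UmiMask()) is None


class TestGroupFamilies:
    def _reads(self, umi, n, payload="TTTTGGGG"):
        return [mk_read("GTC" + umi + payload, rid=f"{umi}_{i}") for i in range(n)]

    def test_exact_grouping(self):
        u1, u2 = "A" * 13, "C" * 13
        fams = group_families(self._reads(u1, 5) + self._reads(u2, 2))
        assert [(f.umi, f.size) for f in fams] == [(u1, 5), (u2, 2)]

    def test_size_conservation(self, rng):
        reads = []
        for _ in range(20):
            umi = random_dna(rng, 13)
            reads.extend(self._reads(umi, int(rng.integers(1, 6))))
        tally = UmiTally()
        fams = group_families(reads, tally=tally)
        assert sum(f.size for f in fams) == len(reads) == tally.n_grouped

    def test_1mm_absorption(self):
        big = "A" * 13
        small = "A" * 12 + "T"
        reads = self._reads(big, 50) + self._reads(small, 2)
        fams = group_families(reads, merge_1mm=True)
        assert len(fams) == 1
        assert fams[0].size == 52

    def test_no_absorption_when_sizes_comparable(self):
        fams = group_families(
            self._reads("A" * 13, 5) + self._reads("A" * 12 + "T", 2),
            merge_1mm=True,
        )
        assert len(fams) == 2


def _family(seqs, qual=35, umi="A" * 13):
    return UmiFamily(umi, [mk_read(s, qual, rid=f"m{i}") for i, s in enumerate(seqs)])


class TestCallConsensus:
    def test_identical_members_capped_quality(self):
        fam = _family(["ACGTACGT"] * 5, qual=35)
        res = call_consensus(fam)
        assert res.reason == "ok"
        assert res.consensus.seq == "ACGTACGT"
        assert (res.consensus.qual == 40).all()  # 5*35 support, capped at 40
        assert res.consensus.family_size == 5

    def test_single_dissenter_corrected(self):
        fam = _family(["ACGTACGT"] * 4 + ["ACGTACTT"])
        res = call_consensus(fam)
        assert res.consensus.seq == "ACGTACGT"

    def test_small_family_rejected(self):
        res = call_consensus(_family(["ACGT"] * 2))
        assert res.consensus is None
        assert res.reason == "family-too-small"

    def test_even_split_rejected_as_ambiguous(self):
        fam = _family(["ACGTACGT"] * 2 + ["ACGTACTT"] * 2)
        res = call_consensus(fam)
        assert res.consensus is None
        assert res.reason == "ambiguous"

    def test_below_agreement_floor_rejected(self):
        # 3/5 = 0.6 < 0.7 even though the majority base wins by weight
        fam = _family(["ACGTACGT"] * 3 + ["ACGTACTT"] * 2)
        assert call_consensus(fam).reason == "ambiguous"

    def test_modal_length_exclusion(self):
        fam = _family(["ACGTACGT"] * 3 + ["ACGT"])
        res = call_consensus(fam)
        assert res.consensus.seq == "ACGTACGT"
        assert res.n_voters == 3

    def test_consensus_quality_is_support_minus_dissent(self):
        fam = _family(["ACGTACGT"] * 4 + ["ACGTACTT"], qual=10)
        res = call_consensus(fam)
        # dissenting position: 4*10 - 10 = 30; unanimous positions capped at 40
        assert res.consensus.qual[6] == 30
        assert res.consensus.qual[0] == 40


class TestErrorScrubbing:
    def test_consensus_beats_raw_reads_and_improves_with_size(self, rng):
        truth = random_dna(rng, 120)
        err = 0.01
        raw_correct = 0
        n_raw = 0
        emitted = {5: [0, 0], 10: [0, 0]}  # size -> [correct, emitted]
        for size in (5, 10):
            for _ in range(150):
                members = []
                for i in range(size):
                    arr = np.frombuffer(truth.encode(), dtype=np.uint8).copy()
                    flips = rng.random(len(arr)) < err
                    alts = rng.choice(
                        [ord(c) for c in "ACGT"], size=int(flips.sum())
                    )
                    arr[flips] = alts
                    seq = arr.tobytes().decode()
                    members.append(mk_read(seq, 30, rid=f"m{i}"))
                    n_raw += 1
                    raw_correct += seq == truth
                res = call_consensus(UmiFamily("A" * 13, members))
                if res.consensus is not None:
                    emitted[size][1] += 1
                    emitted[size][0] += res.consensus.seq == truth
        raw_frac = raw_correct / n_raw
        for size in (5, 10):
            correct, total = emitted[size]
            assert total > 0
            assert correct / total > raw_frac
        assert emitted[10][0] / emitted[10][1] >= emitted[5][0] / emitted[5][1] - 0.01

    def test_read_conservation_across_buckets(self, rng):
        reads = []
        for _ in range(30):
            umi = random_dna(rng, 13)
            size = int(rng.integers(1, 7))
            payload = random_dna(rng, 30)
            reads.extend(
                mk_read("GTC" + umi + payload, rid=f"{umi}{i}") for i in range(size)
            )
        reads.append(mk_read("GTC" + "N" * 13 + "ACGT" * 10))  # invalid UMI
        reads.append(mk_read("ACGT"))  # shorter than the mask
        tally = UmiTally()
        fams = group_families(reads, tally=tally)
        consensus_reads(fams, tally=tally)
        buckets = (
            tally.n_consensus_members
            + tally.n_umi_invalid
            + tally.n_too_short
            + tally.n_family_too_small
            + tally.n_ambiguous
            + tally.n_length_excluded
        )
        assert buckets == tally.n_input == len(reads)
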