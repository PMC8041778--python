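"""Dereplication, detection thresholds, scoring and calibration."""

import numpy as np
import pytest

from conftest import random_dna
from haced.haplotyper import (
    HaplotypeTable,
    ReferenceSet,
    ThresholdCalibrationError,
    calibrate_threshold,
    default_threshold_grid,
    dereplicate,
    detect,
    score_detection,
    union_haplotypes,
)


def sharing_structure(rng, n_singletons=59, n_pairs=4, n_triples=1, length=30):
    """Per-individual sequences with a known duplication structure."""
    uniq = []
    while len(uniq) < n_singletons + n_pairs + n_triples:
        s = random_dna(rng, length)
        if s not in uniq:
            uniq.append(s)
    seqs = list(uniq[:n_singletons])
    for s in uniq[n_singletons : n_singletons + n_pairs]:
        seqs += [s, s]
    for s in uniq[n_singletons + n_pairs :]:
        seqs += [s, s, s]
    return seqs, uniq


class TestDereplicate:
    def test_70_individuals_with_shared_haplotypes_give_64_clusters(self, rng):
        seqs, uniq = sharing_structure(rng)
        assert len(seqs) == 70
        table = dereplicate(seqs)
        assert len(table) == 64
        assert table.n_reads == 70

    def test_relative_abundance_of_max_cluster(self):
        counts = {"A" * 5: 1000, "C" * 5: 15, "G" * 5: 2}
        table = HaplotypeTable.from_counts(counts)
        assert list(table.rel_abundance) == [100.0, 1.5, 0.2]

    def test_all_identical_single_cluster(self):
        table = dereplicate(["ACGT"] * 9)
        assert len(table) == 1
        assert table.rel_abundance[0] == 100.0

    def test_empty_input(self):
        assert len(dereplicate([])) == 0

    def test_sorted_by_count_then_sequence(self):
        table = dereplicate(["TT", "AA", "CC", "CC"])
        assert table.sequences == ["CC", "AA", "TT"]


class TestDetect:
    @pytest.fixture
    def table(self):
        return HaplotypeTable.from_counts({"A" * 5: 1000, "C" * 5: 15, "G" * 5: 2})

    def test_threshold_1_5_keeps_two(self, table):
        assert detect(table, 1.5) == {"A" * 5, "C" * 5}

    def test_threshold_0_2_keeps_three(self, table):
        assert len(detect(table, 0.2)) == 3

    def test_threshold_100_keeps_only_max(self, table):
        assert detect(table, 100) == {"A" * 5}

    def test_nesting_in_threshold(self, rng):
        counts = {random_dna(rng, 12): int(c) for c in rng.integers(1, 500, 40)}
        table = HaplotypeTable.from_counts(counts)
        grid = default_threshold_grid()
        prev = None
        for t in grid:
            cur = detect(table, t)
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestScoreDetection:
    def test_nine_of_ten_true(self):
        truth = {f"h{i}" for i in range(10)}
        detected = set(list(truth)[:9])
        r = score_detection(detected, truth)
        assert r.sensitivity == 90.0
        assert r.specificity == 100.0

    def test_specificity_with_false_detections(self):
        truth = {f"h{i}" for i in range(67)}
        detected = truth | {f"f{i}" for i in range(4)}
        r = score_detection(detected, truth)
        assert r.n_false_detected == 4
        assert round(r.specificity, 1) == round(100 * 67 / 71, 1)

    def test_perfect_detection(self):
        truth = {"a", "b"}
        r = score_detection(truth, truth)
        assert (r.sensitivity, r.specificity) == (100.0, 100.0)

    def test_empty_detected_specificity_vacuous(self):
        r = score_detection(set(), {"a"})
        assert r.specificity == 100.0
        assert r.sensitivity == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            score_detection({"a"}, set())


class TestCalibrateThreshold:
    def _sample(self, rng, error_rel_max=0.9):
        """Truth at 100% and 50% of max; error haplotypes below 1%."""
        truth = [random_dna(rng, 20), random_dna(rng, 20)]
        counts = {truth[0]: 1000, truth[1]: 500}
        for _ in range(8):
            counts[random_dna(rng, 20)] = int(rng.integers(1, int(10 * error_rel_max)))
        return HaplotypeTable.from_counts(counts), set(truth)

    def test_chosen_equals_exhaustive_scan(self, rng):
        samples = [self._sample(rng) for _ in range(3)]
        grid = default_threshold_grid()
        curve = calibrate_threshold(samples, grid=grid)
        # independent oracle: exhaustive scan with raw set arithmetic
        chosen = None
        for t in grid:
            specs = []
            for table, truth in samples:
                det = {
                    s
                    for s, rel in zip(table.sequences, table.rel_abundance)
                    if rel + 1e-9 >= t
                }
                tp = len(det & truth)
                specs.append(100.0 * tp / len(det) if det else 100.0)
            if np.mean(specs) >= 85.0:
                chosen = t
                break
        assert curve.chosen_threshold == chosen

    def test_min_specificity_zero_returns_grid_minimum(self, rng):
        curve = calibrate_threshold([self._sample(rng)], min_specificity=0.0)
        assert curve.chosen_threshold == default_threshold_grid()[0]

    def test_no_qualifying_threshold_raises(self):
        # every detectable haplotype is false
        table = HaplotypeTable.from_counts({"AAAA": 100, "CCCC": 100})
        with pytest.raises(ThresholdCalibrationError):
            calibrate_threshold([(table, {"GGGG"})], grid=[1.0, 2.0])

    def test_specificity_floor_respected(self, rng):
        samples = [self._sample(rng) for _ in range(3)]
        curve = calibrate_threshold(samples)
        idx = list(curve.thresholds).index(curve.chosen_threshold)
        assert curve.specificity[idx] >= 85.0
        assert all(s < 85.0 for s in curve.specificity[:idx])


class TestUnionHaplotypes:
    def test_two_sets_sharing_four(self, rng):
        pool = [random_dna(rng, 15) for _ in range(96)]
        a = set(pool[:36])
        b = set(pool[32:])
        report = union_haplotypes([a, b])
        assert report.n_union == 96
        assert report.pair_intersections[(0, 1)] == 4

    def test_disjoint_sets(self):
        report = union_haplotypes([{"a", "b"}, {"c"}])
        assert report.n_union == 3

    def test_subset(self):
        report = union_haplotypes([{"a"}, {"a", "b", "c"}])
        assert report.n_union == 3
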