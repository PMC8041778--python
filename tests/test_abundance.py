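"""Haplotype diversity, rarefaction/extrapolation and curve inversion."""

from itertools import combinations

import numpy as np
import pytest

from haced.abundance import (
    OutOfRangeError,
    ReferenceFreqs,
    chao1_unseen,
    estimate_individuals,
    expected_richness,
    extrapolate,
    haplotype_diversity,
    rarefy,
)


def brute_force_rarefaction(counts, m):
    """Average distinct-haplotype count over all C(n, m) subsamples."""
    labels = [i for i, c in enumerate(counts) for _ in range(c)]
    subs = list(combinations(range(len(labels)), m))
    return sum(len({labels[i] for i in sub}) for sub in subs) / len(subs)


class TestHaplotypeDiversity:
    def test_two_distinct_individuals(self):
        assert haplotype_diversity(ReferenceFreqs([1, 1])) == 1.0

    def test_two_pairs(self):
        h = haplotype_diversity(ReferenceFreqs([2, 2]))
        assert round(h, 4) == 0.6667

    def test_single_haplotype(self):
        assert haplotype_diversity(ReferenceFreqs([5])) == 0.0

    def test_matches_pairwise_difference_probability(self):
        # brute-force check: h = n/(n-1) * P(two random individuals differ)
        counts = [3, 2, 1]
        labels = [i for i, c in enumerate(counts) for _ in range(c)]
        n = len(labels)
        pairs = list(combinations(range(n), 2))
        p_diff = sum(labels[i] != labels[j] for i, j in pairs) / len(pairs)
        # P over unordered pairs already includes the n/(n-1) correction
        assert haplotype_diversity(ReferenceFreqs(counts)) == pytest.approx(p_diff)

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            haplotype_diversity(ReferenceFreqs([1]))


class TestRarefy:
    @pytest.mark.parametrize(
        "counts", [(2, 2), (3, 2, 1), (5, 1, 1, 1), (2, 2, 2, 2, 2), (4, 4, 2, 1, 1)]
    )
    def test_matches_exhaustive_subsample_average(self, counts):
        freqs = ReferenceFreqs(list(counts))
        for m in range(1, freqs.n + 1):
            assert rarefy(freqs, m) == pytest.approx(
                brute_force_rarefaction(counts, m), abs=1e-9
            )

    def test_one_individual_shows_one_haplotype(self):
        assert rarefy(ReferenceFreqs([3, 5, 2]), 1) == pytest.approx(1.0)

    def test_full_sample_recovers_observed_richness(self):
        freqs = ReferenceFreqs([3, 5, 2])
        assert rarefy(freqs, freqs.n) == pytest.approx(3.0)

    def test_two_pairs_at_two(self):
        assert rarefy(ReferenceFreqs([2, 2]), 2) == pytest.approx(5 / 3)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rarefy(ReferenceFreqs([2, 2]), 5)


class TestChao1:
    def test_no_singletons_no_unseen(self):
        assert chao1_unseen(ReferenceFreqs([2, 3, 5])) == 0.0

    def test_with_doubletons(self):
        # n=10, f1=2, f2=1 -> (9/10) * 4/2 = 1.8
        assert chao1_unseen(ReferenceFreqs([1, 1, 2, 3, 3])) == pytest.approx(1.8)

    def test_bias_corrected_form_without_doubletons(self):
        # n=10, f1=2, f2=0 -> (9/10) * 2*1/2 = 0.9
        assert chao1_unseen(ReferenceFreqs([1, 1, 8])) == pytest.approx(0.9)


class TestExtrapolate:
    def test_zero_steps_is_observed_richness(self):
        freqs = ReferenceFreqs([1, 1, 2, 3, 3])
        assert extrapolate(freqs, 0) == freqs.s_obs

    def test_monotone_approach_to_asymptote(self):
        freqs = ReferenceFreqs([1, 1, 2, 3, 3])
        asymptote = freqs.s_obs + chao1_unseen(freqs)
        vals = [extrapolate(freqs, m) for m in range(0, 200, 5)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(v < asymptote for v in vals[1:])
        assert extrapolate(freqs, 10_000) == pytest.approx(asymptote, rel=1e-6)

    def test_first_step_bounded_by_singleton_rate(self):
        # expected new haplotypes from one more individual <= f1/n
        freqs = ReferenceFreqs([1, 1, 2, 3, 3])
        gain = extrapolate(freqs, 1) - freqs.s_obs
        assert 0 < gain <= freqs.f(1) / freqs.n + 1e-12

    def test_combined_curve_continuous_and_nondecreasing(self):
        freqs = ReferenceFreqs([1, 1, 1, 2, 2, 3, 6])
        vals = [expected_richness(freqs, m) for m in range(1, 3 * freqs.n)]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
        assert expected_richness(freqs, freqs.n) == pytest.approx(freqs.s_obs)


class TestEstimateIndividuals:
    def test_single_haplotype_maps_to_single_individual(self):
        freqs = ReferenceFreqs(np.ones(50, dtype=int))
        est = estimate_individuals(1, freqs, n_bootstrap=20, seed=0)
        assert est.m_point == 1

    def test_identity_on_all_singleton_reference(self):
        freqs = ReferenceFreqs(np.ones(200, dtype=int))
        for m in (10, 50, 120, 200):
            est = estimate_individuals(m, freqs, n_bootstrap=20, seed=0)
            assert est.m_point == m
            assert est.m_low <= m <= est.m_high

    def test_monotone_in_observed_count(self):
        rng = np.random.default_rng(3)
        freqs = ReferenceFreqs(rng.multinomial(300, np.full(1000, 1e-3)))
        points = [
            estimate_individuals(h, freqs, n_bootstrap=10, seed=0).m_point
            for h in range(10, freqs.s_obs, 20)
        ]
        assert all(b >= a for a, b in zip(points, points[1:]))

    def test_out_of_range_rejected(self):
        freqs = ReferenceFreqs([2, 3, 5])  # no singletons: asymptote = S_obs
        with pytest.raises(OutOfRangeError):
            estimate_individuals(10, freqs, n_bootstrap=10, seed=0)

    def test_interval_brackets_point(self):
        rng = np.random.default_rng(4)
        freqs = ReferenceFreqs(rng.multinomial(507, np.full(3000, 1 / 3000)))
        est = estimate_individuals(96, freqs, n_bootstrap=100, seed=0)
        assert est.m_low <= est.m_point <= est.m_high
        assert est.m_high - est.m_low < 30  # informative interval
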