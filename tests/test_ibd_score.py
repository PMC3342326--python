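import math

import numpy as np
import pytest
import scipy.stats

from foundertracker import (
    GumbelNull,
    HaplotypePanel,
    IBDSegment,
    MatchParams,
    Origin,
    PanelGenConfig,
    ScoreTrack,
    bh_qvalues,
    build_null,
    estimate_b_freqs,
    estimate_generations,
    fit_gumbel,
    generate_reference_panel,
    per_snp_scores,
    score_pvalues,
    score_segments,
    segment_score,
    significant_regions,
)
from foundertracker.ibd_score import subset_null_scores

from conftest import make_markers, make_panel


def seg(a, b, hap1="h0", hap2="h1", score=float("nan")):
    return IBDSegment(hap1, hap2, a, b, 0.0, score)


class TestSegmentScore:
    def test_zero_information_limit(self):
        """Alleles carried at frequency ~1 contribute (almost) nothing."""
        alleles = np.ones((2, 10), dtype=np.int8)
        panel = make_panel(alleles, b_freq=np.ones(10))
        assert segment_score(seg(0, 9), panel) == pytest.approx(0.0, abs=0.01)

    def test_two_marker_closed_form(self):
        # both haplotypes carry B at f=0.5 and A at 1-f=0.2
        alleles = np.array([[1, 0], [1, 0]], dtype=np.int8)
        panel = make_panel(alleles, b_freq=[0.5, 0.8])
        expected = -2 * (math.log(0.5) + math.log(0.2))
        assert segment_score(seg(0, 1), panel) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(4.6052, abs=1e-4)

    def test_ten_even_markers(self):
        alleles = np.ones((2, 10), dtype=np.int8)
        panel = make_panel(alleles, b_freq=np.full(10, 0.5))
        assert segment_score(seg(0, 9), panel) == pytest.approx(20 * math.log(2), rel=1e-9)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(0)
        alleles = np.tile(rng.integers(0, 2, 50), (2, 1)).astype(np.int8)
        panel = make_panel(alleles, b_freq=rng.uniform(0.1, 0.9, 50))
        total = segment_score(seg(0, 49), panel)
        parts = sum(segment_score(seg(a, b), panel) for a, b in [(0, 9), (10, 30), (31, 49)])
        assert total == pytest.approx(parts, rel=1e-12)

    def test_monotone_in_frequency(self):
        """Lowering a covered allele's frequency strictly increases S."""
        alleles = np.ones((2, 5), dtype=np.int8)
        f = np.full(5, 0.5)
        hi = segment_score(seg(0, 4), make_panel(alleles, b_freq=f))
        f2 = f.copy()
        f2[2] = 0.3
        lo = segment_score(seg(0, 4), make_panel(alleles, b_freq=f2))
        assert lo > hi

    def test_undefined_freq_rejected(self):
        panel = make_panel(np.ones((2, 3), dtype=np.int8))  # b_freq all NaN
        with pytest.raises(ValueError, match="b_freq"):
            segment_score(seg(0, 2), panel)


class TestPerSnpScores:
    def test_no_segments_all_zero(self):
        track = per_snp_scores([], make_markers(8))
        np.testing.assert_array_equal(track.ibd_score, np.zeros(8))

    def test_single_segment(self):
        track = per_snp_scores([seg(2, 5, score=7.2)], make_markers(8))
        expected = np.array([0, 0, 7.2, 7.2, 7.2, 7.2, 0, 0])
        np.testing.assert_allclose(track.ibd_score, expected)

    def test_overlap_sums(self):
        track = per_snp_scores(
            [seg(0, 4, score=3.0), seg(3, 7, score=4.5)], make_markers(8)
        )
        assert track.ibd_score[3] == pytest.approx(7.5)
        assert track.ibd_score[4] == pytest.approx(7.5)

    def test_conservation(self):
        """Sum of per-SNP scores equals sum over segments of S * markers."""
        rng = np.random.default_rng(1)
        segs = []
        for _ in range(40):
            a = int(rng.integers(0, 90))
            b = int(a + rng.integers(0, 10))
            segs.append(seg(a, b, score=float(rng.random() * 5)))
        track = per_snp_scores(segs, make_markers(100))
        expected = sum(s.score * (s.end_idx - s.start_idx + 1) for s in segs)
        assert track.ibd_score.sum() == pytest.approx(expected, rel=1e-9)

    def test_unscored_segment_rejected(self):
        with pytest.raises(ValueError, match="scored"):
            per_snp_scores([seg(0, 1)], make_markers(4))


class TestEstimateBFreqs:
    def test_direct_fractions(self):
        alleles = np.array([[1, 0, 1], [1, 0, 0], [0, 0, 1], [0, 0, 0]], dtype=np.int8)
        out = estimate_b_freqs(make_panel(alleles))
        np.testing.assert_allclose(out.b_freq, [0.5, 0.0, 0.5])

    def test_three_of_ten(self):
        alleles = np.zeros((10, 1), dtype=np.int8)
        alleles[:3, 0] = 1
        out = estimate_b_freqs(make_panel(alleles))
        assert out.b_freq[0] == pytest.approx(0.3)

    def test_all_missing_marker_rejected(self):
        alleles = np.full((3, 2), -1, dtype=np.int8)
        alleles[:, 0] = 0
        with pytest.raises(ValueError):
            estimate_b_freqs(make_panel(alleles))


class TestFitGumbel:
    def test_parameter_recovery(self):
        x = scipy.stats.gumbel_r.rvs(loc=2.0, scale=1.0, size=10_000,
                                     random_state=np.random.default_rng(42))
        mu, beta = fit_gumbel(x)
        assert mu == pytest.approx(2.0, abs=0.05)
        assert beta == pytest.approx(1.0, abs=0.05)

    def test_agrees_with_scipy_mle(self):
        x = scipy.stats.gumbel_r.rvs(loc=-1.0, scale=3.0, size=500,
                                     random_state=np.random.default_rng(0))
        mu, beta = fit_gumbel(x)
        mu_sp, beta_sp = scipy.stats.gumbel_r.fit(x)
        assert mu == pytest.approx(mu_sp, abs=1e-3)
        assert beta == pytest.approx(beta_sp, abs=1e-3)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_gumbel(np.full(10, 3.3))

    def test_location_equivariance(self):
        x = scipy.stats.gumbel_r.rvs(loc=0, scale=2, size=2000,
                                     random_state=np.random.default_rng(1))
        mu, beta = fit_gumbel(x)
        mu2, beta2 = fit_gumbel(x + 5.0)
        assert mu2 - mu == pytest.approx(5.0, abs=1e-6)
        assert beta2 == pytest.approx(beta, abs=1e-6)


class TestScorePvalues:
    def null(self, n, mu=2.0, beta=1.0):
        return GumbelNull(
            markers=make_markers(n),
            mu=np.full(n, mu),
            beta=np.full(n, beta),
            degenerate=np.zeros(n, dtype=bool),
            n_subsets=50,
            subset_size=10,
        )

    def test_p_at_location(self):
        track = ScoreTrack(make_markers(1), ibd_score=[2.0])
        p = score_pvalues(track, self.null(1)).p_value
        assert p[0] == pytest.approx(1 - math.exp(-1), rel=1e-9)

    def test_tail_limits(self):
        track = ScoreTrack(make_markers(2), ibd_score=[200.0, -200.0])
        p = score_pvalues(track, self.null(2)).p_value
        assert p[0] < 1e-12
        assert p[1] == pytest.approx(1.0)

    def test_degenerate_markers(self):
        null = self.null(2, mu=0.0)
        null.degenerate[:] = True
        track = ScoreTrack(make_markers(2), ibd_score=[0.5, 0.0])
        p = score_pvalues(track, null).p_value
        np.testing.assert_array_equal(p, [0.0, 1.0])

    def test_scaffold_mismatch_rejected(self):
        track = ScoreTrack(make_markers(3), ibd_score=np.zeros(3))
        with pytest.raises(ValueError, match="scaffold"):
            score_pvalues(track, self.null(4))


class TestBhQvalues:
    def test_single_p(self):
        assert bh_qvalues([0.03])[0] == pytest.approx(0.03)

    def test_hand_computation(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_step_up_property(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q = bh_qvalues(p)
        order = np.argsort(p)
        m = len(p)
        expected = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(q[order], np.minimum(expected, 1.0))


class TestSignificantRegions:
    def make_track(self, q):
        n = len(q)
        return ScoreTrack(make_markers(n), np.zeros(n), np.asarray(q), np.asarray(q))

    def test_single_run(self):
        regions = significant_regions(self.make_track([0.5, 0.005, 0.005, 0.5]), 0.01)
        assert len(regions) == 1
        assert (regions[0].start_idx, regions[0].end_idx) == (1, 2)

    def test_none_below_threshold(self):
        assert significant_regions(self.make_track([0.5, 0.2]), 0.01) == []

    def test_two_runs(self):
        q = [0.001, 0.5, 0.001, 0.001, 0.5, 0.001]
        regions = significant_regions(self.make_track(q), 0.01)
        assert [(r.start_idx, r.end_idx) for r in regions] == [(0, 0), (2, 3), (5, 5)]


class TestEstimateGenerations:
    def test_worked_example(self):
        """Mean pairwise IBD of 5.4 cM dates the founder event to about
        nine generations."""
        n = estimate_generations(5.4)
        assert n == pytest.approx(9.259, abs=0.01)
        assert round(n) == 9

    @pytest.mark.parametrize("length,expected", [(50.0, 1.0), (2.0, 25.0)])
    def test_closed_form(self, length, expected):
        assert estimate_generations(length) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            estimate_generations(0.0)


@pytest.fixture(scope="module")
def reference():
    return generate_reference_panel(
        PanelGenConfig(n_haplotypes=60, n_markers=2000, chrom_length_cM=20,
                       n_founders=10, seed=3),
        origin=Origin.REFERENCE,
    )


class TestNullUniformity:
    def test_pvalues_of_reference_like_panels_are_uniform(self):
        """Scanning tumor sets drawn from the reference's own population
        yields approximately Uniform(0,1) p-values (KS p > 0.01; markers
        thinned to ~2 cM spacing to decorrelate)."""
        import foundertracker as ft

        pvals = []
        for rep_seed in np.random.SeedSequence(99).spawn(2):
            s = int(rep_seed.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF
            pop = generate_reference_panel(
                PanelGenConfig(n_haplotypes=548, n_markers=4000,
                               chrom_length_cM=40, seed=s)
            )
            ref = pop.subset_haplotypes(np.arange(274))
            rng = np.random.default_rng(s + 2)
            tum = pop.subset_haplotypes(
                274 + np.sort(rng.choice(274, 100, replace=False))
            )
            track = ft.foundertracker_scan(tum, ref, n_null_subsets=50, seed=s + 1)
            pvals.append(track.p_value[::200])
        ks = scipy.stats.kstest(np.concatenate(pvals), "uniform")
        assert ks.pvalue > 0.01


class TestBuildNull:

    def test_deterministic_for_fixed_seed(self, reference):
        a = build_null(reference, 20, MatchParams(), n_subsets=10, seed=5)
        b = build_null(reference, 20, MatchParams(), n_subsets=10, seed=5)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_single_subset_rejected(self, reference):
        with pytest.raises(ValueError):
            build_null(reference, 20, n_subsets=1, seed=0)

    def test_small_reference_rejected(self, reference):
        with pytest.raises(ValueError, match="smaller"):
            build_null(reference, 100, n_subsets=10, seed=0)

    def test_subset_scores_match_direct_subset_scan(self, reference):
        """Null subset scores equal running the matcher + scorer directly on
        the sampled subset (segment reuse across subsets is exact)."""
        from foundertracker.ibd_score import (
            _marker_costs,
            _per_marker_scores_arrays,
        )
        from foundertracker.ibd_match import _exact_segments_arrays

        freq = estimate_b_freqs(reference)
        ref = HaplotypePanel(freq, reference.haplotype_ids, reference.alleles,
                             Origin.REFERENCE)
        scores = subset_null_scores(ref, 20, MatchParams(), n_subsets=3, seed=7)
        rng = np.random.default_rng(7)
        for s in range(3):
            chosen = rng.choice(60, size=20, replace=False)
            sub = ref.subset_haplotypes(np.sort(chosen))
            i, j, a, b, _ = _exact_segments_arrays(sub, MatchParams())
            cum = np.concatenate(
                [np.zeros((20, 1)), np.cumsum(_marker_costs(sub, sub.markers), axis=1)],
                axis=1,
            )
            direct = _per_marker_scores_arrays(2000, a, b, cum[i, b + 1] - cum[i, a])
            np.testing.assert_allclose(scores[s], direct, rtol=1e-10)
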