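import numpy as np
import pytest

from foundertracker import (
    ALLELE_A,
    ALLELE_B,
    MISSING,
    AscnSegment,
    BafProfile,
    HaplotypePanel,
    LOHRegion,
    Origin,
    call_loh,
    drop_unreliable_markers,
    haplotype_error_rate,
    infer_tumor_haplotype,
    reconstruct_lost_haplotype,
    recurrent_loh_regions,
)

from conftest import make_markers, make_panel


def seg(sample, start, end, major, minor, chrom="1"):
    return AscnSegment(sample, chrom, start, end, major, minor)


class TestCallLoh:
    @pytest.mark.parametrize(
        "major,minor,is_loh",
        [
            (1.0, 0.0, True),   # hemizygous deletion
            (1.0, 1.0, False),  # heterozygous diploid
            (2.0, 0.3, True),   # copy-neutral-with-gain LOH under contamination
            (2.0, 0.5, False),  # boundary: minor copy not below 0.5
        ],
    )
    def test_minor_copy_rule(self, major, minor, is_loh):
        """LOH iff minor copy < 0.5, whatever the retained copy number."""
        out = call_loh([seg("s1", 1, 100, major, minor)])
        assert (len(out) == 1) == is_loh


class TestRecurrentRegions:
    def test_single_interval_frequency(self):
        segs = [seg(f"s{i}", 100, 200, 1, 0) for i in range(3)]
        regions = recurrent_loh_regions(segs, n_samples=10, min_frequency=0.2)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (100, 200)
        assert r.frequency == pytest.approx(0.3)
        assert r.carrier_samples == {"s0", "s1", "s2"}

    def test_threshold_filters(self):
        segs = [seg(f"s{i}", 100, 200, 1, 0) for i in range(3)]
        assert recurrent_loh_regions(segs, 10, min_frequency=0.5) == []

    def test_matches_per_bp_counting_oracle(self):
        """Region boundaries agree with brute-force per-basepair counting."""
        rng = np.random.default_rng(3)
        n_samples, limit = 8, 400
        segs = []
        for i in range(n_samples):
            for _ in range(rng.integers(1, 4)):
                a = int(rng.integers(1, limit - 10))
                b = int(a + rng.integers(1, 60))
                segs.append(seg(f"s{i}", a, min(b, limit), 1, 0))
        min_f = 0.25
        regions = recurrent_loh_regions(segs, n_samples, min_f)
        depth = np.zeros(limit + 2)
        for s in segs:
            depth[s.start_bp] += 1
            depth[s.end_bp + 1] -= 1
        cover = np.cumsum(depth)[1 : limit + 1] >= min_f * n_samples - 1e-9
        hit = np.zeros(limit + 2, dtype=bool)
        for r in regions:
            hit[r.start_bp : r.end_bp + 1] = True
        np.testing.assert_array_equal(hit[1 : limit + 1], cover)

    def test_two_disjoint_regions_carrier_sets(self):
        segs = [seg("a", 10, 20, 1, 0), seg("b", 10, 20, 1, 0), seg("c", 50, 60, 1, 0), seg("d", 50, 60, 1, 0)]
        regions = recurrent_loh_regions(segs, 4, 0.5)
        assert len(regions) == 2
        assert regions[0].carrier_samples == {"a", "b"}
        assert regions[1].carrier_samples == {"c", "d"}

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            recurrent_loh_regions([], 0, 0.2)


class TestInferHaplotype:
    def region(self, lo=1, hi=10**9):
        return LOHRegion("1", lo, hi, frozenset({"t"}), 1.0)

    def test_baf_thresholds(self):
        markers = make_markers(5)
        baf = BafProfile(markers, "t", [0.92, 0.08, 0.50, 0.66, 0.34])
        hap = infer_tumor_haplotype(baf, self.region())
        np.testing.assert_array_equal(hap, [ALLELE_B, ALLELE_A, MISSING, ALLELE_B, ALLELE_A])

    def test_outside_region_missing(self):
        markers = make_markers(4)
        baf = BafProfile(markers, "t", [0.9, 0.9, 0.9, 0.9])
        hap = infer_tumor_haplotype(baf, self.region(lo=1, hi=int(markers.pos_bp[1])))
        np.testing.assert_array_equal(hap, [ALLELE_B, ALLELE_B, MISSING, MISSING])

    def test_noisy_baf_recovery(self):
        """BAF synthesised from a known haplotype (0.95/0.05, sigma 0.05)
        is recovered with error rate below 1e-3."""
        rng = np.random.default_rng(11)
        n = 20_000
        truth = rng.integers(0, 2, n).astype(np.int8)
        baf = np.where(truth == 1, 0.95, 0.05) + rng.normal(0, 0.05, n)
        baf = np.clip(baf, 0, 1)
        markers = make_markers(n)
        hap = infer_tumor_haplotype(BafProfile(markers, "t", baf), self.region())
        assert haplotype_error_rate(hap, truth) < 1e-3

    def test_lossless_round_trip_recovers_both_parents(self):
        """With noiseless BAF, retained + reconstructed lost haplotype equal
        the two parental haplotypes exactly."""
        rng = np.random.default_rng(5)
        n = 500
        retained = rng.integers(0, 2, n).astype(np.int8)
        lost = rng.integers(0, 2, n).astype(np.int8)
        baf = np.where(retained == 1, 1.0, 0.0)
        hap = infer_tumor_haplotype(BafProfile(make_markers(n), "t", baf), self.region())
        np.testing.assert_array_equal(hap, retained)
        geno = retained + lost  # 0=AA, 1=AB, 2=BB
        np.testing.assert_array_equal(reconstruct_lost_haplotype(hap, geno), lost)


class TestDropUnreliable:
    def test_drops_columns_with_missing(self):
        alleles = np.zeros((2, 5), dtype=np.int8)
        alleles[1, 2] = MISSING
        panel = make_panel(alleles, origin=Origin.TUMOR)
        out = drop_unreliable_markers(panel)
        assert out.n_markers == 4
        assert "snp2" not in out.markers.marker_id

    def test_identity_when_clean(self):
        panel = make_panel(np.ones((3, 4), dtype=np.int8))
        out = drop_unreliable_markers(panel)
        assert out.n_markers == 4

    def test_all_missing_rejected(self):
        panel = make_panel(np.full((2, 3), MISSING, dtype=np.int8))
        with pytest.raises(ValueError):
            drop_unreliable_markers(panel)


class TestReconstructLost:
    @pytest.mark.parametrize(
        "tumor,geno,lost",
        [
            (ALLELE_B, 1, ALLELE_A),  # heterozygous: lost is the other allele
            (ALLELE_A, 0, ALLELE_A),  # homozygous AA
            (ALLELE_B, 0, MISSING),   # inconsistent: B not in AA
            (ALLELE_A, 2, MISSING),   # inconsistent: A not in BB
            (MISSING, 1, MISSING),
        ],
    )
    def test_comparison_rule(self, tumor, geno, lost):
        out = reconstruct_lost_haplotype([tumor], [geno])
        assert out[0] == lost

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            reconstruct_lost_haplotype([0, 1], [1])


class TestErrorRate:
    def test_identical(self):
        h = np.zeros(1000, dtype=np.int8)
        assert haplotype_error_rate(h, h) == 0.0

    def test_one_in_ten_thousand(self):
        h1 = np.zeros(10_000, dtype=np.int8)
        h2 = h1.copy()
        h2[1234] = 1
        assert haplotype_error_rate(h1, h2) == pytest.approx(1e-4)

    def test_missing_excluded_pairwise(self):
        h1 = np.array([0, MISSING, 1], dtype=np.int8)
        h2 = np.array([0, 1, MISSING], dtype=np.int8)
        assert haplotype_error_rate(h1, h2) == 0.0

    def test_no_comparable_positions(self):
        h = np.full(5, MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            haplotype_error_rate(h, h)
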