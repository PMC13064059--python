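"""Weir-Cockerham estimator against an exact-rational transcription, the
window ratio-of-sums convention, percentile flagging and QC presets."""

from fractions import Fraction

import numpy as np
import pytest

from zwscan import SimParams, fst, simulate_dataset
from zwscan.fst import BiallelicSiteCounts, flag_p99, qc_filter, wc_site, windowed_fst
from zwscan.records import SexedGenotypeMatrix, SexedSample


def wc_oracle(n1, n2, p1, p2, h1, h2):
    """Independent exact-rational transcription of the two-level 1984
    variance-components estimator (r = 2 populations)."""
    n1, n2 = Fraction(n1), Fraction(n2)
    p1, p2 = Fraction(p1), Fraction(p2)
    h1, h2 = Fraction(h1), Fraction(h2)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - Fraction(1, 1) / (nbar - 1)
        * (pbar * (1 - pbar) - s2 * Fraction(r - 1, r) - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - s2 * Fraction(r - 1, r)
        - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


class TestWcSite:
    @pytest.mark.parametrize("n", [2, 5, 10, 50])
    def test_canonical_sexlinked_theta_half(self, n):
        """All-heterozygous females vs homozygous males: theta = 1/2 at any
        equal group size, matching the exact-rational oracle to 1e-12."""
        comp = wc_site(BiallelicSiteCounts(n, n, Fraction(1, 2), 1.0, 1.0, 0.0))
        a, b, c = wc_oracle(n, n, Fraction(1, 2), 1, 1, 0)
        assert comp.a == pytest.approx(float(a), abs=1e-12)
        assert comp.b == pytest.approx(float(b), abs=1e-12)
        assert comp.c == pytest.approx(float(c), abs=1e-12)
        assert comp.theta == pytest.approx(0.5, abs=1e-12)
        if n == 10:
            assert (comp.a, comp.b, comp.c) == pytest.approx((0.125, -0.125, 0.25))

    def test_random_counts_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n1, n2 = rng.integers(2, 30, size=2)
            k1, k2 = rng.integers(0, 2 * n1 + 1), rng.integers(0, 2 * n2 + 1)
            het1 = rng.integers(0, min(k1, 2 * n1 - k1) + 1)
            het2 = rng.integers(0, min(k2, 2 * n2 - k2) + 1)
            p1, p2 = Fraction(int(k1), 2 * int(n1)), Fraction(int(k2), 2 * int(n2))
            h1, h2 = Fraction(int(het1), int(n1)), Fraction(int(het2), int(n2))
            counts = BiallelicSiteCounts(int(n1), int(n2), p1, p2, h1, h2)
            comp = wc_site(counts)
            if comp is None:
                assert p1 == p2 and p1 in (0, 1) and h1 == h2 == 0
                continue
            a, b, c = wc_oracle(n1, n2, p1, p2, h1, h2)
            assert comp.a == pytest.approx(float(a), abs=1e-12)
            assert comp.b == pytest.approx(float(b), abs=1e-12)
            assert comp.c == pytest.approx(float(c), abs=1e-12)

    def test_identical_groups_nonpositive_theta(self):
        comp = wc_site(BiallelicSiteCounts(10, 10, 0.5, 0.5, 0.4, 0.4))
        assert comp.theta <= 0

    def test_monomorphic_excluded(self):
        assert wc_site(BiallelicSiteCounts(10, 10, 1.0, 1.0, 0.0, 0.0)) is None


class TestWindowedFst:
    def _components(self, specs):
        """specs: [(pos, (n1,n2,p1,p2,h1,h2))]"""
        pos, a, b, c = [], [], [], []
        for p, args in specs:
            comp = wc_site(BiallelicSiteCounts(*args))
            pos.append(p)
            a.append(comp.a if comp else np.nan)
            b.append(comp.b if comp else np.nan)
            c.append(comp.c if comp else np.nan)
        return np.array(pos), np.array(a), np.array(b), np.array(c)

    def test_single_site_window(self):
        pos, a, b, c = self._components([(500, (10, 10, 0.5, 0.0, 1.0, 0.0))])
        theta, n = windowed_fst(pos, a, b, c, 10_000, 1_000)
        assert theta[0] == pytest.approx(0.5)
        assert np.isnan(theta[1])

    def test_ratio_of_sums_not_mean_of_ratios(self):
        specs = [
            (100, (10, 10, 0.5, 0.0, 1.0, 0.0)),
            (200, (10, 10, 0.45, 0.40, 0.5, 0.6)),
        ]
        pos, a, b, c = self._components(specs)
        theta, _ = windowed_fst(pos, a, b, c, 1_000, 1_000)
        ratio_of_sums = (a.sum()) / (a + b + c).sum()
        mean_of_ratios = np.mean(a / (a + b + c))
        assert theta[0] == pytest.approx(ratio_of_sums, abs=1e-12)
        assert abs(theta[0] - mean_of_ratios) > 1e-3

    def test_nonpositive_denominator_sites_excluded(self):
        # a monomorphic-in-truth site gives NaN components -> excluded
        pos = np.array([100, 200])
        a = np.array([0.125, np.nan])
        b = np.array([-0.125, np.nan])
        c = np.array([0.25, np.nan])
        theta, n = windowed_fst(pos, a, b, c, 1_000, 1_000)
        assert n[0] == 1 and theta[0] == pytest.approx(0.5)


class TestFlagP99:
    def test_nearest_rank_1_to_100(self):
        values = np.arange(1.0, 101.0)
        threshold, exceeds = flag_p99(values)
        assert threshold == 99.0
        assert list(np.nonzero(exceeds)[0]) == [99]

    def test_all_equal_flags_nothing(self):
        threshold, exceeds = flag_p99(np.full(50, 0.3))
        assert threshold == 0.3
        assert not exceeds.any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            flag_p99(np.array([np.nan]))


class TestQcFilter:
    def _matrix(self, gt, ad, qual=60.0):
        gt = np.asarray(gt, dtype=np.int8)
        n_sites, n_samples, _ = gt.shape
        samples = [SexedSample(f"F{i}", "F") for i in range(n_samples // 2)] + [
            SexedSample(f"M{i}", "M") for i in range(n_samples - n_samples // 2)
        ]
        return SexedGenotypeMatrix(
            chrom="c",
            positions=np.arange(n_sites) * 100,
            ref=["A"] * n_sites,
            alts=[("G",)] * n_sites,
            gt=gt,
            ad=np.asarray(ad, dtype=np.int32),
            qual=np.full(n_sites, qual),
            samples=samples,
        )

    def test_maf_exactly_point_one_removed(self):
        # 20 samples, 4 alt alleles of 40 -> MAF exactly 0.10 -> removed
        gt = np.zeros((1, 20, 2), dtype=np.int8)
        gt[0, :4, 1] = 1  # four heterozygotes
        ad = np.full((1, 20, 2), 15)
        out = qc_filter(self._matrix(gt, ad), "slr")
        assert out.n_sites == 0

    def test_one_missing_genotype_fails_max_missing_one(self):
        gt = np.zeros((1, 20, 2), dtype=np.int8)
        gt[0, :10, 1] = 1  # MAF 0.25, fine
        gt[0, 19] = -1
        ad = np.full((1, 20, 2), 15)
        out = qc_filter(self._matrix(gt, ad), "slr")
        assert out.n_sites == 0

    def test_dp_bounds_inclusive(self):
        gt = np.zeros((2, 20, 2), dtype=np.int8)
        gt[:, :10, 1] = 1
        ad_hi = np.full((20, 2), 50)  # DP 100: retained
        ad_low = np.full((20, 2), 4)  # DP 8: genotype dropped -> site fails
        ad = np.stack([ad_hi, ad_low])
        out = qc_filter(self._matrix(gt, ad), "slr")
        assert out.n_sites == 1 and out.positions[0] == 0

    def test_degeneration_preset_quality_floor(self):
        gt = np.zeros((1, 20, 2), dtype=np.int8)
        gt[0, :10, 1] = 1
        ad = np.full((1, 20, 2), 15)
        assert qc_filter(self._matrix(gt, ad, qual=29.0), "degeneration").n_sites == 0
        assert qc_filter(self._matrix(gt, ad, qual=30.0), "degeneration").n_sites == 1

    def test_unknown_preset_rejected(self):
        gt = np.zeros((1, 2, 2), dtype=np.int8)
        ad = np.full((1, 2, 2), 15)
        with pytest.raises(ValueError):
            qc_filter(self._matrix(gt, ad), "bogus")


def test_permutation_null_controls_pseudoautosomal_windows():
    """Shuffling sex labels on autosomal data yields a null 99th percentile
    that bounds nearly all observed autosomal window values."""
    res = simulate_dataset(SimParams(seed=21, chrom_length=100_000,
                                     region_bounds=(20_000, 40_000, 70_000, 75_000),
                                     autosome_length=500_000))
    matrix = res.genotypes["chrA"]
    filtered = qc_filter(matrix, "slr")
    a, b, c = fst.wc_components(filtered)
    theta_obs, _ = windowed_fst(filtered.positions, a, b, c, 500_000, 10_000)

    rng = np.random.default_rng(0)
    null_values = []
    for _ in range(3):
        perm = rng.permutation(filtered.n_samples)
        shuffled = SexedGenotypeMatrix(
            chrom="chrA", positions=filtered.positions, ref=filtered.ref,
            alts=filtered.alts, gt=filtered.gt[:, perm], ad=filtered.ad[:, perm],
            qual=filtered.qual, samples=filtered.samples,
        )
        a2, b2, c2 = fst.wc_components(shuffled)
        t, _ = windowed_fst(filtered.positions, a2, b2, c2, 500_000, 10_000)
        null_values.append(t)
    null_p99, _ = flag_p99(np.concatenate(null_values))
    obs = theta_obs[np.isfinite(theta_obs)]
    assert (obs > null_p99).mean() <= 0.05
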