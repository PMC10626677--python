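"""EHH / iHS / nSL: all-pairs oracles, symmetries, standardization, windows."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepstack import (
    ehh,
    ihs_raw,
    neglog_two_tailed_p,
    nsl_raw,
    standardize,
    window_scan,
)
from sweepstack.data import HaplotypeMatrix, Region
from sweepstack.haplostats import polarize_haplotypes, score_track

from .conftest import make_variants


def ehh_bruteforce(haps, focal, allele, target):
    """EHH over [focal, target] as the fraction of identical carrier pairs."""
    car = np.flatnonzero(haps[:, focal] == allele)
    lo, hi = min(focal, target), max(focal, target)
    n_pairs = 0
    n_same = 0
    for a, b in itertools.combinations(car, 2):
        n_pairs += 1
        if np.array_equal(haps[a, lo:hi + 1], haps[b, lo:hi + 1]):
            n_same += 1
    return n_same / n_pairs


class TestEhh:
    def test_identical_carriers_stay_at_one(self):
        haps = np.zeros((6, 10), dtype=np.int8)
        haps[:3, 4] = 1
        c = ehh(haps, 4, 1, min_ehh_cutoff=0.0)
        assert (c.right_ehh == 1.0).all()
        assert (c.left_ehh == 1.0).all()

    def test_carriers_all_pairwise_distinct_give_zero(self):
        # four carriers that are pairwise distinct two SNPs out -> EHH = 0
        haps = np.zeros((8, 4), dtype=np.int8)
        haps[:4, 1] = 1  # carriers of allele 1 at focal SNP 1
        haps[:4, 2] = [0, 0, 1, 1]
        haps[:4, 3] = [0, 1, 0, 1]  # all four haplotypes now distinct
        c = ehh(haps, 1, 1, min_ehh_cutoff=0.0)
        assert c.right_ehh[1] == pytest.approx(2 / 6)  # two groups of two
        assert c.right_ehh[2] == 0.0  # singletons only: no identical pairs
        # a two-carrier pair differing at the adjacent SNP drops straight to 0
        c2 = ehh(haps[[0, 2, 4, 5]], 1, 1, min_ehh_cutoff=0.0)
        assert c2.right_ehh[1] == 0.0

    def test_monomorphic_core_rejected(self):
        haps = np.zeros((4, 3), dtype=np.int8)
        with pytest.raises(ValueError):
            ehh(haps, 1, 1)

    def test_matches_all_pairs_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for trial in range(40):
            haps = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 50_000), 12, replace=False))
            for focal in range(12):
                for allele in (0, 1):
                    if (haps[:, focal] == allele).sum() < 2:
                        continue
                    c = ehh(haps, focal, allele, pos, min_ehh_cutoff=0.0,
                            max_gap_bp=10**9)
                    for j, e in zip(c.right_idx, c.right_ehh):
                        assert e == pytest.approx(
                            ehh_bruteforce(haps, focal, allele, j), abs=1e-12
                        )
                    for j, e in zip(c.left_idx, c.left_ehh):
                        assert e == pytest.approx(
                            ehh_bruteforce(haps, focal, allele, j), abs=1e-12
                        )

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            haps = rng.integers(0, 2, size=(10, 20)).astype(np.int8)
            focal = 10
            for allele in (0, 1):
                if (haps[:, focal] == allele).sum() < 2:
                    continue
                c = ehh(haps, focal, allele, min_ehh_cutoff=0.0)
                assert np.all(np.diff(c.right_ehh) <= 1e-12)
                assert np.all(np.diff(c.left_ehh) <= 1e-12)


class TestIhsRaw:
    def test_mirror_structure_gives_zero(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 2, size=(5, 11)).astype(np.int8)
        haps = np.vstack([block, block])
        haps[:5, 5] = 0
        haps[5:, 5] = 1
        haps[5:, :5] = block[:, :5]
        haps[5:, 6:] = block[:, 6:]
        pos = np.arange(11) * 1000 + 1
        assert ihs_raw(haps, pos, 5) == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            haps = rng.integers(0, 2, size=(10, 15)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 100_000), 15, replace=False))
            v = ihs_raw(haps, pos, 7)
            w = ihs_raw(1 - haps, pos, 7)
            if np.isnan(v):
                assert np.isnan(w)
            else:
                assert w == pytest.approx(-v, abs=1e-12)

    def test_sweep_elevates_ihs_near_focal_site(self):
        # partial sweep on chromosome 1 of a 4-chromosome genome: the
        # standardized score magnitude near the focal site exceeds the
        # genome background in every replicate
        from sweepstack.experiments import sweep_genome
        from sweepstack.haplostats import HaplotypeScan

        for rep in range(3):
            haps, variants, _ = sweep_genome(6000 + 37 * rep, target_freq=0.8)
            res = HaplotypeScan(haps, variants, "ihs").fit()
            t = res.track
            near = (t["chrom"] == "1") & (
                np.abs(t["pos_bp"] - 1_000_000) <= 100_000
            )
            z = np.abs(t["std"].to_numpy())
            assert np.nanmean(z[near]) > np.nanmean(z[~near])


def nsl_sl_means(haps, pos, focal, max_gap, gap_scale, max_extend):
    """Per-allele mean shared lengths (SL_A, SL_D) by all-pairs enumeration."""
    out = {}
    for allele in (0, 1):
        car = np.flatnonzero(haps[:, focal] == allele)
        if car.size < 2:
            return None
        tot = 0.0
        n = 0
        for a, b in itertools.combinations(car, 2):
            n += 1
            length = 1.0
            for direction in (1, -1):
                j = focal
                steps = 0
                while steps < max_extend:
                    jn = j + direction
                    if jn < 0 or jn >= haps.shape[1]:
                        break
                    gap = abs(int(pos[jn]) - int(pos[j]))
                    if gap > max_gap:
                        break
                    lo, hi = min(focal, jn), max(focal, jn)
                    if not np.array_equal(haps[a, lo:hi + 1], haps[b, lo:hi + 1]):
                        break
                    length += 1.0 if gap <= gap_scale else gap_scale / gap
                    j = jn
                    steps += 1
            tot += length
        out[allele] = tot / n
    return out


def nsl_bruteforce(haps, pos, focal, max_gap, gap_scale, max_extend):
    out = nsl_sl_means(haps, pos, focal, max_gap, gap_scale, max_extend)
    if out is None or out[0] <= 0 or out[1] <= 0:
        return np.nan
    return np.log(out[0] / out[1])


class TestNslRaw:
    def test_identical_pair_contributes_full_length(self):
        # two identical derived haplotypes spanning all m sites -> SL_D = m
        m = 9
        rng = np.random.default_rng(12)
        haps = rng.integers(0, 2, size=(6, m)).astype(np.int8)
        focal = 4
        haps[0] = haps[1]  # identical derived pair
        haps[0, focal] = haps[1, focal] = 1
        haps[2:, focal] = 0
        pos = np.arange(m) * 100 + 1
        means = nsl_sl_means(haps, pos, focal, 10**9, 10**9, 100)
        assert means[1] == pytest.approx(m)
        raw = nsl_raw(haps, pos, focal, max_gap_bp=10**9, gap_scale_bp=10**9)
        assert raw == pytest.approx(np.log(means[0] / means[1]), abs=1e-12)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        checked = 0
        for trial in range(60):
            haps = rng.integers(0, 2, size=(6, 10)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 8000), 10, replace=False))
            for focal in range(10):
                nd = haps[:, focal].sum()
                if nd < 2 or 6 - nd < 2:
                    continue
                mine = nsl_raw(haps, pos, focal, max_gap_bp=10**9,
                               gap_scale_bp=10**9)
                orc = nsl_bruteforce(haps, pos, focal, 10**9, 10**9, 100)
                assert mine == pytest.approx(orc, abs=1e-12)
                checked += 1
        assert checked > 100

    def test_gap_penalty_matches_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            haps = rng.integers(0, 2, size=(6, 10)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 200_000), 10, replace=False))
            for focal in (4, 5):
                nd = haps[:, focal].sum()
                if nd < 2 or 6 - nd < 2:
                    continue
                mine = nsl_raw(haps, pos, focal, max_gap_bp=100_000,
                               gap_scale_bp=20_000)
                orc = nsl_bruteforce(haps, pos, focal, 100_000, 20_000, 100)
                if np.isnan(mine):
                    assert np.isnan(orc)
                else:
                    assert mine == pytest.approx(orc, abs=1e-12)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(6)
        haps = rng.integers(0, 2, size=(8, 12)).astype(np.int8)
        pos = np.arange(12) * 500 + 1
        v = nsl_raw(haps, pos, 6)
        w = nsl_raw(1 - haps, pos, 6)
        if np.isnan(v):
            assert np.isnan(w)
        else:
            assert w == pytest.approx(-v, abs=1e-12)


class TestStandardize:
    def test_per_bin_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=2000)
        freq = rng.uniform(0.05, 0.95, size=2000)
        z = standardize(raw, freq, n_bins=20)
        edges = np.linspace(0, 1, 21)
        for b in range(20):
            sel = (freq >= edges[b]) & (freq < edges[b + 1]) & np.isfinite(z)
            if sel.sum() >= 10:
                assert abs(z[sel].mean()) < 1e-10
                assert abs(z[sel].std(ddof=0) - 1) < 1e-10

    def test_single_bin_reduces_to_plain_zscore(self):
        rng = np.random.default_rng(1)
        raw = rng.normal(size=100)
        freq = np.full(100, 0.5)
        z = standardize(raw, freq, n_bins=1)
        np.testing.assert_allclose(
            z, (raw - raw.mean()) / raw.std(ddof=0), atol=1e-12
        )

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=500)
        freq = rng.uniform(0, 1, size=500)
        once = standardize(raw, freq, n_bins=10)
        twice = standardize(once, freq, n_bins=10)
        ok = np.isfinite(once)
        np.testing.assert_allclose(twice[ok], once[ok], atol=1e-12)

    def test_degenerate_bin_set_missing(self):
        raw = np.array([1.0, 1.0, 1.0])
        freq = np.array([0.5, 0.5, 0.5])
        z = standardize(raw, freq)
        assert np.isnan(z).all()


class TestNeglogTwoTailedP:
    @pytest.mark.parametrize(
        "z,expected,tol",
        [(0.0, 0.0, 1e-12), (1.959964, 1.301, 1e-3), (3.890592, 4.000, 1e-3)],
    )
    def test_gaussian_cdf_oracle(self, z, expected, tol):
        assert neglog_two_tailed_p(z) == pytest.approx(expected, abs=tol)

    @given(st.floats(-30, 30))
    @settings(derandomize=True, max_examples=50)
    def test_symmetric_and_nonnegative(self, z):
        v = neglog_two_tailed_p(z)
        assert v >= 0
        assert v == pytest.approx(neglog_two_tailed_p(-z), abs=1e-12)


class TestWindowScan:
    def _track(self, pos, nlp, chrom="1"):
        return pd.DataFrame(
            {"chrom": chrom, "pos_bp": pos, "freq_derived": 0.5, "raw": 0.0,
             "std": 0.0, "neglog10p": nlp}
        )

    def test_three_hits_significant_two_not(self):
        track = self._track([100_000, 200_000, 300_000], [4.1, 4.1, 4.1])
        windows, regions = window_scan(track, step_bp=500_000)
        assert windows["significant"].iloc[0]
        assert len(regions) == 1
        track2 = self._track([100_000, 200_000, 300_000], [4.1, 4.1, 3.9])
        windows2, regions2 = window_scan(track2, step_bp=500_000)
        assert not windows2["significant"].any()
        assert regions2 == []

    def test_merged_regions_match_bruteforce_union(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            m = 60
            pos = np.sort(rng.choice(np.arange(1, 3_000_000), m, replace=False))
            nlp = rng.choice([0.5, 5.0], size=m, p=[0.8, 0.2])
            track = self._track(pos, nlp)
            windows, regions = window_scan(track, window_bp=500_000,
                                           step_bp=100_000)
            sig = windows[windows["significant"]]
            # brute force: union of significant windows, merged if overlapping
            intervals = sorted(
                (int(r.start_bp), int(r.end_bp)) for r in sig.itertuples()
            )
            merged = []
            for s, e in intervals:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            assert [(r.start_bp, r.end_bp) for r in regions] == merged


class TestPolarize:
    def test_flips_columns_with_allele_b_ancestral(self):
        haps = HaplotypeMatrix(np.array([[0, 1], [1, 1], [0, 0], [1, 0]],
                                        dtype=np.int8))
        variants = make_variants([100, 200])
        variants.ancestral[1] = "B"
        out, flagged = polarize_haplotypes(haps, variants)
        np.testing.assert_array_equal(out.haps[:, 1], 1 - haps.haps[:, 1])
        assert not flagged.any()

    def test_unknown_polarity_major_becomes_ancestral(self):
        haps = HaplotypeMatrix(np.array([[1], [1], [1], [0]], dtype=np.int8))
        variants = make_variants([100])
        variants.ancestral[0] = "."
        out, flagged = polarize_haplotypes(haps, variants)
        assert flagged[0]
        assert out.haps[:, 0].sum() == 1  # minor allele recoded as derived
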