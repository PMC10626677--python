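"""QC chain: exact HWE test, call-rate/MAF filters, relatedness, LD decay."""

import itertools
from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from sweepstack import (
    GenotypeMatrix,
    degrade,
    hwe_exact_p,
    ibd_pihat,
    ld_decay,
    prune_related,
    qc_filter,
)
from sweepstack.qc import QCReport

from .conftest import make_samples, make_variants


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact two-sided HWE P by rational-arithmetic enumeration."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    rare = min(n_a, 2 * n - n_a)

    def weight(h):
        hr = (rare - h) // 2
        hc = n - h - hr
        return Fraction(2**h, factorial(hr) * factorial(h) * factorial(hc))

    hets = range(rare % 2, rare + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_ab] / total
    return float(sum(w for w in weights.values() if w / total <= obs) / total)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts",
        [
            (25, 50, 25),
            (50, 0, 50),
            (10, 30, 60),
            (1, 1, 1),
            (0, 5, 95),
            (40, 20, 40),
            (7, 0, 3),
        ],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    def test_random_configurations_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 200))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            assert hwe_exact_p(n_aa, n_ab, n_bb) == pytest.approx(
                hwe_enumeration_oracle(n_aa, n_ab, n_bb), abs=1e-12
            )

    def test_extreme_heterozygote_deficit_is_significant(self):
        assert hwe_exact_p(50, 0, 50) < 1e-4

    def test_monomorphic_convention(self):
        assert hwe_exact_p(100, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 42) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_p(-1, 2, 3)


class TestQcFilter:
    def test_toy_matrix_removes_expected_snp_and_individual(self):
        # 4 individuals x 5 SNPs: SNP 0 rare (MAF < 0.01 impossible at n=4,
        # so use monomorphic-ish filtering via MAF=0.2), individual 3 half missing
        dosage = np.array(
            [
                [0, 1, 2, 1, 0],
                [0, 1, 0, 1, 1],
                [0, 2, 1, 0, 1],
                [-1, -1, 1, 0, -1],
            ],
            dtype=np.int8,
        )
        geno = GenotypeMatrix(dosage)
        variants = make_variants([100, 200, 300, 400, 500])
        samples = make_samples(4)
        _, fv, fs, report = qc_filter(
            geno, variants, samples,
            {"indiv_call": 0.9, "snp_call": 0.0, "maf": 0.1, "hwe_p": 0.0},
        )
        assert fs.n_samples == 3  # individual 3 dropped (40% missing)
        assert fv.n_variants == 4  # SNP 0 monomorphic after drop -> MAF 0
        steps = dict((s[0], s[2]) for s in report.steps)
        assert steps["individual_call_rate"] == 1
        assert steps["maf"] == 1

    def test_extreme_thresholds_keep_everything(self, neutral_dataset):
        haps, variants, _, _ = neutral_dataset
        geno = haps.to_genotypes()
        samples = make_samples(geno.n_samples)
        fg, fv, fs, report = qc_filter(
            geno, variants, samples,
            {"indiv_call": 0.0, "snp_call": 0.0, "maf": 0.0, "hwe_p": 0.0},
        )
        assert fg.n_variants == geno.n_variants
        assert fs.n_samples == geno.n_samples
        np.testing.assert_array_equal(fg.dosage, geno.dosage)

    def test_removal_counts_match_independent_recount(self):
        rng = np.random.default_rng(42)
        n, m = 120, 800
        dosage = rng.choice([0, 1, 2], size=(n, m), p=[0.4, 0.3, 0.3])
        dosage[rng.random((n, m)) < 0.05] = -1
        geno = GenotypeMatrix(dosage.astype(np.int8))
        variants = make_variants(np.arange(1, m + 1) * 1000)
        samples = make_samples(n)
        th = {"indiv_call": 0.96, "snp_call": 0.96, "maf": 0.05, "hwe_p": 1e-4}
        _, _, _, report = qc_filter(geno, variants, samples, th)

        # independent recount in filter order
        keep_i = (dosage != -1).mean(axis=1) >= th["indiv_call"]
        d1 = dosage[keep_i]
        keep_s = (d1 != -1).mean(axis=0) >= th["snp_call"]
        d2 = d1[:, keep_s]
        with np.errstate(invalid="ignore"):
            f = np.nanmean(np.where(d2 == -1, np.nan, d2), axis=0) / 2
        maf = np.minimum(f, 1 - f)
        keep_m = np.where(np.isnan(maf), False, maf >= th["maf"])
        d3 = d2[:, keep_m]
        hwe_keep = np.array(
            [
                hwe_exact_p(
                    int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())
                )
                >= th["hwe_p"]
                for c in d3.T
            ]
        )
        expected = {
            "individual_call_rate": int((~keep_i).sum()),
            "snp_call_rate": int((~keep_s).sum()),
            "maf": int((~keep_m).sum()),
            "hwe": int((~hwe_keep).sum()),
        }
        got = {s[0]: s[2] for s in report.steps}
        assert got == expected

    def test_report_conservation(self, neutral_dataset):
        haps, variants, _, _ = neutral_dataset
        geno = haps.to_genotypes()
        samples = make_samples(geno.n_samples)
        _, fv, fs, report = qc_filter(geno, variants, samples, {"maf": 0.05})
        assert report.n_snps_retained + report.n_snps_removed == report.n_snps_in
        assert report.n_indiv_retained + report.n_indiv_removed == report.n_indiv_in
        assert report.n_snps_retained == fv.n_variants
        assert report.n_indiv_retained == fs.n_samples


class TestIbdPihat:
    def test_duplicates_near_one_and_symmetric_bounds(self, neutral_dataset):
        haps, variants, _, _ = neutral_dataset
        geno = haps.to_genotypes()
        samples = make_samples(geno.n_samples)
        geno2, samples2 = degrade(geno, samples, n_duplicates=1, seed=7)
        tab = ibd_pihat(geno2)
        assert ((tab["pi_hat"].dropna() >= 0) & (tab["pi_hat"].dropna() <= 1)).all()
        dup_idx = geno2.n_samples - 1
        src = [
            i for i in range(geno.n_samples)
            if np.array_equal(geno2.dosage[i], geno2.dosage[dup_idx])
        ][0]
        row = tab[(tab["i"] == src) & (tab["j"] == dup_idx)]
        assert row["pi_hat"].iloc[0] >= 0.95

    def test_unrelated_low_and_parent_child_near_half(self):
        params_rng = np.random.default_rng(3)
        n, m = 40, 5000
        freq = params_rng.uniform(0.1, 0.9, size=m)
        dosage = params_rng.binomial(2, freq[None, :], size=(n, m)).astype(np.int8)
        geno = GenotypeMatrix(dosage)
        samples = make_samples(n)
        geno2, samples2 = degrade(geno, samples, n_parent_child=2, seed=9)
        tab = ibd_pihat(geno2)
        unrel = tab[(tab["i"] < n) & (tab["j"] < n)]["pi_hat"]
        assert unrel.abs().max() < 0.1
        for k in range(2):
            child = n + k
            flag = samples2.flags[samples2.sample_id[child]]
            parents = [
                int(np.flatnonzero(samples2.sample_id == p)[0])
                for p in flag.split(":")[1].split(",")
            ]
            for p in parents:
                row = tab[(tab["i"] == min(p, child)) & (tab["j"] == max(p, child))]
                assert abs(row["pi_hat"].iloc[0] - 0.5) < 0.1

    def test_too_few_informative_snps_flagged(self):
        dosage = np.array([[0, 1], [1, 2], [2, 2]], dtype=np.int8)
        tab = ibd_pihat(GenotypeMatrix(dosage), min_informative=50)
        assert (~tab["reliable"]).all()
        assert tab["pi_hat"].isna().all()


class TestPruneRelated:
    def test_duplicate_pair_drops_exactly_one(self):
        tab = pd.DataFrame({"i": [0], "j": [1], "n_snps": [1000],
                            "pi_hat": [0.99], "reliable": [True]})
        kept = prune_related(tab, 3, threshold=0.18)
        assert len(kept) == 2 and (0 in kept) != (1 in kept)

    def test_no_pairs_above_threshold_keeps_all(self):
        tab = pd.DataFrame({"i": [0, 1], "j": [1, 2], "n_snps": [9, 9],
                            "pi_hat": [0.1, 0.05], "reliable": [True, True]})
        assert len(prune_related(tab, 3)) == 3

    def test_clique_matches_exhaustive_minimal_removal(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 8
            pairs = []
            pi = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                v = rng.choice([0.02, 0.5], p=[0.7, 0.3])
                pi[i, j] = v
                pairs.append((i, j, 100, v, True))
            tab = pd.DataFrame(pairs, columns=["i", "j", "n_snps", "pi_hat",
                                               "reliable"])
            kept = set(prune_related(tab, n, threshold=0.18))
            # exhaustive: the largest subset with no pair above threshold
            best = 0
            for r in range(n, -1, -1):
                found = False
                for sub in itertools.combinations(range(n), r):
                    if all(pi[i, j] <= 0.18
                           for i, j in itertools.combinations(sub, 2)):
                        found = True
                        break
                if found:
                    best = r
                    break
            assert all(
                pi[i, j] <= 0.18 for i, j in itertools.combinations(sorted(kept), 2)
            )
            assert len(kept) == best


class TestLdDecay:
    def test_duplicated_column_gives_r2_one(self):
        rng = np.random.default_rng(1)
        col = rng.choice([0, 1, 2], size=50).astype(np.int8)
        dosage = np.column_stack([col, col, rng.choice([0, 1, 2], 50)]).astype(np.int8)
        geno = GenotypeMatrix(dosage)
        variants = make_variants([1000, 2000, 900_000])
        out = ld_decay(geno, variants, max_dist_bp=10_000, n_bins=2)
        first = out[out["n_pairs"] > 0].iloc[0]
        assert first["mean_r2"] == pytest.approx(1.0)

    def test_independent_snps_near_bias_floor(self):
        rng = np.random.default_rng(2)
        n, m = 60, 400
        dosage = rng.binomial(2, 0.5, size=(n, m)).astype(np.int8)
        geno = GenotypeMatrix(dosage)
        variants = make_variants(np.arange(1, m + 1) * 100)
        out = ld_decay(geno, variants, max_dist_bp=50_000, n_bins=1)
        # E[r2] for independent loci is ~1/(n-1)
        assert out["mean_r2"].iloc[0] == pytest.approx(1 / (n - 1), rel=0.35)

    def test_mean_r2_non_increasing_on_recombining_neutral_sims(self):
        from sweepstack import SimParams, simulate_neutral

        acc = []
        for rep in range(20):
            params = SimParams(
                n_diploids=25, seq_length_bp=500_000, mu=2e-7, r=4e-7,
                pop_size_N=100, seed=100 + rep,
            )
            haps, variants, _ = simulate_neutral(params)
            out = ld_decay(haps.to_genotypes(), variants,
                           max_dist_bp=200_000, n_bins=4)
            acc.append(out["mean_r2"].to_numpy())
        mean_curve = np.nanmean(np.array(acc), axis=0)
        assert np.all(np.diff(mean_curve) <= 1e-3)
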