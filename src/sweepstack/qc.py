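"""Quality control for SNP-array genotypes.

Implements the standard pre-scan QC chain for a single population:
per-individual and per-SNP call-rate filters, minor-allele-frequency and
Hardy–Weinberg exact-test filters (applied in the fixed order individuals →
SNP call rate → MAF → HWE, each step logged), method-of-moments relatedness
(PI_HAT) with greedy pruning above a threshold, and an LD-decay summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import GenotypeMatrix, SampleInfo, VariantTable

DEFAULT_THRESHOLDS = {
    "indiv_call": 0.90,
    "snp_call": 0.95,
    "maf": 0.01,
    "hwe_p": 1e-4,
}


@dataclass
class QCReport:
    """Ordered log of filters applied with per-axis removal counts."""

    n_snps_in: int
    n_indiv_in: int
    steps: list = field(default_factory=list)  # (name, axis, n_removed)
    kept_variant_idx: np.ndarray | None = None  # indices into the input axes
    kept_sample_idx: np.ndarray | None = None

    def log(self, name: str, axis: str, n_removed: int) -> None:
        self.steps.append((name, axis, int(n_removed)))

    @property
    def n_snps_removed(self) -> int:
        return sum(n for _, ax, n in self.steps if ax == "snp")

    @property
    def n_indiv_removed(self) -> int:
        return sum(n for _, ax, n in self.steps if ax == "individual")

    @property
    def n_snps_retained(self) -> int:
        return self.n_snps_in - self.n_snps_removed

    @property
    def n_indiv_retained(self) -> int:
        return self.n_indiv_in - self.n_indiv_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "axis", "n_removed"])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy–Weinberg test on genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no greater than that of the
    observed configuration.  Monomorphic sites return 1 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # conditional pmf: P(h | allele counts) ∝ 2^h / (n_hom_rare! n_het! n_hom_common!)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = hets * np.log(2.0) - (
        gammaln(hom_rare + 1) + gammaln(hets + 1) + gammaln(hom_common + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = n_ab
    p_obs = p[np.flatnonzero(hets == obs)[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def hwe_exact_p_vec(geno: GenotypeMatrix) -> np.ndarray:
    """Per-SNP exact HWE P over non-missing genotypes."""
    d = geno.dosage
    n_aa = (d == 0).sum(axis=0)
    n_ab = (d == 1).sum(axis=0)
    n_bb = (d == 2).sum(axis=0)
    return np.array(
        [hwe_exact_p(int(a), int(h), int(b)) for a, h, b in zip(n_aa, n_ab, n_bb)]
    )


def qc_filter(
    geno: GenotypeMatrix,
    variants: VariantTable,
    samples: SampleInfo,
    thresholds: dict | None = None,
) -> tuple[GenotypeMatrix, VariantTable, SampleInfo, QCReport]:
    """Apply the QC chain in fixed order, logging each step.

    Order: individual call rate, SNP call rate, MAF, HWE.  Thresholds are
    retention rules: an item is kept iff call rate >= threshold, MAF >=
    threshold, HWE P >= threshold.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    report = QCReport(n_snps_in=geno.n_variants, n_indiv_in=geno.n_samples)
    var_idx = np.arange(geno.n_variants)

    present = geno.dosage != -1
    ind_call = present.mean(axis=1) if geno.n_variants else np.ones(geno.n_samples)
    keep_ind = ind_call >= th["indiv_call"]
    report.log("individual_call_rate", "individual", (~keep_ind).sum())
    geno = geno.take_samples(np.flatnonzero(keep_ind))
    samples = samples.take(np.flatnonzero(keep_ind))
    report.kept_sample_idx = np.flatnonzero(keep_ind)

    present = geno.dosage != -1
    snp_call = present.mean(axis=0) if geno.n_samples else np.ones(geno.n_variants)
    keep = snp_call >= th["snp_call"]
    report.log("snp_call_rate", "snp", (~keep).sum())
    geno = geno.take_variants(np.flatnonzero(keep))
    variants = variants.take(np.flatnonzero(keep))
    var_idx = var_idx[keep]

    maf = geno.maf()
    keep = np.where(np.isnan(maf), False, maf >= th["maf"])
    if th["maf"] <= 0:
        keep = np.ones(geno.n_variants, dtype=bool)
    report.log("maf", "snp", (~keep).sum())
    geno = geno.take_variants(np.flatnonzero(keep))
    variants = variants.take(np.flatnonzero(keep))
    var_idx = var_idx[keep]

    if th["hwe_p"] > 0 and geno.n_variants:
        hwe_p = hwe_exact_p_vec(geno)
        keep = hwe_p >= th["hwe_p"]
    else:
        keep = np.ones(geno.n_variants, dtype=bool)
    report.log("hwe", "snp", (~keep).sum())
    geno = geno.take_variants(np.flatnonzero(keep))
    variants = variants.take(np.flatnonzero(keep))
    var_idx = var_idx[keep]
    report.kept_variant_idx = var_idx

    if geno.n_variants == 0:
        raise ValueError("QC removed every SNP")
    return geno, variants, samples, report


def ibd_pihat(geno: GenotypeMatrix, min_informative: int = 50) -> pd.DataFrame:
    """Pairwise method-of-moments IBD sharing (PI_HAT) from IBS counts.

    Estimates P(IBD=0/1/2) per pair from the observed IBS-0/1/2 counts and
    sample allele frequencies; PI_HAT = P(IBD=2) + P(IBD=1)/2, clamped to
    [0, 1].  Pairs with fewer than ``min_informative`` jointly called SNPs
    are flagged unreliable (PI_HAT = NaN).

    Returns a long-format DataFrame (i, j, n_snps, pi_hat, reliable).
    """
    d = geno.dosage
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    p = geno.allele_b_freq()
    ok_snp = ~np.isnan(p)
    d = d[:, ok_snp].astype(np.int16)
    p = p[ok_snp]
    q = 1.0 - p
    # per-SNP expected IBS-class probabilities under each IBD state
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e0_ibs2 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibs1 = 2 * p * q
    e1_ibs2 = p**2 + q**2
    rows = []
    miss = d == -1
    for i in range(n):
        for j in range(i + 1, n):
            use = ~(miss[i] | miss[j])
            m = int(use.sum())
            if m == 0:
                rows.append((i, j, 0, np.nan, False))
                continue
            diff = np.abs(d[i, use] - d[j, use])
            n_ibs0 = int((diff == 2).sum())
            n_ibs1 = int((diff == 1).sum())
            n_ibs2 = m - n_ibs0 - n_ibs1
            s0_ibs0 = e0_ibs0[use].sum()
            p0 = n_ibs0 / s0_ibs0 if s0_ibs0 > 0 else 0.0
            s1 = e1_ibs1[use].sum()
            p1 = (n_ibs1 - p0 * e0_ibs1[use].sum()) / s1 if s1 > 0 else 0.0
            p2 = (n_ibs2 - p0 * e0_ibs2[use].sum() - p1 * e1_ibs2[use].sum()) / m
            p0, p1, p2 = np.clip([p0, p1, p2], 0.0, 1.0)
            tot = p0 + p1 + p2
            if tot > 0:
                p0, p1, p2 = p0 / tot, p1 / tot, p2 / tot
            pi_hat = float(np.clip(p2 + 0.5 * p1, 0.0, 1.0))
            reliable = m >= min_informative
            rows.append((i, j, m, pi_hat if reliable else np.nan, reliable))
    return pd.DataFrame(rows, columns=["i", "j", "n_snps", "pi_hat", "reliable"])


def prune_related(
    pihat: pd.DataFrame,
    n_samples: int,
    threshold: float = 0.18,
    sample_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy relatedness pruning: repeatedly drop the individual involved in
    most pairs with PI_HAT above ``threshold`` until none remain.

    Ties break on sample-ID order (lowest index dropped first).  Returns the
    indices of retained individuals.
    """
    above = pihat[pihat["pi_hat"] > threshold]
    pairs = {(int(r.i), int(r.j)) for r in above.itertuples()}
    removed: set[int] = set()
    while True:
        deg = np.zeros(n_samples, dtype=int)
        for i, j in pairs:
            if i not in removed and j not in removed:
                deg[i] += 1
                deg[j] += 1
        worst = int(deg.max()) if deg.size else 0
        if worst == 0:
            break
        removed.add(int(np.flatnonzero(deg == worst)[0]))
    return np.array([i for i in range(n_samples) if i not in removed])


def ld_decay(
    geno: GenotypeMatrix,
    variants: VariantTable,
    max_dist_bp: int = 1_000_000,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean composite genotype-correlation r² by physical distance bin.

    All intra-chromosome SNP pairs within ``max_dist_bp`` contribute; pairs
    involving a zero-variance SNP are skipped.  Returns a DataFrame with
    bin_start, bin_end, n_pairs, mean_r2.
    """
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    d = geno.dosage.astype(float)
    d[d == -1] = np.nan
    for chrom in variants.chromosomes():
        idx = variants.chrom_slice(chrom)
        if idx.size < 2:
            continue
        pos = variants.pos_bp[idx]
        x = d[:, idx]
        mu = np.nanmean(x, axis=0)
        xc = x - mu
        sd = np.sqrt(np.nanmean(xc**2, axis=0))
        for a in range(idx.size - 1):
            hi = np.searchsorted(pos, pos[a] + max_dist_bp, side="right")
            js = np.arange(a + 1, hi)
            if js.size == 0 or sd[a] == 0:
                continue
            js = js[sd[js] > 0]
            if js.size == 0:
                continue
            both = ~np.isnan(xc[:, a][:, None]) & ~np.isnan(xc[:, js])
            xa = np.where(both, np.nan_to_num(xc[:, a])[:, None], 0.0)
            xb = np.where(both, np.nan_to_num(xc[:, js]), 0.0)
            nn = both.sum(axis=0)
            cov = (xa * xb).sum(axis=0) / np.maximum(nn, 1)
            va = (xa**2).sum(axis=0) / np.maximum(nn, 1)
            vb = (xb**2).sum(axis=0) / np.maximum(nn, 1)
            valid = (nn > 1) & (va > 0) & (vb > 0)
            r2 = np.zeros(js.size)
            r2[valid] = (cov[valid] ** 2) / (va[valid] * vb[valid])
            dist = pos[js] - pos[a]
            b = np.minimum(
                np.searchsorted(edges, dist, side="right") - 1, n_bins - 1
            )
            np.add.at(sums, b[valid], r2[valid])
            np.add.at(counts, b[valid], 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1].astype(np.int64),
            "bin_end": edges[1:].astype(np.int64),
            "n_pairs": counts,
            "mean_r2": mean_r2,
        }
    )
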