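"""Runs of homozygosity (ROH) and extreme-ROH-island (eROHi) selection scan.

ROHs are detected per individual by the consecutive-runs ("windowless")
method: maximal stretches of consecutive homozygous calls, allowing a
configurable number of heterozygous/missing calls, broken at large
inter-SNP gaps, and retained only if they pass length, SNP-count and
density thresholds (defaults tuned for HD SNP-array data: 1 Mb, 15 SNPs,
one SNP per 0.1 Mb, 1 Mb gap, one heterozygote allowed).

The per-SNP ROH incidence (number of individuals whose ROH covers the SNP)
is z-scored within each chromosome and transformed to -log10 of the right
Gaussian tail probability; stretches of consecutive outlier SNPs
(-log10 P >= 4), extended by 100 kb each side, are called eROHi regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import GenotypeMatrix, Region, SampleInfo, VariantTable


@dataclass(frozen=True)
class ROHParams:
    min_length_bp: int = 1_000_000
    min_snps: int = 15
    min_density_snp_per_bp: float = 1.0 / 100_000
    max_gap_bp: int = 1_000_000
    max_het: int = 1
    max_missing_in_run: int = 0

    def __post_init__(self) -> None:
        if min(self.min_length_bp, self.min_snps, self.max_gap_bp) <= 0:
            raise ValueError("length/count/gap parameters must be positive")
        if self.max_het < 0 or self.max_missing_in_run < 0:
            raise ValueError("allowance parameters must be non-negative")


@dataclass
class ROHRun:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int  # homozygous SNPs in the run
    n_het: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def detect_roh(
    dosage_row: np.ndarray,
    pos: np.ndarray,
    params: ROHParams = ROHParams(),
    chrom: str = "1",
    sample_id: str = "NA",
) -> list[ROHRun]:
    """Consecutive-runs ROH detection for one individual on one chromosome.

    A run is a maximal SNP interval whose endpoints are homozygous calls,
    containing at most ``max_het`` heterozygotes and ``max_missing_in_run``
    missing calls, with every inter-SNP gap <= ``max_gap_bp``; it is
    reported iff it has >= ``min_snps`` homozygous SNPs, spans >=
    ``min_length_bp`` and has SNP density >= ``min_density_snp_per_bp``.
    """
    pos = np.asarray(pos, dtype=np.int64)
    d = np.asarray(dosage_row)
    if pos.size != d.size:
        raise ValueError("dosage and position lengths differ")
    if pos.size > 1 and not np.all(np.diff(pos) > 0):
        raise ValueError("positions must be strictly increasing")
    m = pos.size
    if m == 0:
        return []
    is_het = d == 1
    is_miss = d == -1
    is_hom = ~is_het & ~is_miss
    # segment id: breaks where the gap to the previous SNP exceeds max_gap
    seg = np.zeros(m, dtype=np.int64)
    if m > 1:
        seg[1:] = np.cumsum(np.diff(pos) > params.max_gap_bp)
    cum_het = np.concatenate([[0], np.cumsum(is_het)])
    cum_miss = np.concatenate([[0], np.cumsum(is_miss)])

    runs: list[ROHRun] = []
    hom_idx = np.flatnonzero(is_hom)
    prev_best_j = -1
    jptr = 0
    for ii, i in enumerate(hom_idx):
        # furthest hom endpoint j >= i satisfying all window constraints
        if jptr < ii:
            jptr = ii
        while jptr + 1 < hom_idx.size:
            j_next = hom_idx[jptr + 1]
            if (
                seg[j_next] == seg[i]
                and cum_het[j_next + 1] - cum_het[i] <= params.max_het
                and cum_miss[j_next + 1] - cum_miss[i] <= params.max_missing_in_run
            ):
                jptr += 1
            else:
                break
        j = hom_idx[jptr]
        if (
            seg[j] != seg[i]
            or cum_het[j + 1] - cum_het[i] > params.max_het
            or cum_miss[j + 1] - cum_miss[i] > params.max_missing_in_run
        ):
            j = i  # window never expanded validly beyond i itself
        if j <= prev_best_j:
            continue  # contained in the previous maximal run
        prev_best_j = j
        n_hom = int(is_hom[i : j + 1].sum())
        n_het = int(cum_het[j + 1] - cum_het[i])
        length = int(pos[j] - pos[i])
        if (
            n_hom >= params.min_snps
            and length >= params.min_length_bp
            and length > 0
            and n_hom / length >= params.min_density_snp_per_bp
        ):
            runs.append(
                ROHRun(sample_id, chrom, int(pos[i]), int(pos[j]), n_hom, n_het)
            )
    return runs


def detect_roh_all(
    geno: GenotypeMatrix,
    variants: VariantTable,
    samples: SampleInfo,
    params: ROHParams = ROHParams(),
) -> list[ROHRun]:
    runs: list[ROHRun] = []
    for chrom in variants.chromosomes():
        idx = variants.chrom_slice(chrom)
        pos = variants.pos_bp[idx]
        sub = geno.dosage[:, idx]
        for i, sid in enumerate(samples.sample_id):
            runs.extend(detect_roh(sub[i], pos, params, chrom, str(sid)))
    return runs


def runs_to_frame(runs: list[ROHRun]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in runs],
            "chrom": [r.chrom for r in runs],
            "start_bp": [r.start_bp for r in runs],
            "end_bp": [r.end_bp for r in runs],
            "n_snps": [r.n_snps for r in runs],
            "n_het": [r.n_het for r in runs],
            "length_bp": [r.length_bp for r in runs],
        }
    )


def roh_incidence(
    runs: list[ROHRun], variants: VariantTable, n_individuals: int
) -> pd.DataFrame:
    """Per-SNP count of individuals with at least one ROH covering the SNP."""
    count = np.zeros(variants.n_variants, dtype=np.int64)
    by_sample: dict[str, np.ndarray] = {}
    chrom_index = {c: variants.chrom_slice(c) for c in variants.chromosomes()}
    for r in runs:
        idx = chrom_index.get(r.chrom)
        if idx is None:
            continue
        pos = variants.pos_bp[idx]
        lo = np.searchsorted(pos, r.start_bp, side="left")
        hi = np.searchsorted(pos, r.end_bp, side="right")
        cov = by_sample.setdefault(
            r.sample_id, np.zeros(variants.n_variants, dtype=bool)
        )
        cov[idx[lo:hi]] = True
    for cov in by_sample.values():
        count += cov
    if (count > n_individuals).any():
        raise ValueError("incidence exceeds the number of individuals")
    return pd.DataFrame(
        {"chrom": variants.chrom, "pos_bp": variants.pos_bp, "count": count}
    )


def eroi_scores(track: pd.DataFrame) -> pd.DataFrame:
    """Chromosome-normalised incidence: per-chromosome z score and the
    -log10 right Gaussian tail probability of that z."""
    track = track.reset_index(drop=True).copy()
    z = np.zeros(len(track))
    nlp = np.zeros(len(track))
    for chrom, sub in track.groupby("chrom", sort=False):
        c = sub["count"].to_numpy(dtype=float)
        sd = c.std(ddof=0)
        if sd == 0:
            continue  # degenerate chromosome: no outliers, all -log10 P = 0
        zi = (c - c.mean()) / sd
        z[sub.index] = zi
        nlp[sub.index] = -np.log10(np.maximum(norm.sf(zi), 1e-300))
    track["z"] = z
    track["neglog10p"] = nlp
    return track


def call_eroi_regions(
    track: pd.DataFrame,
    threshold: float = 4.0,
    min_consecutive: int = 2,
    extension_bp: int = 100_000,
) -> list[Region]:
    """eROHi regions: >= ``min_consecutive`` adjacent outlier SNPs
    (-log10 P >= threshold), extended by ``extension_bp`` each side."""
    regions: list[Region] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        out = sub["neglog10p"].to_numpy() >= threshold
        i = 0
        while i < out.size:
            if out[i]:
                j = i
                while j + 1 < out.size and out[j + 1]:
                    j += 1
                if j - i + 1 >= min_consecutive:
                    regions.append(
                        Region(
                            str(chrom),
                            max(1, int(pos[i]) - extension_bp),
                            int(pos[j]) + extension_bp,
                            frozenset({"ROHS"}),
                        )
                    )
                i = j + 1
            else:
                i += 1
    return regions


LENGTH_CLASSES = ["1-2", "2-4", "4-8", "8-16", ">16"]


def roh_length_classes(runs: list[ROHRun]) -> dict[str, int]:
    """Class counts by run length in Mb; bins left-closed right-open."""
    edges = np.array([1.0, 2.0, 4.0, 8.0, 16.0, np.inf])
    counts = dict.fromkeys(LENGTH_CLASSES, 0)
    for r in runs:
        mb = r.length_bp / 1e6
        k = int(np.searchsorted(edges, mb, side="right") - 1)
        k = max(0, min(k, len(LENGTH_CLASSES) - 1))
        counts[LENGTH_CLASSES[k]] += 1
    return counts


class RohScan:
    """eROHi selection scan as a model object.

    Parameters are the genotype data; ``fit`` runs detection, incidence
    scoring and region calling and returns a :class:`RohScanResults`.
    """

    def __init__(
        self, geno: GenotypeMatrix, variants: VariantTable, samples: SampleInfo
    ):
        self.geno = geno
        self.variants = variants
        self.samples = samples

    def fit(
        self,
        params: ROHParams = ROHParams(),
        threshold: float = 4.0,
        min_consecutive: int = 2,
        extension_bp: int = 100_000,
    ) -> "RohScanResults":
        runs = detect_roh_all(self.geno, self.variants, self.samples, params)
        track = eroi_scores(
            roh_incidence(runs, self.variants, self.samples.n_samples)
        )
        regions = call_eroi_regions(track, threshold, min_consecutive, extension_bp)
        return RohScanResults(self, params, runs, track, regions, threshold)


class RohScanResults:
    def __init__(self, model, params, runs, track, regions, threshold):
        self.model = model
        self.params = params
        self.runs = runs
        self.track = track
        self.regions = regions
        self.threshold = threshold

    def runs_frame(self) -> pd.DataFrame:
        return runs_to_frame(self.runs)

    def length_classes(self) -> dict[str, int]:
        return roh_length_classes(self.runs)

    def summary(self) -> str:
        cls = self.length_classes()
        lines = [
            "eROHi selection scan",
            "====================",
            f"individuals: {self.model.samples.n_samples}   "
            f"SNPs: {self.model.variants.n_variants}",
            f"ROH runs detected: {len(self.runs)}",
            "length classes (Mb): "
            + ", ".join(f"{k}: {v}" for k, v in cls.items()),
            f"outlier threshold: -log10 P >= {self.threshold}",
            f"eROHi regions: {len(self.regions)}",
        ]
        for r in self.regions:
            lines.append(f"  chr{r.chrom}:{r.start_bp}-{r.end_bp}")
        return "\n".join(lines)
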