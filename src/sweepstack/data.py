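"""Core in-memory containers for SNP-array genotype data.

The package works on dense biallelic SNP data: a variant map, a diploid
genotype matrix (allele-b dosages), optionally a phased haplotype matrix,
and a sample table.  Coordinates are 1-based inclusive base pairs
throughout; BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # missing dosage code in GenotypeMatrix arrays


@dataclass
class VariantTable:
    """Ordered SNP map.

    Parameters
    ----------
    chrom : array of str
        Chromosome label per SNP (autosome codes "1".."26" for sheep).
    pos_bp : array of int
        1-based physical position; strictly increasing within chromosome.
    snp_id : array of str
    allele_a, allele_b : array of single characters
        The two alleles; dosages count copies of allele_b.
    ancestral : array of str
        "A" if allele_a is ancestral, "B" if allele_b is, "." if unknown.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    snp_id: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    ancestral: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        self.ancestral = np.asarray(self.ancestral, dtype=object)
        for chrom in self.chromosomes():
            pos = self.pos_bp[self.chrom == chrom]
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_variants(self) -> int:
        return self.pos_bp.size

    def __len__(self) -> int:
        return self.n_variants

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def take(self, idx: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.chrom[idx],
            self.pos_bp[idx],
            self.snp_id[idx],
            self.allele_a[idx],
            self.allele_b[idx],
            self.ancestral[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "snp_id": self.snp_id,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
                "ancestral": self.ancestral,
            }
        )


@dataclass
class SampleInfo:
    """Sample identifiers plus optional provenance flags (duplicates, relatives)."""

    sample_id: np.ndarray
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if len(set(self.sample_id)) != self.sample_id.size:
            raise ValueError("duplicate sample IDs")

    @property
    def n_samples(self) -> int:
        return self.sample_id.size

    def take(self, idx: np.ndarray) -> "SampleInfo":
        kept = set(np.asarray(self.sample_id)[idx])
        return SampleInfo(
            self.sample_id[idx],
            {k: v for k, v in self.flags.items() if k in kept},
        )


@dataclass
class GenotypeMatrix:
    """samples x variants matrix of allele-b dosages in {0, 1, 2, -1(missing)}."""

    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def allele_b_freq(self) -> np.ndarray:
        """Per-SNP allele-b frequency over non-missing calls (NaN if all missing)."""
        d = self.dosage.astype(float)
        d[d == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_b_freq()
        return np.minimum(f, 1.0 - f)

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[idx])

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[:, idx])


@dataclass
class HaplotypeMatrix:
    """(2*samples) x variants binary matrix; rows (2i, 2i+1) phase sample i.

    Entry 1 is the derived allele when polarity is known (allele coded as
    allele_b / `ancestral == "A"` in the companion VariantTable).
    """

    haps: np.ndarray

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.ndim != 2:
            raise ValueError("haps must be 2-D ((2*samples) x variants)")
        if self.haps.shape[0] % 2:
            raise ValueError("haplotype rows must come in pairs")
        if not np.isin(self.haps, (0, 1)).all():
            raise ValueError("haplotypes must be binary")

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.haps.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.haps.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.haps.sum(axis=0, dtype=np.int64)

    def to_genotypes(self) -> GenotypeMatrix:
        return GenotypeMatrix(self.haps[0::2] + self.haps[1::2])

    def take_variants(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.haps[:, idx])


@dataclass
class Region:
    """A 1-based inclusive chromosome interval with method provenance."""

    chrom: str
    start_bp: int
    end_bp: int
    methods: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"degenerate region {self.chrom}:{self.start_bp}-{self.end_bp}"
            )
        self.methods = frozenset(self.methods)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start_bp": [r.start_bp for r in regions],
            "end_bp": [r.end_bp for r in regions],
            "methods": ["-".join(sorted(r.methods)) for r in regions],
        }
    )


def regions_to_bed(regions: list[Region], path: str) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            name = "-".join(sorted(r.methods)) or "."
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")
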