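"""Readers for standard genotype formats (VCF 4.x, PLINK ped/map and bed/bim/fam).

All readers return the package's common data model: a GenotypeMatrix of
allele-b dosages, a VariantTable with 1-based positions, and a SampleInfo.
``read_vcf`` additionally returns a HaplotypeMatrix when every genotype in
the file is phased ('|' separator) and non-missing.

Conventions: in VCF, allele_a = REF and allele_b = ALT; in .bim, allele_b =
the A1 column (5th) and allele_a = A2; in .ped, alleles are assigned
lexicographically (allele_a = the smaller character), which round-trips the
package's own writers exactly.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
from cyvcf2 import VCF

from .data import GenotypeMatrix, HaplotypeMatrix, SampleInfo, VariantTable


class FormatError(ValueError):
    pass


def read_vcf(path: str):
    """Read a VCF into (GenotypeMatrix, HaplotypeMatrix | None, VariantTable,
    SampleInfo).

    Multiallelic records are skipped (counted in a warning); half-missing
    genotypes are treated as fully missing.  Haplotypes are returned only if
    every genotype is phased and called.
    """
    vcf = VCF(path)
    sample_ids = np.array(vcf.samples, dtype=object)
    n = sample_ids.size
    chroms, poss, ids, ref, alt, anc = [], [], [], [], [], []
    dosage_rows, hap_rows = [], []
    all_phased = True
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        g = np.array(v.genotypes, dtype=np.int64)  # n x 3: a0, a1, phased
        a = g[:, :2]
        miss = (a < 0).any(axis=1)
        dos = a.sum(axis=1).astype(np.int8)
        dos[miss] = -1
        dosage_rows.append(dos)
        if all_phased:
            if miss.any() or not g[:, 2].all():
                all_phased = False
            else:
                hap_rows.append(a.reshape(-1).astype(np.int8))
        chroms.append(v.CHROM)
        poss.append(v.POS)
        ids.append(v.ID if v.ID else f"{v.CHROM}_{v.POS}")
        ref.append(v.REF)
        alt.append(v.ALT[0])
        aa = v.INFO.get("AA")
        if aa == v.REF:
            anc.append("A")
        elif aa == v.ALT[0]:
            anc.append("B")
        else:
            anc.append(".")
    if n_multi:
        warnings.warn(f"skipped {n_multi} multiallelic records in {path}")
    variants = VariantTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(ids, dtype=object),
        np.array(ref, dtype=object),
        np.array(alt, dtype=object),
        np.array(anc, dtype=object),
    )
    geno = GenotypeMatrix(
        np.array(dosage_rows, dtype=np.int8).T
        if dosage_rows
        else np.zeros((n, 0), dtype=np.int8)
    )
    haps = None
    if all_phased and hap_rows:
        haps = HaplotypeMatrix(np.array(hap_rows, dtype=np.int8).T)
    return geno, haps, variants, SampleInfo(sample_ids)


def read_plink(prefix: str):
    """Read PLINK data (.ped/.map or .bed/.bim/.fam) under ``prefix``.

    Returns (GenotypeMatrix, VariantTable, SampleInfo).
    """
    if os.path.exists(prefix + ".bed"):
        return _read_bed_bim_fam(prefix)
    if os.path.exists(prefix + ".ped"):
        return _read_ped_map(prefix)
    raise FileNotFoundError(f"no .bed or .ped found for prefix {prefix}")


def _read_map(path: str):
    chroms, ids, poss = [], [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: expected 4 columns")
            chroms.append(parts[0])
            ids.append(parts[1])
            poss.append(int(parts[3]))
    return chroms, ids, poss


def _read_ped_map(prefix: str):
    chroms, ids, poss = _read_map(prefix + ".map")
    m = len(ids)
    sample_ids, allele_rows = [], []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{prefix}.ped:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(sample_ids), m, 2)
    dosage = np.zeros((len(sample_ids), m), dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        col = alleles[:, j, :]
        obs = sorted({x for x in col.reshape(-1) if x != "0"})
        if len(obs) > 2:
            raise FormatError(f"SNP {ids[j]} has >2 alleles in {prefix}.ped")
        a = obs[0] if obs else "0"
        b = obs[1] if len(obs) > 1 else "."
        allele_a[j], allele_b[j] = a, b
        miss = (col == "0").any(axis=1)
        dosage[:, j] = (col == b).sum(axis=1)
        dosage[miss, j] = -1
    variants = VariantTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(ids, dtype=object),
        allele_a,
        allele_b,
        np.full(m, ".", dtype=object),
    )
    return (
        GenotypeMatrix(dosage),
        variants,
        SampleInfo(np.array(sample_ids, dtype=object)),
    )


def _read_bed_bim_fam(prefix: str):
    chroms, ids, poss, a1, a2 = [], [], [], [], []
    with open(prefix + ".bim") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"{prefix}.bim:{ln}: expected 6 columns")
            chroms.append(parts[0])
            ids.append(parts[1])
            poss.append(int(parts[3]))
            a1.append(parts[4])
            a2.append(parts[5])
    sample_ids = []
    with open(prefix + ".fam") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{prefix}.fam: malformed line")
            sample_ids.append(parts[1])
    n, m = len(sample_ids), len(ids)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != bytes([0x6C, 0x1B, 0x01]):
            raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK)")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if data.size != bytes_per_snp * m:
        raise FormatError(
            f"{prefix}.bed: size mismatch ({data.size} bytes for {n}x{m})"
        )
    data = data.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, individual-fastest within byte
    shifts = np.arange(4) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]  # m x n
    # code -> A1 dosage: 00->2, 10->1, 11->0, 01->missing
    lut = np.array([2, -1, 1, 0], dtype=np.int8)
    dosage = lut[codes].T  # n x m, dosage of A1 = allele_b
    variants = VariantTable(
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.array(ids, dtype=object),
        np.array(a2, dtype=object),
        np.array(a1, dtype=object),
        np.full(m, ".", dtype=object),
    )
    return (
        GenotypeMatrix(dosage),
        variants,
        SampleInfo(np.array(sample_ids, dtype=object)),
    )
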