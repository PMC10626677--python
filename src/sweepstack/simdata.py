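"""Synthetic phased SNP datasets: neutral and hard-sweep Wright–Fisher simulations.

A dataset emulates dense SNP-array data from a single diploid population:
biallelic sites with known ancestral allele, a physical map with roughly
uniform spacing, and optional QC stressors (missingness, duplicated
individuals, parent–child composites).

Neutral standing variation is drawn from the discrete-time Wright–Fisher
model via msprime; a hard sweep is then simulated forward in time from that
standing variation: a single beneficial mutation with additive fitness
(1, 1+s, 1+2s) is introduced on one haplotype and the whole population is
resampled each generation with fitness-weighted multinomial parent choice,
Poisson recombination and Poisson mutation influx, until the sweep allele
reaches the requested frequency.  Trajectories losing the allele are
restarted from the same standing variation (conditioning by resampling).
Chromosomes are simulated independently and concatenated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import msprime
import numpy as np

from .data import GenotypeMatrix, HaplotypeMatrix, SampleInfo, VariantTable

_MAX_SEED = 2**31 - 1


class SweepConditioningError(RuntimeError):
    """Raised when no sweep trajectory reaches the target frequency in budget."""

    def __init__(self, attempts: int):
        self.attempts = attempts
        super().__init__(
            f"sweep conditioning failed after {attempts} trajectory attempts"
        )


@dataclass(frozen=True)
class SimParams:
    """Per-chromosome simulation parameters.

    Attributes
    ----------
    n_diploids : sampled diploid individuals (<= pop_size_N)
    seq_length_bp : chromosome length in bp
    mu : per-bp per-generation mutation rate
    r : per-bp per-generation recombination rate
    pop_size_N : diploid effective population size
    s : selection coefficient per copy of the sweep allele (0 = neutral)
    sweep_pos_bp : 1-based focal position of the beneficial mutation
    target_freq : sweep-allele sample frequency to condition on, in (0, 1]
    seed : RNG seed (also drives msprime)
    chrom : chromosome label for the output map
    """

    n_diploids: int
    seq_length_bp: int
    mu: float
    r: float
    pop_size_N: int
    s: float = 0.0
    sweep_pos_bp: int | None = None
    target_freq: float = 1.0
    seed: int = 1
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_diploids <= 0 or self.pop_size_N <= 0:
            raise ValueError("population sizes must be positive")
        if self.n_diploids > self.pop_size_N:
            raise ValueError("n_diploids must not exceed pop_size_N")
        if self.seq_length_bp <= 0:
            raise ValueError("seq_length_bp must be positive")
        if self.mu <= 0 or self.r < 0:
            raise ValueError("rates must be positive (mu) / non-negative (r)")
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0.0 < self.target_freq <= 1.0:
            raise ValueError("target_freq must be in (0, 1]")


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    chrom: str
    sweep_pos_bp: int | None
    s: float
    realized_freq: float
    derived_counts: np.ndarray
    n_attempts: int = 0

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tsweep_pos_bp\ts\trealized_freq\n")
            pos = self.sweep_pos_bp if self.sweep_pos_bp is not None else "NA"
            fh.write(f"{self.chrom}\t{pos}\t{self.s}\t{self.realized_freq:.6g}\n")


def _msprime_population(
    n_diploids: int, params: SimParams, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled WF-equilibrium haplotypes -> ((2n x S) int8, 1-based positions)."""
    ts = msprime.sim_ancestry(
        samples=n_diploids,
        population_size=params.pop_size_N,
        sequence_length=params.seq_length_bp,
        recombination_rate=params.r,
        model="dtwf",
        ploidy=2,
        random_seed=1 + seed % _MAX_SEED,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=params.mu,
        model=msprime.BinaryMutationModel(),
        random_seed=1 + (seed + 7) % _MAX_SEED,
    )
    geno = mts.genotype_matrix()  # sites x haplotypes, 0 = ancestral
    pos = mts.sites_position.astype(np.int64) + 1  # 1-based
    haps = np.ascontiguousarray(geno.T, dtype=np.int8)
    return haps, pos


def _segregating(haps: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = haps.sum(axis=0)
    keep = (counts > 0) & (counts < haps.shape[0])
    return haps[:, keep], pos[keep]


def _variant_table(params: SimParams, pos: np.ndarray) -> VariantTable:
    n = pos.size
    return VariantTable(
        chrom=np.full(n, params.chrom, dtype=object),
        pos_bp=pos,
        snp_id=np.array([f"snp{params.chrom}_{p}" for p in pos], dtype=object),
        allele_a=np.full(n, "A", dtype=object),
        allele_b=np.full(n, "C", dtype=object),
        ancestral=np.full(n, "A", dtype=object),  # allele_a ancestral by construction
    )


def _sample_info(n: int, prefix: str = "IND") -> SampleInfo:
    return SampleInfo(np.array([f"{prefix}{i:04d}" for i in range(n)], dtype=object))


def simulate_neutral(
    params: SimParams,
) -> tuple[HaplotypeMatrix, VariantTable, SimTruth]:
    """Simulate a neutral phased sample of ``n_diploids`` individuals.

    Returns binary phased haplotypes (rows 2i, 2i+1 belong to sample i),
    a strictly increasing 1-based map, and a SimTruth with no sweep.
    Deterministic given the seed.
    """
    if params.s != 0.0:
        raise ValueError("simulate_neutral requires s == 0")
    haps, pos = _msprime_population(params.n_diploids, params, params.seed)
    haps, pos = _segregating(haps, pos)
    truth = SimTruth(
        chrom=params.chrom,
        sweep_pos_bp=None,
        s=0.0,
        realized_freq=float("nan"),
        derived_counts=haps.sum(axis=0),
    )
    return HaplotypeMatrix(haps), _variant_table(params, pos), truth


def _forward_sweep_phase(
    pop: np.ndarray,
    pos: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
    max_attempts: int,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Run the selective phase forward in time over the whole population.

    ``pop`` is the (2N x S) standing-variation matrix.  Returns the evolved
    population, updated positions (mutation influx adds sites), the column
    index of the sweep site, and the number of trajectory attempts used.
    """
    two_n = pop.shape[0]
    n_dip = two_n // 2
    L = params.seq_length_bp
    sweep_pos = params.sweep_pos_bp
    if sweep_pos is None:
        raise ValueError("sweep_pos_bp is required when s > 0")
    if not 1 <= sweep_pos <= L:
        raise ValueError("sweep_pos_bp outside the simulated sequence")

    # append the (initially empty) sweep column; column order is free during
    # the forward phase and restored by a final argsort on position.
    # Nudge by 1 bp if the focal position collides with a standing variant.
    while sweep_pos in pos:
        sweep_pos += 1
        if sweep_pos > L:
            raise ValueError("no free position for the sweep site")
    base_pos = np.concatenate([pos, [sweep_pos]])
    base_pop = np.concatenate(
        [pop, np.zeros((two_n, 1), dtype=pop.dtype)], axis=1
    )
    ins = base_pos.size - 1

    mut_rate_pop = two_n * params.mu * L
    rec_rate = params.r * L
    max_gens = 200 * params.pop_size_N  # loss/absorption guard

    for attempt in range(1, max_attempts + 1):
        cur = base_pop.copy()
        cur_pos = base_pos.copy()
        sweep_idx = ins
        cur[rng.integers(two_n), sweep_idx] = 1
        gen_count = 0
        for _ in range(max_gens):
            dosage = cur[0::2, sweep_idx].astype(np.float64) + cur[1::2, sweep_idx]
            w = 1.0 + params.s * dosage
            parents = rng.choice(n_dip, size=two_n, p=w / w.sum())
            n_cross = rng.poisson(rec_rate, size=two_n)
            which = rng.integers(2, size=two_n)
            child = cur[2 * parents + which]
            single = np.flatnonzero(n_cross == 1)
            if single.size:
                # bulk path: one crossover -> sites left of the breakpoint
                # from one parental haplotype, the rest from the other
                bps = rng.integers(1, params.seq_length_bp + 1, size=single.size)
                other = cur[2 * parents[single] + 1 - which[single]]
                mask = cur_pos[None, :] >= bps[:, None]
                child[single] = np.where(mask, other, child[single])
            multi = np.flatnonzero(n_cross > 1)
            for k in multi:
                p0 = cur[2 * parents[k] + which[k]]
                p1 = cur[2 * parents[k] + 1 - which[k]]
                bps = np.sort(rng.integers(1, params.seq_length_bp + 1,
                                           size=n_cross[k]))
                seg = np.searchsorted(bps, cur_pos, side="left") % 2
                child[k] = np.where(seg == 0, p0, p1)
            cur = np.ascontiguousarray(child)
            # batched mutation influx: new columns appended at the end
            n_new = rng.poisson(mut_rate_pop)
            if n_new:
                mp = np.unique(rng.integers(1, L + 1, size=n_new))
                mp = mp[~np.isin(mp, cur_pos)]
                if mp.size:
                    block = np.zeros((two_n, mp.size), dtype=cur.dtype)
                    block[rng.integers(two_n, size=mp.size),
                          np.arange(mp.size)] = 1
                    cur = np.concatenate([cur, block], axis=1)
                    cur_pos = np.concatenate([cur_pos, mp])
            gen_count += 1
            if gen_count % 20 == 0:
                # purge sites fixed or lost in the population
                col_sum = cur.sum(axis=0, dtype=np.int64)
                keep = (col_sum > 0) & (col_sum < two_n)
                keep[sweep_idx] = True
                if not keep.all():
                    sweep_idx -= int((~keep[:sweep_idx]).sum())
                    cur = np.ascontiguousarray(cur[:, keep])
                    cur_pos = cur_pos[keep]
            freq = cur[:, sweep_idx].mean()
            if freq == 0.0:
                break  # lost: next attempt
            if freq >= params.target_freq:
                order = np.argsort(cur_pos)
                return (
                    np.ascontiguousarray(cur[:, order]),
                    cur_pos[order],
                    int(np.flatnonzero(order == sweep_idx)[0]),
                    attempt,
                )
    raise SweepConditioningError(max_attempts)


def simulate_sweep(
    params: SimParams, max_attempts: int = 10_000
) -> tuple[HaplotypeMatrix, VariantTable, SimTruth]:
    """Simulate a hard selective sweep at ``sweep_pos_bp``.

    The whole population (pop_size_N diploids) is drawn at Wright–Fisher
    equilibrium, the beneficial allele is introduced on one haplotype and
    evolved forward with selection until its population frequency reaches
    ``target_freq``; ``n_diploids`` individuals are then sampled.  The
    trajectory (and, if needed, the sample draw) is repeated until the
    sampled sweep-allele frequency is within 0.05 of the target.
    """
    if params.s <= 0:
        raise ValueError("simulate_sweep requires s > 0")
    rng = np.random.default_rng(params.seed)
    pop, pos = _msprime_population(params.pop_size_N, params, params.seed + 13)

    attempts_used = 0
    while attempts_used < max_attempts:
        evolved, evo_pos, sweep_idx, used = _forward_sweep_phase(
            pop, pos, params, rng, max_attempts - attempts_used
        )
        attempts_used += used
        # sample individuals; re-draw if hypergeometric noise misses the target
        for _ in range(100):
            ind = rng.choice(params.pop_size_N, size=params.n_diploids, replace=False)
            rows = np.sort(np.concatenate([2 * ind, 2 * ind + 1]))
            sample = evolved[rows]
            realized = float(sample[:, sweep_idx].mean())
            if abs(realized - params.target_freq) <= 0.05:
                keep_counts = sample.sum(axis=0)
                keep = (keep_counts > 0) & (keep_counts < sample.shape[0])
                haps = sample[:, keep]
                out_pos = evo_pos[keep]
                truth = SimTruth(
                    chrom=params.chrom,
                    sweep_pos_bp=params.sweep_pos_bp,
                    s=params.s,
                    realized_freq=realized,
                    derived_counts=haps.sum(axis=0),
                    n_attempts=attempts_used,
                )
                return HaplotypeMatrix(haps), _variant_table(params, out_pos), truth
    raise SweepConditioningError(attempts_used)


def simulate_genome(
    base: SimParams,
    n_chromosomes: int,
    sweep_chroms: tuple[str, ...] = (),
) -> tuple[HaplotypeMatrix, VariantTable, list[SimTruth]]:
    """Concatenate independent per-chromosome simulations into one dataset.

    Chromosome labels are "1".."n"; chromosomes named in ``sweep_chroms``
    carry a hard sweep with the base parameters, the rest are neutral.
    """
    haps_parts, var_parts, truths = [], [], []
    for i in range(n_chromosomes):
        label = str(i + 1)
        p = dataclasses.replace(
            base,
            chrom=label,
            seed=(base.seed + 1009 * (i + 1)) % _MAX_SEED,
            s=base.s if label in sweep_chroms else 0.0,
            sweep_pos_bp=base.sweep_pos_bp if label in sweep_chroms else None,
        )
        if label in sweep_chroms:
            h, v, t = simulate_sweep(p)
        else:
            h, v, t = simulate_neutral(p)
        haps_parts.append(h.haps)
        var_parts.append(v)
        truths.append(t)
    haps = np.concatenate(haps_parts, axis=1)
    variants = VariantTable(
        np.concatenate([v.chrom for v in var_parts]),
        np.concatenate([v.pos_bp for v in var_parts]),
        np.concatenate([v.snp_id for v in var_parts]),
        np.concatenate([v.allele_a for v in var_parts]),
        np.concatenate([v.allele_b for v in var_parts]),
        np.concatenate([v.ancestral for v in var_parts]),
    )
    return HaplotypeMatrix(haps), variants, truths


def scaled_study_params(
    seed: int,
    s: float = 0.0,
    sweep_pos_bp: int | None = None,
    target_freq: float = 1.0,
    chrom: str = "1",
) -> SimParams:
    """Desk-scale standard conditions for scan experiments.

    A 2 Mb chromosome sampled in 50 diploids from a population of N = 800,
    with mutation and recombination rates scaled up (mu = 1e-7, r = 2.5e-7
    per bp per generation) so that per-bp diversity (4N*mu) and linkage
    (4N*r) match a large livestock population studied with a dense SNP
    array, while keeping simulation cost desk-scale.  Under these rates a
    complete s = 0.1 sweep leaves a footprint of roughly 100 kb
    (s / (r * ln 2Ns)) — well inside the chromosome and resolvable against
    the 2 Mb of flanking variation.
    """
    return SimParams(
        n_diploids=50,
        seq_length_bp=2_000_000,
        mu=1e-7,
        r=2.5e-7,
        pop_size_N=800,
        s=s,
        sweep_pos_bp=sweep_pos_bp,
        target_freq=target_freq,
        seed=seed,
        chrom=chrom,
    )


def degrade(
    geno: GenotypeMatrix,
    samples: SampleInfo,
    missing_rate: float = 0.0,
    n_duplicates: int = 0,
    n_parent_child: int = 0,
    seed: int = 1,
) -> tuple[GenotypeMatrix, SampleInfo]:
    """Add QC stressors: random missingness, duplicated individuals and
    Mendelian parent–child composites (appended with flagged IDs)."""
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    dosage = geno.dosage.copy()
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = -1

    ids = list(samples.sample_id)
    flags = dict(samples.flags)
    freq = GenotypeMatrix(dosage).allele_b_freq()
    freq = np.where(np.isnan(freq), 0.5, freq)
    extra = []
    n0 = dosage.shape[0]
    for i in range(n_duplicates):
        src = int(rng.integers(n0))
        extra.append(dosage[src].copy())
        new_id = f"DUP{i:02d}_{ids[src]}"
        ids.append(new_id)
        flags[new_id] = f"duplicate_of:{ids[src]}"
    for i in range(n_parent_child):
        pa, pb = rng.choice(n0, size=2, replace=False)
        child = _mendelian_child(dosage[pa], dosage[pb], freq, rng)
        new_id = f"CHILD{i:02d}_{ids[pa]}_{ids[pb]}"
        ids.append(new_id)
        flags[new_id] = f"child_of:{ids[pa]},{ids[pb]}"
        extra.append(child)
    if extra:
        dosage = np.vstack([dosage, np.array(extra, dtype=np.int8)])
    return GenotypeMatrix(dosage), SampleInfo(np.array(ids, dtype=object), flags)


def _mendelian_child(
    pa: np.ndarray, pb: np.ndarray, freq: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One transmitted allele from each parent (frequency draw if missing)."""

    def transmit(par: np.ndarray) -> np.ndarray:
        allele = np.where(par == 2, 1, 0).astype(np.int8)
        het = par == 1
        allele[het] = rng.integers(2, size=int(het.sum()))
        miss = par == -1
        allele[miss] = (rng.random(int(miss.sum())) < freq[miss]).astype(np.int8)
        return allele

    return (transmit(pa) + transmit(pb)).astype(np.int8)


# ---------------------------------------------------------------------------
# writers

def write_dataset(
    variants: VariantTable,
    samples: SampleInfo,
    out_prefix: str,
    haps: HaplotypeMatrix | None = None,
    geno: GenotypeMatrix | None = None,
    formats: tuple[str, ...] = ("vcf", "ped"),
    truths: list[SimTruth] | None = None,
) -> list[str]:
    """Write a dataset as VCF 4.2 (phased GT + AA tag) and/or PLINK files.

    Round-trips losslessly through the package's readers.  Returns the list
    of files written.
    """
    if haps is None and geno is None:
        raise ValueError("need haplotypes or genotypes")
    if geno is None:
        geno = haps.to_genotypes()
    written = []
    if "vcf" in formats:
        path = f"{out_prefix}.vcf"
        _write_vcf(path, variants, samples, haps, geno)
        written.append(path)
    if "ped" in formats:
        written += _write_ped_map(out_prefix, variants, samples, geno)
    if "bed" in formats:
        written += _write_bed_bim_fam(out_prefix, variants, samples, geno)
    if truths:
        path = f"{out_prefix}.truth.tsv"
        with open(path, "w") as fh:
            fh.write("chrom\tsweep_pos_bp\ts\trealized_freq\n")
            for t in truths:
                pos = t.sweep_pos_bp if t.sweep_pos_bp is not None else "NA"
                fh.write(f"{t.chrom}\t{pos}\t{t.s}\t{t.realized_freq:.6g}\n")
        written.append(path)
    return written


def _write_vcf(path, variants, samples, haps, geno) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepstack-simdata\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in variants.chromosomes():
            length = int(variants.pos_bp[variants.chrom == chrom].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples.sample_id)
            + "\n"
        )
        for j in range(variants.n_variants):
            aa_code = variants.ancestral[j]
            aa = (
                variants.allele_a[j]
                if aa_code == "A"
                else variants.allele_b[j] if aa_code == "B" else "."
            )
            if haps is not None:
                gts = "\t".join(
                    f"{haps.haps[2 * i, j]}|{haps.haps[2 * i + 1, j]}"
                    for i in range(samples.n_samples)
                )
            else:
                codes = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
                gts = "\t".join(codes[int(g)] for g in geno.dosage[:, j])
            fh.write(
                f"{variants.chrom[j]}\t{variants.pos_bp[j]}\t{variants.snp_id[j]}\t"
                f"{variants.allele_a[j]}\t{variants.allele_b[j]}\t.\tPASS\t"
                f"AA={aa}\tGT\t{gts}\n"
            )


def _write_ped_map(prefix, variants, samples, geno) -> list[str]:
    map_path, ped_path = f"{prefix}.map", f"{prefix}.ped"
    with open(map_path, "w") as fh:
        for j in range(variants.n_variants):
            fh.write(
                f"{variants.chrom[j]}\t{variants.snp_id[j]}\t0\t{variants.pos_bp[j]}\n"
            )
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(samples.sample_id):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(variants.n_variants):
                a, b = variants.allele_a[j], variants.allele_b[j]
                g = int(geno.dosage[i, j])
                pair = {0: (a, a), 1: (a, b), 2: (b, b), -1: ("0", "0")}[g]
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")
    return [ped_path, map_path]


def _write_bed_bim_fam(prefix, variants, samples, geno) -> list[str]:
    """SNP-major PLINK .bed with .bim/.fam sidecars (for reader tests)."""
    bim_path, fam_path, bed_path = f"{prefix}.bim", f"{prefix}.fam", f"{prefix}.bed"
    with open(bim_path, "w") as fh:
        for j in range(variants.n_variants):
            # .bim A1 = minor-ish allele: keep allele_b as A1, allele_a as A2
            fh.write(
                f"{variants.chrom[j]}\t{variants.snp_id[j]}\t0\t"
                f"{variants.pos_bp[j]}\t{variants.allele_b[j]}\t{variants.allele_a[j]}\n"
            )
    with open(fam_path, "w") as fh:
        for sid in samples.sample_id:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    n = samples.n_samples
    # 2-bit codes per individual, A1-dosage: 00=2, 10=1, 11=0, 01=missing
    code = {2: 0b00, 1: 0b10, 0: 0b11, -1: 0b01}
    with open(bed_path, "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        for j in range(variants.n_variants):
            row = bytearray((n + 3) // 4)
            for i in range(n):
                c = code[int(geno.dosage[i, j])]
                row[i // 4] |= c << (2 * (i % 4))
            fh.write(bytes(row))
    return [bed_path, bim_path, fam_path]
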