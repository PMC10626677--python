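"""Reproducible simulation experiments exercising the full scan stack.

These functions define the package's standard validation experiments at the
desk-scale study conditions of :func:`sweepstack.simdata.scaled_study_params`:
a genome of four 2 Mb chromosomes sampled in 50 diploids, with (optionally)
one complete hard sweep (s = 0.1) at the middle of chromosome 1 and the
remaining chromosomes neutral, so the empirical background spectrum is
dominated by neutral variation as in a genome-wide scan.

They are used by the test suite and by ``scripts/acceptance.py``; all
randomness flows from the caller's seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import fisher_exact, kstest

from .clrscan import ClrScan
from .consensus import build_consensus
from .data import HaplotypeMatrix, Region, VariantTable
from .haplostats import HaplotypeScan
from .rohscan import ROHParams, RohScan
from .simdata import SampleInfo, scaled_study_params, simulate_genome

SWEEP_POS = 1_000_000
N_CHROM = 4

# scan settings scaled to the 2 Mb-per-chromosome genomes: ROH length/gap/
# density thresholds shrink with the ~10-20x compression of the simulated
# map relative to an HD array genome (1 Mb -> 50 kb minimum run, 1 Mb ->
# 100 kb gap, one SNP per 10 kb); statistical thresholds stay at the
# standard values (outlier -log10 P >= 4, 0.5 Mb windows with >= 3 hits)
SCALED_ROH = ROHParams(
    min_length_bp=50_000, min_snps=15, min_density_snp_per_bp=1e-4,
    max_gap_bp=100_000, max_het=1,
)
CLR_GRID = 250
CLR_TOP_FRACTION = 0.005


def sweep_genome(seed: int, s: float = 0.1, target_freq: float = 1.0):
    base = scaled_study_params(seed, s=s, sweep_pos_bp=SWEEP_POS,
                               target_freq=target_freq)
    return simulate_genome(base, N_CHROM, sweep_chroms=("1",))


def neutral_genome(seed: int):
    base = scaled_study_params(seed)
    return simulate_genome(base, N_CHROM)


def clr_argmax(haps: HaplotypeMatrix, variants: VariantTable):
    """(chrom, position) of the genome-wide CLR maximum."""
    res = ClrScan(variants, haps=haps).fit(
        grid_size=CLR_GRID, top_fraction=CLR_TOP_FRACTION
    )
    chrom, pos, _ = res.argmax()
    return chrom, pos, res


def clr_recovery_experiment(n_rep: int = 30, seed: int = 1) -> dict:
    """Fraction of sweep replicates whose genome-wide CLR argmax falls
    within 200 kb of the true sweep site."""
    hits = 0
    for rep in range(n_rep):
        haps, variants, _ = sweep_genome(seed + 211 * rep)
        chrom, pos, _ = clr_argmax(haps, variants)
        if chrom == "1" and abs(pos - SWEEP_POS) <= 200_000:
            hits += 1
    return {"hit_rate": hits / n_rep, "hits": hits, "n": n_rep}


def scan_regions(haps: HaplotypeMatrix, variants: VariantTable) -> list[Region]:
    """Regions from all four methods on one simulated genome."""
    geno = haps.to_genotypes()
    samples = SampleInfo(
        np.array([f"S{i:03d}" for i in range(geno.n_samples)], dtype=object)
    )
    regions: list[Region] = []
    roh = RohScan(geno, variants, samples).fit(SCALED_ROH)
    regions += roh.regions
    for stat in ("ihs", "nsl"):
        res = HaplotypeScan(haps, variants, stat).fit()
        regions += res.regions
    clr = ClrScan(variants, haps=haps).fit(
        grid_size=CLR_GRID, top_fraction=CLR_TOP_FRACTION
    )
    regions += clr.regions
    return regions


def consensus_hits_sweep(haps, variants, min_methods: int = 2) -> bool:
    cons = build_consensus(scan_regions(haps, variants), min_methods)
    return any(
        r.chrom == "1" and r.start_bp <= SWEEP_POS <= r.end_bp for r in cons
    )


def consensus_power_experiment(
    n_sweep: int = 15, n_neutral: int = 15, seed: int = 1
) -> dict:
    """Overlap of >=2-method consensus regions with the sweep site, on sweep
    vs matched neutral genomes, with a one-sided Fisher exact comparison."""
    sweep_hits = sum(
        consensus_hits_sweep(*sweep_genome(seed + 307 * rep)[:2])
        for rep in range(n_sweep)
    )
    neutral_hits = sum(
        consensus_hits_sweep(*neutral_genome(seed + 509 * rep)[:2])
        for rep in range(n_neutral)
    )
    table = [
        [sweep_hits, n_sweep - sweep_hits],
        [neutral_hits, n_neutral - neutral_hits],
    ]
    p = fisher_exact(table, alternative="greater")[1]
    return {
        "sweep_hit_rate": sweep_hits / n_sweep,
        "neutral_hit_rate": neutral_hits / n_neutral,
        "p_value": float(p),
        "n_sweep": n_sweep,
        "n_neutral": n_neutral,
    }


def haplo_calibration_experiment(seed: int = 1) -> dict:
    """KS distance of standardized iHS/nSL from N(0,1) on one large neutral
    chromosome (~10,000 scored SNPs)."""
    from .simdata import simulate_neutral

    big = dataclasses.replace(scaled_study_params(seed),
                              seq_length_bp=20_000_000, mu=5e-8, r=1e-7)
    haps, variants, _ = simulate_neutral(big)
    out = {"n_snps": int(variants.n_variants)}
    for stat in ("ihs", "nsl"):
        res = HaplotypeScan(haps, variants, stat).fit()
        z = res.track["std"].dropna().to_numpy()
        out[f"ks_{stat}"] = float(kstest(z, "norm").statistic)
        out[f"n_scored_{stat}"] = int(z.size)
    return out


def eroi_null_calibration(n_rep: int = 20, seed: int = 1) -> dict:
    """Fraction of SNPs called eROHi outliers (-log10 P >= 4) on neutral
    single-chromosome replicates."""
    n_out = 0
    n_tot = 0
    for rep in range(n_rep):
        params = scaled_study_params(seed + 97 * rep)
        from .simdata import simulate_neutral

        haps, variants, _ = simulate_neutral(params)
        geno = haps.to_genotypes()
        samples = SampleInfo(
            np.array([f"S{i:03d}" for i in range(geno.n_samples)], dtype=object)
        )
        res = RohScan(geno, variants, samples).fit(SCALED_ROH)
        n_out += int((res.track["neglog10p"] >= 4.0).sum())
        n_tot += int(len(res.track))
    return {"outlier_fraction": n_out / n_tot, "n_snps": n_tot}


def clr_null_vs_sweep_experiment(seed: int = 1, n_null: int = 5) -> dict:
    """Genome-wide mean Lambda on neutral genomes vs the Lambda at the focal
    site of a sweep genome."""
    null_means = []
    for rep in range(n_null):
        haps, variants, _ = neutral_genome(seed + 13 * rep)
        res = ClrScan(variants, haps=haps).fit(
            grid_size=CLR_GRID, top_fraction=CLR_TOP_FRACTION
        )
        null_means.append(
            float(np.mean(np.concatenate([g.lam for g in res.grids])))
        )
    haps, variants, _ = sweep_genome(seed + 811)
    _, _, res = clr_argmax(haps, variants)
    g1 = [g for g in res.grids if g.chrom == "1"][0]
    near = np.abs(g1.grid_pos - SWEEP_POS) <= 200_000
    return {
        "null_mean_lambda": float(np.mean(null_means)),
        "sweep_site_lambda": float(g1.lam[near].max()),
    }
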