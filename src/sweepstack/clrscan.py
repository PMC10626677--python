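"""Composite likelihood ratio (CLR) sweep scan, SweepFinder-style.

The null model is the genome-wide empirical site frequency spectrum (SFS).
Under a sweep at distance d with strength alpha, each of the n sampled
lineages escapes the sweep with probability p_e = 1 - exp(-alpha * d)
independently; the lineages that fail to escape coalesce onto the single
sweeping haplotype, whose own allelic state is that of one extra lineage
drawn from the pre-sweep population.  Conditional on k escapees, the
pre-sweep sample of k + 1 lineages is a hypergeometric subsample of the
background spectrum; the post-sweep derived count is the escapees' count
plus n - k if the swept lineage carried the derived allele.  Non-segregating
outcomes are dropped and the spectrum renormalized, since only SNPs are
modelled (array data).

For every position on an evenly spaced per-chromosome grid, the composite
log likelihood of the observed allele counts is maximized over a grid of
alpha values; Lambda = 2 * (max log L1 - log L0), clamped at zero (the null
is nested via the full-escape limit).  The genome-wide significance
threshold is the empirical top-fraction quantile of all grid values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .data import HaplotypeMatrix, Region, VariantTable

FULL_ESCAPE = np.inf  # sentinel alpha: p_e = 1, model reduces to the null


def default_alpha_grid(n_values: int = 40) -> np.ndarray:
    """Log-spaced sweep strengths covering footprints from ~35 kb to ~10 Mb,
    plus the full-escape sentinel that nests the null model.

    The upper bound deliberately excludes footprints below the scale of a
    few dozen SNPs: stronger alphas let the model lock onto chance clusters
    of two or three extreme-frequency SNPs at essentially zero distance,
    producing sub-grid spikes of spurious likelihood.  Sweeps narrower than
    the local SNP spacing are not resolvable on array-density data anyway.
    """
    return np.concatenate([np.geomspace(1e-7, 2e-5, n_values), [FULL_ESCAPE]])


@dataclass
class SFS:
    """Site frequency spectrum of a sample of ``n`` haplotypes.

    ``p`` holds probabilities indexed by derived (or minor, if folded)
    count; entries outside the segregating range are zero.
    """

    n: int
    p: np.ndarray  # length n + 1, indexed by count
    folded: bool

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size != self.n + 1:
            raise ValueError("spectrum must have n + 1 entries")
        if (self.p < 0).any() or not np.isclose(self.p.sum(), 1.0):
            raise ValueError("spectrum must be a probability distribution")


def empirical_sfs(counts: np.ndarray, n: int, folded: bool = False) -> SFS:
    """Normalized histogram of derived (or minor) allele counts.

    ``counts`` are per-SNP derived counts in 1..n-1; with ``folded`` they
    are replaced by min(count, n - count).
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("no segregating sites")
    if ((counts <= 0) | (counts >= n)).any():
        raise ValueError("counts must be segregating (1..n-1)")
    if folded:
        counts = np.minimum(counts, n - counts)
    hist = np.bincount(counts, minlength=n + 1).astype(float)
    return SFS(n, hist / hist.sum(), folded)


def _unfolded_background(background: SFS) -> np.ndarray:
    """Background probabilities by derived count 0..n; folded spectra are
    unfolded symmetrically (mass split equally between j and n - j)."""
    n = background.n
    if not background.folded:
        return background.p.copy()
    p = np.zeros(n + 1)
    for j in range(1, n // 2 + 1):
        if j == n - j:
            p[j] = background.p[j]
        else:
            p[j] += background.p[j] / 2
            p[n - j] += background.p[j] / 2
    return p / p.sum()


def sweep_spectrum(background: SFS, alpha: float, d_bp: float) -> np.ndarray:
    """Probability of each segregating derived count at distance ``d_bp``
    from a sweep of strength ``alpha``, given the background spectrum.

    Returns a length n+1 vector over counts 0..n with zero mass outside
    1..n-1 (renormalized over segregating outcomes).  Folded backgrounds
    give a folded (minor-count) output.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if d_bp < 0:
        raise ValueError("distance must be non-negative")
    p_e = 1.0 if np.isinf(alpha) else -np.expm1(-alpha * d_bp)
    out = _sweep_spectrum_table(background, np.array([p_e]))[0]
    return out


def _escape_mixture(background: SFS) -> np.ndarray:
    """F[k, b]: P(derived count b | exactly k of n lineages escaped)."""
    n = background.n
    pb = _unfolded_background(background)
    f = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        if k == n:
            f[n] = pb
            continue
        t = k + 1  # escapees plus the swept lineage's ancestor
        # hypergeometric downsampling of the background to t lineages
        q = np.zeros(t + 1)
        for big_j in range(n + 1):
            if pb[big_j] == 0:
                continue
            m = np.arange(0, t + 1)
            q += pb[big_j] * hypergeom.pmf(m, n, big_j, t)
        for m in range(t + 1):
            if q[m] == 0:
                continue
            pr_rep_derived = m / t
            b_derived = m - 1 + (n - k)
            b_ancestral = m
            f[k, b_derived] += q[m] * pr_rep_derived
            f[k, b_ancestral] += q[m] * (1 - pr_rep_derived)
    return f


def _sweep_spectrum_table(background: SFS, p_e_values: np.ndarray) -> np.ndarray:
    """Rows of sweep spectra (counts 0..n) for each escape probability."""
    n = background.n
    f = _escape_mixture(background)
    k = np.arange(n + 1)
    w = binom.pmf(k[None, :], n, np.clip(p_e_values, 0.0, 1.0)[:, None])
    spec = w @ f  # (n_pe, n+1) over derived counts
    if background.folded:
        folded = np.zeros_like(spec)
        for j in range(1, n // 2 + 1):
            folded[:, j] = spec[:, j] + (spec[:, n - j] if j != n - j else 0.0)
        spec = folded
    spec[:, 0] = 0.0
    spec[:, n] = 0.0
    row_sums = spec.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return spec / row_sums


@dataclass
class CLRGrid:
    chrom: str
    grid_pos: np.ndarray
    lam: np.ndarray
    alpha_hat: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "grid_pos": self.grid_pos.astype(np.int64),
                "clr": self.lam,
                "alpha_hat": self.alpha_hat,
            }
        )


def clr_scan(
    variants: VariantTable,
    counts: np.ndarray,
    background: SFS,
    grid_size: int = 10_000,
    alpha_grid: np.ndarray | None = None,
    lr_factor: float = 2.0,
    n_pe_bins: int = 400,
) -> list[CLRGrid]:
    """Composite likelihood ratio scan on an evenly spaced grid per chromosome.

    ``counts`` are per-SNP derived counts (minor counts when the background
    is folded).  For each grid position, Lambda = lr_factor * (max over the
    alpha grid of the sweep composite log likelihood minus the background
    log likelihood), clamped at zero; ``alpha_hat`` is the maximizer.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    counts = np.asarray(counts, dtype=np.int64)
    n = background.n
    if background.folded:
        counts = np.minimum(counts, n - counts)
    # precompute spectra on a lattice of x = alpha * d, log-spaced so the
    # near-sweep regime (small escape probability) is finely resolved
    x_lattice = np.concatenate([[0.0], np.geomspace(1e-6, 50.0, n_pe_bins - 2),
                                [np.inf]])
    with np.errstate(over="ignore"):
        pe_lattice = -np.expm1(-x_lattice)
    log_x = np.log(x_lattice[1:-1])
    with np.errstate(divide="ignore"):
        log_table = np.log(_sweep_spectrum_table(background, pe_lattice))
        log_null = np.log(background.p)
    results = []
    for chrom in variants.chromosomes():
        idx = variants.chrom_slice(chrom)
        if idx.size == 0:
            continue
        pos = variants.pos_bp[idx].astype(float)
        b = counts[idx]
        ll0 = log_null[b].sum()
        grid = np.linspace(pos.min(), pos.max(), grid_size)
        lam = np.zeros(grid_size)
        ahat = np.zeros(grid_size)
        log_by_alpha = log_table[:, b]  # lattice x SNPs, gathered at counts
        snp_ix = np.arange(b.size)
        for gi, g in enumerate(grid):
            d = np.abs(pos - g)
            best = -np.inf
            best_a = alpha_grid[0]
            for a in alpha_grid:
                if np.isinf(a):
                    bins = np.full(b.size, n_pe_bins - 1, dtype=np.int64)
                else:
                    with np.errstate(divide="ignore"):
                        lx = np.log(np.maximum(a * d, 1e-300))
                    bins = np.clip(
                        np.searchsorted(log_x, lx) + 1, 0, n_pe_bins - 1
                    )
                    bins[a * d < 1e-6] = 0
                ll1 = log_by_alpha[bins, snp_ix].sum()
                if ll1 > best:
                    best = ll1
                    best_a = a
            lam[gi] = max(0.0, lr_factor * (best - ll0))
            ahat[gi] = best_a
        results.append(CLRGrid(str(chrom), grid, lam, ahat))
    return results


def empirical_threshold(
    grids: list[CLRGrid] | np.ndarray,
    top_fraction: float = 0.001,
) -> tuple[float, list[Region]]:
    """Genome-wide empirical threshold and the regions above it.

    The threshold is the (1 - top_fraction) quantile (higher interpolation)
    of all grid Lambda values; contiguous runs of strictly-above-threshold
    grid points merge into regions, padded by half a grid step so single-
    point hits form proper intervals.
    """
    if isinstance(grids, np.ndarray):
        values = grids
        grids = []
    else:
        values = np.concatenate([g.lam for g in grids]) if grids else np.array([])
    if values.size == 0:
        raise ValueError("no grid values")
    if values.size < 1.0 / max(top_fraction, 1e-12):
        warnings.warn("too few grid values for the requested top fraction; "
                      "threshold set to the maximum")
        threshold = float(values.max())
    else:
        threshold = float(np.quantile(values, 1.0 - top_fraction, method="higher"))
    regions: list[Region] = []
    for g in grids:
        above = g.lam > threshold
        if not above.any():
            continue
        pad = (g.grid_pos[1] - g.grid_pos[0]) / 2 if g.grid_pos.size > 1 else 1.0
        i = 0
        while i < above.size:
            if above[i]:
                j = i
                while j + 1 < above.size and above[j + 1]:
                    j += 1
                start = max(1, int(np.floor(g.grid_pos[i] - pad)))
                end = int(np.ceil(g.grid_pos[j] + pad))
                regions.append(Region(g.chrom, start, max(end, start + 1),
                                      frozenset({"CLR"})))
                i = j + 1
            else:
                i += 1
    return threshold, regions


class ClrScan:
    """SweepFinder-style CLR scan as a model object.

    Built from phased haplotypes (or per-SNP derived counts plus sample
    size); ``fit`` builds the empirical background SFS from the same data,
    runs the grid scan and applies the empirical top-fraction threshold.
    """

    def __init__(
        self,
        variants: VariantTable,
        haps: HaplotypeMatrix | None = None,
        counts: np.ndarray | None = None,
        n_haplotypes: int | None = None,
        folded: bool | str = "auto",
    ):
        if haps is not None:
            counts = haps.derived_counts()
            n_haplotypes = haps.n_haplotypes
            polarity_known = True
        else:
            if counts is None or n_haplotypes is None:
                raise ValueError("need haplotypes, or counts with n_haplotypes")
            counts = np.asarray(counts, dtype=np.int64)
            polarity_known = False
        self.n = int(n_haplotypes)
        seg = (counts > 0) & (counts < self.n)
        self.counts = counts[seg]
        self.variants = variants.take(np.flatnonzero(seg))
        if folded == "auto":
            folded = not polarity_known
        self.folded = bool(folded)

    def fit(
        self,
        grid_size: int = 10_000,
        alpha_grid: np.ndarray | None = None,
        top_fraction: float = 0.001,
        lr_factor: float = 2.0,
    ) -> "ClrScanResults":
        background = empirical_sfs(self.counts, self.n, self.folded)
        grids = clr_scan(
            self.variants, self.counts, background, grid_size, alpha_grid, lr_factor
        )
        threshold, regions = empirical_threshold(grids, top_fraction)
        return ClrScanResults(self, background, grids, threshold, regions)


class ClrScanResults:
    def __init__(self, model, background, grids, threshold, regions):
        self.model = model
        self.background = background
        self.grids = grids
        self.threshold = threshold
        self.regions = regions

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([g.to_frame() for g in self.grids], ignore_index=True)

    def argmax(self) -> tuple[str, float, float]:
        """(chrom, position, Lambda) of the genome-wide maximum."""
        best = None
        for g in self.grids:
            i = int(np.argmax(g.lam))
            if best is None or g.lam[i] > best[2]:
                best = (g.chrom, float(g.grid_pos[i]), float(g.lam[i]))
        return best

    def summary(self) -> str:
        chrom, pos, lam = self.argmax()
        lines = [
            "CLR sweep scan",
            "==============",
            f"sample size (haplotypes): {self.model.n}   "
            f"spectrum: {'folded' if self.model.folded else 'unfolded'}",
            f"grid points: {sum(g.grid_pos.size for g in self.grids)}",
            f"empirical threshold (top fraction): {self.threshold:.3f}",
            f"max Lambda {lam:.3f} at chr{chrom}:{pos:.0f}",
            f"regions above threshold: {len(self.regions)}",
        ]
        for r in self.regions:
            lines.append(f"  chr{r.chrom}:{r.start_bp}-{r.end_bp}")
        return "\n".join(lines)
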