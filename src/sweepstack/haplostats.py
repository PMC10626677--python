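"""Extended-haplotype statistics: EHH, iHS and nSL from phased haplotypes.

EHH(x) at a focal SNP is the probability that two randomly drawn haplotypes
carrying the same core allele are identical at every SNP between the focal
SNP and x.  iHS integrates the EHH curves of the ancestral and derived
alleles over physical distance (trapezoid rule, curve truncated below an
EHH cutoff or at large inter-SNP gaps) and takes ln(iHH_A / iHH_D).  nSL
measures the same contrast in units of segregating sites: the mean, over
same-allele haplotype pairs, of the number of sites in the maximal interval
containing the focal SNP over which the pair is identical.

Raw scores are standardized within derived-allele-frequency bins (default
100 equal-width bins pooled genome-wide) and converted to two-tailed
Gaussian -log10 P values, -log10(2*Phi(-|z|)).  Significant windows are
0.5 Mb sliding windows containing at least three SNPs above -log10 P >= 4.

Unphased input is rejected: both statistics are defined on haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import HaplotypeMatrix, Region, VariantTable


@dataclass
class EHHCurve:
    """EHH values at successive SNPs outward from the focal SNP.

    ``idx``/``ehh`` run from the focal SNP outward (first entry is the focal
    SNP itself with EHH = 1); negative direction lists SNPs leftward.
    """

    focal_idx: int
    core_allele: int
    right_idx: np.ndarray
    right_ehh: np.ndarray
    left_idx: np.ndarray
    left_ehh: np.ndarray


def polarize_haplotypes(
    haps: HaplotypeMatrix, variants: VariantTable
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Orient haplotype entries so 1 = derived allele.

    Columns whose ancestral allele is allele_b are flipped.  Where polarity
    is unknown the major allele is treated as ancestral (flagged True in
    the returned boolean array).
    """
    h = haps.haps.copy()
    flagged = np.zeros(h.shape[1], dtype=bool)
    freq = h.mean(axis=0)
    for j in range(h.shape[1]):
        anc = variants.ancestral[j]
        if anc == "B":
            h[:, j] = 1 - h[:, j]
        elif anc == ".":
            flagged[j] = True
            if freq[j] > 0.5:
                h[:, j] = 1 - h[:, j]
    return HaplotypeMatrix(h), flagged


def _refine(ids: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Refine a partition id vector by one more SNP column."""
    _, inv = np.unique(ids * 2 + col, return_inverse=True)
    return inv.astype(np.int64)


def _ehh_from_ids(ids: np.ndarray) -> float:
    sizes = np.bincount(ids)
    n = ids.size
    if n < 2:
        return 0.0
    return float((sizes * (sizes - 1)).sum() / (n * (n - 1)))


def ehh(
    haps: HaplotypeMatrix | np.ndarray,
    focal_idx: int,
    core_allele: int,
    pos: np.ndarray | None = None,
    min_ehh_cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
) -> EHHCurve:
    """EHH curve for the carriers of ``core_allele`` at ``focal_idx``.

    The curve is truncated after the first SNP where EHH drops below
    ``min_ehh_cutoff`` (that SNP is still recorded) or before a gap larger
    than ``max_gap_bp`` (only when positions are given).
    """
    h = haps.haps if isinstance(haps, HaplotypeMatrix) else np.asarray(haps)
    m = h.shape[1]
    carriers = np.flatnonzero(h[:, focal_idx] == core_allele)
    if carriers.size < 2:
        raise ValueError("need at least two carriers of the core allele")
    sub = h[carriers]

    def walk(direction: int) -> tuple[np.ndarray, np.ndarray]:
        idxs = [focal_idx]
        vals = [1.0]
        ids = np.zeros(carriers.size, dtype=np.int64)
        j = focal_idx
        while True:
            jn = j + direction
            if jn < 0 or jn >= m:
                break
            if pos is not None and abs(int(pos[jn]) - int(pos[j])) > max_gap_bp:
                break
            ids = _refine(ids, sub[:, jn])
            e = _ehh_from_ids(ids)
            idxs.append(jn)
            vals.append(e)
            if e < min_ehh_cutoff or e == 0.0:
                break
            j = jn
        return np.array(idxs), np.array(vals)

    r_idx, r_ehh = walk(+1)
    l_idx, l_ehh = walk(-1)
    return EHHCurve(focal_idx, core_allele, r_idx, r_ehh, l_idx, l_ehh)


def _integrate_bp(curve_idx: np.ndarray, curve_ehh: np.ndarray,
                  pos: np.ndarray) -> float:
    """Trapezoid integral of an EHH curve over bp distance from the focal
    SNP; the recorded curve already ends at its first below-cutoff value."""
    if curve_idx.size < 2:
        return 0.0
    x = np.abs(pos[curve_idx].astype(float) - float(pos[curve_idx[0]]))
    return float(np.trapezoid(curve_ehh, x))


def ihs_raw(
    haps: HaplotypeMatrix | np.ndarray,
    pos: np.ndarray,
    focal_idx: int,
    min_ehh_cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
) -> float:
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) at one SNP.

    Haplotype entries must be polarized (1 = derived).  Returns NaN when
    either integral is zero or an allele has fewer than two carriers.
    """
    h = haps.haps if isinstance(haps, HaplotypeMatrix) else np.asarray(haps)
    counts = h[:, focal_idx].sum()
    if counts < 2 or h.shape[0] - counts < 2:
        return np.nan
    ihh = {}
    for allele in (0, 1):
        c = ehh(h, focal_idx, allele, pos, min_ehh_cutoff, max_gap_bp)
        ihh[allele] = _integrate_bp(c.right_idx, c.right_ehh, pos) + \
            _integrate_bp(c.left_idx, c.left_ehh, pos)
    if ihh[0] <= 0 or ihh[1] <= 0:
        return np.nan
    return float(np.log(ihh[0] / ihh[1]))


def nsl_raw(
    haps: HaplotypeMatrix | np.ndarray,
    pos: np.ndarray,
    focal_idx: int,
    max_gap_bp: int = 200_000,
    gap_scale_bp: int = 20_000,
    max_extend_sites: int = 100,
) -> float:
    """Unstandardized nSL = ln(SL_ancestral / SL_derived) at one SNP.

    SL for an allele is the mean over carrier pairs of the (gap-weighted)
    number of sites in the maximal interval containing the focal SNP over
    which the pair is identical.  Steps across gaps larger than
    ``gap_scale_bp`` are down-weighted by gap_scale/gap; extension stops at
    gaps above ``max_gap_bp`` or after ``max_extend_sites`` sites.
    """
    h = haps.haps if isinstance(haps, HaplotypeMatrix) else np.asarray(haps)
    nd = int(h[:, focal_idx].sum())
    if nd < 2 or h.shape[0] - nd < 2:
        return np.nan
    sl = {}
    for allele in (0, 1):
        carriers = np.flatnonzero(h[:, focal_idx] == allele)
        sub = h[carriers]
        total = 1.0  # the focal site itself
        for direction in (+1, -1):
            ids = np.zeros(carriers.size, dtype=np.int64)
            j = focal_idx
            steps = 0
            while steps < max_extend_sites:
                jn = j + direction
                if jn < 0 or jn >= h.shape[1]:
                    break
                gap = abs(int(pos[jn]) - int(pos[j]))
                if gap > max_gap_bp:
                    break
                w = 1.0 if gap <= gap_scale_bp else gap_scale_bp / gap
                ids = _refine(ids, sub[:, jn])
                e = _ehh_from_ids(ids)
                total += w * e
                if e == 0.0:
                    break
                j = jn
                steps += 1
        sl[allele] = total
    if sl[0] <= 0 or sl[1] <= 0:
        return np.nan
    return float(np.log(sl[0] / sl[1]))


def _scan(
    haps: HaplotypeMatrix,
    variants: VariantTable,
    statistic: str,
    maf_min: float = 0.05,
    min_ehh_cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
    gap_scale_bp: int = 20_000,
    max_extend_sites: int = 100,
) -> pd.DataFrame:
    """Per-SNP raw scores for every SNP with derived frequency in
    [maf_min, 1 - maf_min], chromosome by chromosome (compiled inner loop)."""
    from ._kernels import ihs_kernel, nsl_kernel

    if statistic not in ("ihs", "nsl"):
        raise ValueError("statistic must be 'ihs' or 'nsl'")
    frames = []
    for chrom in variants.chromosomes():
        idx = variants.chrom_slice(chrom)
        sub = np.ascontiguousarray(haps.haps[:, idx])
        pos = np.ascontiguousarray(variants.pos_bp[idx])
        freq = sub.mean(axis=0)
        focal = np.flatnonzero((freq >= maf_min) & (freq <= 1 - maf_min))
        if statistic == "ihs":
            raw = ihs_kernel(sub, pos, focal, min_ehh_cutoff, max_gap_bp)
        else:
            raw = nsl_kernel(
                sub, pos, focal, max_gap_bp, float(gap_scale_bp), max_extend_sites
            )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos_bp": pos[focal],
                    "freq_derived": freq[focal],
                    "raw": raw,
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos_bp", "freq_derived", "raw"]
    )


def standardize(
    raw: np.ndarray, freq: np.ndarray, n_bins: int = 100
) -> np.ndarray:
    """Standardize raw scores within equal-width derived-frequency bins.

    Bins are pooled genome-wide; within each occupied bin (>= 2 scores with
    positive spread) the bin mean is subtracted and the bin SD divided out.
    Scores in degenerate bins come back NaN.
    """
    raw = np.asarray(raw, dtype=float)
    freq = np.asarray(freq, dtype=float)
    out = np.full(raw.size, np.nan)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, freq, side="right") - 1, 0, n_bins - 1)
    for b in np.unique(bin_idx):
        sel = (bin_idx == b) & np.isfinite(raw)
        if sel.sum() < 2:
            continue
        mu = raw[sel].mean()
        sd = raw[sel].std(ddof=0)
        if sd == 0:
            continue
        out[sel] = (raw[sel] - mu) / sd
    return out


def neglog_two_tailed_p(z: np.ndarray | float) -> np.ndarray | float:
    """-log10 of the two-tailed Gaussian P value, -log10(2*Phi(-|z|))."""
    z = np.abs(np.asarray(z, dtype=float))
    p = 2.0 * norm.cdf(-z)
    res = -np.log10(np.maximum(p, 1e-300)) + 0.0  # normalize -0.0
    return float(res) if res.ndim == 0 else res


def score_track(
    raw_track: pd.DataFrame, n_bins: int = 100
) -> pd.DataFrame:
    """Attach standardized scores and -log10 two-tailed P to a raw track."""
    track = raw_track.copy()
    track["std"] = standardize(
        track["raw"].to_numpy(), track["freq_derived"].to_numpy(), n_bins
    )
    with np.errstate(invalid="ignore"):
        track["neglog10p"] = np.where(
            np.isfinite(track["std"]),
            neglog_two_tailed_p(track["std"].to_numpy()),
            np.nan,
        )
    return track


def window_scan(
    track: pd.DataFrame,
    window_bp: int = 500_000,
    step_bp: int = 10_000,
    threshold: float = 4.0,
    min_hits: int = 3,
    method_label: str = "IHS",
) -> tuple[pd.DataFrame, list[Region]]:
    """Sliding-window significance calls and merged candidate regions.

    Windows of ``window_bp`` slide by ``step_bp`` along each chromosome; a
    window is significant when it holds >= ``min_hits`` SNPs with
    -log10 P >= ``threshold``.  Overlapping or book-ended significant
    windows merge into regions (min start, max end).
    """
    win_rows = []
    regions: list[Region] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        hit = (sub["neglog10p"].to_numpy() >= threshold) & np.isfinite(
            sub["neglog10p"].to_numpy()
        )
        hit_pos = pos[hit]
        if pos.size == 0:
            continue
        starts = np.arange(1, int(pos.max()) + 1, step_bp)
        sig_intervals = []
        for s in starts:
            e = s + window_bp - 1
            n_hits = int(
                np.searchsorted(hit_pos, e, side="right")
                - np.searchsorted(hit_pos, s, side="left")
            )
            sig = n_hits >= min_hits
            win_rows.append((chrom, int(s), int(e), n_hits, sig))
            if sig:
                sig_intervals.append((int(s), int(e)))
        # merge overlapping/adjacent significant windows
        for s, e in sig_intervals:
            if regions and regions[-1].chrom == str(chrom) and s <= regions[-1].end_bp + 1:
                last = regions.pop()
                regions.append(
                    Region(last.chrom, last.start_bp, max(last.end_bp, e),
                           frozenset({method_label}))
                )
            else:
                regions.append(Region(str(chrom), s, e, frozenset({method_label})))
    windows = pd.DataFrame(
        win_rows, columns=["chrom", "start_bp", "end_bp", "n_hits", "significant"]
    )
    return windows, regions


class HaplotypeScan:
    """iHS / nSL selection scan as a model object over phased haplotypes."""

    def __init__(
        self,
        haps: HaplotypeMatrix,
        variants: VariantTable,
        statistic: str = "ihs",
    ):
        if statistic not in ("ihs", "nsl"):
            raise ValueError("statistic must be 'ihs' or 'nsl'")
        self.haps = haps
        self.variants = variants
        self.statistic = statistic

    @classmethod
    def from_genotypes(cls, *args, **kwargs):
        raise ValueError(
            "iHS/nSL require phased haplotypes; phase the data upstream"
        )

    def fit(
        self,
        maf_min: float = 0.05,
        n_bins: int = 100,
        window_bp: int = 500_000,
        step_bp: int = 10_000,
        threshold: float = 4.0,
        min_hits: int = 3,
        **stat_kwargs,
    ) -> "HaplotypeScanResults":
        raw = _scan(self.haps, self.variants, self.statistic, maf_min, **stat_kwargs)
        track = score_track(raw, n_bins)
        windows, regions = window_scan(
            track, window_bp, step_bp, threshold, min_hits,
            method_label=self.statistic.upper(),
        )
        return HaplotypeScanResults(self, track, windows, regions, threshold)


class HaplotypeScanResults:
    def __init__(self, model, track, windows, regions, threshold):
        self.model = model
        self.track = track
        self.windows = windows
        self.regions = regions
        self.threshold = threshold

    def summary(self) -> str:
        t = self.track
        n_sig = int((t["neglog10p"] >= self.threshold).sum())
        lines = [
            f"{self.model.statistic.upper()} selection scan",
            "========================",
            f"SNPs scored: {len(t)}   "
            f"standardized mean {np.nanmean(t['std']):+.3f} "
            f"SD {np.nanstd(t['std']):.3f}",
            f"SNPs with -log10 P >= {self.threshold}: {n_sig}",
            f"significant regions: {len(self.regions)}",
        ]
        for r in self.regions:
            lines.append(f"  chr{r.chrom}:{r.start_bp}-{r.end_bp}")
        return "\n".join(lines)
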