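"""Compiled inner loops for the haplotype scans.

These reproduce, SNP for SNP, the pure-Python reference implementations in
:mod:`sweepstack.haplostats` (`ihs_raw`, `nsl_raw`); the scan entry points
call these for speed and the test suite asserts agreement between the two
routes on random fixtures.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _walk(haps, pos, focal, direction, cutoff, max_gap_bp, use_sites,
          gap_scale_bp, max_extend_sites, ihh_out):
    """One-directional EHH walk tracking both focal alleles jointly.

    In bp mode (use_sites False) accumulates the trapezoid integral of each
    allele's EHH curve over physical distance, stopping an allele once its
    EHH falls below ``cutoff`` (that step still contributes) or hits zero.
    In site mode accumulates gap-weighted per-site EHH sums for nSL.
    Results are added into ``ihh_out`` (length 2: allele 0, allele 1).
    """
    n_hap, m = haps.shape
    ids = np.empty(n_hap, np.int64)
    for h in range(n_hap):
        ids[h] = haps[h, focal]
    n0 = 0
    for h in range(n_hap):
        if haps[h, focal] == 0:
            n0 += 1
    n1 = n_hap - n0
    denom0 = n0 * (n0 - 1)
    denom1 = n1 * (n1 - 1)
    e0 = 1.0
    e1 = 1.0
    active0 = denom0 > 0
    active1 = denom1 > 0
    n_groups = 2
    label = np.empty(2 * n_hap + 2, np.int64)
    sizes = np.empty(n_hap, np.int64)
    group_allele = np.empty(n_hap, np.int64)
    j = focal
    steps = 0
    while (active0 or active1) and (use_sites == 0 or steps < max_extend_sites):
        jn = j + direction
        if jn < 0 or jn >= m:
            break
        gap = pos[jn] - pos[j]
        if gap < 0:
            gap = -gap
        if gap > max_gap_bp:
            break
        w = 1.0
        if use_sites == 1 and gap > gap_scale_bp:
            w = gap_scale_bp / gap
        # refine the partition by column jn
        for k in range(2 * n_groups + 2):
            label[k] = -1
        nxt = 0
        for h in range(n_hap):
            key = ids[h] * 2 + haps[h, jn]
            if label[key] < 0:
                label[key] = nxt
                sizes[nxt] = 0
                group_allele[nxt] = haps[h, focal]
                nxt += 1
            g = label[key]
            ids[h] = -key - 1  # mark; rewritten below
            sizes[g] += 1
        # second pass to store compact ids
        for h in range(n_hap):
            key = -(ids[h] + 1)
            ids[h] = label[key]
        n_groups = nxt
        s0 = 0.0
        s1 = 0.0
        for g in range(n_groups):
            contrib = sizes[g] * (sizes[g] - 1)
            if group_allele[g] == 0:
                s0 += contrib
            else:
                s1 += contrib
        new_e0 = s0 / denom0 if denom0 > 0 else 0.0
        new_e1 = s1 / denom1 if denom1 > 0 else 0.0
        if use_sites == 1:
            if active0:
                ihh_out[0] += w * new_e0
                if new_e0 == 0.0:
                    active0 = False
            if active1:
                ihh_out[1] += w * new_e1
                if new_e1 == 0.0:
                    active1 = False
        else:
            dist = float(gap)
            if active0:
                ihh_out[0] += 0.5 * (e0 + new_e0) * dist
                if new_e0 < cutoff or new_e0 == 0.0:
                    active0 = False
            if active1:
                ihh_out[1] += 0.5 * (e1 + new_e1) * dist
                if new_e1 < cutoff or new_e1 == 0.0:
                    active1 = False
        e0 = new_e0
        e1 = new_e1
        j = jn
        steps += 1
    return 0


@njit(cache=True)
def ihs_kernel(haps, pos, focal_indices, cutoff, max_gap_bp):
    """Unstandardized iHS for each focal index; NaN where undefined."""
    out = np.full(focal_indices.size, np.nan)
    buf = np.zeros(2, np.float64)
    n_hap = haps.shape[0]
    for i in range(focal_indices.size):
        focal = focal_indices[i]
        nd = 0
        for h in range(n_hap):
            nd += haps[h, focal]
        if nd < 2 or n_hap - nd < 2:
            continue
        buf[0] = 0.0
        buf[1] = 0.0
        _walk(haps, pos, focal, 1, cutoff, max_gap_bp, 0, 0.0, 0, buf)
        _walk(haps, pos, focal, -1, cutoff, max_gap_bp, 0, 0.0, 0, buf)
        if buf[0] > 0.0 and buf[1] > 0.0:
            out[i] = np.log(buf[0] / buf[1])
    return out


@njit(cache=True)
def nsl_kernel(haps, pos, focal_indices, max_gap_bp, gap_scale_bp,
               max_extend_sites):
    """Unstandardized nSL for each focal index; NaN where undefined."""
    out = np.full(focal_indices.size, np.nan)
    buf = np.zeros(2, np.float64)
    n_hap = haps.shape[0]
    for i in range(focal_indices.size):
        focal = focal_indices[i]
        nd = 0
        for h in range(n_hap):
            nd += haps[h, focal]
        if nd < 2 or n_hap - nd < 2:
            continue
        buf[0] = 1.0  # the focal site itself
        buf[1] = 1.0
        _walk(haps, pos, focal, 1, 0.0, max_gap_bp, 1, gap_scale_bp,
              max_extend_sites, buf)
        _walk(haps, pos, focal, -1, 0.0, max_gap_bp, 1, gap_scale_bp,
              max_extend_sites, buf)
        if buf[0] > 0.0 and buf[1] > 0.0:
            out[i] = np.log(buf[0] / buf[1])
    return out
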