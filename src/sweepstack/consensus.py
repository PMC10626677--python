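"""Multi-method consensus of candidate selection regions.

Regions from the individual scans (ROHS, IHS, NSL, CLR) are merged by
connected components of the pairwise-overlap graph (closed intervals,
shared endpoints overlap); components supported by at least two distinct
methods are emitted as consensus regions spanning the union of their
members.  Region lengths are reported in Mb, half-up rounded to three
decimals.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .data import Region, regions_to_frame


def overlap(a: Region, b: Region) -> bool:
    """Closed-interval overlap on the same chromosome (shared endpoint counts)."""
    if a.chrom != b.chrom:
        return False
    return a.start_bp <= b.end_bp and b.start_bp <= a.end_bp


def region_length_mb(start_bp: int, end_bp: int) -> float:
    """(end - start) / 1e6, half-up rounded to 3 decimals."""
    if end_bp <= start_bp:
        raise ValueError("end must exceed start")
    mb = Decimal(end_bp - start_bp) / Decimal(1_000_000)
    return float(mb.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def build_consensus(
    method_regions: list[Region], min_methods: int = 2
) -> list[Region]:
    """Merge per-method regions into >= ``min_methods``-method consensus regions.

    Connected components of the cross-method overlap graph become one region
    each (start = min start, end = max end, methods = union); components
    with fewer than ``min_methods`` distinct methods are dropped.  Output is
    sorted by chromosome then start.
    """
    n = len(method_regions)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    order = sorted(range(n), key=lambda i: (method_regions[i].chrom,
                                            method_regions[i].start_bp))
    # sweep per chromosome: overlapping intervals are adjacent after sorting
    active: list[int] = []
    for i in order:
        r = method_regions[i]
        active = [
            j
            for j in active
            if method_regions[j].chrom == r.chrom
            and method_regions[j].end_bp >= r.start_bp
        ]
        for j in active:
            union(i, j)
        active.append(i)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        methods = frozenset().union(*(method_regions[i].methods for i in members))
        if len(methods) < min_methods:
            continue
        chrom = method_regions[members[0]].chrom
        start = min(method_regions[i].start_bp for i in members)
        end = max(method_regions[i].end_bp for i in members)
        out.append(Region(chrom, start, end, methods))
    out.sort(key=lambda r: (_chrom_key(r.chrom), r.start_bp))
    return out


def _chrom_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def consensus_table(regions: list[Region]) -> pd.DataFrame:
    """Candidate-region table: chrom, bounds, length in Mb, methods."""
    df = regions_to_frame(regions)
    df.insert(0, "region", range(1, len(regions) + 1))
    df["length_mb"] = [
        region_length_mb(r.start_bp, r.end_bp) for r in regions
    ]
    return df[["region", "chrom", "start_bp", "end_bp", "length_mb", "methods"]]
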