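"""Gene/QTL annotation of candidate regions and QTL-class enrichment.

Candidate regions are intersected with user-supplied feature intervals
(genes from GFF3/BED, QTLs from an Animal-QTLdb-style TSV).  Per QTL trait
class, enrichment is measured as observed / expected overlapping QTLs
(the "richness factor"), with a hypergeometric upper-tail P value and
Benjamini–Hochberg FDR across classes — the GALLO-style analysis.  A QTL
spanning several regions is counted once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import Region


def read_gff3_genes(path: str, feature_types: tuple[str, ...] = ("gene",)
                    ) -> pd.DataFrame:
    """Gene intervals from a GFF3 file (1-based inclusive coordinates).

    Returns columns chrom, start_bp, end_bp, feature_id, feature_class
    (feature_class = gene name/ID).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"{parts[0]}:{parts[3]}"
            rows.append((parts[0], int(parts[3]), int(parts[4]), name, name))
    return pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "feature_id", "feature_class"]
    )


def read_bed_features(path: str) -> pd.DataFrame:
    """Feature intervals from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start_bp": df[1].astype(int) + 1,
            "end_bp": df[2].astype(int),
        }
    )
    out["feature_id"] = (
        df[3].astype(str) if df.shape[1] > 3
        else out["chrom"] + ":" + out["start_bp"].astype(str)
    )
    out["feature_class"] = out["feature_id"]
    return out


def read_qtl_tsv(path: str) -> pd.DataFrame:
    """QTL intervals: TSV with columns chrom, start_bp, end_bp, trait, class."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start_bp", "end_bp", "trait", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"QTL table missing columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    return df.rename(columns={"trait": "feature_id", "class": "feature_class"})[
        ["chrom", "start_bp", "end_bp", "feature_id", "feature_class"]
    ]


def features_in_regions(
    regions: list[Region], features: pd.DataFrame
) -> pd.DataFrame:
    """All (region, feature) pairs with closed-interval overlap.

    Features on chromosomes absent from the regions are simply not
    reported; a feature overlapping several regions appears once per
    region.
    """
    rows = []
    for ri, r in enumerate(regions):
        sub = features[features["chrom"] == r.chrom]
        hit = sub[(sub["start_bp"] <= r.end_bp) & (r.start_bp <= sub["end_bp"])]
        for f in hit.itertuples():
            rows.append(
                (ri, r.chrom, r.start_bp, r.end_bp, f.feature_id, f.feature_class,
                 int(f.start_bp), int(f.end_bp))
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_index", "chrom", "region_start_bp", "region_end_bp",
            "feature_id", "feature_class", "feature_start_bp", "feature_end_bp",
        ],
    )


def qtl_enrichment(
    regions: list[Region], qtls: pd.DataFrame, scope: str = "genome"
) -> pd.DataFrame:
    """QTL-class enrichment of candidate regions.

    Per class within the scope (whole genome, or each chromosome when
    ``scope == "chromosome"``): observed = class QTLs overlapping any
    region (each QTL once); expected = class total x (overlapping QTLs of
    all classes / all QTLs); richness = observed / expected; P =
    hypergeometric upper tail; FDR = Benjamini–Hochberg across classes.
    """
    if scope not in ("genome", "chromosome"):
        raise ValueError("scope must be 'genome' or 'chromosome'")
    qtls = qtls.reset_index(drop=True)
    hit_ids = set()
    for r in regions:
        sub = qtls[qtls["chrom"] == r.chrom]
        hit = sub[(sub["start_bp"] <= r.end_bp) & (r.start_bp <= sub["end_bp"])]
        hit_ids.update(hit.index)
    qtls = qtls.assign(_hit=qtls.index.isin(hit_ids))
    scopes = (
        [("genome", qtls)]
        if scope == "genome"
        else [(c, g) for c, g in qtls.groupby("chrom", sort=False)]
    )
    rows = []
    for scope_id, sub in scopes:
        total = len(sub)
        n_hit = int(sub["_hit"].sum())
        if total == 0:
            continue
        for cls, grp in sub.groupby("feature_class", sort=False):
            k_total = len(grp)
            if k_total == 0:
                continue
            observed = int(grp["_hit"].sum())
            expected = k_total * n_hit / total
            richness = observed / expected if expected > 0 else np.nan
            p = float(hypergeom.sf(observed - 1, total, k_total, n_hit))
            rows.append((scope_id, cls, observed, expected, richness, p))
    out = pd.DataFrame(
        rows,
        columns=["scope", "feature_class", "observed", "expected", "richness", "p"],
    )
    if len(out):
        out["fdr"] = np.nan
        for _, grp in out.groupby("scope", sort=False):
            out.loc[grp.index, "fdr"] = multipletests(
                grp["p"].to_numpy(), method="fdr_bh"
            )[1]
        out["neglog10_fdr"] = -np.log10(np.maximum(out["fdr"], 1e-300))
    return out


def classify_regions_by_qtl(overlap_table: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of overlap-table rows per QTL class
    (pie-chart-ready)."""
    counts = overlap_table.groupby("feature_class", sort=False).size()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "feature_class": counts.index,
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / total if total else 0.0,
        }
    ).reset_index(drop=True)
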