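"""Config-driven orchestration of the full selection-signature pipeline.

Stage order: QC (call rates, MAF, HWE, relatedness pruning) -> the four
scans (eROHi, iHS, nSL, CLR) -> multi-method consensus -> optional gene/QTL
annotation.  Every stage writes plot-ready TSV/BED output plus a JSON
manifest recording parameters, input hashes and row counts; identical
config and seed give bit-identical outputs.  Stages whose outputs already
exist can be reused with ``resume=True``.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import annotate as annot
from . import genio
from .clrscan import CLRGrid, ClrScan, empirical_threshold
from .consensus import build_consensus, consensus_table
from .data import HaplotypeMatrix, Region, regions_to_bed, regions_to_frame
from .haplostats import HaplotypeScan, polarize_haplotypes, window_scan
from .qc import ibd_pihat, prune_related, qc_filter
from .rohscan import ROHParams, RohScan


@dataclass
class PipelineConfig:
    """All pipeline settings with the scan defaults pre-filled.

    The defaults reproduce the standard HD-array configuration: ROH 1 Mb /
    15 SNPs, outlier threshold -log10 P >= 4, 0.5 Mb windows with >= 3 hits,
    100 frequency bins, CLR grid 10,000 per chromosome with top 0.1%, IBD
    pruning above PI_HAT 0.18.
    """

    vcf: str = ""
    out_dir: str = "sweepstack_out"
    seed: int = 1
    qc: dict = field(default_factory=lambda: {
        "indiv_call": 0.90, "snp_call": 0.95, "maf": 0.01, "hwe_p": 1e-4,
        "ibd_threshold": 0.18,
    })
    roh: dict = field(default_factory=lambda: {
        "min_length_bp": 1_000_000, "min_snps": 15,
        "min_density_snp_per_bp": 1e-5, "max_gap_bp": 1_000_000,
        "max_het": 1, "max_missing_in_run": 0,
        "threshold": 4.0, "min_consecutive": 2, "extension_bp": 100_000,
    })
    haplo: dict = field(default_factory=lambda: {
        "maf_min": 0.05, "n_bins": 100, "window_bp": 500_000,
        "step_bp": 10_000, "threshold": 4.0, "min_hits": 3,
    })
    clr: dict = field(default_factory=lambda: {
        "grid_size": 10_000, "top_fraction": 0.001,
    })
    min_methods: int = 2
    gff: str | None = None
    qtl: str | None = None
    enrichment_scope: str = "genome"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def validate(self) -> None:
        if not self.vcf or not os.path.exists(self.vcf):
            raise FileNotFoundError(f"input VCF not found: {self.vcf}")
        for p in (self.gff, self.qtl):
            if p and not os.path.exists(p):
                raise FileNotFoundError(p)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


def run(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the pipeline; returns the run manifest (also written as JSON)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "input": {"vcf": config.vcf, "sha256": _sha256(config.vcf)},
        "seed": config.seed,
        "stages": {},
    }

    def outpath(name: str) -> str:
        return os.path.join(config.out_dir, name)

    # ---- QC ---------------------------------------------------------------
    stage = "qc"
    try:
        geno, haps, variants, samples = genio.read_vcf(config.vcf)
        th = {k: config.qc[k] for k in ("indiv_call", "snp_call", "maf", "hwe_p")}
        geno, variants, samples, report = qc_filter(geno, variants, samples, th)
        if haps is not None:
            haps = haps.take_variants(report.kept_variant_idx)
            hap_rows = np.sort(
                np.concatenate(
                    [2 * report.kept_sample_idx, 2 * report.kept_sample_idx + 1]
                )
            )
            haps = HaplotypeMatrix(haps.haps[hap_rows])
        pihat = ibd_pihat(geno)
        retained = prune_related(
            pihat, samples.n_samples, config.qc["ibd_threshold"],
        )
        n_removed_ibd = samples.n_samples - retained.size
        report.log("ibd_pihat", "individual", n_removed_ibd)
        geno = geno.take_samples(retained)
        samples = samples.take(retained)
        if haps is not None:
            rows = np.sort(np.concatenate([2 * retained, 2 * retained + 1]))
            haps = HaplotypeMatrix(haps.haps[rows])
        report.to_tsv(outpath("qc_report.tsv"))
        manifest["stages"][stage] = {
            "params": th | {"ibd_threshold": config.qc["ibd_threshold"]},
            "n_snps": int(variants.n_variants),
            "n_individuals": int(samples.n_samples),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageFailure(stage, exc) from exc

    method_regions: list[Region] = []
    tracks: dict[str, pd.DataFrame] = {}
    thresholds: dict[str, float] = {}

    # ---- eROHi ------------------------------------------------------------
    stage = "roh"
    try:
        rp = {k: config.roh[k] for k in (
            "min_length_bp", "min_snps", "min_density_snp_per_bp",
            "max_gap_bp", "max_het", "max_missing_in_run")}
        res = RohScan(geno, variants, samples).fit(
            ROHParams(**rp),
            threshold=config.roh["threshold"],
            min_consecutive=config.roh["min_consecutive"],
            extension_bp=config.roh["extension_bp"],
        )
        res.runs_frame().to_csv(outpath("roh_runs.tsv"), sep="\t", index=False)
        res.track.to_csv(outpath("roh_incidence.tsv"), sep="\t", index=False)
        tracks["ROHS"] = res.track.assign(value=res.track["neglog10p"])
        thresholds["ROHS"] = config.roh["threshold"]
        regions_to_frame(res.regions).to_csv(
            outpath("roh_regions.tsv"), sep="\t", index=False
        )
        regions_to_bed(res.regions, outpath("roh_regions.bed"))
        method_regions += res.regions
        manifest["stages"][stage] = {
            "params": rp, "n_runs": len(res.runs), "n_regions": len(res.regions),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageFailure(stage, exc) from exc

    # ---- iHS / nSL --------------------------------------------------------
    for stat in ("ihs", "nsl"):
        stage = stat
        try:
            if haps is None:
                manifest["stages"][stage] = {"skipped": "input not phased"}
                continue
            score_path = outpath(f"{stat}_scores.tsv")
            n_unpolarized = 0
            if resume and os.path.exists(score_path):
                track = pd.read_csv(score_path, sep="\t", dtype={"chrom": str})
                windows, regions = window_scan(
                    track,
                    window_bp=config.haplo["window_bp"],
                    step_bp=config.haplo["step_bp"],
                    threshold=config.haplo["threshold"],
                    min_hits=config.haplo["min_hits"],
                    method_label=stat.upper(),
                )
            else:
                phaps, flagged = polarize_haplotypes(haps, variants)
                n_unpolarized = int(flagged.sum())
                res = HaplotypeScan(phaps, variants, stat).fit(
                    maf_min=config.haplo["maf_min"],
                    n_bins=config.haplo["n_bins"],
                    window_bp=config.haplo["window_bp"],
                    step_bp=config.haplo["step_bp"],
                    threshold=config.haplo["threshold"],
                    min_hits=config.haplo["min_hits"],
                )
                track, windows, regions = res.track, res.windows, res.regions
                track.to_csv(score_path, sep="\t", index=False)
            windows.to_csv(outpath(f"{stat}_windows.tsv"), sep="\t", index=False)
            regions_to_frame(regions).to_csv(
                outpath(f"{stat}_regions.tsv"), sep="\t", index=False
            )
            regions_to_bed(regions, outpath(f"{stat}_regions.bed"))
            method_regions += regions
            tracks[stat.upper()] = track.assign(value=track["neglog10p"])
            thresholds[stat.upper()] = config.haplo["threshold"]
            manifest["stages"][stage] = {
                "params": dict(config.haplo),
                "n_snps_scored": int(len(track)),
                "n_regions": len(regions),
                "n_unpolarized": n_unpolarized,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageFailure(stage, exc) from exc

    # ---- CLR --------------------------------------------------------------
    stage = "clr"
    try:
        grid_path = outpath("clr_grid.tsv")
        if resume and os.path.exists(grid_path):
            df = pd.read_csv(grid_path, sep="\t", dtype={"chrom": str})
            grids = [
                CLRGrid(
                    str(c),
                    sub["grid_pos"].to_numpy(float),
                    sub["clr"].to_numpy(float),
                    sub["alpha_hat"].to_numpy(float),
                )
                for c, sub in df.groupby("chrom", sort=False)
            ]
            threshold, clr_regions = empirical_threshold(
                grids, config.clr["top_fraction"]
            )
            clr_frame = df
        else:
            if haps is not None:
                model = ClrScan(variants, haps=haps)
            else:
                counts = np.where(geno.dosage == -1, 0, geno.dosage).sum(axis=0)
                n_hap = 2 * geno.n_samples
                seg = (counts > 0) & (counts < n_hap)
                model = ClrScan(
                    variants.take(np.flatnonzero(seg)),
                    counts=counts[seg], n_haplotypes=n_hap, folded=True,
                )
            res = model.fit(
                grid_size=config.clr["grid_size"],
                top_fraction=config.clr["top_fraction"],
            )
            threshold, clr_regions = res.threshold, res.regions
            clr_frame = res.to_frame()
            clr_frame.to_csv(grid_path, sep="\t", index=False)
        regions_to_frame(clr_regions).to_csv(
            outpath("clr_regions.tsv"), sep="\t", index=False
        )
        regions_to_bed(clr_regions, outpath("clr_regions.bed"))
        method_regions += clr_regions
        tracks["CLR"] = clr_frame.rename(
            columns={"grid_pos": "pos_bp", "clr": "value"}
        )
        thresholds["CLR"] = threshold
        manifest["stages"][stage] = {
            "params": dict(config.clr),
            "threshold": threshold,
            "n_regions": len(clr_regions),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageFailure(stage, exc) from exc

    # ---- consensus --------------------------------------------------------
    stage = "consensus"
    try:
        cons = build_consensus(method_regions, config.min_methods)
        table = consensus_table(cons)
        table.to_csv(outpath("consensus.tsv"), sep="\t", index=False)
        regions_to_bed(cons, outpath("consensus.bed"))
        for name, track in tracks.items():
            manhattan_table(
                track, thresholds[name], cons
            ).to_csv(outpath(f"manhattan_{name.lower()}.tsv"), sep="\t", index=False)
        manifest["stages"][stage] = {
            "min_methods": config.min_methods,
            "n_method_regions": len(method_regions),
            "n_consensus_regions": len(cons),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageFailure(stage, exc) from exc

    # ---- annotation -------------------------------------------------------
    stage = "annotate"
    try:
        if config.gff or config.qtl:
            if config.gff:
                genes = annot.read_gff3_genes(config.gff)
                hits = annot.features_in_regions(cons, genes)
                hits.to_csv(outpath("genes_in_regions.tsv"), sep="\t", index=False)
                manifest["stages"].setdefault(stage, {})["n_gene_hits"] = len(hits)
            if config.qtl:
                qtls = annot.read_qtl_tsv(config.qtl)
                enr = annot.qtl_enrichment(cons, qtls, config.enrichment_scope)
                enr.to_csv(outpath("qtl_enrichment.tsv"), sep="\t", index=False)
                manifest["stages"].setdefault(stage, {})["n_classes"] = len(enr)
    except Exception as exc:  # noqa: BLE001
        raise StageFailure(stage, exc) from exc

    with open(outpath("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def manhattan_table(
    track: pd.DataFrame, threshold: float, confirmed: list[Region]
) -> pd.DataFrame:
    """Plot-ready per-SNP table: chrom, pos, value, is_extreme,
    in_confirmed_region (inside a multi-method consensus region)."""
    out = track[["chrom", "pos_bp", "value"]].copy()
    out["chrom"] = out["chrom"].astype(str)
    out["is_extreme"] = out["value"] >= threshold
    flag = np.zeros(len(out), dtype=bool)
    pos = out["pos_bp"].to_numpy()
    for r in confirmed:
        flag |= (
            (out["chrom"].to_numpy() == r.chrom)
            & (pos >= r.start_bp)
            & (pos <= r.end_bp)
        )
    out["in_confirmed_region"] = flag
    return out
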