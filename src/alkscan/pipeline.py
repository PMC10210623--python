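"""Stage orchestration: compose the scan, triage, effect and convergence
stages over a fixture (or user-supplied) input directory and write
deterministic artifacts.

Analysis stages are pure functions of their inputs; the only randomness in
the package lives in the simulator. Logging goes to stderr, results to
files, so stdout stays clean for piping.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .model import GenotypeTable, ScanConfig, TriageConfig, GeneModel, GenomeSequence
from .popstats import window_stats, per_chromosome_pi, compare_diversity, site_stats
from .scan import (ScanThresholds, select_outlier_windows, call_candidate_regions,
                   assign_genes, fine_map, regions_to_frame)
from .effects import triage_snvs
from .convergence import detect_convergent_sites, report_convergence

log = logging.getLogger(__name__)


@dataclass
class Inputs:
    table: GenotypeTable
    genomes: dict[str, GenomeSequence]
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]


def load_inputs(indir: str | Path,
                site_filter: gio.SiteFilter | None = None) -> Inputs:
    """Load the standard fixture directory layout."""
    indir = Path(indir)
    for name in ("variants.vcf", "popmap.tsv", "genome.fa", "genes.gff3"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing input: {indir / name}")
    popmap = gio.read_popmap(indir / "popmap.tsv")
    table = gio.read_vcf(indir / "variants.vcf", popmap, site_filter)
    genomes = {g.name: g for g in gio.read_fasta(indir / "genome.fa")}
    genes = gio.read_gff3(indir / "genes.gff3", genome=genomes)
    return Inputs(table, genomes, genes,
                  {n: g.length for n, g in genomes.items()})


def scan_stage(table: GenotypeTable, chrom_lengths: dict[str, int],
               genes: list[GeneModel], config: ScanConfig | None = None
               ) -> tuple[pd.DataFrame, ScanThresholds, list]:
    """Windowed statistics -> outlier selection -> merged regions with genes."""
    cfg = config or ScanConfig()
    windows = window_stats(table, chrom_lengths, cfg)
    thresholds, selected = select_outlier_windows(windows, cfg)
    regions = call_candidate_regions(selected, cfg.merge_gap_bp)
    assign_genes(regions, genes)
    return selected, thresholds, regions


def _prepare_outdir(outdir: str | Path, force: bool) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    existing = list(out.glob("*.tsv")) + list(out.glob("*.json"))
    if existing and not force:
        raise FileExistsError(
            f"{out} already holds outputs; pass force=True/--force to overwrite")
    return out


def run_scan(indir: str | Path, outdir: str | Path,
             config: ScanConfig | None = None, force: bool = False) -> dict:
    """Scan stage from files to files: windows.tsv, thresholds.json,
    regions.tsv (BED-compatible coordinates)."""
    inputs = load_inputs(indir)
    out = _prepare_outdir(outdir, force)
    windows, thresholds, regions = scan_stage(
        inputs.table, inputs.chrom_lengths, inputs.genes, config)
    gio.write_tsv(windows, out / "windows.tsv")
    gio.write_tsv(regions_to_frame(regions), out / "regions.tsv")
    genes_fst = sorted({g for r in regions if "FST" in r.criteria for g in r.genes})
    genes_ratio = sorted({g for r in regions if "PI_RATIO" in r.criteria
                          for g in r.genes})
    summary = {
        "thresholds": thresholds.to_dict(),
        "n_windows": int(len(windows)),
        "n_selected": int(windows["selected"].sum()),
        "n_regions": len(regions),
        "candidate_genes_fst": genes_fst,
        "candidate_genes_pi_ratio": genes_ratio,
        "candidate_genes_union": sorted(set(genes_fst) | set(genes_ratio)),
    }
    with open(out / "thresholds.json", "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
    log.info("scan: %d windows, %d selected, %d regions; Fst threshold %.3f, "
             "|log2 ratio| threshold %.3f; %d / %d candidate genes by Fst / pi-ratio",
             summary["n_windows"], summary["n_selected"], summary["n_regions"],
             thresholds.fst_threshold, thresholds.log2_ratio_threshold,
             len(genes_fst), len(genes_ratio))
    return summary


def run_all(indir: str | Path, outdir: str | Path,
            scan_config: ScanConfig | None = None,
            triage_config: TriageConfig | None = None,
            force: bool = False) -> dict:
    """Full pipeline: scan + fine-map + triage + effects + convergence.

    Writes one aggregated report.json; every number in it is traceable to a
    stage artifact in the same directory.
    """
    indir = Path(indir)
    inputs = load_inputs(indir)
    out = _prepare_outdir(outdir, force)
    cfg = scan_config or ScanConfig()

    windows, thresholds, regions = scan_stage(
        inputs.table, inputs.chrom_lengths, inputs.genes, cfg)
    gio.write_tsv(windows, out / "windows.tsv")
    gio.write_tsv(regions_to_frame(regions), out / "regions.tsv")

    fine_frames = []
    for region in regions:
        fm = fine_map(region, inputs.table, inputs.chrom_lengths[region.chrom], cfg)
        fm.insert(0, "region", f"{region.chrom}:{region.start}-{region.end}")
        fine_frames.append(fm)
    if fine_frames:
        gio.write_tsv(pd.concat(fine_frames, ignore_index=True),
                      out / "fine_windows.tsv")

    stats = site_stats(inputs.table)
    tri_cfg = triage_config or TriageConfig.preset_a()
    triaged = triage_snvs(stats, tri_cfg, inputs.genes, inputs.genomes)
    gio.write_tsv(triaged, out / "triage.tsv")

    chrom_pi = per_chromosome_pi(windows)
    if len(chrom_pi) >= 2:
        ttest = compare_diversity(chrom_pi["pi_alk"].to_numpy(),
                                  chrom_pi["pi_fw"].to_numpy())
    else:
        ttest = None  # a paired per-chromosome test needs >= 2 chromosomes

    convergence = None
    aln_path, roles_path = indir / "ortholog.aln.fa", indir / "roles.tsv"
    if aln_path.exists() and roles_path.exists():
        alignment = {s.name: s.residues for s in gio.read_fasta(aln_path)}
        roles = dict(pd.read_csv(roles_path, sep="\t", header=None).values)
        sites = detect_convergent_sites(alignment, roles)
        convergence = report_convergence(sites, gene_id="ortholog")
        with open(out / "convergence.json", "w") as fh:
            json.dump(convergence, fh, indent=2)
            fh.write("\n")

    report = {
        "thresholds": thresholds.to_dict(),
        "n_windows": int(len(windows)),
        "n_regions": len(regions),
        "candidate_genes": sorted({g for r in regions for g in r.genes}),
        "n_triaged": int(len(triaged)),
        "triaged_by_class": (triaged["klass"].value_counts().to_dict()
                             if "klass" in triaged.columns else {}),
        "pi_ttest": ttest,
        "convergence": ({"n_differentiating": convergence["n_differentiating"],
                         "n_convergent": convergence["n_convergent"]}
                        if convergence else None),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
        fh.write("\n")
    return report
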