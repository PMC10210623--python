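"""Readers and writers for the standard formats the pipeline touches.

VCF parsing is delegated to cyvcf2, GFF3 to gffutils, FASTA to Biopython;
this module only normalizes their output into the internal data model
(0-based half-open coordinates, dosage-encoded genotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import MISSING, GeneModel, GenomeSequence, GenotypeTable, PopulationMap

log = logging.getLogger(__name__)


@dataclass
class SiteFilter:
    """Low-quality-site filtering stage. Every switch can be turned off.

    max_missing_rate: drop sites where more than this fraction of genotypes is
    missing (default 0.2). min_mac: minimum minor-allele count over both
    populations (default 0 = keep monomorphic sites; they exercise NA paths
    downstream). biallelic_only: skip multi-allelic records instead of
    recoding them.
    """

    max_missing_rate: float | None = 0.2
    min_mac: int = 0
    biallelic_only: bool = False

    @classmethod
    def off(cls) -> "SiteFilter":
        return cls(max_missing_rate=None, min_mac=0, biallelic_only=False)


def read_popmap(path: str | Path) -> PopulationMap:
    """Two-column TSV (sample, population) -> PopulationMap."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return PopulationMap(dict(zip(df["sample"], df["population"])))


def _recode_multiallelic(gts: list, n_alts: int) -> tuple[int | None, list]:
    """Pick the most frequent ALT among called alleles; other alleles -> missing.

    Returns (kept alt index 1-based, genotype rows). The REF allele is always
    kept so downstream reference-dependent annotation stays valid; when every
    called allele is REF the first ALT is kept arbitrarily.
    """
    counts = np.zeros(n_alts + 1, dtype=int)
    for g in gts:
        for a in g[:2]:
            if a is not None and a >= 0:
                counts[a] += 1
    alt_counts = counts[1:]
    keep = int(np.argmax(alt_counts)) + 1 if alt_counts.sum() else 1
    return keep, gts


def read_vcf(
    path: str | Path,
    popmap: PopulationMap,
    site_filter: SiteFilter | None = None,
) -> GenotypeTable:
    """Read a VCF into a GenotypeTable.

    Multi-allelic records are recoded to REF + the most frequent ALT by
    default (genotypes carrying other alleles become missing), or skipped when
    ``site_filter.biallelic_only`` is set. Positions are converted to 0-based.
    """
    from cyvcf2 import VCF

    sf = site_filter or SiteFilter()
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in popmap.assignments]
    if unmapped:
        raise ValueError(f"samples in VCF but not in population map: {unmapped}")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    snps: list[bool] = []
    dosages: list[np.ndarray] = []
    n = len(samples)

    for var in vcf:
        if len(var.ALT) == 0:
            continue
        if len(var.ALT) > 1:
            if sf.biallelic_only:
                continue
            keep_alt, _ = _recode_multiallelic(var.genotypes, len(var.ALT))
        else:
            keep_alt = 1
        alt_allele = var.ALT[keep_alt - 1]
        row = np.full(n, MISSING, dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            a1, a2 = g[0], g[1]
            if a1 is None or a2 is None or a1 < 0 or a2 < 0:
                continue
            if a1 > len(var.ALT) or a2 > len(var.ALT):
                raise ValueError(
                    f"malformed GT at {var.CHROM}:{var.POS} sample {samples[j]}")
            if (a1 not in (0, keep_alt)) or (a2 not in (0, keep_alt)):
                continue  # third allele recoded to missing
            row[j] = (a1 == keep_alt) + (a2 == keep_alt)

        called = int((row >= 0).sum())
        if sf.max_missing_rate is not None and n > 0:
            if 1 - called / n > sf.max_missing_rate:
                continue
        if sf.min_mac > 0 and called > 0:
            ac = int(row[row >= 0].sum())
            if min(ac, 2 * called - ac) < sf.min_mac:
                continue

        chroms.append(var.CHROM)
        poss.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(alt_allele)
        snps.append(len(var.REF) == 1 and len(alt_allele) == 1)
        dosages.append(row)

    order = np.lexsort((np.asarray(poss, dtype=np.int64),
                        np.asarray(chroms, dtype=object)))
    if len(order) and not np.array_equal(order, np.arange(len(order))):
        log.warning("VCF records were not (chrom, pos) sorted; sorting")
    table = GenotypeTable(
        chrom=np.asarray(chroms, dtype=object)[order],
        pos=np.asarray(poss, dtype=np.int64)[order],
        ref=np.asarray(refs, dtype=object)[order],
        alt=np.asarray(alts, dtype=object)[order],
        is_snp=np.asarray(snps, dtype=bool)[order],
        dosage=(np.vstack(dosages)[order] if dosages
                else np.zeros((0, n), dtype=np.int8)),
        samples=samples,
        popmap=popmap,
    )
    return table


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: GenotypeTable, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeTable back out as a minimal GT-only VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            gts = "\t".join(_GT_STR[int(d)] for d in table.dosage[i])
            fh.write(f"{table.chrom[i]}\t{table.pos[i] + 1}\t.\t{table.ref[i]}\t"
                     f"{table.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read FASTA; residues are uppercased. Duplicate names are an error."""
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence name {rec.id!r}")
            seen.add(rec.id)
            seqs.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    return seqs


def write_fasta(seqs: list[GenomeSequence], path: str | Path, wrap: int = 60) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.name, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def read_gff3(path: str | Path,
              genome: dict[str, GenomeSequence] | None = None) -> list[GeneModel]:
    """GFF3 gene/mRNA/CDS -> one GeneModel per gene (longest-CDS transcript).

    Minus-strand cds_parts come out in transcription order (descending start).
    CDS features without a resolvable parent are skipped with a warning; CDS
    coordinates beyond the reference sequence are an error when a genome is
    supplied.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        candidates: list[list] = []
        if transcripts:
            for tr in transcripts:
                cds = list(db.children(tr, featuretype="CDS", order_by="start"))
                if cds:
                    candidates.append(cds)
        else:
            cds = list(db.children(gene, featuretype="CDS", order_by="start"))
            if cds:
                candidates.append(cds)
        if not candidates:
            log.warning("gene %s has no CDS; skipped", gene.id)
            continue
        cds = max(candidates, key=lambda parts: sum(f.end - f.start + 1 for f in parts))
        parts = [(f.start - 1, f.end, int(f.frame) if f.frame != "." else 0)
                 for f in cds]
        if gene.strand == "-":
            parts = parts[::-1]
        if genome is not None:
            seq = genome.get(gene.seqid)
            if seq is None or any(e > seq.length for _, e, _ in parts):
                raise ValueError(f"gene {gene.id}: CDS outside reference {gene.seqid}")
        model = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            cds_parts=parts,
            gene_span=(gene.start - 1, gene.end),
        )
        from .effects import check_phases
        check_phases(model)  # declared phases are trusted; mismatches logged
        models.append(model)
    # orphan CDS diagnostics
    for f in db.features_of_type("CDS"):
        if "Parent" not in f.attributes:
            log.warning("CDS at %s:%d-%d has no Parent; skipped", f.seqid, f.start, f.end)
    return models


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Uniform TSV writer: tab-separated, NA spelled 'NA', no index."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
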