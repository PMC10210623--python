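"""Highly differentiated SNV triage and strand-aware coding-effect annotation.

A variant is mapped through the gene's CDS chain (minus-strand parts
reverse-complemented, GFF3 phase honoured), the affected codon is rebuilt
from the reference genome, the alternate base substituted, and both codons
translated with the standard nuclear genetic code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import GeneModel, GenomeSequence, TriageConfig

log = logging.getLogger(__name__)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
FRAMESHIFT = "frameshift"
INFRAME_INDEL = "inframe_indel"
NONCODING = "noncoding"
SPLICE_UNKNOWN = "splice_unknown"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CodingEffect:
    gene_id: str
    klass: str
    cds_offset: int | None = None
    codon_index: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


def spliced_cds(gene: GeneModel, genome: GenomeSequence) -> str:
    """Concatenate CDS parts in transcription order; minus-strand parts are
    reverse-complemented. Includes any leading phase overhang."""
    chunks = []
    for s, e, _ in gene.cds_parts:
        part = genome.residues[s:e]
        chunks.append(revcomp(part) if gene.strand == "-" else part)
    return "".join(chunks)


def cds_offset_of(gene: GeneModel, pos0: int) -> int | None:
    """Offset of a genomic position within the spliced CDS (transcription
    order), or None when the position is not inside any CDS part."""
    acc = 0
    for s, e, _ in gene.cds_parts:
        if s <= pos0 < e:
            within = (pos0 - s) if gene.strand == "+" else (e - 1 - pos0)
            return acc + within
        acc += e - s
    return None


def check_phases(gene: GeneModel) -> bool:
    """Compare declared GFF3 phases against the cumulative reading frame.

    The declared phases are trusted for annotation; a mismatch is only
    logged. Returns True when consistent."""
    p0 = gene.cds_parts[0][2]
    acc = 0
    ok = True
    for s, e, ph in gene.cds_parts:
        expect = (3 - (acc - p0) % 3) % 3 if acc else p0
        if ph != expect:
            log.warning("gene %s: CDS part %d-%d declares phase %d, frame says %d",
                        gene.gene_id, s, e, ph, expect)
            ok = False
        acc += e - s
    return ok


def _indel_class(pos0: int, ref: str, alt: str, gene: GeneModel) -> str:
    if len(ref) > len(alt):          # deletion: bases after the anchor go
        lo, hi = pos0 + 1, pos0 + len(ref)
    elif len(alt) > len(ref):        # insertion between pos0 and pos0+1
        lo, hi = pos0 + 1, pos0 + 1
    else:
        lo, hi = pos0, pos0 + len(ref)
    in_cds = out_cds = False
    for s, e, _ in gene.cds_parts:
        if lo == hi:                 # insertion point strictly inside a part
            if s < lo < e:
                in_cds = True
        else:
            ov = min(hi, e) - max(lo, s)
            if ov > 0:
                in_cds = True
                if ov < hi - lo:
                    out_cds = True
    if not in_cds:
        return NONCODING
    if out_cds:
        return SPLICE_UNKNOWN
    return FRAMESHIFT if abs(len(ref) - len(alt)) % 3 else INFRAME_INDEL


def annotate_coding_effect(chrom: str, pos0: int, ref: str, alt: str,
                           gene: GeneModel, genome: GenomeSequence
                           ) -> CodingEffect:
    """Classify one variant against one gene model.

    pos0 is 0-based. SNPs inside the CDS get codon-level calls; indels get
    frameshift / inframe_indel; anything inside the gene span but outside the
    CDS is noncoding. The reference allele must match the genome."""
    if chrom != gene.chrom or not gene.contains(pos0):
        raise ValueError(f"variant {chrom}:{pos0 + 1} outside gene {gene.gene_id}")
    if genome.residues[pos0:pos0 + len(ref)].upper() != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos0 + 1}: genome has "
            f"{genome.residues[pos0:pos0 + len(ref)]!r}, VCF says {ref!r}")

    if len(ref) != 1 or len(alt) != 1:
        return CodingEffect(gene.gene_id, _indel_class(pos0, ref, alt, gene))

    offset = cds_offset_of(gene, pos0)
    if offset is None:
        return CodingEffect(gene.gene_id, NONCODING)

    p0 = gene.cds_parts[0][2]
    if offset < p0:
        return CodingEffect(gene.gene_id, SPLICE_UNKNOWN, cds_offset=offset)
    coding = spliced_cds(gene, genome)[p0:]
    codon_index = (offset - p0) // 3
    within = (offset - p0) % 3
    ref_codon = coding[codon_index * 3: codon_index * 3 + 3]
    if len(ref_codon) < 3:
        return CodingEffect(gene.gene_id, SPLICE_UNKNOWN, cds_offset=offset,
                            codon_index=codon_index)
    alt_base = alt if gene.strand == "+" else revcomp(alt)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        klass = SYNONYMOUS
    elif alt_aa == "*":
        klass = STOP_GAINED
    elif ref_aa == "*":
        klass = STOP_LOST
    else:
        klass = NONSYNONYMOUS
    return CodingEffect(gene.gene_id, klass, cds_offset=offset,
                        codon_index=codon_index, ref_codon=ref_codon,
                        alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa)


def _genes_containing(genes: list[GeneModel], chrom: str, pos0: int
                      ) -> list[GeneModel]:
    return [g for g in genes if g.chrom == chrom and g.contains(pos0)]


def annotate_variants(stats: pd.DataFrame, genes: list[GeneModel],
                      genomes: dict[str, GenomeSequence]) -> pd.DataFrame:
    """One row per (variant, overlapping gene) with the coding-effect call;
    variants outside every gene get gene = NA, klass = noncoding."""
    rows = []
    for row in stats.itertuples(index=False):
        hits = _genes_containing(genes, row.chrom, row.pos)
        if not hits:
            rows.append({**row._asdict(), "gene": None, "klass": NONCODING,
                         "ref_aa": None, "alt_aa": None, "in_cds": False})
            continue
        for g in hits:
            eff = annotate_coding_effect(row.chrom, row.pos, row.ref, row.alt,
                                         g, genomes[row.chrom])
            rows.append({**row._asdict(), "gene": g.gene_id, "klass": eff.klass,
                         "ref_aa": eff.ref_aa, "alt_aa": eff.alt_aa,
                         "in_cds": eff.cds_offset is not None
                         or eff.klass in (FRAMESHIFT, INFRAME_INDEL)})
    if not rows:
        cols = list(stats.columns) + ["gene", "klass", "ref_aa", "alt_aa", "in_cds"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def triage_snvs(stats: pd.DataFrame, config: TriageConfig,
                genes: list[GeneModel] | None = None,
                genomes: dict[str, GenomeSequence] | None = None
                ) -> pd.DataFrame:
    """Retain highly differentiated variants.

    Keeps rows with fst > fst_min, and maf_alk < maf_alk_max when that bound
    is set. With ``restrict_to_genes`` only variants inside the listed genes'
    spans survive; with ``require_cds`` only variants whose effect call is
    CDS-level. The output carries Fst, MAF_ALK and delta-H (the triage-plot
    axes) plus per-gene effect calls when gene models are supplied.
    """
    if config.restrict_to_genes is not None and not config.restrict_to_genes:
        raise ValueError("restrict_to_genes set but empty")
    need_genes = config.require_cds or config.restrict_to_genes is not None
    if need_genes and not genes:
        raise ValueError("this triage configuration needs gene models")

    fst = stats["fst"].to_numpy(dtype=float)
    keep = np.isfinite(fst) & (fst > config.fst_min)
    if config.maf_alk_max is not None:
        maf = stats["maf_alk"].to_numpy(dtype=float)
        keep &= np.isfinite(maf) & (maf < config.maf_alk_max)
    out = stats.loc[keep].copy()

    if genes and genomes:
        out = annotate_variants(out, genes, genomes)
        if config.restrict_to_genes is not None:
            out = out[out["gene"].isin(config.restrict_to_genes)]
        if config.require_cds:
            out = out[out["in_cds"]]
    return out.reset_index(drop=True)


def summarize_gene_snvs(gene_ids: list[str], stats: pd.DataFrame,
                        genes: list[GeneModel],
                        genomes: dict[str, GenomeSequence]
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All variants within each listed gene's span, with stats and effect
    calls, plus per-gene counts by effect class."""
    by_id = {g.gene_id: g for g in genes}
    unknown = [g for g in gene_ids if g not in by_id]
    if unknown:
        raise ValueError(f"unknown gene ids: {unknown}")
    wanted = [by_id[g] for g in gene_ids]
    annotated = annotate_variants(stats, wanted, genomes)
    annotated = annotated[annotated["gene"].isin(gene_ids)]
    counts = (annotated.groupby(["gene", "klass"]).size()
              .unstack(fill_value=0).reindex(gene_ids, fill_value=0)
              .reset_index())
    return annotated.reset_index(drop=True), counts
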