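"""Cross-species convergent amino-acid substitution detection.

Given a protein multiple alignment containing the focal alkaline (ALK) and
freshwater (FW) population consensus sequences alongside independently
alkaline-adapted species and freshwater reference species, a column is

  differentiating  — the two focal residues differ (both non-gap);
  convergent       — additionally at least one alkaline-adapted species
                     carries the focal ALK residue while every non-gap
                     freshwater reference carries the focal FW residue.

The strict all-freshwater-consistent rule reflects that a freshwater species
sharing the derived residue would undercut the convergence interpretation; a
majority-rule relaxation is available as a switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import ALK, GeneModel, GenomeSequence, GenotypeTable
from .effects import revcomp, spliced_cds

log = logging.getLogger(__name__)

FOCAL_ALK = "FOCAL_ALK"
FOCAL_FW = "FOCAL_FW"
ALKALINE_ADAPTED = "ALKALINE_ADAPTED"
FRESHWATER_REF = "FRESHWATER_REF"

GAP = "-"


@dataclass
class ConvergentSite:
    column: int                     # 1-based alignment column
    focal_alk_aa: str
    focal_fw_aa: str
    supporting_species: list[str] = field(default_factory=list)
    freshwater_consistent: bool = False

    @property
    def status(self) -> str:
        return "convergent" if self.is_convergent else "differentiating"

    @property
    def is_convergent(self) -> bool:
        return bool(self.supporting_species) and self.freshwater_consistent

    @property
    def substitution(self) -> str:
        """FW residue -> ALK residue, printed 'X-Y'."""
        return f"{self.focal_fw_aa}-{self.focal_alk_aa}"


def validate_roles(names: list[str], roles: dict[str, str]) -> None:
    missing = [n for n in names if n not in roles]
    if missing:
        raise ValueError(f"alignment sequences without a role: {missing}")
    counts = pd.Series(list(roles.values())).value_counts()
    if counts.get(FOCAL_ALK, 0) != 1 or counts.get(FOCAL_FW, 0) != 1:
        raise ValueError("need exactly one FOCAL_ALK and one FOCAL_FW sequence")
    for role in (ALKALINE_ADAPTED, FRESHWATER_REF):
        if counts.get(role, 0) < 1:
            raise ValueError(f"need at least one {role} sequence")


def detect_convergent_sites(alignment: dict[str, str], roles: dict[str, str],
                            freshwater_majority: bool = False
                            ) -> list[ConvergentSite]:
    """Scan alignment columns for differentiating and convergent sites.

    ``alignment`` maps sequence name -> aligned residues (equal lengths).
    Columns where either focal sequence is gapped are skipped; gapped
    non-focal species simply drop out of the tests they would enter.
    The result is independent of row order and naming.
    """
    validate_roles(list(alignment), roles)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    focal_alk = next(n for n, r in roles.items() if r == FOCAL_ALK)
    focal_fw = next(n for n, r in roles.items() if r == FOCAL_FW)
    alk_species = sorted(n for n, r in roles.items() if r == ALKALINE_ADAPTED)
    fw_species = sorted(n for n, r in roles.items() if r == FRESHWATER_REF)

    sites: list[ConvergentSite] = []
    for col in range(lengths.pop() if lengths else 0):
        aa_alk = alignment[focal_alk][col].upper()
        aa_fw = alignment[focal_fw][col].upper()
        if GAP in (aa_alk, aa_fw) or aa_alk == aa_fw:
            continue
        supporting = [sp for sp in alk_species
                      if alignment[sp][col].upper() == aa_alk]
        fw_res = [alignment[sp][col].upper() for sp in fw_species
                  if alignment[sp][col].upper() != GAP]
        if freshwater_majority:
            consistent = bool(fw_res) and (
                sum(r == aa_fw for r in fw_res) * 2 > len(fw_res))
        else:
            consistent = bool(fw_res) and all(r == aa_fw for r in fw_res)
        sites.append(ConvergentSite(
            column=col + 1, focal_alk_aa=aa_alk, focal_fw_aa=aa_fw,
            supporting_species=supporting if consistent else supporting,
            freshwater_consistent=consistent,
        ))
    return sites


def report_convergence(sites: list[ConvergentSite],
                       gene_id: str | None = None,
                       cds_parts: list[tuple[int, int, int]] | None = None
                       ) -> dict:
    """Per-gene convergence report: counts plus per-column details."""
    convergent = [s for s in sites if s.is_convergent]
    report = {
        "gene": gene_id,
        "n_differentiating": len(sites),
        "n_convergent": len(convergent),
        "columns": [{
            "column": s.column,
            "substitution": s.substitution,
            "status": s.status,
            "supporting_species": s.supporting_species if s.is_convergent else [],
        } for s in sites],
    }
    if cds_parts:
        # map codon index -> exon ordinal (1-based, transcription order)
        bounds = np.cumsum([e - s for s, e, _ in cds_parts])
        for entry, s in zip(report["columns"], sites):
            off = (s.column - 1) * 3
            entry["exon"] = int(np.searchsorted(bounds, off, side="right") + 1)
    return report


def major_allele_dosage(table: GenotypeTable, label: str) -> np.ndarray:
    """Per-site population-major allele (0 = ref, 1 = alt); exact 50/50 ties
    resolve to the reference allele (logged)."""
    d = table.pop_dosage(label)
    called = d >= 0
    alt = np.where(called, d, 0).sum(axis=1)
    tot = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / tot, 0.0)
    ties = (tot > 0) & (alt * 2 == tot)
    if ties.any():
        log.info("%d exact 50/50 sites resolved to the reference allele in %s",
                 int(ties.sum()), label)
    return (p > 0.5).astype(int)


def build_population_consensus(gene: GeneModel, genome: GenomeSequence,
                               table: GenotypeTable,
                               site_mask: np.ndarray | None = None
                               ) -> dict[str, str]:
    """Translate the gene CDS with each population's major SNP allele applied.

    Only SNPs inside the CDS are applied (indels would need realignment).
    Returns {'ALK': protein, 'FW': protein}; a premature stop truncates the
    protein with a warning.
    """
    from .effects import cds_offset_of

    usable = table.is_snp & (table.chrom == gene.chrom)
    if site_mask is not None:
        usable = usable & site_mask
    idx = np.flatnonzero(usable)
    p0 = gene.cds_parts[0][2]
    base = spliced_cds(gene, genome)
    proteins = {}
    for label in ("ALK", "FW"):
        major = major_allele_dosage(table, label)
        cds = list(base)
        for i in idx:
            off = cds_offset_of(gene, int(table.pos[i]))
            if off is None or major[i] == 0:
                continue
            alt = table.alt[i]
            cds[off] = alt if gene.strand == "+" else revcomp(alt)
        prot = str(Seq("".join(cds)[p0:]).translate())
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            log.warning("gene %s: premature stop in %s consensus; truncated",
                        gene.gene_id, label)
            prot = prot.split("*")[0]
        proteins[label if label == ALK else "FW"] = prot
    return proteins
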