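"""Core in-memory data model shared by every pipeline stage.

Coordinates are 0-based half-open everywhere inside the package; the VCF/GFF3
1-based convention is converted exactly once, at parse time (and back once, at
write time). Genotypes are stored as an alt-allele dosage matrix: for a diploid
biallelic call the dosage (0/1/2) fully determines the genotype, and -1 marks a
missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

ALK = "ALK"
FW = "FW"

MISSING = -1


@dataclass
class GenomeSequence:
    """A single chromosome: name plus an uppercase A/C/G/T/N residue string."""

    name: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A protein-coding gene reduced to one transcript's CDS chain.

    ``cds_parts`` are (start, end, phase) triples in 0-based half-open genomic
    coordinates, ordered in transcription order: ascending start on the plus
    strand, descending on the minus strand. ``gene_span`` covers all parts.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_parts: list[tuple[int, int, int]]
    gene_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.cds_parts:
            raise ValueError(f"{self.gene_id}: no CDS parts")
        for s, e, ph in self.cds_parts:
            if ph not in (0, 1, 2):
                raise ValueError(f"{self.gene_id}: bad phase {ph}")
            if not (self.gene_span[0] <= s < e <= self.gene_span[1]):
                raise ValueError(f"{self.gene_id}: CDS part outside gene span")
        starts = [p[0] for p in self.cds_parts]
        expect = sorted(starts, reverse=self.strand == "-")
        if starts != expect:
            raise ValueError(f"{self.gene_id}: CDS parts not in transcription order")
        if self.cds_length < 3:
            raise ValueError(f"{self.gene_id}: CDS shorter than one codon")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds_parts)

    def contains(self, pos0: int) -> bool:
        return self.gene_span[0] <= pos0 < self.gene_span[1]

    def cds_part_at(self, pos0: int) -> int | None:
        """Index (in transcription order) of the CDS part containing pos0."""
        for i, (s, e, _) in enumerate(self.cds_parts):
            if s <= pos0 < e:
                return i
        return None


@dataclass
class PopulationMap:
    """sample -> population label; exactly the two labels ALK and FW."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        extra = labels - {ALK, FW}
        if extra:
            raise ValueError(f"unknown population labels: {sorted(extra)}")
        for lab in (ALK, FW):
            if lab not in labels:
                raise ValueError(f"population {lab} has no samples")

    def samples(self, label: str) -> list[str]:
        return [s for s, l in self.assignments.items() if l == label]


@dataclass
class GenotypeTable:
    """Per-site diploid genotypes for the two populations.

    ``dosage`` is an int8 (n_sites, n_samples) matrix of alt-allele counts per
    diploid genotype, MISSING (-1) for uncalled. Sites are sorted by
    (chrom, pos). ``pos`` is 0-based.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    is_snp: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    popmap: PopulationMap

    alk_cols: np.ndarray = field(init=False)
    fw_cols: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        unmapped = [s for s in self.samples if s not in self.popmap.assignments]
        if unmapped:
            raise ValueError(f"samples not in population map: {unmapped}")
        labels = np.array([self.popmap.assignments[s] for s in self.samples])
        self.alk_cols = np.flatnonzero(labels == ALK)
        self.fw_cols = np.flatnonzero(labels == FW)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def pop_dosage(self, label: str) -> np.ndarray:
        cols = self.alk_cols if label == ALK else self.fw_cols
        return self.dosage[:, cols]

    def subset(self, mask_or_index) -> "GenotypeTable":
        return GenotypeTable(
            chrom=self.chrom[mask_or_index],
            pos=self.pos[mask_or_index],
            ref=self.ref[mask_or_index],
            alt=self.alt[mask_or_index],
            is_snp=self.is_snp[mask_or_index],
            dosage=self.dosage[mask_or_index],
            samples=self.samples,
            popmap=self.popmap,
        )


@dataclass
class ScanConfig:
    window_bp: int = 20_000
    step_bp: int = 10_000
    fine_window_bp: int = 10_000
    top_fraction: float = 0.01
    fst_min: float | None = None          # fixed-threshold override
    abs_log2_ratio_min: float | None = None
    one_sided_alk_depleted: bool = False
    merge_gap_bp: int = 0

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must be <= window_bp")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")


@dataclass
class TriageConfig:
    """Highly-differentiated SNV filter.

    Preset A reproduces the strict genome-wide rule (Fst > 0.9 and
    MAF_ALK < 0.1); preset B the within-CDS rule (Fst > 0.8, CDS required).
    Inequalities are strict, as printed.
    """

    fst_min: float = 0.9
    maf_alk_max: float | None = 0.1
    require_cds: bool = False
    restrict_to_genes: list[str] | None = None

    @classmethod
    def preset_a(cls, restrict_to_genes: list[str] | None = None) -> "TriageConfig":
        return cls(fst_min=0.9, maf_alk_max=0.1, require_cds=False,
                   restrict_to_genes=restrict_to_genes)

    @classmethod
    def preset_b(cls, restrict_to_genes: list[str] | None = None) -> "TriageConfig":
        return cls(fst_min=0.8, maf_alk_max=None, require_cds=True,
                   restrict_to_genes=restrict_to_genes)
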