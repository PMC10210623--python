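"""Truth-annotated synthetic fixture generator.

Emulates the two-population contrast the scan assumes: a small diploid
genome, background allele-frequency divergence under the Balding–Nichols
model (population frequencies Beta-distributed around a shared ancestral
frequency with concentration (1-F)/F), planted sweep intervals where the
alkaline population's frequencies are drawn at an elevated F and pushed
toward fixation (reduced diversity, elevated differentiation), planted
fixed-difference coding variants in designated genes, and a toy ortholog
protein alignment with planted differentiating and convergent columns.

Sites are independent — no linkage is simulated; windows aggregate
independent sites. All randomness flows from one seed through named
SeedSequence spawns, so fixtures are reproducible piecewise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .model import ALK, FW, MISSING, GeneModel, GenomeSequence, GenotypeTable, PopulationMap
from .effects import annotate_coding_effect, revcomp, spliced_cds, NONSYNONYMOUS, SYNONYMOUS
from . import io as gio

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}

CA15_LIKE = "ca15_like"
RHCG_LIKE = "rhcg_like"


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic two-population fixture."""

    n_chrom: int = 2
    chrom_len_bp: int = 500_000
    snp_density: float = 1 / 200
    n_alk: int = 30
    n_fw: int = 30
    background_F: float = 0.05
    sweep_F: float = 0.6
    sweeps_per_chrom: int = 2
    sweep_len_bp: int = 40_000
    alk_diversity_factor: float = 0.1
    missing_rate: float = 0.02
    n_genes: int = 20
    gene_span_bp: int = 3_000
    n_nonsyn_ca15: int = 5
    n_syn_ca15: int = 1
    n_indel_ca15: int = 2
    n_nonsyn_rhcg: int = 5
    n_negative_controls: int = 2
    n_diff_columns: int = 7
    n_convergent_columns: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_density", "background_F", "sweep_F",
                     "alk_diversity_factor", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_convergent_columns > self.n_diff_columns:
            raise ValueError("cannot plant more convergent than differentiating columns")
        total_sweep = self.sweeps_per_chrom * self.sweep_len_bp
        if total_sweep >= self.chrom_len_bp:
            raise ValueError("sweep intervals exceed chromosome length")


@dataclass
class PlantedVariant:
    chrom: str
    pos: int                    # 0-based
    ref: str
    alt: str
    gene: str
    klass: str
    pass_preset_a: bool
    pass_preset_b: bool
    is_negative_control: bool = False


@dataclass
class Fixture:
    """In-memory fixture set plus the truth manifest."""

    config: SimConfig
    genomes: dict[str, GenomeSequence]
    genes: list[GeneModel]
    popmap: PopulationMap
    table: GenotypeTable
    frequencies: pd.DataFrame
    planted: list[PlantedVariant]
    alignment: dict[str, str]
    roles: dict[str, str]
    manifest: dict = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: g.length for name, g in self.genomes.items()}


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ["genome", "plant", "freqs", "genotypes", "ortholog"]
    seqs = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, seqs)}


def sweep_intervals(cfg: SimConfig) -> dict[str, list[tuple[int, int]]]:
    """Fixed, deterministic sweep placement: evenly spaced interval starts."""
    out = {}
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        gap = cfg.chrom_len_bp // (cfg.sweeps_per_chrom + 1)
        out[chrom] = [(k * gap, k * gap + cfg.sweep_len_bp)
                      for k in range(1, cfg.sweeps_per_chrom + 1)]
    return out


def _stop_free_cds(length: int, rng: np.random.Generator) -> str:
    """Random coding sequence of the given length with no internal stops."""
    assert length % 3 == 0
    codons = []
    while len(codons) < length // 3:
        c = "".join(rng.choice(BASES, 3))
        if c not in STOPS:
            codons.append(c)
    return "".join(codons)


def _gene_layout(cfg: SimConfig, sweeps: dict[str, list[tuple[int, int]]]
                 ) -> list[GeneModel]:
    """Evenly spaced three-exon genes, alternating strand; the two designated
    genes are placed outside sweep intervals so their planted variants sit on
    a neutral background."""
    per_chrom = cfg.n_genes // cfg.n_chrom
    rel_parts = [(0, 301), (800, 1401), (2200, 2801)]  # 301+601+601 = 1503
    phases = [0, 2, 1]
    genes: list[GeneModel] = []
    designated = [CA15_LIKE, RHCG_LIKE]
    gid = 0
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        step = cfg.chrom_len_bp // (per_chrom + 1)
        for k in range(per_chrom):
            start = (k + 1) * step - cfg.gene_span_bp // 2
            end = start + cfg.gene_span_bp
            in_sweep = any(start < e and end > s for s, e in sweeps[chrom])
            if designated and not in_sweep:
                gene_id = designated.pop(0)
            else:
                gid += 1
                gene_id = f"gene{gid:03d}"
            strand = "+" if k % 2 == 0 else "-"
            parts = [(start + s, start + e) for s, e in rel_parts]
            if strand == "-":
                parts = parts[::-1]
            cds = [(s, e, ph) for (s, e), ph in zip(parts, phases)]
            genes.append(GeneModel(gene_id, chrom, strand, cds, (start, end)))
    return genes


def _write_genome(cfg: SimConfig, genes: list[GeneModel],
                  rng: np.random.Generator) -> dict[str, GenomeSequence]:
    genomes = {}
    arrays = {f"chr{c + 1}": rng.choice(BASES, cfg.chrom_len_bp)
              for c in range(cfg.n_chrom)}
    for gene in genes:
        arr = arrays[gene.chrom]
        coding = _stop_free_cds(gene.cds_length, rng)
        off = 0
        for s, e, _ in gene.cds_parts:
            chunk = coding[off:off + (e - s)]
            if gene.strand == "-":
                chunk = revcomp(chunk)
            arr[s:e] = list(chunk)
            off += e - s
    for name, arr in arrays.items():
        genomes[name] = GenomeSequence(name, "".join(arr))
    return genomes


def balding_nichols(p_anc: np.ndarray, F: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Population frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F); the F -> 0
    limit degenerates to the ancestral frequency itself."""
    if F <= 0:
        return p_anc.copy()
    conc = (1 - F) / F
    return rng.beta(p_anc * conc, (1 - p_anc) * conc)


def _push_to_fixation(p: np.ndarray, factor: float) -> np.ndarray:
    """Shrink the distance to the nearest fixed state by ``factor`` —
    heterozygosity scales roughly linearly with the factor."""
    return np.where(p <= 0.5, p * factor, 1 - (1 - p) * factor)


def simulate_site_frequencies(cfg: SimConfig, rng: np.random.Generator,
                              positions: dict[str, np.ndarray],
                              sweeps: dict[str, list[tuple[int, int]]]
                              ) -> pd.DataFrame:
    """Per-site (p_anc, p_alk, p_fw) under Balding–Nichols divergence; inside
    sweep intervals ALK is drawn at sweep_F and pushed toward fixation."""
    frames = []
    for chrom, pos in positions.items():
        n = len(pos)
        p_anc = rng.uniform(0.05, 0.95, n)
        in_sweep = np.zeros(n, dtype=bool)
        for s, e in sweeps.get(chrom, []):
            in_sweep |= (pos >= s) & (pos < e)
        p_fw = balding_nichols(p_anc, cfg.background_F, rng)
        p_alk = balding_nichols(p_anc, cfg.background_F, rng)
        alk_sweep = _push_to_fixation(
            balding_nichols(p_anc, cfg.sweep_F, rng), cfg.alk_diversity_factor)
        p_alk = np.where(in_sweep, alk_sweep, p_alk)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "p_anc": p_anc,
            "p_alk": np.clip(p_alk, 0.001, 0.999),
            "p_fw": np.clip(p_fw, 0.001, 0.999),
            "in_sweep": in_sweep,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_genotypes(freqs: pd.DataFrame, cfg: SimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Diploid dosages ~ Binomial(2, p_pop) per sample, with per-genotype
    missingness; columns are [ALK samples..., FW samples...]."""
    n_sites = len(freqs)
    d_alk = rng.binomial(2, freqs["p_alk"].to_numpy()[:, None],
                         (n_sites, cfg.n_alk))
    d_fw = rng.binomial(2, freqs["p_fw"].to_numpy()[:, None],
                        (n_sites, cfg.n_fw))
    dosage = np.concatenate([d_alk, d_fw], axis=1).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = MISSING
    return dosage


def _mutate_base(ref: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(len(choices))]


def plant_coding_variants(cfg: SimConfig, genomes: dict[str, GenomeSequence],
                          genes: list[GeneModel], rng: np.random.Generator
                          ) -> list[PlantedVariant]:
    """Choose CDS positions whose alt allele yields the requested effect
    class (verified through the effect annotator) in the designated genes.

    Pass-by-construction sites are written with deterministic genotypes (ALK
    fixed alt, FW fixed ref) so the manifest exactly determines triage;
    negative controls sit at 0.5/0.5.
    """
    by_id = {g.gene_id: g for g in genes}
    planted: list[PlantedVariant] = []
    used_codons: dict[str, set[int]] = {CA15_LIKE: set(), RHCG_LIKE: set()}

    def plant_snp(gene_id: str, klass: str, negative: bool = False) -> None:
        gene = by_id[gene_id]
        genome = genomes[gene.chrom]
        cds_pos = np.concatenate([np.arange(s, e) for s, e, _ in gene.cds_parts])
        for _ in range(2000):
            pos = int(rng.choice(cds_pos))
            ref = genome.residues[pos]
            alt = _mutate_base(ref, rng)
            eff = annotate_coding_effect(gene.chrom, pos, ref, alt, gene, genome)
            if eff.klass != klass or eff.codon_index in used_codons[gene_id]:
                continue
            used_codons[gene_id].add(eff.codon_index)
            planted.append(PlantedVariant(
                gene.chrom, pos, ref, alt, gene_id, klass,
                pass_preset_a=not negative, pass_preset_b=not negative,
                is_negative_control=negative))
            return
        raise RuntimeError(f"could not plant a {klass} SNP in {gene_id}")

    for _ in range(cfg.n_nonsyn_ca15):
        plant_snp(CA15_LIKE, NONSYNONYMOUS)
    for _ in range(cfg.n_syn_ca15):
        plant_snp(CA15_LIKE, SYNONYMOUS)
    for _ in range(cfg.n_nonsyn_rhcg):
        plant_snp(RHCG_LIKE, NONSYNONYMOUS)
    for i in range(cfg.n_negative_controls):
        plant_snp(CA15_LIKE if i % 2 == 0 else RHCG_LIKE, NONSYNONYMOUS,
                  negative=True)

    # fixed-difference indels in the ca15-like gene: one CDS frameshift
    # (passes preset A, not B's CDS-SNP question but it is in CDS) and one
    # intronic deletion.
    gene = by_id[CA15_LIKE]
    genome = genomes[gene.chrom]
    if cfg.n_indel_ca15 >= 1:
        s, e, _ = gene.cds_parts[0]
        lo, hi = sorted((s, e))
        pos = int(rng.integers(lo + 3, hi - 6))
        ref = genome.residues[pos:pos + 3]
        planted.append(PlantedVariant(gene.chrom, pos, ref, ref[0], CA15_LIKE,
                                      "frameshift", True, False))
    if cfg.n_indel_ca15 >= 2:
        spans = sorted((s, e) for s, e, _ in gene.cds_parts)
        intron_lo, intron_hi = spans[0][1] + 5, spans[1][0] - 5
        pos = int(rng.integers(intron_lo, intron_hi - 3))
        ref = genome.residues[pos:pos + 2]
        planted.append(PlantedVariant(gene.chrom, pos, ref, ref[0], CA15_LIKE,
                                      "noncoding", True, False))
    return planted


def _planted_dosage(pv: PlantedVariant, cfg: SimConfig) -> np.ndarray:
    if pv.is_negative_control:
        return np.ones(cfg.n_alk + cfg.n_fw, dtype=np.int8)  # p = 0.5 both
    return np.concatenate([np.full(cfg.n_alk, 2, dtype=np.int8),
                           np.zeros(cfg.n_fw, dtype=np.int8)])


def build_ortholog_fixture(cfg: SimConfig, rng: np.random.Generator,
                           base_protein: str,
                           planted_columns: list[tuple[int, str, str]]
                           ) -> tuple[dict[str, str], dict[str, str], dict]:
    """Aligned protein FASTA with planted differentiating/convergent columns.

    ``planted_columns`` are (0-based column, fw_aa, alk_aa) from the planted
    nonsynonymous variants; extra random columns are added up to
    ``n_diff_columns``. Of these, ``n_convergent_columns`` get alkaline-
    adapted supporters while every freshwater reference keeps the FW residue.
    """
    from .convergence import FOCAL_ALK, FOCAL_FW, ALKALINE_ADAPTED, FRESHWATER_REF

    aa_pool = list("ARNDCQEGHILKMFPSTWYV")
    cols = {c: (fw, alk) for c, fw, alk in planted_columns}
    while len(cols) < cfg.n_diff_columns:
        c = int(rng.integers(len(base_protein)))
        if c in cols:
            continue
        fw = base_protein[c]
        alk = aa_pool[int(rng.integers(len(aa_pool)))]
        if alk != fw:
            cols[c] = (fw, alk)
    diff_cols = sorted(cols)[:cfg.n_diff_columns]
    conv_cols = [int(c) for c in
                 rng.choice(diff_cols, cfg.n_convergent_columns, replace=False)]

    def with_subs(subs: dict[int, str]) -> str:
        s = list(base_protein)
        for c, aa in subs.items():
            s[c] = aa
        return "".join(s)

    focal_alk = with_subs({c: cols[c][1] for c in diff_cols})
    names_alk = ["alk_adapted_sp1", "alk_adapted_sp2", "alk_adapted_sp3"]
    names_fw = ["freshwater_ref1", "freshwater_ref2"]
    # convergence pattern mirroring one species sharing both sites and a
    # second sharing one
    support: dict[int, list[str]] = {}
    for i, c in enumerate(conv_cols):
        support[c] = names_alk[:2] if i == 0 else names_alk[:1]

    alignment = {"focal_alk_consensus": focal_alk,
                 "focal_fw_consensus": base_protein}
    for name in names_alk:
        subs = {c: cols[c][1] for c, who in support.items() if name in who}
        seq = list(with_subs(subs))
        for _ in range(3):  # neutral species-private noise off the planted set
            c = int(rng.integers(len(seq)))
            if c not in cols:
                seq[c] = aa_pool[int(rng.integers(len(aa_pool)))]
        alignment[name] = "".join(seq)
    for name in names_fw:
        alignment[name] = base_protein

    roles = {"focal_alk_consensus": FOCAL_ALK, "focal_fw_consensus": FOCAL_FW}
    roles.update({n: ALKALINE_ADAPTED for n in names_alk})
    roles.update({n: FRESHWATER_REF for n in names_fw})
    truth = {
        "differentiating_columns": [c + 1 for c in diff_cols],
        "convergent_columns": {str(c + 1): sorted(support[c])
                               for c in sorted(support)},
    }
    return alignment, roles, truth


def generate_fixture(cfg: SimConfig, outdir: str | Path | None = None
                     ) -> Fixture:
    """Build the full fixture set; optionally write it to a directory as
    genome.fa / genes.gff3 / variants.vcf / popmap.tsv / ortholog.aln.fa /
    roles.tsv / truth.json / sites.tsv."""
    rngs = _rngs(cfg.seed)
    sweeps = sweep_intervals(cfg)
    genes = _gene_layout(cfg, sweeps)
    genomes = _write_genome(cfg, genes, rngs["genome"])
    planted = plant_coding_variants(cfg, genomes, genes, rngs["plant"])
    planted_pos = {(p.chrom, p.pos) for p in planted}

    positions = {}
    n_sites = int(cfg.chrom_len_bp * cfg.snp_density)
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        pos = rngs["freqs"].choice(cfg.chrom_len_bp, n_sites, replace=False)
        pos = np.sort(pos)
        pos = pos[[int(p) not in {q for ch, q in planted_pos if ch == chrom}
                   for p in pos]]
        positions[chrom] = pos
    freqs = simulate_site_frequencies(cfg, rngs["freqs"], positions, sweeps)
    dosage = simulate_genotypes(freqs, cfg, rngs["genotypes"])

    samples = ([f"ALK_{i + 1:02d}" for i in range(cfg.n_alk)]
               + [f"FW_{i + 1:02d}" for i in range(cfg.n_fw)])
    popmap = PopulationMap({s: (ALK if s.startswith("ALK") else FW)
                            for s in samples})

    rows = []
    for i, row in enumerate(freqs.itertuples(index=False)):
        genome = genomes[row.chrom]
        ref = genome.residues[row.pos]
        rows.append((row.chrom, int(row.pos), ref,
                     _mutate_base(ref, rngs["genotypes"]), dosage[i]))
    for pv in planted:
        rows.append((pv.chrom, pv.pos, pv.ref, pv.alt, _planted_dosage(pv, cfg)))
    rows.sort(key=lambda r: (r[0], r[1]))
    table = GenotypeTable(
        chrom=np.array([r[0] for r in rows], dtype=object),
        pos=np.array([r[1] for r in rows], dtype=np.int64),
        ref=np.array([r[2] for r in rows], dtype=object),
        alt=np.array([r[3] for r in rows], dtype=object),
        is_snp=np.array([len(r[2]) == 1 and len(r[3]) == 1 for r in rows]),
        dosage=np.vstack([r[4] for r in rows]),
        samples=samples,
        popmap=popmap,
    )

    # ortholog fixture seeded from the rhcg-like protein and its planted sites
    rhcg = next(g for g in genes if g.gene_id == RHCG_LIKE)
    genome = genomes[rhcg.chrom]
    p0 = rhcg.cds_parts[0][2]
    base_protein = str(Seq(spliced_cds(rhcg, genome)[p0:]).translate()).rstrip("*")
    planted_cols = []
    for pv in planted:
        if pv.gene == RHCG_LIKE and pv.klass == NONSYNONYMOUS and not pv.is_negative_control:
            eff = annotate_coding_effect(pv.chrom, pv.pos, pv.ref, pv.alt,
                                         rhcg, genome)
            planted_cols.append((eff.codon_index, eff.ref_aa, eff.alt_aa))
    alignment, roles, ortho_truth = build_ortholog_fixture(
        cfg, rngs["ortholog"], base_protein, planted_cols)

    genes_in_sweeps = sorted(
        g.gene_id for g in genes
        if any(g.gene_span[0] < e and g.gene_span[1] > s
               for s, e in sweeps[g.chrom]))
    manifest = {
        "config": asdict(cfg),
        "sweep_intervals": {c: [list(iv) for iv in ivs]
                            for c, ivs in sweeps.items()},
        "genes_in_sweeps": genes_in_sweeps,
        "designated_genes": [CA15_LIKE, RHCG_LIKE],
        "planted_variants": [asdict(p) for p in planted],
        "n_pass_preset_a": sum(p.pass_preset_a for p in planted),
        "n_pass_preset_b": sum(p.pass_preset_b and p.klass in
                               (NONSYNONYMOUS, SYNONYMOUS) for p in planted),
        "ortholog": ortho_truth,
    }
    fx = Fixture(cfg, genomes, genes, popmap, table, freqs, planted,
                 alignment, roles, manifest)
    if outdir is not None:
        write_fixture(fx, outdir)
    return fx


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.gene_span
            fh.write(f"{g.chrom}\t.\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\t.\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={mrna};Parent={g.gene_id}\n")
            for cs, ce, ph in sorted(g.cds_parts):
                fh.write(f"{g.chrom}\t.\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t"
                         f"{ph}\tID={mrna}.cds;Parent={mrna}\n")


def write_fixture(fx: Fixture, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_fasta(list(fx.genomes.values()), out / "genome.fa")
    write_gff3(fx.genes, out / "genes.gff3")
    gio.write_vcf(fx.table, out / "variants.vcf",
                  contig_lengths=fx.chrom_lengths)
    with open(out / "popmap.tsv", "w") as fh:
        for s in fx.table.samples:
            fh.write(f"{s}\t{fx.popmap.assignments[s]}\n")
    with open(out / "ortholog.aln.fa", "w") as fh:
        for name, seq in fx.alignment.items():
            fh.write(f">{name}\n{seq}\n")
    with open(out / "roles.tsv", "w") as fh:
        for name, role in fx.roles.items():
            fh.write(f"{name}\t{role}\n")
    gio.write_tsv(fx.frequencies, out / "sites.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(fx.manifest, fh, indent=2)
        fh.write("\n")
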