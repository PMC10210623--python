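# Methods

## The scientific setting

The package implements a two-population selective-sweep discovery procedure
for the contrast between an alkaline-adapted population (ALK) and a pooled
freshwater population (FW) of the same fish species. Selection for survival
in a highly alkaline lake is expected to leave three joint signatures in the
alkaline population's genome: locally elevated allele-frequency
differentiation (Fst), locally depressed nucleotide diversity (a low
π_ALK/π_FW ratio), and a skew toward rare variants (negative Tajima's D).
The pipeline scans for these signatures in sliding windows, triages
individual highly differentiated variants, annotates their protein-coding
consequences, and asks whether the alkaline population's derived amino acids
recur in independently alkaline-adapted species (convergence).

## Estimators

**Site Fst.** Weir & Cockerham's (1984) variance-components estimator for
two populations, θ̂ = a/(a+b+c), computed from per-population sample sizes,
allele frequencies and *observed* heterozygote counts. This is the estimator
the standard VCF toolchain (vcftools) implements, which is why it was chosen
over alternatives (Hudson's, Nei's G_ST); the source analysis does not name
its estimator. Sites with fewer than two called diploids in either
population, or monomorphic across both, propagate NA.

**Windowed Fst.** The ratio of sums Σa / Σ(a+b+c) over the sites in a
window — the multilocus weighted estimator Weir & Cockerham prescribe for
aggregating loci. The alternative (mean of per-site ratios) is a biased
aggregate: on Balding–Nichols simulations with 30+30 diploids it
underestimates a true F of 0.2 by about 0.05, while the ratio of sums
recovers 0.02 / 0.05 / 0.2 within ±0.01 (the parameter-recovery test pins
this down). The same choice applies wherever a multi-site Fst is reported.

**Nucleotide diversity.** Per site, the unbiased pairwise estimator
2p(1−p)·n/(n−1) with n the called chromosomes; per window, the sum over
sites divided by the *full window span* in bp (the `--window-pi`
convention), not by callable sites. The window π-ratio is reported as
log2(π_ALK/π_FW); when either side is exactly zero the zero is replaced by
the smallest nonzero per-bp window π observed in the run and the window is
flagged (`ratio_floored`), so the ratio remains finite and the flag keeps
such windows auditable.

**Tajima's D.** Tajima (1989): D = (π̂ − S/a₁)/√(e₁S + e₂S(S−1)) with the
standard constants computed from the sample size in chromosomes; π̂ here is
the *sum* of per-site π over the window (not per-bp). With missing data the
per-site sample size varies; the constants use the modal called-chromosome
count across the window's sites, and sites whose n deviates from the mode by
more than 20% are excluded from S and π̂. Windows with no segregating sites,
or modal n < 4, give NA.

**Diversity contrast.** The ALK-vs-FW diversity comparison is a paired
two-sided t-test on per-chromosome mean π (scipy's `ttest_rel`). Zero
variance of the paired differences is flagged degenerate rather than
returning a spurious P.

## Scan and region calling

Windows are 20 kb sliding by 10 kb (defaults; fine mapping uses 10 kb
non-overlapping windows with one window of padding on each side so edge
signals stay visible). Outliers are selected *by rank*: the top
⌈top_fraction·N⌉ windows by windowed Fst, and independently by |log2
π-ratio|, where N counts windows with a finite value for that criterion.
The reported threshold per criterion is the smallest selected value — this
reproduces how empirical cutoffs (e.g. "the 1% highest Fst, Fst > 0.476")
arise as outputs of a scan. Fixed thresholds can override rank selection;
a one-sided (ALK-depleted only) π-ratio mode is a switch. Selected windows
that overlap or are book-ended merge into candidate regions (merge gap 0 by
default); region criteria are the union over member windows and genes are
assigned by ≥1 bp overlap of the gene span with the region, half-open.

NA windows never enter percentile computations. Ranking ties break by
window order (stable sort), so output is deterministic byte for byte.

## SNV triage and coding effects

Triage preset A keeps variants with Fst > 0.9 **and** MAF_ALK < 0.1
(strict inequalities, as the rule is usually printed); preset B keeps
Fst > 0.8 within CDS. Triage can be restricted to a gene list — the
intended use mirrors a candidate-family analysis where all variants inside
a set of genes are scored first and the thresholds applied second. INDELs
participate in triage but receive frameshift/in-frame classes rather than
amino-acid substitutions.

Effect annotation maps a variant through the transcript's CDS chain
(minus-strand parts reverse-complemented; GFF3 phase trusted, with a logged
consistency check against the cumulative reading frame), rebuilds the
affected codon from the reference genome, substitutes the (strand-adjusted)
alternate base and translates both codons with the standard nuclear code.
Variants in a gene span but outside the CDS are `noncoding`; SNPs in an
incomplete terminal codon or before the frame start are `splice_unknown`;
indels whose changed bases cross a CDS boundary are `splice_unknown`. When
a variant hits several overlapping genes, one call per gene is emitted.
The long-route check — translating the entire mutant CDS and differencing
proteins — is kept in the test suite as an oracle, never as the
implementation.

## Convergence detection

The focal ALK and FW sequences are population consensus proteins: the
reference CDS with each population's major allele applied at every SNP
(exact 50/50 ties resolve to the reference and are logged), translated and
truncated at any premature stop with a warning. In the ortholog protein
alignment a column is *differentiating* when the two focal residues differ
(both non-gap), and *convergent* when additionally at least one
alkaline-adapted species carries the focal ALK residue while **every**
non-gap freshwater reference carries the focal FW residue. The strict
all-freshwater rule is deliberate — a freshwater species sharing the
derived residue would undercut a convergence interpretation — and a
majority-rule relaxation is available. Columns where a focal sequence is
gapped are skipped. Substitutions are printed "X-Y" (FW residue → ALK
residue). Detection is invariant to row order and renaming.

## The synthetic generator

The generator exists to give every stage a fixture with known truth, at the
statistical structure the scan assumes:

- **Geometry.** Two 500 kb chromosomes; two 40 kb sweep intervals per
  chromosome at deterministic positions; 20 three-exon genes (1,503 bp CDS,
  internal phases 0/2/1, alternating strands) evenly spaced; SNP density
  1/200 bp; 30+30 diploids; 2% missing genotypes.
- **Background divergence.** Balding–Nichols: ancestral frequencies
  uniform on (0.05, 0.95); population frequencies Beta-distributed around
  them with concentration (1−F)/F at F = 0.05. Frequencies are clipped to
  [0.001, 0.999] before binomial genotype sampling; realized-monomorphic
  sites are kept (they exercise the NA paths).
- **Sweeps.** Inside sweep intervals the ALK frequency is drawn at
  F = 0.6 and then pushed toward the nearest fixed state so its
  heterozygosity shrinks to ~10% of background (factor 0.1); FW stays at
  background F. Only ALK is perturbed — drifting FW as well would erase
  the π-ratio signal the interval is meant to plant.
- **Planted coding variants.** In two designated genes placed *outside*
  the sweeps ("ca15_like": 5 nonsynonymous + 1 synonymous SNPs + 2 indels;
  "rhcg_like": 5 nonsynonymous SNPs), positions and alternate alleles are
  chosen so the effect annotator verifies the requested class in a
  pre-check, one variant per codon. These sites get deterministic
  genotypes — ALK all alternate homozygotes, FW all reference, no
  missingness — so realized Fst is exactly 1 and MAF_ALK exactly 0, and the
  truth manifest *exactly* determines triage outcomes. Negative controls
  are planted all-heterozygous (p = 0.5 in both populations) and fail every
  preset. Placing the designated genes outside sweeps matters: sweep
  intervals produce near-fixed differences by design, so an exact-count
  triage check is meaningful only against the neutral background.
- **Ortholog alignment.** The rhcg-like reference protein is the base;
  the focal ALK sequence carries the planted substitutions plus extra
  random differentiating columns up to 7, of which 2 are made convergent:
  one alkaline-adapted species shares both derived residues, a second
  shares one, freshwater references keep the FW residue everywhere, and
  each non-focal species gets a little private noise at non-differentiating
  columns.
- **Reproducibility.** One seed feeds named `SeedSequence` spawns
  (genome / plant / freqs / genotypes / ortholog), so each stage's stream
  is stable even if another stage's draw count changes. Same seed ⇒
  byte-identical fixture files.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage (sites are independent, so windows
aggregate independent draws and real sweep-scan variance is higher),
realistic demography (no bottlenecks or expansions), mutation-rate
heterogeneity, genotyping error beyond uniform missingness, and a
coalescent site-frequency spectrum. The last point is why the neutral
Tajima's-D calibration does *not* use this generator: Balding–Nichols
frequencies have a near-flat spectrum and give strongly positive D
(≈ +2.2 at the defaults) by construction. Neutral-D behaviour is instead
checked on constant-size coalescent simulations (msprime), where our D and
π also agree with tskit's implementations to 1e-12 — an independent
dual-route check.

## Evaluation design

The sweep-scan operating characteristics are measured on the default
fixture over 10 seeds. The planted sweeps cover ~16% of the genome, so a
literal top-1% rank selection could select at most 1 of ~100 windows and no
sensitivity target would be measurable; the evaluation therefore sizes the
rank selection to the planted coverage fraction (top_fraction = swept
bp / genome bp, read off the truth manifest) — an ROC-style evaluation at
the true positive count. The *default* analysis `top_fraction` remains
0.01. Sensitivity counts windows fully contained in a planted interval;
precision counts selected windows overlapping one by ≥1 bp; threshold
separation requires the reported Fst cutoff to lie between the background
and planted windows' median scores.

Problem sizes used throughout (fixture: 1 Mb genome, ~5,000 sites, 60
diploids; oracle checks: 500 random ≤6-diploid instances; recovery: 6,000
sites per F; neutral D: 25–60 coalescent windows of 50 kb) were chosen so
the full suite exercises every code path at statistically meaningful scale.

## Numerical conventions

Internal coordinates are 0-based half-open everywhere; VCF/GFF3 1-based
coordinates are converted exactly once at parse time. NA is spelled "NA" in
TSV output and propagates through all estimators; multi-allelic VCF records
are recoded to reference plus the most frequent alternate (other alleles
become missing calls) with a switch to skip them instead — the reference
allele is always retained so reference-dependent annotation stays valid.
Site filtering (max missingness 0.2, minor-allele count, biallelic-only) is
configurable and entirely switchable-off. Per gene, the transcript with the
longest total CDS is used.

## Known limitations

- No LD-aware or haplotype-based sweep statistics (iHS/XP-EHH) — the scan
  is frequency-based only.
- The π-ratio pseudo-floor makes zero-diversity windows rankable but their
  magnitude is a convention; they are flagged for exactly this reason.
- Tajima's D with heavy, site-specific missingness reduces to a modal-n
  approximation; windows with very uneven calling are better interpreted
  via the excluded-site count.
- Convergence detection is alignment-based: it does not reconstruct
  ancestral states, so parallel retention of an ancestral residue and true
  convergence are not distinguished.
- UTR annotation classes are emitted only when the GFF3 contains UTR
  features; otherwise non-CDS genic variants are `noncoding`.
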