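# Methods

## Data model

The unit of analysis is a per-locus multiple alignment of diploid consensus
sequences obtained by direct Sanger resequencing: one sequence per
individual, heterozygous positions encoded as the six two-allele IUPAC codes
(R, Y, S, W, K, M). Three-allele codes (B, D, H, V) are rejected — a diploid
chromatogram cannot produce them. Each individual contributes two
chromosomes; all statistics are allele-frequency based, so no within-individual
phase and no Hardy–Weinberg assumption is needed anywhere.

Annotations (CDS with strand and frame, intron, UTR) are read from a GFF3
subset, 1-based inclusive externally and converted to 0-based half-open
internally; reported SNP positions are 1-based. Unannotated bases are
excluded from every statistic. Minus-strand ORFs are reverse-complemented for
codon work only.

**Missing data (complete deletion).** Any column containing `N` or `-` in any
retained individual is excluded from all statistics of that locus. Sample
size still varies across loci because whole individuals may be absent from an
alignment (direct sequencing stops at the first heterozygous indel, so real
surveys of this kind have variable per-locus panels). Within a locus the
per-column chromosome count n is therefore constant, which keeps columns
comparable; across loci n varies and every estimator uses the per-locus aₙ.
This is a choice: per-column (pairwise) deletion would retain slightly more
data at the cost of within-locus heterogeneity in n.

## Site counting and SNP effects

Synonymous and nonsynonymous site counts follow Nei–Gojobori (1986): each of
the nine single-base changes of a codon contributes 1/3 site to the class of
its effect; changes creating stop codons count as nonsynonymous. Counts are
evaluated on the per-codon **consensus codon** (majority base per column,
ties toward the alphabetically smaller base — a deterministic rule the data
format does not dictate). Codons containing an invalid column, and the rare
codons whose consensus is a stop, are dropped entirely, so that
syn + nonsyn sites = 3 × (usable codons) holds exactly.

SNPs in coding regions are synonymous iff the two codon variants translate
identically; intron/UTR SNPs are noncoding; synonymous + noncoding = silent.
For codons with two segregating positions the effect of each SNP is evaluated
along both mutational pathways (both background alleles at the other site);
only if every pathway is synonymous is the SNP called synonymous. A mixed
pathway set resolves to nonsynonymous — a categorical effect class cannot
hold a fractional average, and the conservative resolution is consistent with
the stop-codon rule. Tri-allelic columns are counted in S but excluded from
MAF classes and SNP records (the frequency classes are defined for a minor
variant); each exclusion is logged.

ENC is Wright's (1990) estimator with per-family homozygosity
F̂ = (nΣp̂² − 1)/(n − 1), family means per degeneracy class, and
ENC = n₁ + Σ_c k_c/F̄_c clamped to [20, 61]. Families with n < 2 or F̂ ≤ 0
are unusable; an empty 3-fold class is imputed as the mean of the 2- and
4-fold class values, any other empty class as the mean over all usable
families. Small ORFs make empty classes common, hence the imputation default.

## Diversity estimators

π uses the unbiased per-site heterozygosity n/(n−1)(1 − Σp²); summed over
valid columns it equals the mean pairwise difference count (the test suite
checks this identity against exhaustive pairwise comparison). θ_W = S/(aₙL)
per category, with the category's fractional site count as L. Tajima's D
uses the 1989 constants (verified against an exact-rational re-derivation)
and is undefined — reported as missing, never as 0 — when S = 0.

"Average" diversity across loci is ambiguous in classical reports; both are
computed: the **pooled** (site-weighted) estimate Σ S/Σ(aₙ·L), which is the
headline value and the one propagated to the DFE chain, and the unweighted
across-locus mean for comparison.

Weir–Cockerham F_ST is the haplotype-level (chromosome-sampling) variance
components estimator; it may be negative, monomorphic populations are
allowed, and multiallelic sites sum components across alleles.

Per-locus Tajima's D significance (optional, off by default) is evaluated by
neutral coalescent simulation conditional on n and S, with Bonferroni or
Benjamini–Hochberg correction across loci.

## The DFE partition and the load chain

The ratio ladder R = θ_n/θ_si is computed for: all SNPs, without singletons,
MAF > 0.1, MAF > 0.2, and SNPs shared between at least two populations. Only
the S numerators are restricted to the subset; the site denominators stay
fixed, so each R compares like-for-like θ estimates. Frequency-class
boundaries are MAF < 0.1, 0.1 ≤ MAF ≤ 0.2 (closed interval), MAF > 0.2 —
boundary membership is a documented convention.

f0 defaults to the MAF > 0.2 ratio (where the ladder converges); the
shared-SNP ratio can be selected instead. f1 = R_all − f0 and f2 = 1 − R_all
are clamped to their valid ranges with explicit warnings and are never
silently renormalized. Because the text of classical reports is inconsistent
about whether the all-SNP ratio uses silent or synonymous-only sites, both
ratios are reported; the silent-based one drives the partition.

The method assumes only that silent and nonsynonymous sites of a locus share
one genealogy (they are interspersed within loci), so the expected neutral
count S_exp = Σ_loci S_si · L_n/L_si needs no population-genetic model — the
aₙ factor cancels within each locus because both categories share the same
chromosomes. The neutral share of the observed nonsynonymous SNPs is
round(f0·S_exp), capped at the observed count. For the conservative
per-individual load the non-neutral count is attributed to the lowest-MAF
nonsynonymous SNPs (ties by locus id, then position — deterministic and
consistent with the assumption that non-neutral alleles are the rarest);
each such allele, present once among n_j sampled individuals, is
heterozygous in exactly one of them, giving Σ_j 1/n_j. The genome
extrapolation scales by (genome-wide nonsynonymous sites)/(surveyed
nonsynonymous sites); the surveyed total comes from the retained loci's site
counts and is reported explicitly because the extrapolated load is directly
proportional to its inverse. Display rounding (ratios to 2 decimals,
fractions to whole percent, loads to 1 decimal) never feeds back into the
computation.

## Synthetic data

The generator's defaults are the survey conditions the analysis targets:
35 nuclear loci; 16 diploid individuals in 4 populations (two per basin);
whole-individual missingness 0.1 per locus; silent θ = 0.007/site; DFE
(f0, f1, f2) = (0.23, 0.33, 0.44) with γ = −5 for the weak class; coding
lengths 150–660 bp (EST-amplicon range, rounded to codons), one intron of
92–600 bp in ~23/37 of loci, UTRs up to 120 bp. Values not fixed by the
emulated survey design (intron/UTR length caps, the missingness rate) are
field-realistic choices made once.

Two levels share this configuration. The **independent-sites** level draws
per-category folded spectra directly: silent counts Poisson(θ·aₙ·L_si) with
neutral folded frequencies; nonsynonymous counts split into the f0 share
(neutral), the f1 share with frequencies from the Poisson-random-field
sampled spectrum w_i ∝ ∫ H(q;γ) C(n,i) qⁱ(1−q)^{n−i} dq (Gauss–Legendre
quadrature with a doubling convergence check; the γ→0 limit is exactly 1/i),
and the f2 share contributing nothing — "strongly deleterious" is
implemented literally as unsampled rather than as explicit lethality. The
**locus level** simulates one neutral genealogy per locus (sites free across
loci, fully linked within), places infinite-sites mutations on branches at
class-appropriate rates, thins weak-class candidates by the ratio of the
selected to the neutral sampled spectrum at their realized derived count
(oversampling candidates so the f1 influx is preserved), pairs chromosomes
randomly into diploids, and emits the exact input formats of the pipeline
plus a truth JSON. Placement enforces at most one mutation per codon
(and per noncoding site), so effect labels recovered from the alignments
reconcile with the truth record exactly; nonsense changes are excluded from
the placeable pool (their rate is absorbed by missense changes) because a
majority-derived premature stop would invalidate its codon. The
pathway-averaging classifier is exercised by direct unit tests instead.

The ψ mode adds a multiple-merger event class at a configurable rate; at
each event every lineage joins the merger independently with probability ψ
(events engaging fewer than two lineages are null, so ψ = 0 recovers the
Kingman process exactly). This emulates sweepstakes reproductive success,
under which Tajima's D is negative at steady state; the default rate is
illustrative, not calibrated to any species.

**What passing tests do and do not show.** The generator realizes the
analysis model's own assumptions: equilibrium, no recombination within loci,
no demography or subdivision, no sequencing error, no alignment artifacts.
Recovery of (f0, f1, f2) on synthetic data therefore validates the
implementation and the estimator's sampling behaviour, not robustness to
model violations in real data. Two specific calibration facts, both computed
by the test suite: (1) SNPs within a locus share a genealogy, so locus-level
folded spectra are overdispersed relative to a multinomial — goodness-of-fit
calibration uses the independent-sites level, which is the correct null;
(2) the weak-selection sampled spectrum retains a small tail above MAF 0.2
(about 17% of the neutral common-class mass at n = 32, γ = −5), so the
common-SNP ratio overestimates f0 by f1 times that leakage — an intrinsic
property of the estimator, sharp-tested against the independently computed
leakage and visible as a mild upward bias of f̂0 in end-to-end recovery.

## Numerical and reproducibility choices

Quadrature: 256 Gauss–Legendre nodes with a doubling check at 1e−8 relative
tolerance; the stable expm1 form of the sojourn density avoids overflow for
strongly negative γ. Ties: consensus bases and major/minor assignment break
alphabetically; rounding of the neutral SNP count is half-up. Degenerate
inputs: loci with fewer than two individuals are skipped with a warning;
subsets without silent SNPs yield an undefined ratio (error or missing
value, never 0). All randomness flows from a single seeded NumPy generator
with fixed draw order; simulation and analysis outputs are byte-identical
across runs, and reports are invariant to locus and individual input order.
Report sizes in the default test run (500 calibration loci, 100 replicate
recovery surveys, 500 ψ replicates) are the package's chosen trade-off
between Monte-Carlo resolution and a test suite that runs in a couple of
minutes.

## Limitations

No haplotype statistics (LD, haplotype diversity), no unfolded SFS (no
outgroup), no divergence-based tests, no maximum-likelihood DFE density —
the three-class partition is deliberately model-light. The per-individual
load uses the once-in-the-sample assumption and is therefore a lower bound;
the genome extrapolation inherits the uncertainty of the assumed genome-wide
nonsynonymous site count and map length. Chromatogram-level processing
(base calling, the heterozygote peak rule) is upstream of this package:
annotations and consensus sequences are inputs.
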