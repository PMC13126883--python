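# Methods

This note documents the models, estimators and numerical choices behind
`polymeth`, and what the synthetic cohort does and does not emulate.

## Coordinates and formats

Internal coordinates are 0-based half-open; cytosine-report positions are
1-based (the Bismark convention) and converted only at the I/O boundary.
Interval membership everywhere is `start <= pos-1 < end`. Strands are
kept separate by default; `destrand_cpg` merges symmetric CpG pairs by
summing counts, for users who prefer destranded CpG analyses (whether to
destrand is a genuine open choice; none of the shipped analyses assume
it).

## Methylation-level estimators

Two estimators with different coverage floors serve different purposes:

- mean level, `(1/k) Σ mᵢ/nᵢ` over sites with `nᵢ ≥ 10` — used for
  global per-context and per-subgenome summaries, where each site should
  count equally and low-coverage ratios would be too noisy;
- weighted level, `Σmᵢ / Σnᵢ` over sites with `nᵢ ≥ 3` — used for every
  region-based analysis. The low floor maximises the number of evaluated
  cytosines without bias because a low-coverage site contributes
  proportionally less.

Both floors are parameters (`min_cov`), not constants. Under uniform
coverage the two estimators coincide exactly; under heterogeneous
coverage the weighted estimator has the smaller variance (both facts are
asserted in the test suite). The coverage filter also removes presumed
PCR artifacts above the per-sample 99.99th-percentile coverage,
computed with the nearest-rank definition over all covered sites with
contexts pooled.

## Conversion rate and the CHH screen

The bisulfite conversion rate is estimated on the chloroplast genome
(assumed fully unmethylated): `converted / analyzed × 100` over all
chloroplast cytosine calls. Its complement, the non-conversion rate p₀,
is the null for the CHH screen: each CHH site with coverage ≥ 10 is
tested one-sided against Binomial(n, p₀).

Numerical choice: the default p-value is the Lancaster **mid-p**
(`P(X > m) + ½·P(X = m)`) rather than the exact tail. At capture-typical
coverages (negative-binomial around 30×) the exact tail test attains
size ≈ 0.024 at nominal 0.05 because of count discreteness, which makes
"fraction of significant sites" systematically misleading as an estimate
of the truly methylated fraction; the mid-p restores near-nominal size
(≈ 0.040–0.048 across coverages, approaching 0.05 as coverage grows).
The exact tail is available via `method="exact"`, and a BH-adjusted
variant via `adjust=True`. The screen is unadjusted at α = 0.05 by
default, matching how the proportion of significantly methylated CHH
sites is conventionally summarised.

## Differential methylation

Per unit (cytosine, 300 bp window, or segment) with replicate counts
`(m_gi, n_gi)` in groups g = 1, 2, the test is a binomial logistic
regression on the group indicator. With one binary covariate the MLE is
closed-form (pooled proportion per group), so the likelihood-ratio χ²
is computed directly and scaled by the Pearson dispersion
`φ̂ = max(1, Σ (m_gi − n_gi·p̂_g)² / (n_gi·p̂_g·(1−p̂_g)) / (N − 2))`
before the χ²₁ p-value. Flooring φ̂ at 1 means underdispersion never
sharpens the test. p-values are BH-adjusted within each context. A unit
is called hyper/hypomethylated only when `q < 0.01` (a `use_q=False`
switch substitutes raw p, since both conventions exist for cytosine-level
calls) **and** the pooled weighted-level difference exceeds 25 percentage
points. With a single replicate per group, dispersion cannot be
estimated and the test falls back to a two-sided Fisher exact test,
flagged in the output.

Sites are tested only when covered ≥ 10× in *every* replicate of both
groups. Because the AB parent carries only A/B chromosomes and the D
parent only D, `combine_parents` concatenates the two parents'
replicate-i tables into joint parent replicates covering all three
subgenomes; synthetic-vs-parent comparisons are then plain 2-vs-2.

### Segmentation

Parental replicates are pooled by summing counts per site. Within each
target region, per-site pooled CpG levels (pooled coverage ≥ 10) are
split by recursive binary segmentation minimising within-segment squared
error; a split is accepted only if the BIC
(`n·ln(RSS/n + ε) + 2k·ln n`, two parameters per segment: mean and
boundary) improves. Candidate cuts are restricted so every segment keeps
≥ 3 qualifying CpGs; regions with fewer than 3 qualifying CpGs yield a
single degenerate segment flagged untestable. On noise-free step signals
this recovers the change point exactly, and on constant signals it
returns a single segment. Segment boundaries snap to the covered-site
span (first site − 1, last site). Established segmentation tools often also cluster segments into
methylation classes; segments here are used
purely as test units, so that step is deliberately omitted.

### Set statistics

DMR/DEG set overlaps: expectation `n₁·n₂/N` and the upper-tail
hypergeometric p, exact for universes up to 10⁵ and a normal
approximation with continuity correction above. DMC density per 1,000
covered cytosines is compared between DEGs and non-DEGs with a 2×2
chi-square (Yates) and a hypergeometric placement test; only DEGs with
covered cytosines in the tested data enter the DEG partition.

## Landscapes

- **Subgenome means** use complete-case sites (≥ 10× in every library)
  and two-sided Wilcoxon rank-sum tests between the per-site level
  distributions of subgenome pairs, per sample, starred at
  0.05/0.01/0.001.
- **Chromosome scans** pool all contexts into one weighted-level track
  over target-region cytosines (floor 3) in 2 Mb windows with 1 Mb step;
  windows are emitted only when they fit inside the chromosome, and
  windows without covered target cytosines are gaps. Track similarity
  between samples uses Pearson r and the *paired* (signed-rank) Wilcoxon
  on the shared window grid — windows are naturally paired across
  samples, which makes the signed-rank test the coherent choice where a
  bare "Wilcoxon test" would be ambiguous.
- **PCA** treats libraries as observations and sites as variables,
  centred and unit-scaled with zero-variance sites dropped (the prcomp
  default behaviour), computed by SVD; the AB and D subgenome partitions
  are analysed separately because the diploid/tetraploid parents carry
  no data on the other partition.
- **Metaprofiles** cut each 300 bp region into 30 bins of 10 bp oriented
  5'→3' (bins flip on minus-strand genes). Per bin the weighted level is
  computed per gene and sample, averaged over genes within a sample and
  then over samples — the double average weights samples equally instead
  of letting high-coverage libraries dominate, and the two variance
  modes (across samples vs across genes) are reported separately because
  across-gene spread is much larger. Genes with multiple 5'-UTR
  annotations are removed from the TSS set, since their effective TSS is
  ambiguous at 10 bp resolution.
- **Expression transform**: `log10(TPM + 1)`, which handles zeros
  without a magic pseudo-TPM. Expressed = TPM > 0.1 in ≥ 2 libraries.
  Correlations are Pearson by default (r and r² are the reported
  scale); Spearman is available.
- **Centromere distance** is measured from the region midpoint to a
  single per-chromosome centromere coordinate supplied with the
  annotation.

## Triads

Contribution thresholds are stored as exact fractions 1/6 and 2/3
(displayed 16.7 %/66.7 %), with boundaries inclusive in the balanced
class. Triads enter only when the summed TPM exceeds a floor (default
0.5, configurable) — the floor keeps near-zero ratios out of the ternary
plane. Category-level comparisons report both the Wilcoxon rank-sum and
a Welch t-test side by side, since both conventions appear in the
ternary-plot literature; a category with fewer than 3 members skips its
tests. The variance association correlates within-triad SD of
contributions with within-triad SD of levels, which is agnostic to the
direction of any methylation effect.

## Probe design

The built-in mapper indexes exact 21-mers of the reference and scores
candidate placements by ungapped extension (+1 match / −4 mismatch). A
fragment is kept only with a unique best placement whose score beats the
runner-up by ≥ 20 — a proxy for MAPQ ≥ 20 — and reaches half the perfect
score; an external aligner can replace this path for real genomes via
pre-computed mappings. Consensus is a per-column majority vote among the
mapped fragments of one assembly over each window side; coverage gaps
split the consensus, and pieces shorter than 120 bp are discarded (they
can neither seed an assembly overlap nor reach probe length). Assembly is
greedy: repeatedly merge the pair with the longest ungapped overlap
≥ 120 bp at ≤ 3 % mismatches, ties broken lexicographically, keeping the
left sequence's bases in the overlap. Filters run in order — redundancy
(identical or reverse-complement-identical across the upstream +
downstream sets), chloroplast similarity (alignment covering ≥ 80 % of
the candidate at ≤ 10 % mismatches), pan-genome presence (a "valid
alignment" covers ≥ 80 % of the candidate at ≥ 90 % identity; fewer than
`min_assemblies` such assemblies removes the candidate), and off-target
excess (reference hits with score ≥ 80; more off- than on-target hits
removes it). Shredding is tail-anchored: when the sequence length is not
a step multiple, a final full-length fragment starts at `L − 500` so the
sequence end is always covered.

## The synthetic cohort

What it emulates: nine genotypes × two replicates (an AB tetraploid
parent, two D diploid parents, five synthetics — three with both parents
sampled — and a natural hexaploid); one chromosome per subgenome with
the centromere at the midpoint and a +10-point methylation bump within
10 % of it; 300 bp regions around TSS (an exact 63.7 % of genes by
default) or SC; per-site latent levels drawn Beta(precision 3) around
class/context/subgenome means multiplied by a unit-mean log-normal
per-(gene, context) effect (σ = 0.8); 85 % of CHH sites at latent zero;
negative-binomial coverage (mean 30, dispersion 5); observed methylated
counts Binomial(coverage, level + p₀·(1−level)) with p₀ = 0.02
non-conversion; a latent-zero chloroplast; ternary-structured triad
expression with log-normal totals; and injected parent→synthetic DMRs
(exact ±0.40 latent shifts on every cytosine of one context, parental
latents clamped so the shifted level stays in [0, 1]) and ≥ 4-fold DEGs,
all recorded in truth tables.

Parameter rationale. The latent means are set so the *apparent* levels
(latent + non-conversion + gradient) land in the emulation targets
(CpG 20–27 %, CHG 12–15 %, CHH 2–3 %). The gene-level effect is the
load-bearing choice: per-site spread alone cannot produce realistic
per-gene scatter because region-weighted levels average tens of sites,
and σ = 0.8 puts the methylation–expression shared variance (r²) in the
weak-coupling regime (~0.004–0.025) while preserving the ~6-point
expressed/silent CpG class difference visible in metaprofiles. Coverage
mean 30 reflects a 40× design minus capture losses. Synthetics inherit
parental latents exactly, so parent-vs-synthetic comparisons are null
everywhere except the injected effects.

What it does not emulate — and hence what passing tests do not show
about real data: transposable elements and their methylation context,
linked sites (site levels are independent given the gene effect),
sequence-driven methylation (sequence is uniform random), mapping or
conversion biases, batch effects between replicates beyond counting
noise, and read-level structure (no FASTQ/alignment simulation). The
CHH screen's significant fraction on the default cohort (~7.5 %) is
slightly below the 10–16 % seen in real data: with the 85 % latent-zero
mixture and the 2–3 % apparent-mean constraint both fixed, the two
cannot be matched jointly at 30× by a two-point mixture.

## Problem sizes and determinism

Default analyses run at 60–1,000 triads (180–3,000 genes); the shipped
end-to-end configuration (9 × 2 libraries, 1,000 triads) generates,
writes and analyses the cohort in about two minutes on one CPU. All
randomness flows from a single integer seed through one
`numpy.random.Generator`; a rerun with the same seed reproduces every
on-disk artifact bit for bit, which the pipeline manifest verifies by
sha256.

## Known limitations

- The dispersion-scaled χ² is asymptotic; at very low coverage with two
  replicates it can be conservative (the FDR-control tests bound, but do
  not pin, its size).
- The segmentation is binary splitting with a BIC gate, not an exhaustive
  optimal segmentation; on noisy signals it can under-split short
  features (the fixed-window route is the complement, and the two
  deliberately disagree on borderline genes).
- The built-in probe mapper is exact-seed based: it will miss placements
  whose every 21-mer window is mutated, which is fine at pan-genome
  divergence scales but not for cross-species use.
- `dmc_density` attributes cytosines to genes through the target
  regions, so DMCs outside any region are not counted.
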