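# polymeth

Capture-bisulfite methylome analysis of natural and synthetic hexaploid
wheat, from cytosine-level counts to subgenome summaries, TSS/SC
metaprofiles, homeolog-triad statistics and differential-methylation calls
— driven by a seeded synthetic-cohort generator so every stage runs at
desk scale.

## The scientific problem

Bread wheat is an allohexaploid (AABBDD) formed from a tetraploid (AABB) ×
diploid (DD) cross. Whether cytosine methylation around transcription
start sites (TSS) — or around start codons (SC) for genes without a
5'-UTR annotation — acts as an on/off switch for transcription, and
whether whole-genome duplication reshapes those methylation patterns, are
open questions. A targeted capture design enriches 300 bp windows around
the TSS/SC of each high-confidence gene; bisulfite sequencing then yields
per-cytosine methylated/unmethylated read counts in the CpG, CHG and CHH
contexts. `polymeth` implements the downstream statistics:

- **Methylation-level estimators.** For a set of sites with methylated
  counts mᵢ and coverages nᵢ, the *mean* level is (1/k)·Σ mᵢ/nᵢ over
  sites with nᵢ ≥ 10, and the *weighted* level is Σmᵢ / Σnᵢ over sites
  with nᵢ ≥ 3 (a low-coverage site contributes proportionally less).
- **Conversion efficiency** from an unmethylated chloroplast control:
  rate = converted / analyzed × 100; the complement is the non-conversion
  background against which CHH methylation is screened with a one-sided
  binomial test.
- **Landscapes.** Complete-case (≥ 10× in every library) site matrices
  feed per-subgenome means with Wilcoxon tests, a prcomp-style PCA
  (samples as observations, sites centred/scaled), 2 Mb / 1 Mb-step
  chromosome scans, 10 bp metaprofiles split by expression status
  (TPM > 0.1 in ≥ 2 libraries), and methylation ~ log₁₀(TPM+1) ~
  centromere-distance correlations.
- **Triads.** A homeolog's contribution is its TPM over the triad total;
  contributions in [1/6, 2/3] are *balanced*, below *suppressed*, above
  *dominant*. Contributions and their within-triad SDs are related to
  TSS/SC methylation by correlation and rank tests.
- **Differential methylation.** Synthetics vs parents are compared with a
  binomial logistic regression on the group indicator whose
  likelihood-ratio χ² is scaled by the Pearson dispersion
  φ̂ = max(1, χ²_Pearson/df) before the p-value; BH-adjusted q < 0.01
  *and* a level difference > 25 points are both required for a call.
  Regions are either the fixed 300 bp windows or variable-length
  segments of homogeneous parental CpG methylation from binary
  change-point splitting (BIC-gated, ≥ 3 CpGs at ≥ 10× per segment).
  DMR/DEG set overlaps use the hypergeometric test.
- **Probe design.** A pan-genome consensus pipeline: shred assemblies
  into 500 bp fragments (250 bp step), map them uniquely to the
  reference, collapse per-assembly majority consensus around each
  TSS/SC, re-assemble across assemblies (ungapped overlaps ≥ 120 bp,
  ≤ 3 % mismatch) and filter candidates for redundancy, chloroplast
  similarity, pan-genome presence and off-target excess.

The synthetic-cohort generator emulates the study design — 9 genotypes ×
2 replicates across three subgenomes with B > A > D offsets,
context-specific levels (CpG ≈ 20–27 %, CHG ≈ 12–15 %, CHH ≈ 2–3 %
apparent), an unmethylated chloroplast with ~2 % non-conversion,
expressed/silent gene classes, ternary triad structure, and injected
parent→synthetic DMRs and DEGs with recorded truth — so that every
statistical claim is testable against a known ground truth.

## Worked example

```bash
python examples/01_simulate_and_summarize.py
```

prints (numbers from the fixed seed in the script):

```
18 libraries, 600 genes in 200 triads

Recital rep1 CHG: mean 14.43 % (16008 sites >= 10x), weighted 14.44 % (16671 sites >= 3x)
Recital rep1 CHH: mean  2.96 % (49023 sites >= 10x), weighted  2.94 % (50949 sites >= 3x)
Recital rep1 CpG: mean 25.68 % (21307 sites >= 10x), weighted 25.53 % (22130 sites >= 3x)

bisulfite conversion rate: 97.94 % (90769 chloroplast cytosine calls)
```

CpG is the most methylated context; CHH barely exceeds the ~2 %
non-conversion background, which is why the CHH screen matters. The other
examples cover differential methylation (`02`), triad statistics (`03`),
probe design (`04`) and the end-to-end pipeline with its artifact
manifest (`05`). The same stages are scriptable from the shell:

```bash
polymeth simulate --outdir cohort --n-triads 300 --seed 1
polymeth run --cohort cohort --outdir results
```

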