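"""Homeolog-triad expression bias and its (lack of) methylation signal.

Computes per-homeolog contributions to triad expression, classifies them
as suppressed / balanced / dominant on the ternary thresholds (16.7 % and
66.7 %), and asks whether TSS/SC methylation explains the bias.
"""

import warnings

from polymeth import methcore, triads
from polymeth.synthetic_cohort import SimConfig, generate_cohort

warnings.filterwarnings("ignore")

cohort = generate_cohort(SimConfig(n_triads=400, seed=3))
expr = cohort.expression
tpm = expr[expr["sample_id"] == "Recital"].groupby("gene_id")["tpm"].mean()

contrib = triads.compute_contributions(tpm, cohort.annotation.triads)
included = contrib[contrib["included"] == True]  # noqa: E712
counts = included[["cat_A", "cat_B", "cat_D"]].stack().value_counts()
print(f"{len(included)} triads above the expression floor")
print("homeolog categories:",
      {str(k): int(v) for k, v in counts.items()})

rm = methcore.region_methylation(cohort.methylomes[("Recital", 1)],
                                 cohort.annotation.regions)
tm = triads.triad_methylation(rm, cohort.annotation.triads, "CpG")
assoc = triads.contribution_methylation_association(contrib, tm)
var = triads.variance_association(contrib, tm)
c = assoc["correlation"]
print(f"\ncontribution ~ CpG level: r = {c.r:+.3f}, r2 = {c.r2:.4f}, "
      f"p = {c.p:.3g} (n = {c.n} homeologs)")
print(f"SD(contributions) ~ SD(levels): r = {var.r:+.3f}, r2 = {var.r2:.4f}")
print("Near-zero shared variance: expression bias is not explained by "
      "TSS/SC methylation in this cohort, matching the null structure "
      "of the generator.")
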