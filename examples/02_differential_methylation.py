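"""Call DMRs between a synthetic allohexaploid and its parents.

Injects 20 known 40-point CpG effects, runs both region definitions
(fixed 300 bp TSS/SC windows and parental change-point segments) and
compares the calls with the recorded truth.
"""

import warnings

from polymeth import diffmeth
from polymeth.synthetic_cohort import SimConfig, generate_cohort

warnings.filterwarnings("ignore")

cohort = generate_cohort(SimConfig(n_triads=200, n_injected_dmrs=20, seed=2))
regions = cohort.annotation.regions

parents = diffmeth.combine_parents(
    [cohort.methylomes[("Langdon", r)] for r in (1, 2)],
    [cohort.methylomes[("Tauschii-109", r)] for r in (1, 2)])
synthetic = [cohort.methylomes[("109xL-C2", r)] for r in (1, 2)]

fixed = diffmeth.dmr_fixed_windows(parents, synthetic, regions)
segments = diffmeth.segment_parents(
    [cohort.methylomes[("Langdon", r)] for r in (1, 2)],
    [cohort.methylomes[("Tauschii-109", r)] for r in (1, 2)], regions)
seg = diffmeth.dmr_segments(parents, synthetic, segments)

truth = set(cohort.truth.dmr_truth["gene_id"])
for name, res in (("fixed windows", fixed), ("segments", seg)):
    calls = res[res["status"] != "ns"]
    genes = set(calls["gene_id"])
    print(f"{name}: {len(calls)} significant units in {len(genes)} genes; "
          f"{len(genes & truth)}/{len(truth)} injected effects recovered, "
          f"{len(genes - truth)} false gene calls")
print(f"\n{len(segments)} parental segments over {len(regions)} regions "
      f"(each >= 3 CpG sites at >= 10x pooled coverage)")
print("A call needs both a >25-point level difference and q < 0.01.")
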