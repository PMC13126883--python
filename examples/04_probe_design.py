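"""Design consensus capture probes on a toy five-assembly pan-genome.

Shreds each assembly into 500 bp fragments (250 bp step), maps them back
to the reference with the built-in k-mer mapper, collapses them into
per-assembly consensus sequences around each TSS/SC, re-assembles the
consensus set into probe candidates and applies the four filters.
"""

import numpy as np
import pandas as pd

from polymeth import probedesign as pdx

rng = np.random.default_rng(4)


def random_seq(n):
    return "".join(rng.choice(list("ACGT"), size=n))


# a 3-gene reference and four slightly diverged assemblies
spacer = [random_seq(800) for _ in range(4)]
windows = [random_seq(300) for _ in range(3)]
ref_seq = spacer[0] + windows[0] + spacer[1] + windows[1] + spacer[2] \
    + windows[2] + spacer[3]
reference = {"chr1": ref_seq}
assemblies = {"ref_copy": {"chr1": ref_seq}}
for i in range(3):
    seq = list(ref_seq)
    for p in rng.choice(len(seq), size=15, replace=False):
        seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
    assemblies[f"asm{i + 1}"] = {"chr1": "".join(seq)}

anchors = [800 + 150, 1900 + 150, 3000 + 150]
ann = []
for i, a in enumerate(anchors):
    ann.append({"seqid": "chr1", "source": ".", "type": "gene",
                "start": a - 149, "end": a + 450, "score": ".", "strand": "+",
                "phase": ".", "attributes": f"ID=g{i}", "gene_id": f"g{i}"})
    ann.append({"seqid": "chr1", "source": ".", "type": "five_prime_UTR",
                "start": a + 1, "end": a + 60, "score": ".", "strand": "+",
                "phase": ".", "attributes": f"Parent=g{i}", "gene_id": f"g{i}"})
annotation = pd.DataFrame(ann)

targets = pdx.derive_targets(annotation, {"chr1": len(ref_seq)})
fragments = []
for name, seqs in assemblies.items():
    fragments.extend(pdx.shred(seqs, name))
mapped = pdx.map_fragments(fragments, reference)
consensus = pdx.extract_consensus(mapped, targets)
candidates = (pdx.assemble_candidates(consensus, "upstream")
              + pdx.assemble_candidates(consensus, "downstream"))
candidates = pdx.filter_candidates(candidates, reference, targets, None,
                                   assemblies, min_assemblies=4)

print(f"{len(fragments)} fragments, {len(mapped)} uniquely mapped")
print(f"{len(consensus)} per-assembly consensus sequences -> "
      f"{len(candidates)} probe candidates")
for c in candidates:
    print(f"  {c.id}: {len(c.sequence)} bp from "
          f"{c.n_source_assemblies} assemblies -> {c.status}")
print("Each retained probe is a cross-assembly consensus of one side "
      "(upstream/downstream) of a TSS window.")
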