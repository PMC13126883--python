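import warnings

import numpy as np
import pandas as pd
import pytest

from polymeth.synthetic_cohort import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic study shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(SimConfig(n_triads=60, seed=7,
                                         n_injected_dmrs=10,
                                         n_injected_degs=10))


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    small_cohort.write(d)
    return d


def make_records(rows):
    """Cytosine DataFrame from (chrom, pos, strand, m, u, context) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count_meth",
                                       "count_unmeth", "context"]).assign(
        trinucleotide="CGA")


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def build_toy_pangenome():
    """Reference, five assemblies, chloroplast and annotation with
    hand-enumerable probe fates (four genes, one scenario per filter)."""
    rng = np.random.default_rng(42)
    windows = {g: _random_seq(rng, 300) for g in ("g1", "g2", "g3", "g4")}
    # g3 upstream duplicates g1 downstream
    windows["g3"] = windows["g1"][150:300] + windows["g3"][150:]
    spacers = [_random_seq(rng, 700) for _ in range(5)]
    # off-target copies of g2 upstream (6 mutations each, clustered at the
    # start so that clean seed k-mers survive)
    g2_up = windows["g2"][:150]
    copy1 = _mutate(rng, g2_up, [2, 21, 45, 47, 52, 58])
    copy2 = _mutate(rng, g2_up, [5, 13, 33, 39, 50, 57])
    spacers[3] = spacers[3][:200] + copy1 + spacers[3][350:]
    spacers[4] = spacers[4][:200] + copy2 + spacers[4][350:]
    ref_seq = (spacers[0] + windows["g1"] + spacers[1] + windows["g2"]
               + spacers[2] + windows["g3"] + spacers[3] + windows["g4"]
               + spacers[4])
    reference = {"chr1": ref_seq}
    anchors = {"g1": 700 + 150, "g2": 1700 + 150, "g3": 2700 + 150,
               "g4": 3700 + 150}
    ann_rows = []
    for gid, anchor in anchors.items():
        ann_rows.append({"seqid": "chr1", "source": ".", "type": "gene",
                         "start": anchor - 149, "end": anchor + 450,
                         "score": ".", "strand": "+", "phase": ".",
                         "attributes": f"ID={gid}", "gene_id": gid})
        ann_rows.append({"seqid": "chr1", "source": ".",
                         "type": "five_prime_UTR", "start": anchor + 1,
                         "end": anchor + 60, "score": ".", "strand": "+",
                         "phase": ".", "attributes": f"Parent={gid}",
                         "gene_id": gid})
    annotation = pd.DataFrame(ann_rows)
    assemblies = {f"A{i}": {"chr1": ref_seq} for i in range(1, 6)}
    # A3-A5 carry foreign sequence in place of g4's downstream window
    foreign = _random_seq(rng, 150)
    g4_down_start = 3700 + 150
    for name in ("A3", "A4", "A5"):
        s = assemblies[name]["chr1"]
        assemblies[name] = {
            "chr1": s[:g4_down_start] + foreign + s[g4_down_start + 150:]}
    # chloroplast holds a 2 %-diverged copy of g2's downstream window
    g2_down = windows["g2"][150:300]
    chl_copy = _mutate(rng, g2_down, [100, 120, 140])
    chloroplast = {"chl": _random_seq(rng, 900) + chl_copy
                   + _random_seq(rng, 900)}
    return reference, annotation, assemblies, chloroplast


def run_probe_pipeline(reference, annotation, assemblies, chloroplast,
                       min_assemblies=4):
    """Run the probe-design stages end to end on in-memory genomes."""
    from polymeth import probedesign as pdx

    chrom_lengths = {n: len(s) for n, s in reference.items()}
    targets = pdx.derive_targets(annotation, chrom_lengths)
    fragments = []
    for name, seqs in assemblies.items():
        fragments.extend(pdx.shred(seqs, name))
    mapped = pdx.map_fragments(fragments, reference)
    consensus = pdx.extract_consensus(mapped, targets)
    candidates = (pdx.assemble_candidates(consensus, "upstream")
                  + pdx.assemble_candidates(consensus, "downstream"))
    filtered = pdx.filter_candidates(candidates, reference, targets,
                                     chloroplast, assemblies,
                                     min_assemblies=min_assemblies)
    return targets, consensus, filtered
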