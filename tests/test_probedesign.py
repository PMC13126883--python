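"""Shredding, mapping, consensus, assembly and probe filters.

The integration fixture is a hand-constructed toy pan-genome with four
genes whose probe fates are enumerable by hand:

* g1 upstream  -- clean, present in all assemblies          -> retained
* g1 downstream -- sequence duplicated as g3's upstream     -> redundant
* g2 upstream  -- two mutated off-target copies in the
                  reference spacers                          -> off_target
* g2 downstream -- near-copy present in the chloroplast     -> chloroplast
* g3 upstream / downstream -- clean                          -> retained x2
* g4 upstream  -- clean                                      -> retained
* g4 downstream -- replaced by foreign sequence in three of
                   the five assemblies                       -> few_assemblies
"""

import numpy as np
import pandas as pd
import pytest

from polymeth import probedesign as pdx


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestShred:
    def test_exact_multiple(self):
        frags = pdx.shred({"s": "A" * 1000}, "asm")
        assert [f.source_start for f in frags] == [0, 250, 500]
        assert all(len(f.sequence) == 500 for f in frags)

    def test_tail_anchored_fragment(self):
        frags = pdx.shred({"s": "A" * 1100}, "asm")
        assert [f.source_start for f in frags] == [0, 250, 500, 600]

    def test_short_sequence_flagged(self):
        frags = pdx.shred({"s": "ACGT" * 50}, "asm")
        assert len(frags) == 1 and frags[0].short

    def test_fragments_tile_with_overlap(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 1750)
        frags = pdx.shred({"s": seq}, "asm")
        covered = np.zeros(1750, dtype=bool)
        for f in frags:
            assert seq[f.source_start:f.source_start + 500] == f.sequence
            covered[f.source_start:f.source_start + 500] = True
        assert covered.all()


class TestDeriveTargets:
    @staticmethod
    def _annotation(strand="+", with_utr=True):
        rows = [{"seqid": "chr1", "source": ".", "type": "gene", "start": 1001,
                 "end": 3000, "score": ".", "strand": strand, "phase": ".",
                 "attributes": "ID=geneX", "gene_id": "geneX"}]
        if with_utr:
            utr = {"+": (1001, 1100), "-": (2901, 3000)}[strand]
            rows.append({"seqid": "chr1", "source": ".", "type": "five_prime_UTR",
                         "start": utr[0], "end": utr[1], "score": ".",
                         "strand": strand, "phase": ".",
                         "attributes": "Parent=geneX", "gene_id": "geneX"})
        cds = {"+": (1101, 2900), "-": (1101, 2900)}[strand]
        rows.append({"seqid": "chr1", "source": ".", "type": "CDS",
                     "start": cds[0], "end": cds[1], "score": ".",
                     "strand": strand, "phase": ".",
                     "attributes": "Parent=geneX", "gene_id": "geneX"})
        return pd.DataFrame(rows)

    def test_utr_gene_gets_tss_anchor(self):
        t = pdx.derive_targets(self._annotation("+"), {"chr1": 10_000})
        assert t.loc[0, "anchor_type"] == "TSS"
        assert t.loc[0, "anchor"] == 1000  # 0-based first UTR base
        assert (t.loc[0, "end"] - t.loc[0, "start"]) == 300

    def test_no_utr_gene_gets_sc_anchor(self):
        t = pdx.derive_targets(self._annotation("+", with_utr=False),
                               {"chr1": 10_000})
        assert t.loc[0, "anchor_type"] == "SC"
        assert t.loc[0, "anchor"] == 1100

    def test_minus_strand_anchor_is_rightmost(self):
        t = pdx.derive_targets(self._annotation("-"), {"chr1": 10_000})
        # rightmost transcript base: UTR end 3000 -> 0-based 2999
        assert t.loc[0, "anchor"] == 2999

    def test_strand_flip_oracle(self):
        # deriving on the reverse-complemented genome mirrors the anchor
        L = 10_000
        plus = pdx.derive_targets(self._annotation("+"), {"chr1": L})
        minus_ann = self._annotation("+").copy()
        minus_ann["strand"] = "-"
        starts = L - minus_ann["end"].to_numpy() + 1
        ends = L - minus_ann["start"].to_numpy() + 1
        minus_ann["start"], minus_ann["end"] = starts, ends
        minus = pdx.derive_targets(minus_ann, {"chr1": L})
        assert minus.loc[0, "anchor"] == L - 1 - plus.loc[0, "anchor"]

    def test_gene_without_features_skipped(self):
        ann = self._annotation("+")
        ann = ann[ann["type"] == "gene"]
        t = pdx.derive_targets(ann, {"chr1": 10_000})
        assert len(t) == 0

    def test_multi_utr_flagged(self):
        ann = self._annotation("+")
        extra = ann[ann["type"] == "five_prime_UTR"].copy()
        extra["start"] += 40
        t = pdx.derive_targets(pd.concat([ann, extra]), {"chr1": 10_000})
        assert t.loc[0, "multi_utr"]


class TestMapping:
    @staticmethod
    def _ref(seed=1, n=4000):
        rng = np.random.default_rng(seed)
        return {"chr1": _random_seq(rng, n)}

    def test_verbatim_fragment_maps_at_origin(self):
        ref = self._ref()
        frag = pdx.Fragment("a", "chr1", 700, ref["chr1"][700:1200])
        mapped = pdx.map_fragments([frag], ref)
        assert mapped[0].ref_start == 700
        assert mapped[0].chrom == "chr1"

    def test_duplicated_sequence_dropped_as_ambiguous(self):
        rng = np.random.default_rng(2)
        block = _random_seq(rng, 600)
        ref = {"chr1": block + _random_seq(rng, 500) + block}
        frag = pdx.Fragment("a", "chr1", 0, block[:500])
        assert pdx.map_fragments([frag], ref) == []

    def test_two_percent_substitutions_still_map(self):
        ref = self._ref(seed=3)
        rng = np.random.default_rng(4)
        seq = ref["chr1"][1000:1500]
        mutated = _mutate(rng, seq, rng.choice(500, size=10, replace=False))
        frag = pdx.Fragment("a", "chr1", 1000, mutated)
        mapped = pdx.map_fragments([frag], ref)
        assert len(mapped) == 1 and mapped[0].ref_start == 1000
        # alignment-score oracle: 490 matches - 4*10 mismatches
        assert mapped[0].score == 490 - 40


class TestConsensus:
    def test_single_fragment_gives_window_slice(self):
        rng = np.random.default_rng(5)
        seq = _random_seq(rng, 2000)
        ref = {"chr1": seq}
        targets = pd.DataFrame([{"gene_id": "g", "anchor_type": "TSS",
                                 "chrom": "chr1", "start": 850, "end": 1150,
                                 "anchor": 1000, "strand": "+",
                                 "multi_utr": False}])
        frags = pdx.map_fragments(pdx.shred(ref, "a1"), ref)
        cons = pdx.extract_consensus(frags, targets)
        up = cons[(cons["side"] == "upstream")]
        assert list(up["sequence"]) == [seq[850:1000]]
        down = cons[(cons["side"] == "downstream")]
        assert list(down["sequence"]) == [seq[1000:1150]]

    def test_majority_vote_two_to_one(self):
        rng = np.random.default_rng(6)
        seq = _random_seq(rng, 1200)
        targets = pd.DataFrame([{"gene_id": "g", "anchor_type": "TSS",
                                 "chrom": "chr1", "start": 300, "end": 600,
                                 "anchor": 450, "strand": "+",
                                 "multi_utr": False}])
        clean = pdx.Fragment("a1", "c", 0, seq[200:700], chrom="chr1",
                             ref_start=200)
        clean2 = pdx.Fragment("a1", "c", 0, seq[250:750], chrom="chr1",
                              ref_start=250)
        noisy = pdx.Fragment("a1", "c", 0, _mutate(rng, seq[200:700], [150]),
                             chrom="chr1", ref_start=200)
        cons = pdx.extract_consensus([clean, clean2, noisy], targets)
        up = cons[cons["side"] == "upstream"]["sequence"].iloc[0]
        assert up == seq[300:450]  # 2:1 vote restores the reference base


class TestAssembly:
    def test_identical_sequences_merge_into_one(self):
        rng = np.random.default_rng(7)
        seq = _random_seq(rng, 150)
        cons = pd.DataFrame([{"gene_id": "g", "side": "upstream",
                              "assembly": f"a{i}", "sequence": seq,
                              "n_pieces": 1} for i in range(8)])
        cands = pdx.assemble_candidates(cons, "upstream")
        assert len(cands) == 1
        assert cands[0].n_source_assemblies == 8
        assert cands[0].sequence == seq

    def test_overlap_threshold_119_not_merged(self):
        rng = np.random.default_rng(8)
        seq = _random_seq(rng, 300)
        a, b = seq[:150], seq[31:181]  # 119 bp overlap
        cons = pd.DataFrame([
            {"gene_id": "g", "side": "upstream", "assembly": "a1",
             "sequence": a, "n_pieces": 1},
            {"gene_id": "g", "side": "upstream", "assembly": "a2",
             "sequence": b, "n_pieces": 1}])
        assert len(pdx.assemble_candidates(cons, "upstream")) == 2
        # one base more -> 120 bp overlap -> merged
        cons.loc[1, "sequence"] = seq[30:180]
        merged = pdx.assemble_candidates(cons, "upstream")
        assert len(merged) == 1
        assert merged[0].sequence == seq[:180]

    def test_mismatch_rate_boundary(self):
        rng = np.random.default_rng(9)
        seq = _random_seq(rng, 300)
        a = seq[:150]
        overlap_region = list(range(20, 140))
        # 150 bp overlap with 4 mismatches (2.7 %) merges; 5 (3.3 %) does not
        for n_mut, expect in ((4, 1), (5, 2)):
            b = _mutate(rng, seq[:150], rng.choice(150, n_mut, replace=False))
            cons = pd.DataFrame([
                {"gene_id": "g", "side": "upstream", "assembly": "a1",
                 "sequence": a, "n_pieces": 1},
                {"gene_id": "g", "side": "upstream", "assembly": "a2",
                 "sequence": b, "n_pieces": 1}])
            assert len(pdx.assemble_candidates(cons, "upstream")) == expect


@pytest.fixture(scope="module")
def toy_pangenome():
    """Reference, five assemblies, chloroplast and annotation (see module
    docstring for the hand-enumerated probe fates)."""
    from conftest import build_toy_pangenome

    return build_toy_pangenome()


@pytest.fixture(scope="module")
def toy_run(toy_pangenome):
    from conftest import run_probe_pipeline

    return run_probe_pipeline(*toy_pangenome)


class TestToyPipeline:
    def test_candidate_count(self, toy_run):
        _, _, candidates = toy_run
        assert len(candidates) == 8  # four genes x two sides

    def test_per_filter_removal_counts(self, toy_run):
        _, _, candidates = toy_run
        counts = pd.Series([c.status for c in candidates]).value_counts()
        assert counts.get("removed:redundant", 0) == 1
        assert counts.get("removed:chloroplast", 0) == 1
        assert counts.get("removed:few_assemblies", 0) == 1
        assert counts.get("removed:off_target", 0) == 1
        assert counts["retained"] == 4

    def test_provenance_no_chimeric_bases(self, toy_pangenome, toy_run):
        reference, _, _, _ = toy_pangenome
        _, consensus, candidates = toy_run
        # every candidate derives from at least one real consensus sequence
        seqs = set(consensus["sequence"])
        for c in candidates:
            assert any(s in c.sequence or c.sequence in s for s in seqs)

    def test_source_assembly_counts(self, toy_run):
        _, _, candidates = toy_run
        few = [c for c in candidates if c.status == "removed:few_assemblies"]
        assert few[0].sources == {"A1", "A2"}  # only A1 and A2 carry it
        retained = [c for c in candidates if c.status == "retained"]
        # g4's upstream consensus is interrupted in A3-A5 by the foreign
        # replacement next door; every other retained probe is pan-genomic
        assert sorted(c.n_source_assemblies for c in retained) == [2, 5, 5, 5]
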