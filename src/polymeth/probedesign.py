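"""Consensus hybridization-probe design across a small pan-genome.

Re-creates, at desk scale, the multi-assembly probe pipeline: target
windows (anchor +/- 150 bp on the TSS, or on the start codon for genes
without a 5'-UTR annotation) are derived from the reference annotation;
every assembly is shredded into 500 bp fragments with a 250 bp sliding
step; fragments are mapped back to the reference with a built-in exact
k-mer seed-and-extend mapper (uniquely mapped fragments only, with a
score-margin proxy for MAPQ >= 20); per target and assembly the
overlapping fragments are collapsed into a majority-vote consensus per
window side; the per-side consensus sets are greedily re-assembled into
contigs allowing ungapped overlaps >= 120 bp with <= 3 % mismatches; and
the resulting candidates pass four filters (redundancy, chloroplast
similarity, pan-genome presence, off-target excess).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Fragment", "ProbeCandidate", "derive_targets", "shred",
           "map_fragments", "extract_consensus", "assemble_candidates",
           "filter_candidates", "read_fasta", "write_fasta", "read_gff3",
           "KmerIndex"]

FRAG_LEN = 500
FRAG_STEP = 250
MIN_OVERLAP = 120
MAX_MISMATCH_RATE = 0.03

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def read_fasta(path) -> dict:
    """Read a FASTA file into an {name: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand",
               "phase", "attributes"]


def read_gff3(path) -> pd.DataFrame:
    """Minimal GFF3 reader (gene / CDS / five_prime_UTR features)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=GFF_COLUMNS, dtype={"seqid": str})
    attrs = df["attributes"].str.extract(r"(?:ID|Parent)=([^;]+)")[0]
    df["gene_id"] = attrs.str.replace(r"\.\w+$", "", regex=True)
    return df


@dataclass
class Fragment:
    assembly: str
    source_seq: str
    source_start: int  # 0-based on the source assembly sequence
    sequence: str
    short: bool = False  # source shorter than the fragment length
    chrom: str | None = None  # mapped reference chromosome
    ref_start: int | None = None  # mapped reference position (0-based)
    score: int | None = None
    margin: int | None = None

    @property
    def mapped(self) -> bool:
        return self.ref_start is not None


@dataclass
class ProbeCandidate:
    id: str
    side: str  # upstream | downstream
    sequence: str
    sources: set = field(default_factory=set)  # contributing assemblies
    status: str = "retained"
    on_target_hits: int = 0
    off_target_hits: int = 0
    chloroplast_hit: bool = False

    @property
    def n_source_assemblies(self) -> int:
        return len(self.sources)


def derive_targets(annotation: pd.DataFrame, chrom_lengths: dict) -> pd.DataFrame:
    """Target windows (anchor +/- 150 bp) from a GFF3-like annotation.

    The anchor is the first base of the 5'-UTR when annotated (TSS),
    otherwise the first coding base (SC); both are strand-aware (for a
    minus-strand gene the anchor is the rightmost base and "upstream" is
    rightward).  Genes with several distinct 5'-UTR intervals get the
    ``multi_utr`` flag.  Windows are clipped at chromosome ends.  Genes
    without UTR and without CDS are skipped.
    """
    rows = []
    genes = annotation[annotation["type"] == "gene"]
    for g in genes.itertuples(index=False):
        gid = g.gene_id
        feats = annotation[annotation["gene_id"] == gid]
        utrs = feats[feats["type"] == "five_prime_UTR"]
        cds = feats[feats["type"] == "CDS"]
        strand = g.strand
        if len(utrs):
            anchor_type = "TSS"
            anchor = int(utrs["start"].min()) - 1 if strand == "+" \
                else int(utrs["end"].max()) - 1
            multi = utrs[["start", "end"]].drop_duplicates().shape[0] > 1
        elif len(cds):
            anchor_type = "SC"
            anchor = int(cds["start"].min()) - 1 if strand == "+" \
                else int(cds["end"].max()) - 1
            multi = False
        else:
            continue  # no UTR and no CDS: nothing to anchor on
        L = chrom_lengths[g.seqid]
        start = max(0, anchor - 150)
        end = min(L, anchor + 150)
        rows.append({"gene_id": gid, "anchor_type": anchor_type,
                     "chrom": g.seqid, "start": start, "end": end,
                     "anchor": anchor, "strand": strand, "multi_utr": multi})
    return pd.DataFrame(rows)


def shred(assembly: dict, assembly_name: str, frag: int = FRAG_LEN,
          step: int = FRAG_STEP) -> list:
    """Shred every sequence into ``frag`` bp pieces with ``step`` sliding.

    If the final full-length fragment does not land on a step multiple, a
    tail-anchored fragment starting at L - frag is added.  Sequences
    shorter than ``frag`` emit themselves once, flagged ``short``.
    """
    fragments = []
    for name, seq in assembly.items():
        L = len(seq)
        if L == 0:
            continue
        if L < frag:
            fragments.append(Fragment(assembly_name, name, 0, seq, short=True))
            continue
        starts = list(range(0, L - frag + 1, step))
        if starts[-1] != L - frag:
            starts.append(L - frag)
        for s in starts:
            fragments.append(Fragment(assembly_name, name, s, seq[s:s + frag]))
    return fragments


class KmerIndex:
    """Exact k-mer index of a reference for seed-and-extend mapping."""

    def __init__(self, reference: dict, k: int = 21):
        self.reference = reference
        self.k = k
        self.index = defaultdict(list)
        for chrom, seq in reference.items():
            for i in range(len(seq) - k + 1):
                self.index[seq[i:i + k]].append((chrom, i))

    def candidate_placements(self, query: str, stride: int | None = None):
        """Distinct (chrom, offset) placements suggested by seed k-mers."""
        k = self.k
        stride = stride or max(1, k // 2)
        placements = set()
        positions = list(range(0, len(query) - k + 1, stride))
        if positions and positions[-1] != len(query) - k:
            positions.append(len(query) - k)
        for qpos in positions:
            for chrom, rpos in self.index.get(query[qpos:qpos + k], ()):
                placements.add((chrom, rpos - qpos))
        return placements

    def score(self, query: str, chrom: str, offset: int,
              match: int = 1, mismatch: int = -4):
        """Ungapped alignment score of ``query`` at a reference placement."""
        ref = self.reference[chrom]
        lo = max(0, offset)
        hi = min(len(ref), offset + len(query))
        if hi - lo < len(query) // 2:
            return None
        q = query[lo - offset:hi - offset]
        r = ref[lo:hi]
        mismatches = sum(a != b for a, b in zip(q, r))
        return (len(q) - mismatches) * match + mismatches * mismatch

    def align(self, query: str, both_strands: bool = True):
        """All placements with their scores, best first."""
        hits = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            if strand == "-" and not both_strands:
                continue
            for chrom, offset in self.candidate_placements(q):
                s = self.score(q, chrom, offset)
                if s is not None:
                    hits.append((s, chrom, offset, strand))
        hits.sort(key=lambda h: (-h[0], h[1], h[2]))
        return hits


def map_fragments(fragments, reference: dict, index: KmerIndex | None = None,
                  min_margin: int = 20, min_score_frac: float = 0.5) -> list:
    """Map fragments uniquely to the reference.

    A fragment is retained only when its best placement beats the second
    best by >= ``min_margin`` score points (the MAPQ >= 20 proxy) and the
    best score reaches ``min_score_frac`` of the perfect score.  Only
    plus-strand placements are stored for retained fragments (capture
    consensus building works on the reference strand).
    """
    index = index or KmerIndex(reference)
    mapped = []
    for frag in fragments:
        hits = index.align(frag.sequence)
        if not hits:
            continue
        best = hits[0]
        if best[0] < min_score_frac * len(frag.sequence):
            continue
        if len(hits) > 1 and best[0] - hits[1][0] < min_margin:
            continue  # ambiguous placement
        score, chrom, offset, strand = best
        seq = frag.sequence if strand == "+" else revcomp(frag.sequence)
        mapped.append(Fragment(frag.assembly, frag.source_seq,
                               frag.source_start, seq, short=frag.short,
                               chrom=chrom, ref_start=offset, score=score,
                               margin=(best[0] - hits[1][0]) if len(hits) > 1
                               else score))
    return mapped


def extract_consensus(mapped_fragments, targets: pd.DataFrame,
                      min_length: int = MIN_OVERLAP) -> pd.DataFrame:
    """Per-target per-assembly majority-vote consensus, split by side.

    For each target the window is cut at the anchor into an upstream and a
    downstream side (strand-aware).  Within each assembly the mapped
    fragments overlapping a side are collapsed column-wise by majority
    base; coverage gaps split the consensus into separate pieces, of
    which the longest is kept.  Pieces shorter than ``min_length`` are
    discarded: they can neither seed an assembly overlap nor reach probe
    length.
    """
    by_assembly = defaultdict(list)
    for f in mapped_fragments:
        by_assembly[f.assembly].append(f)
    rows = []
    for t in targets.itertuples(index=False):
        anchor = t.anchor
        if t.strand == "+":
            sides = {"upstream": (t.start, anchor), "downstream": (anchor, t.end)}
        else:
            sides = {"upstream": (anchor, t.end), "downstream": (t.start, anchor)}
        for side, (lo, hi) in sides.items():
            if hi <= lo:
                continue
            width = hi - lo
            for assembly, frags in by_assembly.items():
                votes = np.zeros((width, 5), dtype=np.int32)  # ACGTN
                covered = np.zeros(width, dtype=bool)
                code = {"A": 0, "C": 1, "G": 2, "T": 3}
                for f in frags:
                    if f.chrom != t.chrom:
                        continue
                    s = max(lo, f.ref_start)
                    e = min(hi, f.ref_start + len(f.sequence))
                    if e <= s:
                        continue
                    piece = f.sequence[s - f.ref_start:e - f.ref_start]
                    for i, base in enumerate(piece):
                        votes[s - lo + i, code.get(base, 4)] += 1
                    covered[s - lo:e - lo] = True
                if not covered.any():
                    continue
                consensus = np.array(list("ACGTN"))[votes.argmax(axis=1)]
                # split at coverage gaps, keep the longest covered run
                runs = []
                start = None
                for i, c in enumerate(covered):
                    if c and start is None:
                        start = i
                    elif not c and start is not None:
                        runs.append((start, i))
                        start = None
                if start is not None:
                    runs.append((start, width))
                run = max(runs, key=lambda r: r[1] - r[0])
                if run[1] - run[0] < min_length:
                    continue
                seq = "".join(consensus[run[0]:run[1]])
                rows.append({"gene_id": t.gene_id, "side": side,
                             "assembly": assembly, "sequence": seq,
                             "n_pieces": len(runs)})
    return pd.DataFrame(rows, columns=["gene_id", "side", "assembly",
                                       "sequence", "n_pieces"])


def _overlap_merge(a: str, b: str):
    """Best ungapped merge of two sequences, or None.

    Considers containment and suffix-prefix overlaps in both orders;
    accepts the longest overlap >= MIN_OVERLAP with a mismatch rate
    <= MAX_MISMATCH_RATE.  Returns (merged sequence, overlap length).
    """
    best = None
    for shift in range(-(len(b) - MIN_OVERLAP), len(a) - MIN_OVERLAP + 1):
        lo = max(0, shift)
        hi = min(len(a), shift + len(b))
        ov = hi - lo
        if ov < MIN_OVERLAP:
            continue
        seg_a = a[lo:hi]
        seg_b = b[lo - shift:hi - shift]
        mism = sum(x != y for x, y in zip(seg_a, seg_b))
        if mism > MAX_MISMATCH_RATE * ov:
            continue
        prefix = a[:lo] if shift >= 0 else b[:-shift]
        suffix = b[hi - shift:] if shift + len(b) > len(a) else a[hi:]
        merged = prefix + seg_a + suffix
        if best is None or ov > best[1]:
            best = (merged, ov)
    return best


def assemble_candidates(consensus: pd.DataFrame, side: str) -> list:
    """Greedy overlap-layout assembly of one side's consensus sequences.

    Repeatedly merges the pair with the longest ungapped overlap
    >= 120 bp and <= 3 % mismatches (ties broken by the lexicographically
    smallest pair of current contig ids) until no merge applies.  Every
    final contig becomes a :class:`ProbeCandidate` whose sources record
    the contributing assemblies.
    """
    sub = consensus[consensus["side"] == side]
    contigs = {}
    for i, row in enumerate(sub.itertuples(index=False)):
        cid = f"{side}_{row.gene_id}_{row.assembly}_{i}"
        contigs[cid] = (row.sequence, {row.assembly})
    while True:
        best = None
        ids = sorted(contigs)
        for i, ca in enumerate(ids):
            for cb in ids[i + 1:]:
                m = _overlap_merge(contigs[ca][0], contigs[cb][0])
                if m is None:
                    continue
                key = (-m[1], ca, cb)
                if best is None or key < best[0]:
                    best = (key, ca, cb, m[0])
        if best is None:
            break
        _, ca, cb, merged = best
        sources = contigs[ca][1] | contigs[cb][1]
        del contigs[ca], contigs[cb]
        contigs[min(ca, cb)] = (merged, sources)
    out = []
    for i, cid in enumerate(sorted(contigs)):
        seq, sources = contigs[cid]
        out.append(ProbeCandidate(id=f"{side}_{i:04d}", side=side,
                                  sequence=seq, sources=sources))
    return out


def _valid_alignment(index: KmerIndex, seq: str, min_cov_frac: float = 0.8,
                     min_identity: float = 0.9) -> bool:
    hits = index.align(seq)
    for score, chrom, offset, strand in hits:
        q = seq if strand == "+" else revcomp(seq)
        ref = index.reference[chrom]
        lo, hi = max(0, offset), min(len(ref), offset + len(q))
        aligned = hi - lo
        if aligned < min_cov_frac * len(seq):
            continue
        mism = sum(a != b for a, b in
                   zip(q[lo - offset:hi - offset], ref[lo:hi]))
        if 1.0 - mism / aligned >= min_identity:
            return True
    return False


def filter_candidates(candidates, reference: dict, targets: pd.DataFrame,
                      chloroplast: dict | None, assemblies: dict,
                      min_assemblies: int = 8, min_hit_score: int = 80,
                      chloroplast_max_mismatch: float = 0.10) -> list:
    """Apply the four probe filters; annotate each candidate's status.

    (i) candidates identical (or reverse-complement identical) to an
    earlier candidate across the upstream+downstream sets are redundant;
    (ii) candidates aligning to the chloroplast genome with <= 10 %
    mismatches are removed; (iii) candidates with a valid alignment
    (>= 80 % of their length at >= 90 % identity) in fewer than
    ``min_assemblies`` of the used assemblies are removed; (iv) candidates
    with more off-target than on-target reference hits (ungapped score
    >= ``min_hit_score``) are removed.  Rules apply in that order; the
    first failure sets the status.
    """
    ref_index = KmerIndex(reference)
    chl_index = KmerIndex(chloroplast) if chloroplast else None
    if chloroplast is None:
        import warnings

        warnings.warn("no chloroplast genome: filter (ii) skipped", stacklevel=2)
    assembly_indexes = {name: KmerIndex(seqs) for name, seqs in assemblies.items()}
    target_iv = defaultdict(list)
    for t in targets.itertuples(index=False):
        target_iv[t.chrom].append((t.start, t.end))

    seen = {}
    for cand in candidates:
        # (i) redundancy across sets
        key = min(cand.sequence, revcomp(cand.sequence))
        if key in seen:
            cand.status = "removed:redundant"
            continue
        seen[key] = cand.id
        # (ii) chloroplast similarity
        if chl_index is not None:
            hits = chl_index.align(cand.sequence)
            for score, chrom, offset, strand in hits:
                q = cand.sequence if strand == "+" else revcomp(cand.sequence)
                ref = chl_index.reference[chrom]
                lo, hi = max(0, offset), min(len(ref), offset + len(q))
                if hi - lo < 0.8 * len(q):
                    continue
                mism = sum(a != b for a, b in
                           zip(q[lo - offset:hi - offset], ref[lo:hi]))
                if mism <= chloroplast_max_mismatch * (hi - lo):
                    cand.chloroplast_hit = True
                    break
            if cand.chloroplast_hit:
                cand.status = "removed:chloroplast"
                continue
        # (iii) presence across the pan-genome
        n_valid = sum(_valid_alignment(idx, cand.sequence)
                      for idx in assembly_indexes.values())
        if n_valid < min_assemblies:
            cand.status = "removed:few_assemblies"
            continue
        # (iv) on- vs off-target reference hits
        on = off = 0
        for score, chrom, offset, strand in ref_index.align(cand.sequence):
            if score < min_hit_score:
                continue
            span = (offset, offset + len(cand.sequence))
            if any(span[0] < e and s < span[1] for s, e in target_iv.get(chrom, ())):
                on += 1
            else:
                off += 1
        cand.on_target_hits = on
        cand.off_target_hits = off
        if off > on:
            cand.status = "removed:off_target"
            continue
        cand.status = "retained"
    return candidates
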