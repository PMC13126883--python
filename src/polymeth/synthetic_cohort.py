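"""Synthetic capture-bisulfite cohort generator.

Generates a complete desk-scale study of natural and synthetic hexaploid
wheat under a single seed: a triad-structured annotation on three
subgenome chromosomes (A, B, D), per-sample per-replicate cytosine-level
count tables, an unmethylated chloroplast control, per-library TPM tables,
DEG lists, and ground-truth tables for every injected effect.

The emulated design is nine genotypes with two biological replicates each:

* parents -- the AB tetraploid ``Langdon`` and the D diploids
  ``Tauschii-109`` and ``Tauschii-87``;
* synthetics -- ``109xL-C2``, ``109xL-C4`` and ``Lx109-C2`` derived from
  Langdon x Tauschii-109 (reciprocal crosses, two generations), plus
  ``Jx109-S5`` and ``Jx87-S5`` derived from the unsampled AB genotype
  ``Joyau``;
* the natural hexaploid ``Recital``.

Synthetic subgenome methylomes inherit the parental latent site levels
(AB from the AB parent, D from the D parent) except at injected
differentially methylated genes, where the latent level of every cytosine
of the chosen context is shifted by exactly +/- ``dmr_effect``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats_io
from .formats_io import REGION_LENGTH, SampleEntry, SampleSheet

__all__ = ["SimConfig", "CohortTruth", "Cohort", "build_annotation",
           "simulate_methylomes", "simulate_expression", "generate_cohort",
           "load_cohort", "Annotation"]

_BASES = np.array(list("ACGT"))
_TRINUCS = np.array(["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"])
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT encoding

SUBGENOMES = ("A", "B", "D")

#: founder genotypes and the subgenomes they carry
FOUNDERS = {
    "Langdon": ("A", "B"),
    "Joyau": ("A", "B"),
    "Tauschii-109": ("D",),
    "Tauschii-87": ("D",),
    "Recital": ("A", "B", "D"),
}

#: sampled genotypes: role and (AB founder, D founder)
GENOTYPES = {
    "Langdon": ("parent_AB", "Langdon", None),
    "Tauschii-109": ("parent_D", None, "Tauschii-109"),
    "Tauschii-87": ("parent_D", None, "Tauschii-87"),
    "109xL-C2": ("synthetic", "Langdon", "Tauschii-109"),
    "109xL-C4": ("synthetic", "Langdon", "Tauschii-109"),
    "Lx109-C2": ("synthetic", "Langdon", "Tauschii-109"),
    "Jx109-S5": ("synthetic", "Joyau", "Tauschii-109"),
    "Jx87-S5": ("synthetic", "Joyau", "Tauschii-87"),
    "Recital": ("natural", "Recital", "Recital"),
}

#: synthetics whose both parents are sampled; injected DMR/DEG effects
#: apply to these (parent-vs-synthetic truth is observable only here)
INJECTABLE_SYNTHETICS = ("109xL-C2", "109xL-C4", "Lx109-C2")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the real design: context-specific methylation with
    CpG around 20-27 %, CHG 12-15 % and CHH 2-3 % apparent levels,
    subgenome offsets ordered B > A > D, a ~2 % non-conversion background
    measured on an unmethylated chloroplast, negative-binomial coverage
    around 30x, and two replicates for each of the nine genotypes.
    """

    n_triads: int = 300
    chrom_lengths: dict = field(default_factory=lambda: {
        "A": 40_000_000, "B": 40_000_000, "D": 40_000_000})
    centromere_frac: float = 0.5  # centromere position as fraction of length
    frac_with_utr: float = 0.637
    # mean latent level per context for silent / expressed genes
    context_levels: dict = field(default_factory=lambda: {
        "CpG": {"silent": 0.26, "expressed": 0.20},
        "CHG": {"silent": 0.12, "expressed": 0.10},
        "CHH": {"silent": 0.05, "expressed": 0.04},
    })
    subgenome_offsets: dict = field(default_factory=lambda: {
        "A": 0.0, "B": 0.02, "D": -0.02})
    frac_expressed: float = 0.55
    triad_category_mix: dict = field(default_factory=lambda: {
        "balanced": 0.7, "suppressed": 0.2, "dominant": 0.1})
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    nonconversion_rate: float = 0.02
    error_rate: float = 0.0  # chance a methylated C reads as converted
    beta_precision: float = 3.0
    gene_level_sigma: float = 0.8  # sd of the log-normal per-gene effect
    chh_zero_fraction: float = 0.85
    centromere_gradient: float = 0.10  # level bump within 10 % of centromere
    centromere_reach: float = 0.10
    n_injected_dmrs: int = 30
    dmr_effect: float = 0.40
    dmr_context: str = "CpG"
    n_injected_degs: int = 30
    deg_fold: float = 4.0
    n_replicates: int = 2
    chloroplast_length: int = 6000
    seed: int = 0

    def validate(self) -> None:
        fracs = {"frac_with_utr": self.frac_with_utr,
                 "frac_expressed": self.frac_expressed,
                 "nonconversion_rate": self.nonconversion_rate,
                 "chh_zero_fraction": self.chh_zero_fraction}
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if abs(sum(self.triad_category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("triad_category_mix must sum to 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.dmr_effect < 0.25:
            raise ValueError("dmr_effect below the 25-point call threshold")


@dataclass
class CohortTruth:
    """Ground truth of every injected effect, for parameter-recovery tests."""

    dmr_truth: pd.DataFrame  # gene_id, context, effect, direction, samples
    deg_truth: pd.DataFrame  # gene_id, direction
    expression_class: pd.DataFrame  # gene_id, expr_class
    triad_category_truth: pd.DataFrame  # triad_id, cat_A, cat_B, cat_D


@dataclass
class Annotation:
    genes: pd.DataFrame
    triads: pd.DataFrame
    regions: pd.DataFrame
    centromeres: pd.DataFrame
    chrom_lengths: dict


@dataclass
class Cohort:
    config: SimConfig
    annotation: Annotation
    sample_sheet: SampleSheet
    methylomes: dict  # (sample_id, replicate) -> cytosine DataFrame
    chloroplast: dict  # (sample_id, replicate) -> cytosine DataFrame
    expression: pd.DataFrame
    deg_lists: dict  # synthetic sample_id -> DataFrame(gene_id, direction)
    truth: CohortTruth
    sites: pd.DataFrame  # internal per-site table (not written to disk)

    def write(self, outdir) -> None:
        write_cohort(self, outdir)


def build_annotation(config: SimConfig, rng: np.random.Generator | None = None) -> Annotation:
    """Draw the gene/triad annotation and 300 bp target regions.

    Each triad has one gene per subgenome, placed at evenly spaced,
    jittered, non-overlapping positions on the subgenome's chromosome.
    An exact count round(frac_with_utr * n_genes) of genes receive a TSS
    anchor (the rest SC), randomly assigned; each gene yields one 300 bp
    region centred on its anchor.
    """
    config.validate()
    if config.n_triads < 1:
        raise ValueError("n_triads must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_triads
    margin = 1000
    genes_rows = []
    for sg in SUBGENOMES:
        L = int(config.chrom_lengths[sg])
        spacing = (L - 2 * margin) / n
        if spacing < 2 * REGION_LENGTH:
            raise ValueError(
                f"chromosome for subgenome {sg} too short for {n} genes")
        base = margin + spacing * np.arange(n)
        jitter = rng.uniform(0, spacing - REGION_LENGTH - 1, size=n)
        anchors = (base + jitter).astype(np.int64) + 150
        strands = rng.choice(["+", "-"], size=n)
        for i in range(n):
            genes_rows.append({
                "gene_id": f"g{i + 1:05d}{sg}",
                "triad_id": f"t{i + 1:05d}",
                "subgenome": sg,
                "chrom": f"chr1{sg}",
                "strand": strands[i],
                "anchor_pos": anchors[i],  # 0-based
            })
    genes = pd.DataFrame(genes_rows)
    n_genes = len(genes)
    n_tss = int(round(config.frac_with_utr * n_genes))
    anchor_type = np.array(["SC"] * n_genes, dtype=object)
    anchor_type[rng.permutation(n_genes)[:n_tss]] = "TSS"
    genes["anchor_type"] = anchor_type
    genes["multi_utr"] = False
    genes["region_start"] = genes["anchor_pos"] - 150
    genes["region_end"] = genes["anchor_pos"] + 150

    # latent expression class: active triads have expressed homeologs
    active = rng.random(n) < config.frac_expressed
    triad_active = dict(zip([f"t{i + 1:05d}" for i in range(n)], active))
    genes["expr_class"] = np.where(
        genes["triad_id"].map(triad_active), "expressed", "silent")

    triads = pd.DataFrame({
        "triad_id": [f"t{i + 1:05d}" for i in range(n)],
        "gene_A": [f"g{i + 1:05d}A" for i in range(n)],
        "gene_B": [f"g{i + 1:05d}B" for i in range(n)],
        "gene_D": [f"g{i + 1:05d}D" for i in range(n)],
    })
    regions = genes[["gene_id", "anchor_type", "chrom", "region_start",
                     "region_end", "subgenome", "strand", "multi_utr"]].copy()
    regions = regions.rename(columns={"region_start": "start", "region_end": "end"})
    regions = regions.reset_index(drop=True)
    centromeres = pd.DataFrame({
        "chrom": [f"chr1{sg}" for sg in SUBGENOMES],
        "position": [int(config.chrom_lengths[sg] * config.centromere_frac)
                     for sg in SUBGENOMES],
        "chrom_length": [int(config.chrom_lengths[sg]) for sg in SUBGENOMES],
    })
    return Annotation(genes=genes, triads=triads, regions=regions,
                      centromeres=centromeres,
                      chrom_lengths={f"chr1{sg}": int(config.chrom_lengths[sg])
                                     for sg in SUBGENOMES})


def default_sample_sheet(config: SimConfig) -> SampleSheet:
    samples = []
    for sample_id, (role, ab, d) in GENOTYPES.items():
        reps = [{"replicate": r + 1,
                 "cytosine_report": f"meth/{sample_id}_rep{r + 1}.cytosine_report.tsv",
                 "chloroplast_report": f"meth/{sample_id}_rep{r + 1}.chloroplast.tsv"}
                for r in range(config.n_replicates)]
        samples.append(SampleEntry(sample_id=sample_id, genotype=sample_id,
                                   role=role, replicates=reps,
                                   parent_ab=ab if role == "synthetic" else None,
                                   parent_d=d if role == "synthetic" else None))
    return SampleSheet(samples=samples)


def _region_sites(annotation: Annotation, rng: np.random.Generator) -> pd.DataFrame:
    """Place cytosines in every region from a drawn 300 bp sequence.

    The sequence is drawn with 2 bp of flanking context so that every
    position has a full trinucleotide on both strands.
    """
    regions = annotation.regions
    n_regions = len(regions)
    seq = rng.integers(0, 4, size=(n_regions, REGION_LENGTH + 4), dtype=np.int8)
    body = seq[:, 2:-2]
    rows = []
    # plus strand: C at offset j, context from j+1, j+2
    nxt1, nxt2 = seq[:, 3:-1], seq[:, 4:]
    is_c = body == 1
    ctx_plus = np.where(nxt1 == 2, 0, np.where(nxt2 == 2, 1, 2))
    tri_plus = body * 16 + nxt1 * 4 + nxt2
    # minus strand: G at offset j, context from j-1, j-2 (complemented)
    prv1, prv2 = seq[:, 1:-3], seq[:, 0:-4]
    is_g = body == 2
    ctx_minus = np.where(prv1 == 1, 0, np.where(prv2 == 1, 1, 2))
    tri_minus = (_COMPLEMENT[body] * 16 + _COMPLEMENT[prv1] * 4
                 + _COMPLEMENT[prv2])
    ctx_names = np.array(["CpG", "CHG", "CHH"])
    for strand, mask, ctx, tri in (("+", is_c, ctx_plus, tri_plus),
                                   ("-", is_g, ctx_minus, tri_minus)):
        reg_idx, offset = np.nonzero(mask)
        rows.append(pd.DataFrame({
            "region_idx": reg_idx,
            "offset": offset,
            "strand": strand,
            "context": ctx_names[ctx[reg_idx, offset]],
            "trinucleotide": _TRINUCS[tri[reg_idx, offset]],
        }))
    sites = pd.concat(rows, ignore_index=True)
    sites = sites.sort_values(["region_idx", "offset", "strand"],
                              kind="stable").reset_index(drop=True)
    reg = regions.loc[sites["region_idx"]]
    sites["chrom"] = reg["chrom"].to_numpy()
    sites["pos"] = reg["start"].to_numpy() + sites["offset"].to_numpy() + 1
    sites["subgenome"] = reg["subgenome"].to_numpy()
    sites["gene_id"] = reg["gene_id"].to_numpy()
    return sites


def _site_means(sites: pd.DataFrame, annotation: Annotation,
                config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    genes = annotation.genes.set_index("gene_id")
    expr_class = genes.loc[sites["gene_id"], "expr_class"].to_numpy()
    means = np.empty(len(sites))
    for ctx, levels in config.context_levels.items():
        for cls, mu in levels.items():
            sel = (sites["context"].to_numpy() == ctx) & (expr_class == cls)
            means[sel] = mu
    offsets = sites["subgenome"].map(config.subgenome_offsets).to_numpy()
    means = means + offsets
    # per-(gene, context) log-normal effect (unit mean): genes are
    # coherently more or less methylated than their class average, which
    # gives the wide per-gene spread seen in real capture data
    sigma = config.gene_level_sigma
    if sigma > 0:
        keys = pd.MultiIndex.from_arrays(
            [sites["gene_id"], sites["context"]])
        uniq = keys.unique()
        mult = pd.Series(
            np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, size=len(uniq))),
            index=uniq)
        means = means * mult.loc[keys].to_numpy()
    # centromere-proximity gradient
    cen = annotation.centromeres.set_index("chrom")
    cen_pos = cen.loc[sites["chrom"], "position"].to_numpy()
    cen_len = cen.loc[sites["chrom"], "chrom_length"].to_numpy()
    near = np.abs(sites["pos"].to_numpy() - cen_pos) <= config.centromere_reach * cen_len
    means = means + np.where(near, config.centromere_gradient, 0.0)
    return np.clip(means, 0.001, 0.985)


def _draw_latents(means: np.ndarray, chh_zero: np.ndarray,
                  config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    prec = config.beta_precision
    latent = rng.beta(means * prec, (1.0 - means) * prec)
    latent[chh_zero] = 0.0
    return latent


def simulate_methylomes(annotation: Annotation, config: SimConfig,
                        sample_sheet: SampleSheet | None = None,
                        rng: np.random.Generator | None = None):
    """Simulate per-library cytosine tables plus the chloroplast control.

    Returns ``(methylomes, chloroplast, dmr_truth, sites)`` where
    methylomes maps (sample_id, replicate) to a cytosine DataFrame.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    sheet = sample_sheet or default_sample_sheet(config)
    sites = _region_sites(annotation, rng)
    n_sites = len(sites)
    means = _site_means(sites, annotation, config, rng)
    chh_zero = (sites["context"].to_numpy() == "CHH") & (
        rng.random(n_sites) < config.chh_zero_fraction)

    founder_latents = {}
    for founder, sgs in FOUNDERS.items():
        latent = _draw_latents(means, chh_zero, config, rng)
        founder_latents[founder] = latent  # values outside sgs never used

    # ---- injected DMRs: shift synthetic latents away from the parent ----
    genes = annotation.genes
    if config.n_injected_dmrs > len(genes):
        raise ValueError("requested more injected DMRs than genes")
    dmr_gene_idx = rng.choice(len(genes), size=config.n_injected_dmrs,
                              replace=False)
    dmr_genes = genes.iloc[sorted(dmr_gene_idx)]
    directions = rng.choice(["hyper", "hypo"], size=len(dmr_genes))
    effect = config.dmr_effect
    dmr_shift = {}  # gene_id -> (direction, parent founder key)
    truth_rows = []
    gene_arr = sites["gene_id"].to_numpy()
    ctx_arr = sites["context"].to_numpy()
    for (_, g), direction in zip(dmr_genes.iterrows(), directions):
        parent = "Langdon" if g.subgenome in ("A", "B") else "Tauschii-109"
        sel = (gene_arr == g.gene_id) & (ctx_arr == config.dmr_context)
        base = founder_latents[parent]
        # clamp the parental latent into the feasible range so that the
        # shifted synthetic level stays inside [0, 1] with the exact effect
        if direction == "hyper":
            base[sel] = np.minimum(base[sel], 1.0 - effect)
        else:
            base[sel] = np.maximum(base[sel], effect)
        dmr_shift[g.gene_id] = (direction, sel)
        truth_rows.append({"gene_id": g.gene_id, "context": config.dmr_context,
                           "effect": effect, "direction": direction,
                           "subgenome": g.subgenome,
                           "samples": ";".join(INJECTABLE_SYNTHETICS)})
    dmr_truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "context", "effect", "direction",
                             "subgenome", "samples"])

    genotype_latents = {}
    for sample_id, (role, ab, d) in GENOTYPES.items():
        latent = np.full(n_sites, np.nan)
        sg = sites["subgenome"].to_numpy()
        if ab is not None:
            m = (sg == "A") | (sg == "B")
            latent[m] = founder_latents[ab][m]
        if d is not None:
            m = sg == "D"
            latent[m] = founder_latents[d][m]
        if role == "synthetic" and sample_id in INJECTABLE_SYNTHETICS:
            for gene_id, (direction, sel) in dmr_shift.items():
                shift = effect if direction == "hyper" else -effect
                latent[sel] = latent[sel] + shift
        genotype_latents[sample_id] = latent

    nc = config.nonconversion_rate
    err = config.error_rate
    k = config.coverage_dispersion
    p_nb = k / (k + config.coverage_mean)

    methylomes = {}
    chloroplast = {}
    chl_sites = _chloroplast_sites(config, rng)
    for entry in sheet:
        latent = genotype_latents[entry.sample_id]
        present = ~np.isnan(latent)
        sub = sites[present]
        lat = latent[present]
        apparent = lat * (1.0 - err) + nc * (1.0 - lat)
        for rep in range(1, len(entry.replicates) + 1):
            cov = rng.negative_binomial(k, p_nb, size=len(sub))
            meth = rng.binomial(cov, apparent)
            df = pd.DataFrame({
                "chrom": sub["chrom"].to_numpy(),
                "pos": sub["pos"].to_numpy(),
                "strand": sub["strand"].to_numpy(),
                "count_meth": meth,
                "count_unmeth": cov - meth,
                "context": sub["context"].to_numpy(),
                "trinucleotide": sub["trinucleotide"].to_numpy(),
            })
            methylomes[(entry.sample_id, rep)] = df
            ccov = rng.negative_binomial(k, p_nb, size=len(chl_sites))
            cmeth = rng.binomial(ccov, nc)
            cdf = chl_sites.copy()
            cdf["count_meth"] = cmeth
            cdf["count_unmeth"] = ccov - cmeth
            chloroplast[(entry.sample_id, rep)] = cdf[formats_io.CYTOSINE_COLUMNS]
    sites = sites.copy()
    for sample_id, latent in genotype_latents.items():
        sites[f"latent_{sample_id}"] = latent
    return methylomes, chloroplast, dmr_truth, sites


def _chloroplast_sites(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    L = config.chloroplast_length
    seq = rng.integers(0, 4, size=L + 4, dtype=np.int8)
    body = seq[2:-2]
    ctx_names = np.array(["CpG", "CHG", "CHH"])
    rows = []
    nxt1, nxt2, prv1, prv2 = seq[3:-1], seq[4:], seq[1:-3], seq[0:-4]
    for strand, mask, ctx, tri in (
        ("+", body == 1, np.where(nxt1 == 2, 0, np.where(nxt2 == 2, 1, 2)),
         body * 16 + nxt1 * 4 + nxt2),
        ("-", body == 2, np.where(prv1 == 1, 0, np.where(prv2 == 1, 1, 2)),
         _COMPLEMENT[body] * 16 + _COMPLEMENT[prv1] * 4 + _COMPLEMENT[prv2]),
    ):
        idx = np.nonzero(mask)[0]
        rows.append(pd.DataFrame({
            "chrom": "chloroplast",
            "pos": idx + 1,
            "strand": strand,
            "context": ctx_names[ctx[idx]],
            "trinucleotide": _TRINUCS[tri[idx]],
        }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


def _draw_contributions(category: str, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample a contribution triple inside a ternary domain."""
    lo, hi = 1.0 / 6.0, 2.0 / 3.0
    slot = rng.integers(0, 3)
    for _ in range(10000):
        if category == "balanced":
            c = rng.dirichlet([8.0, 8.0, 8.0])
            if np.all((c >= lo) & (c <= hi)):
                return c
        elif category == "suppressed":
            alpha = np.full(3, 6.0)
            alpha[slot] = 1.0
            c = rng.dirichlet(alpha)
            if c[slot] < lo and np.all(c <= hi):
                return c
        elif category == "dominant":
            alpha = np.full(3, 1.5)
            alpha[slot] = 12.0
            c = rng.dirichlet(alpha)
            if c[slot] > hi:
                return c
        else:
            raise ValueError(f"unknown category {category!r}")
    raise RuntimeError("contribution sampling did not converge")


def simulate_expression(annotation: Annotation, config: SimConfig,
                        sample_sheet: SampleSheet | None = None,
                        rng: np.random.Generator | None = None):
    """Simulate per-library TPM tables, triad structure and DEG lists.

    Returns ``(expression, deg_lists, deg_truth, triad_category_truth,
    expression_class)``.  Silent genes stay below 0.1 TPM in every library;
    expressed genes receive log-normal TPM shares of their triad total,
    with homeolog contributions drawn inside the configured ternary
    domains.  Injected DEGs receive a >= ``deg_fold`` shift between
    parents and the injectable synthetics.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    sheet = sample_sheet or default_sample_sheet(config)
    genes = annotation.genes
    triads = annotation.triads
    n = len(triads)

    cats = list(config.triad_category_mix)
    probs = np.array([config.triad_category_mix[c] for c in cats])
    triad_cats = rng.choice(cats, size=n, p=probs)

    lo, hi = 1.0 / 6.0, 2.0 / 3.0
    contrib = np.zeros((n, 3))
    active = genes.set_index("triad_id")["expr_class"].groupby(level=0).first() == "expressed"
    for i in range(n):
        contrib[i] = _draw_contributions(triad_cats[i], rng)

    def _cat(c):
        return "suppressed" if c < lo else ("dominant" if c > hi else "balanced")

    triad_category_truth = pd.DataFrame({
        "triad_id": triads["triad_id"],
        "triad_class": triad_cats,
        "cat_A": [_cat(c) for c in contrib[:, 0]],
        "cat_B": [_cat(c) for c in contrib[:, 1]],
        "cat_D": [_cat(c) for c in contrib[:, 2]],
    })

    total_tpm = np.exp(rng.normal(2.5, 1.2, size=n)) + 2.0
    base_tpm = {}  # gene_id -> baseline tpm
    for i, trow in enumerate(triads.itertuples(index=False)):
        is_active = bool(active.loc[trow.triad_id])
        for j, gid in enumerate((trow.gene_A, trow.gene_B, trow.gene_D)):
            base_tpm[gid] = total_tpm[i] * contrib[i, j] if is_active else 0.0

    expression_class = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "expr_class": genes["expr_class"],
    })

    # ---- injected DEGs among expressed genes ----
    expressed_ids = genes.loc[genes["expr_class"] == "expressed", "gene_id"]
    if config.n_injected_degs > len(expressed_ids):
        raise ValueError("requested more injected DEGs than expressed genes")
    deg_ids = rng.choice(expressed_ids.to_numpy(), size=config.n_injected_degs,
                         replace=False)
    deg_dirs = rng.choice(["up", "down"], size=len(deg_ids))
    deg_truth = pd.DataFrame({"gene_id": sorted(deg_ids)})
    dir_map = dict(zip(deg_ids, deg_dirs))
    deg_truth["direction"] = deg_truth["gene_id"].map(dir_map)

    gene_sub = genes.set_index("gene_id")["subgenome"]
    rows = []
    lib = 0
    for entry in sheet:
        _, ab, d = GENOTYPES[entry.sample_id]
        sgs = set()
        if ab is not None:
            sgs |= {"A", "B"}
        if d is not None:
            sgs |= {"D"}
        present = genes[genes["subgenome"].isin(sgs)]
        is_injected_synth = entry.sample_id in INJECTABLE_SYNTHETICS
        for rep in range(1, len(entry.replicates) + 1):
            lib += 1
            noise = np.exp(rng.normal(0.0, 0.2, size=len(present)))
            tpm = np.array([base_tpm[g] for g in present["gene_id"]]) * noise
            silent = present["expr_class"].to_numpy() == "silent"
            tpm[silent] = rng.uniform(0.0, 0.08, size=silent.sum())
            # expressed genes always clear the 0.1 TPM detection floor
            tpm[~silent] = np.maximum(tpm[~silent], 0.12)
            if is_injected_synth:
                for gid, direction in dir_map.items():
                    sel = present["gene_id"].to_numpy() == gid
                    if not sel.any():
                        continue
                    tpm[sel] = (tpm[sel] * config.deg_fold if direction == "up"
                                else tpm[sel] / config.deg_fold)
            rows.append(pd.DataFrame({
                "gene_id": present["gene_id"].to_numpy(),
                "sample_id": entry.sample_id,
                "library": lib,
                "tpm": np.round(tpm, 6),
            }))
    expression = pd.concat(rows, ignore_index=True)
    deg_lists = {s: deg_truth.copy() for s in INJECTABLE_SYNTHETICS}
    return expression, deg_lists, deg_truth, triad_category_truth, expression_class


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic study under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    annotation = build_annotation(config, rng=rng)
    sheet = default_sample_sheet(config)
    methylomes, chloro, dmr_truth, sites = simulate_methylomes(
        annotation, config, sheet, rng=rng)
    expression, deg_lists, deg_truth, triad_cats, expr_class = simulate_expression(
        annotation, config, sheet, rng=rng)
    truth = CohortTruth(dmr_truth=dmr_truth, deg_truth=deg_truth,
                        expression_class=expr_class,
                        triad_category_truth=triad_cats)
    return Cohort(config=config, annotation=annotation, sample_sheet=sheet,
                  methylomes=methylomes, chloroplast=chloro,
                  expression=expression, deg_lists=deg_lists, truth=truth,
                  sites=sites)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort to disk in the documented formats."""
    out = Path(outdir)
    (out / "meth").mkdir(parents=True, exist_ok=True)
    (out / "expression").mkdir(exist_ok=True)
    (out / "degs").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    ann = cohort.annotation
    formats_io.write_regions_bed(ann.regions, out / "regions.bed")
    ann.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    formats_io.write_triads(ann.triads, out / "triads.tsv")
    ann.centromeres.to_csv(out / "centromeres.tsv", sep="\t", index=False)
    formats_io.write_sample_sheet(cohort.sample_sheet, out / "sample_sheet.yaml")
    for entry in cohort.sample_sheet:
        for rep_info in entry.replicates:
            rep = rep_info["replicate"]
            formats_io.write_cytosine_report(
                cohort.methylomes[(entry.sample_id, rep)],
                out / "meth" / f"{entry.sample_id}_rep{rep}.cytosine_report.tsv")
            formats_io.write_cytosine_report(
                cohort.chloroplast[(entry.sample_id, rep)],
                out / "meth" / f"{entry.sample_id}_rep{rep}.chloroplast.tsv")
    formats_io.write_expression(cohort.expression, out / "expression" / "tpm.tsv")
    for sample_id, degs in cohort.deg_lists.items():
        formats_io.write_gene_set(degs, out / "degs" / f"{sample_id}.tsv")
    t = cohort.truth
    t.dmr_truth.to_csv(out / "truth" / "dmr_truth.tsv", sep="\t", index=False)
    t.deg_truth.to_csv(out / "truth" / "deg_truth.tsv", sep="\t", index=False)
    t.expression_class.to_csv(out / "truth" / "expression_class.tsv", sep="\t",
                              index=False)
    t.triad_category_truth.to_csv(out / "truth" / "triad_categories.tsv",
                                  sep="\t", index=False)


def load_cohort(outdir):
    """Read a written cohort back through the formats_io readers.

    Returns a dict of the on-disk tables (not a full :class:`Cohort`: the
    internal latent-site table is not persisted).
    """
    out = Path(outdir)
    sheet = formats_io.read_sample_sheet(out / "sample_sheet.yaml")
    regions = formats_io.read_regions_bed(out / "regions.bed")
    methylomes = {}
    chloroplast = {}
    for entry in sheet:
        for rep_info in entry.replicates:
            rep = rep_info["replicate"]
            methylomes[(entry.sample_id, rep)] = formats_io.read_cytosine_report(
                rep_info["cytosine_report"])
            if rep_info.get("chloroplast_report"):
                chloroplast[(entry.sample_id, rep)] = formats_io.read_cytosine_report(
                    rep_info["chloroplast_report"])
    result = {
        "sample_sheet": sheet,
        "regions": regions,
        "genes": pd.read_csv(out / "genes.tsv", sep="\t"),
        "triads": formats_io.read_triads(out / "triads.tsv", regions=regions),
        "centromeres": pd.read_csv(out / "centromeres.tsv", sep="\t"),
        "methylomes": methylomes,
        "chloroplast": chloroplast,
        "expression": formats_io.read_expression(out / "expression" / "tpm.tsv"),
        "deg_lists": {p.stem: formats_io.read_gene_sets(p)
                      for p in sorted((out / "degs").glob("*.tsv"))},
    }
    truth_dir = out / "truth"
    if truth_dir.exists():
        result["truth"] = {p.stem: pd.read_csv(p, sep="\t")
                           for p in sorted(truth_dir.glob("*.tsv"))}
    return result
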