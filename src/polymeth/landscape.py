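"""Genome-scale and fine-scale descriptive methylome analyses.

Covers the per-subgenome summaries (mean levels and pairwise Wilcoxon
tests on complete-case sites), chromosome scans of the target methylome
in 2 Mb windows with 1 Mb step, between-sample track similarity, a
prcomp-style PCA of site-level methylation (samples as observations,
sites centred and unit-scaled), 10 bp metaprofiles around TSS/SC split by
expression status, and the methylation / expression / centromere-distance
correlation triple.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .methcore import assign_regions

__all__ = [
    "CorrelationResult",
    "build_methylation_matrix",
    "subgenome_means",
    "chromosome_scan",
    "track_similarity",
    "pca_methylomes",
    "metaprofile",
    "classify_expression_status",
    "methylation_expression_correlations",
    "flag_outlier_genes",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    p: float
    n: int


def _pearson(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) < 1e-12 or np.std(y) < 1e-12:
        warnings.warn("correlation undefined (constant or too few values)",
                      stacklevel=2)
        return CorrelationResult(np.nan, np.nan, np.nan, len(x))
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(r * r), float(p), len(x))


def _spearman(x, y) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return CorrelationResult(np.nan, np.nan, np.nan, len(x))
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(float(r), float(r * r), float(p), len(x))


def build_methylation_matrix(samples: dict, min_cov: int = 10) -> pd.DataFrame:
    """Complete-case matrix of per-site levels across libraries.

    ``samples`` maps a library name to its cytosine DataFrame.  Only sites
    with coverage >= ``min_cov`` in *every* library are kept (complete
    case); entries are per-site methylated fractions.  The index carries
    (chrom, pos, strand, context).
    """
    merged = None
    for name, df in samples.items():
        cov = df["count_meth"] + df["count_unmeth"]
        sub = df.loc[cov >= min_cov,
                     ["chrom", "pos", "strand", "context"]].copy()
        sub[name] = (df.loc[cov >= min_cov, "count_meth"] / cov[cov >= min_cov]).to_numpy()
        merged = sub if merged is None else merged.merge(
            sub, on=["chrom", "pos", "strand", "context"], how="inner")
    if merged is None:
        raise ValueError("no samples supplied")
    return merged.set_index(["chrom", "pos", "strand", "context"])


_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for cutoff, mark in _STARS:
        if p < cutoff:
            return mark
    return "ns"


def subgenome_means(samples: dict, context: str, min_cov: int = 10):
    """Per-sample per-subgenome mean methylation with pairwise tests.

    Sites are restricted to positions covered >= ``min_cov`` in every
    sample (complete case) and to the requested context.  For each sample
    the unweighted mean of site levels per subgenome is reported; pairwise
    two-sided Wilcoxon rank-sum tests compare the site-level distributions
    of each subgenome pair within each sample.
    """
    matrix = build_methylation_matrix(samples, min_cov=min_cov)
    matrix = matrix[matrix.index.get_level_values("context") == context]
    chroms = matrix.index.get_level_values("chrom")
    subg = pd.Series([c[-1] if c and c[-1] in "ABD" else "unknown"
                      for c in chroms], index=matrix.index)
    means_rows, test_rows = [], []
    for name in matrix.columns:
        levels = matrix[name]
        groups = {}
        for sg in ("A", "B", "D"):
            vals = levels[subg == sg].to_numpy()
            if len(vals) == 0:
                warnings.warn(f"sample {name}: no qualifying {context} sites "
                              f"on subgenome {sg}", stacklevel=2)
                continue
            groups[sg] = vals
            means_rows.append({"sample": name, "subgenome": sg,
                               "context": context,
                               "mean_level": float(vals.mean()),
                               "n_sites": len(vals)})
        pairs = [("A", "B"), ("A", "D"), ("B", "D")]
        for a, b in pairs:
            if a not in groups or b not in groups:
                continue
            if min(len(groups[a]), len(groups[b])) < 3:
                warnings.warn(f"sample {name}: too few sites for {a} vs {b} "
                              "test; skipped", stacklevel=2)
                continue
            stat, p = stats.mannwhitneyu(groups[a], groups[b],
                                         alternative="two-sided")
            test_rows.append({"sample": name, "pair": f"{a}-{b}",
                              "context": context, "p": float(p),
                              "stars": _stars(p)})
    return pd.DataFrame(means_rows), pd.DataFrame(test_rows)


def chromosome_scan(records: pd.DataFrame, regions: pd.DataFrame,
                    chrom_lengths: dict, window: int = 2_000_000,
                    step: int = 1_000_000, min_cov: int = 3) -> pd.DataFrame:
    """Weighted target methylation along chromosomes in sliding windows.

    All sequence contexts are merged into a single track.  Only cytosines
    inside target regions with coverage >= ``min_cov`` contribute.
    Windows are emitted only when fully inside the chromosome; windows
    with no covered target cytosine get NaN level (a gap).
    """
    assigned = assign_regions(records, regions)
    cov = assigned["count_meth"] + assigned["count_unmeth"]
    assigned = assigned[(assigned["region_idx"] >= 0) & (cov >= min_cov)]
    rows = []
    for chrom, L in chrom_lengths.items():
        sub = assigned[assigned["chrom"] == chrom]
        pos = sub["pos"].to_numpy() - 1
        meth = sub["count_meth"].to_numpy()
        total = (sub["count_meth"] + sub["count_unmeth"]).to_numpy()
        start = 0
        while start + window <= L:
            inside = (pos >= start) & (pos < start + window)
            cov_sum = int(total[inside].sum())
            level = float(meth[inside].sum()) / cov_sum if cov_sum else np.nan
            rows.append({"chrom": chrom, "start": start, "end": start + window,
                         "weighted_level": level, "total_cov": cov_sum})
            start += step
    return pd.DataFrame(rows)


def track_similarity(tracks: dict, min_windows: int = 3):
    """Pairwise Pearson r and paired Wilcoxon p between scan tracks.

    Tracks must share a window grid; windows undefined (NaN) in either
    member of a pair are dropped pairwise.  Returns (r matrix, p matrix)
    as DataFrames; entries with fewer than ``min_windows`` shared windows
    are NaN.
    """
    names = list(tracks)
    vectors = {}
    for name in names:
        t = tracks[name].sort_values(["chrom", "start"])
        vectors[name] = t["weighted_level"].to_numpy()
    r_mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p_mat = pd.DataFrame(np.ones((len(names), len(names))), index=names,
                         columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            x, y = vectors[a], vectors[b]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_windows:
                r = p = np.nan
            else:
                r = float(stats.pearsonr(x[ok], y[ok])[0])
                d = x[ok] - y[ok]
                if np.allclose(d, 0.0):
                    p = 1.0
                else:
                    p = float(stats.wilcoxon(x[ok], y[ok])[1])
            r_mat.loc[a, b] = r_mat.loc[b, a] = r
            p_mat.loc[a, b] = p_mat.loc[b, a] = p
    return r_mat, p_mat


def pca_methylomes(matrix: pd.DataFrame, n_components: int = 4):
    """prcomp-style PCA of a methylation matrix.

    Columns (libraries) are the observations and sites the variables;
    variables are centred and unit-scaled, zero-variance sites dropped.
    Returns (coordinates DataFrame, variance-explained fractions).
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least two libraries")
    X = matrix.to_numpy(dtype=float).T  # observations x variables
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n_obs = X.shape[0]
    n_components = min(n_components, n_obs - 1, X.shape[1])
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    total_var = (s ** 2).sum()
    var_explained = (s[:n_components] ** 2) / total_var if total_var else s[:n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(coords, index=matrix.columns, columns=cols),
            var_explained)


def classify_expression_status(expression: pd.DataFrame, threshold: float = 0.1,
                               min_libraries: int = 2) -> pd.Series:
    """Expressed iff TPM exceeds ``threshold`` in >= ``min_libraries``."""
    counts = (expression.assign(hit=expression["tpm"] > threshold)
              .groupby("gene_id")["hit"].sum())
    return pd.Series(np.where(counts >= min_libraries, "expressed", "silent"),
                     index=counts.index, name="expr_class")


def metaprofile(samples: dict, regions: pd.DataFrame,
                expression_class: pd.Series, bin_size: int = 10,
                min_cov: int = 3, exclude_multi_utr: bool = True,
                contexts=("CpG", "CHG", "CHH")):
    """Binned mean methylation around TSS/SC by expression category.

    Each 300 bp region is cut into 30 bins of ``bin_size`` bp oriented
    5'->3' (bins are flipped for minus-strand genes).  Per bin the
    weighted level is computed per gene and sample, averaged over genes
    within each sample, and then averaged over samples (double
    averaging).  Genes with multiple 5'-UTR annotations are dropped from
    the TSS set.  Returns (profile, per_gene) where ``profile`` carries
    the across-sample mean and SD and ``per_gene`` the per-sample
    per-gene bin levels for across-gene variance summaries.
    """
    regs = regions.copy()
    if exclude_multi_utr:
        drop = (regs["anchor_type"] == "TSS") & regs["multi_utr"]
        regs = regs[~drop]
    n_bins = (regs["end"] - regs["start"]).iloc[0] // bin_size if len(regs) else 0
    per_sample_frames = []
    for name, df in samples.items():
        assigned = assign_regions(df, regs)
        cov = assigned["count_meth"] + assigned["count_unmeth"]
        assigned = assigned[(assigned["region_idx"] >= 0) & (cov >= min_cov)]
        reg = regs.loc[assigned["region_idx"]]
        offset = assigned["pos"].to_numpy() - 1 - reg["start"].to_numpy()
        flip = reg["strand"].to_numpy() == "-"
        rel = np.where(flip, (reg["end"] - reg["start"]).to_numpy() - 1 - offset,
                       offset)
        sub = assigned.copy()
        sub["bin"] = rel // bin_size
        sub["anchor_type"] = reg["anchor_type"].to_numpy()
        sub["expr_class"] = expression_class.reindex(sub["gene_id"]).to_numpy()
        sub = sub.dropna(subset=["expr_class"])
        sub = sub[sub["context"].isin(contexts)]
        grouped = (sub.groupby(["anchor_type", "expr_class", "context",
                                "bin", "gene_id"], observed=True)
                   .agg(m=("count_meth", "sum"),
                        u=("count_unmeth", "sum")).reset_index())
        grouped["level"] = grouped["m"] / (grouped["m"] + grouped["u"])
        grouped["sample"] = name
        per_sample_frames.append(grouped)
    per_gene = pd.concat(per_sample_frames, ignore_index=True)
    per_sample = (per_gene.groupby(["sample", "anchor_type", "expr_class",
                                    "context", "bin"], observed=True)["level"]
                  .mean().reset_index())
    profile = (per_sample.groupby(["anchor_type", "expr_class", "context",
                                   "bin"], observed=True)["level"]
               .agg(mean_level="mean", sd_samples="std").reset_index())
    profile["bin_start"] = profile["bin"] * bin_size - (n_bins // 2) * bin_size
    for key, grp in profile.groupby(["anchor_type", "expr_class"], observed=True):
        if len(grp) == 0:
            warnings.warn(f"empty metaprofile category {key}", stacklevel=2)
    return profile, per_gene


def methylation_expression_correlations(region_meth: pd.DataFrame,
                                        expression_tpm: pd.Series,
                                        centromeres: pd.DataFrame,
                                        context: str,
                                        exclude_multi_utr: bool = False,
                                        regions: pd.DataFrame | None = None,
                                        method: str = "pearson",
                                        min_genes: int = 10) -> dict:
    """Correlation triple: methylation ~ logTPM, methylation ~ centromere
    distance, logTPM ~ centromere distance.

    ``region_meth`` is a :func:`polymeth.methcore.region_methylation` table
    restricted to one sample; ``expression_tpm`` maps gene_id -> TPM for
    the matched sample.  The expression transform is log10(TPM + 1);
    centromere distance is |region midpoint - centromere| in bp.
    """
    meth = region_meth[region_meth["context"] == context].copy()
    meth = meth[meth["n_covered_cytosines"] > 0]
    if exclude_multi_utr and regions is not None:
        multi = set(regions.loc[(regions["anchor_type"] == "TSS")
                                & regions["multi_utr"], "gene_id"])
        meth = meth[~meth["gene_id"].isin(multi)]
    cen = centromeres.set_index("chrom")["position"]
    mid = (meth["start"] + meth["end"]) / 2.0
    meth["distance"] = (mid - meth["chrom"].map(cen)).abs()
    meth["log_tpm"] = np.log10(expression_tpm.reindex(meth["gene_id"]).to_numpy() + 1.0)
    meth = meth.dropna(subset=["log_tpm", "distance", "weighted_level"])
    if len(meth) < min_genes:
        warnings.warn("too few genes for correlation analysis", stacklevel=2)
        nan = CorrelationResult(np.nan, np.nan, np.nan, len(meth))
        return {"meth_expression": nan, "meth_distance": nan,
                "expression_distance": nan, "data": meth}
    corr = _pearson if method == "pearson" else _spearman
    return {
        "meth_expression": corr(meth["weighted_level"], meth["log_tpm"]),
        "meth_distance": corr(meth["weighted_level"], meth["distance"]),
        "expression_distance": corr(meth["log_tpm"], meth["distance"]),
        "data": meth,
    }


def flag_outlier_genes(cpg_levels: pd.Series, chg_levels: pd.Series,
                       tpm: pd.Series, tpm_threshold: float = 200.0,
                       cpg_threshold: float = 0.30, chg_threshold: float = 0.15,
                       percentile: float = 95.0) -> dict:
    """Highly expressed yet methylated gene sets for one sample.

    Set A: TPM > 200 and CpG level > 0.30 and simultaneously CHG > 0.15.
    Set B: genes above the sample's ``percentile`` of both the methylation
    (CpG) and expression distributions simultaneously.
    """
    genes = cpg_levels.index.intersection(chg_levels.index).intersection(tpm.index)
    cpg = cpg_levels.reindex(genes)
    chg = chg_levels.reindex(genes)
    t = tpm.reindex(genes)
    set_a = set(genes[(t > tpm_threshold) & (cpg > cpg_threshold)
                      & (chg > chg_threshold)])
    cpg_cut = np.nanpercentile(cpg, percentile)
    tpm_cut = np.nanpercentile(t, percentile)
    set_b = set(genes[(cpg > cpg_cut) & (t > tpm_cut)])
    return {"high_tpm_methylated": set_a, "double_p95": set_b}
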