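"""Differential methylation between sample groups.

The cytosine-level test is a binomial logistic regression of the
methylated proportion on a group indicator, fitted per site across
replicates.  With a single binary covariate the maximum-likelihood fit has
a closed form (the pooled proportion per group), so the likelihood-ratio
chi-square statistic is computed directly.  Overdispersion between
replicates is absorbed by scaling the statistic with the Pearson
dispersion estimate ``phi = max(1, Pearson chi2 / df)`` before the
p-value; p-values are Benjamini-Hochberg adjusted within each context.
A unit is called differentially methylated only when both criteria hold:
|level difference| above a threshold (default 25 percentage points) and
q (or raw p, per mode) below a cutoff (default 0.01).

Region-level variants apply the same test to summed counts, either over
fixed 300 bp target windows or over variable-length segments of
homogeneous methylation obtained by change-point analysis of the pooled
parental CpG methylome (binary segmentation accepting splits only when
the BIC improves, with a minimum of three qualifying CpG sites per
segment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .methcore import assign_regions

__all__ = ["dmc_test", "dmr_fixed_windows", "segment_parents", "dmr_segments",
           "overlap_test", "dmc_density", "OverlapResult", "pool_replicates",
           "combine_parents"]

SITE_KEY = ["chrom", "pos", "strand", "context"]


def combine_parents(parent_ab, parent_d):
    """Pair the AB and D parents' replicates into joint parent replicates.

    The AB parent carries only A/B chromosomes and the D parent only D, so
    replicate i of the combined parent is the concatenation of the two
    parents' replicate-i tables.  The result acts as one replicate group
    covering all three subgenomes in synthetic-vs-parent comparisons.
    """
    if len(parent_ab) != len(parent_d):
        raise ValueError("parents must supply the same number of replicates")
    return [pd.concat([a, d], ignore_index=True)
            for a, d in zip(parent_ab, parent_d)]


def _stack_groups(group1, group2, min_cov):
    """Inner-join replicate tables on sites covered >= min_cov everywhere.

    Returns (key frame, meth matrix, cov matrix, n1) with one column per
    replicate; group-1 replicates first.
    """
    frames = list(group1) + list(group2)
    merged = None
    for i, df in enumerate(frames):
        cov = df["count_meth"] + df["count_unmeth"]
        sub = df.loc[cov >= min_cov, SITE_KEY + ["count_meth"]].copy()
        sub[f"cov{i}"] = cov[cov >= min_cov].to_numpy()
        sub = sub.rename(columns={"count_meth": f"m{i}"})
        merged = sub if merged is None else merged.merge(sub, on=SITE_KEY, how="inner")
    if merged is None or len(merged) == 0:
        empty = pd.DataFrame(columns=SITE_KEY)
        return empty, np.zeros((0, 0)), np.zeros((0, 0)), len(group1)
    n = len(frames)
    meth = merged[[f"m{i}" for i in range(n)]].to_numpy(dtype=float)
    cov = merged[[f"cov{i}" for i in range(n)]].to_numpy(dtype=float)
    return merged[SITE_KEY].copy(), meth, cov, len(group1)


def _lrt_dispersion(meth: np.ndarray, cov: np.ndarray, n1: int):
    """Vectorised LRT with Pearson-dispersion scaling over unit rows.

    ``meth``/``cov`` have one row per tested unit and one column per
    replicate observation (group 1 first).  Returns (p, level1, level2).
    """
    m1 = meth[:, :n1].sum(axis=1)
    c1 = cov[:, :n1].sum(axis=1)
    m2 = meth[:, n1:].sum(axis=1)
    c2 = cov[:, n1:].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = m1 / c1
        p2 = m2 / c2
        p0 = (m1 + m2) / (c1 + c2)

    def ll(m, c, p):
        return xlogy(m, p) + xlogy(c - m, 1.0 - p)

    ll_alt = ll(m1, c1, p1) + ll(m2, c2, p2)
    ll_null = ll(m1 + m2, c1 + c2, p0)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)

    n_obs = meth.shape[1]
    df_resid = n_obs - 2
    if df_resid > 0:
        fitted = np.where(np.arange(n_obs)[None, :] < n1, p1[:, None], p2[:, None])
        with np.errstate(invalid="ignore", divide="ignore"):
            pearson = (meth - cov * fitted) ** 2 / (cov * fitted * (1.0 - fitted))
        pearson = np.where(np.isfinite(pearson), pearson, 0.0)
        phi = np.maximum(pearson.sum(axis=1) / df_resid, 1.0)
    else:
        phi = np.ones(len(lrt))
    p = stats.chi2.sf(lrt / phi, df=1)
    return p, p1, p2


def _fisher_fallback(meth, cov, n1):
    """Two-sided Fisher's exact test on pooled counts (1-vs-1 replicates)."""
    m1 = meth[:, :n1].sum(axis=1)
    c1 = cov[:, :n1].sum(axis=1)
    m2 = meth[:, n1:].sum(axis=1)
    c2 = cov[:, n1:].sum(axis=1)
    p = np.array([
        stats.fisher_exact([[m1[i], c1[i] - m1[i]], [m2[i], c2[i] - m2[i]]])[1]
        for i in range(len(m1))
    ]) if len(m1) else np.array([])
    with np.errstate(invalid="ignore", divide="ignore"):
        return p, m1 / c1, m2 / c2


def _finalize(table: pd.DataFrame, p, level1, level2, diff_threshold,
              q_cutoff, use_q, by_context=True) -> pd.DataFrame:
    out = table.copy()
    out["level_group1"] = level1
    out["level_group2"] = level2
    out["diff"] = 100.0 * (level2 - level1)
    out["p"] = p
    out["q"] = np.nan
    if len(out):
        if by_context and "context" in out.columns:
            for ctx, idx in out.groupby("context").groups.items():
                out.loc[idx, "q"] = multipletests(out.loc[idx, "p"],
                                                  method="fdr_bh")[1]
        else:
            out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    crit = out["q"] if use_q else out["p"]
    sig = (crit < q_cutoff) & (out["diff"].abs() > diff_threshold)
    out["status"] = np.where(~sig, "ns",
                             np.where(out["diff"] > 0, "hyper", "hypo"))
    return out


def dmc_test(group1, group2, min_cov: int = 10, diff_threshold: float = 25.0,
             q_cutoff: float = 0.01, use_q: bool = True) -> pd.DataFrame:
    """Per-cytosine differential methylation between two replicate groups.

    ``group1`` and ``group2`` are lists of per-replicate cytosine
    DataFrames.  Sites are tested only when covered >= ``min_cov`` in every
    replicate of both groups.  ``diff`` is reported in percentage points
    (group 2 minus group 1).  With a single replicate per group, the test
    falls back to a two-sided Fisher's exact test (column ``test`` says
    which was used).
    """
    table, meth, cov, n1 = _stack_groups(group1, group2, min_cov)
    if meth.shape[1] - 2 > 0:
        p, l1, l2 = _lrt_dispersion(meth, cov, n1)
        test = "lrt"
    else:
        p, l1, l2 = _fisher_fallback(meth, cov, n1)
        test = "fisher"
    out = _finalize(table, p, l1, l2, diff_threshold, q_cutoff, use_q)
    out["test"] = test
    return out


def _region_replicate_counts(replicates, regions, min_cov, context):
    """Sum per-replicate counts of qualifying sites over each region."""
    per_rep = []
    for df in replicates:
        cov = df["count_meth"] + df["count_unmeth"]
        sub = df[cov >= min_cov]
        if context is not None:
            sub = sub[sub["context"] == context]
        assigned = assign_regions(sub, regions)
        assigned = assigned[assigned["region_idx"] >= 0]
        agg = assigned.groupby("region_idx").agg(
            m=("count_meth", "sum"), u=("count_unmeth", "sum"),
            n_sites=("count_meth", "size"))
        per_rep.append(agg)
    return per_rep


def dmr_fixed_windows(group1, group2, regions: pd.DataFrame,
                      min_cov: int = 10, diff_threshold: float = 25.0,
                      q_cutoff: float = 0.01, use_q: bool = True,
                      contexts=("CpG", "CHG", "CHH")) -> pd.DataFrame:
    """Differential methylation over fixed 300 bp target windows.

    Counts of sites with coverage >= ``min_cov`` are summed per region and
    replicate, then tested with the same overdispersion-corrected logistic
    test as :func:`dmc_test`, separately per context.  Regions lacking a
    qualifying site in any replicate are untested.
    """
    results = []
    for ctx in contexts:
        reps1 = _region_replicate_counts(group1, regions, min_cov, ctx)
        reps2 = _region_replicate_counts(group2, regions, min_cov, ctx)
        common = None
        for agg in reps1 + reps2:
            idx = agg.index
            common = idx if common is None else common.intersection(idx)
        if common is None or len(common) == 0:
            continue
        common = common.sort_values()
        meth = np.column_stack([a.loc[common, "m"].to_numpy(dtype=float)
                                for a in reps1 + reps2])
        cov = meth + np.column_stack([a.loc[common, "u"].to_numpy(dtype=float)
                                      for a in reps1 + reps2])
        n1 = len(reps1)
        if meth.shape[1] - 2 > 0:
            p, l1, l2 = _lrt_dispersion(meth, cov, n1)
        else:
            p, l1, l2 = _fisher_fallback(meth, cov, n1)
        table = regions.loc[common, ["gene_id", "anchor_type", "chrom",
                                     "start", "end"]].copy()
        table["region_idx"] = common
        table["context"] = ctx
        results.append(_finalize(table.reset_index(drop=True), p, l1, l2,
                                 diff_threshold, q_cutoff, use_q))
    if not results:
        return pd.DataFrame(columns=["gene_id", "context", "status"])
    out = pd.concat(results, ignore_index=True)
    # BH was applied per context inside _finalize on each partial table
    return out


def pool_replicates(replicates) -> pd.DataFrame:
    """Pool replicate tables by summing counts per site."""
    merged = pd.concat(replicates, ignore_index=True)
    pooled = (merged.groupby(SITE_KEY + ["trinucleotide"], as_index=False, sort=True)
              .agg(count_meth=("count_meth", "sum"),
                   count_unmeth=("count_unmeth", "sum")))
    return pooled[["chrom", "pos", "strand", "count_meth", "count_unmeth",
                   "context", "trinucleotide"]]


def _binary_segment(levels: np.ndarray, min_size: int) -> list:
    """Recursive binary segmentation of a 1-D level signal.

    A split is accepted only if the BIC of the two-segment model improves
    on the one-segment model (per-segment mean parameters, one boundary
    parameter per split).  Returns sorted breakpoints (interior indices).
    """
    eps = 1e-12
    n = len(levels)

    def sse(x):
        return float(((x - x.mean()) ** 2).sum()) if len(x) else 0.0

    def bic(rss, k, m):
        return m * np.log((rss + eps) / m) + k * np.log(m)

    def recurse(lo, hi, breaks):
        m = hi - lo
        if m < 2 * min_size:
            return
        seg = levels[lo:hi]
        rss1 = sse(seg)
        best = None
        for cut in range(min_size, m - min_size + 1):
            rss2 = sse(seg[:cut]) + sse(seg[cut:])
            if best is None or rss2 < best[1]:
                best = (cut, rss2)
        if best is None:
            return
        cut, rss2 = best
        if bic(rss2, 4, m) < bic(rss1, 2, m):
            breaks.append(lo + cut)
            recurse(lo, lo + cut, breaks)
            recurse(lo + cut, hi, breaks)

    breaks: list = []
    recurse(0, n, breaks)
    return sorted(breaks)


def segment_parents(parent_ab, parent_d, regions: pd.DataFrame,
                    min_cpg: int = 3, min_cov: int = 10) -> pd.DataFrame:
    """Segment target regions into homogeneous-methylation CpG segments.

    Parental replicates are pooled by summing counts per site; within each
    target region the per-site pooled CpG levels (pooled coverage >=
    ``min_cov``) are split by binary change-point analysis.  Every
    emitted segment holds >= ``min_cpg`` qualifying CpG sites; regions
    with fewer qualifying CpGs in total yield one degenerate segment
    flagged untestable.
    """
    pooled = pool_replicates(list(parent_ab) + list(parent_d))
    cpg = pooled[pooled["context"] == "CpG"]
    cov = cpg["count_meth"] + cpg["count_unmeth"]
    cpg = cpg[cov >= min_cov]
    assigned = assign_regions(cpg, regions)
    assigned = assigned[assigned["region_idx"] >= 0]
    segments = []
    for region_idx, grp in assigned.groupby("region_idx"):
        grp = grp.sort_values(["pos", "strand"])
        pos = grp["pos"].to_numpy()
        cov = (grp["count_meth"] + grp["count_unmeth"]).to_numpy(dtype=float)
        levels = grp["count_meth"].to_numpy(dtype=float) / cov
        region = regions.loc[region_idx]
        if len(grp) < min_cpg:
            segments.append({
                "region_idx": region_idx, "gene_id": region["gene_id"],
                "chrom": region["chrom"], "start": region["start"],
                "end": region["end"], "n_cpg": len(grp),
                "mean_level": float(levels.mean()) if len(grp) else np.nan,
                "testable": False})
            continue
        breaks = _binary_segment(levels, min_size=min_cpg)
        bounds = [0] + breaks + [len(levels)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg_pos = pos[lo:hi]
            segments.append({
                "region_idx": region_idx, "gene_id": region["gene_id"],
                "chrom": region["chrom"],
                "start": int(seg_pos[0] - 1),
                "end": int(seg_pos[-1]),
                "n_cpg": hi - lo,
                "mean_level": float(levels[lo:hi].mean()),
                "testable": True})
    cols = ["region_idx", "gene_id", "chrom", "start", "end", "n_cpg",
            "mean_level", "testable"]
    return pd.DataFrame(segments, columns=cols)


def dmr_segments(group1, group2, segments: pd.DataFrame,
                 min_cov: int = 10, diff_threshold: float = 25.0,
                 q_cutoff: float = 0.01, use_q: bool = True,
                 contexts=("CpG", "CHG", "CHH")) -> pd.DataFrame:
    """Differential methylation over parental change-point segments."""
    testable = segments[segments["testable"]].reset_index(drop=True)
    if len(testable) == 0:
        return pd.DataFrame(columns=["gene_id", "context", "status"])
    seg_regions = testable.rename(columns={"start": "start", "end": "end"})
    seg_regions = seg_regions[["chrom", "start", "end", "gene_id"]].copy()
    seg_regions["anchor_type"] = "segment"
    out = dmr_fixed_windows(group1, group2, seg_regions, min_cov=min_cov,
                            diff_threshold=diff_threshold, q_cutoff=q_cutoff,
                            use_q=use_q, contexts=contexts)
    return out


@dataclass(frozen=True)
class OverlapResult:
    n1: int
    n2: int
    universe: int
    observed: int
    expected: float
    p: float
    method: str


def overlap_test(set1, set2, universe_size: int,
                 exact_max_universe: int = 100_000) -> OverlapResult:
    """Hypergeometric test of the overlap between two gene sets.

    The expectation under independence is n1*n2/N; the p-value is the
    upper tail of the hypergeometric distribution of the observed overlap
    (exact for universes up to ``exact_max_universe``, otherwise a normal
    approximation with continuity correction).
    """
    if universe_size <= 0:
        raise ValueError("empty universe")
    s1, s2 = set(set1), set(set2)
    n1, n2 = len(s1), len(s2)
    observed = len(s1 & s2)
    expected = n1 * n2 / universe_size
    if universe_size <= exact_max_universe:
        p = float(stats.hypergeom.sf(observed - 1, universe_size, n1, n2))
        method = "exact"
    else:
        var = (n1 * n2 * (universe_size - n1) * (universe_size - n2)
               / (universe_size ** 2 * (universe_size - 1)))
        z = (observed - 0.5 - expected) / np.sqrt(var) if var > 0 else np.inf
        p = float(stats.norm.sf(z))
        method = "normal"
    return OverlapResult(n1=n1, n2=n2, universe=universe_size,
                         observed=observed, expected=expected, p=p,
                         method=method)


def dmc_density(dmc_results: pd.DataFrame, regions: pd.DataFrame,
                deg_genes) -> dict:
    """DMC frequency per 1,000 covered cytosines in DEGs vs non-DEGs.

    ``dmc_results`` is the full :func:`dmc_test` output (every tested site
    is a covered cytosine; ``status != 'ns'`` marks DMCs).  Sites are
    attributed to genes through the target regions; the DEG partition is
    restricted to DEGs actually covered in the data.  Returns per-group
    densities with a 2x2 chi-square test and a hypergeometric test of DMC
    placement.
    """
    assigned = assign_regions(dmc_results, regions)
    assigned = assigned[assigned["region_idx"] >= 0]
    if len(assigned) == 0:
        raise ValueError("no tested cytosines fall in target regions")
    covered_genes = set(assigned["gene_id"])
    degs = set(deg_genes) & covered_genes
    in_deg = assigned["gene_id"].isin(degs)
    is_dmc = assigned["status"] != "ns"
    n_deg_sites = int(in_deg.sum())
    n_non_sites = int((~in_deg).sum())
    dmc_deg = int((is_dmc & in_deg).sum())
    dmc_non = int((is_dmc & ~in_deg).sum())
    result = {
        "deg_covered_cytosines": n_deg_sites,
        "nondeg_covered_cytosines": n_non_sites,
        "deg_dmcs": dmc_deg,
        "nondeg_dmcs": dmc_non,
        "deg_density_per_1000": 1000.0 * dmc_deg / n_deg_sites if n_deg_sites else np.nan,
        "nondeg_density_per_1000": (1000.0 * dmc_non / n_non_sites
                                    if n_non_sites else np.nan),
    }
    table = np.array([[dmc_deg, n_deg_sites - dmc_deg],
                      [dmc_non, n_non_sites - dmc_non]])
    if table.sum() and n_deg_sites and n_non_sites and (dmc_deg + dmc_non):
        chi2 = stats.chi2_contingency(table, correction=True)
        result["chi2_p"] = float(chi2.pvalue)
        total = n_deg_sites + n_non_sites
        result["hypergeom_p"] = float(stats.hypergeom.sf(
            dmc_deg - 1, total, dmc_deg + dmc_non, n_deg_sites))
    else:
        result["chi2_p"] = np.nan
        result["hypergeom_p"] = np.nan
    return result
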