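"""Core methylation-level estimators and site-level screens.

Two estimators summarise a set of cytosines:

* the *mean* methylation level, the unweighted average of per-site
  methylated fractions over sites passing a coverage floor (default 10x),
  used for global per-subgenome summaries; and
* the *weighted* methylation level, total methylated reads divided by total
  reads over sites passing a lower floor (default 3x), used for all
  region-based analyses.  A low-coverage site contributes proportionally
  less to the weighted level, which makes the lower floor unbiased.

The module also estimates the bisulfite conversion rate from an
unmethylated control genome (chloroplast) and screens CHH sites for
methylation exceeding the non-conversion background with a one-sided
binomial test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SiteSummary",
    "ConversionStats",
    "filter_by_coverage",
    "conversion_rate",
    "site_level",
    "mean_methylation_level",
    "weighted_methylation_level",
    "assign_regions",
    "region_methylation",
    "chh_significance",
]


@dataclass(frozen=True)
class SiteSummary:
    context: str
    n_sites: int
    mean_level: float  # unweighted average of per-site fractions (NaN if empty)
    weighted_level: float  # sum(meth) / sum(coverage) (NaN if empty)
    total_meth: int
    total_cov: int


@dataclass(frozen=True)
class ConversionStats:
    converted: int
    analyzed: int
    conversion_rate: float  # percent
    nonconversion_rate: float  # fraction


def _coverage(records: pd.DataFrame) -> pd.Series:
    return records["count_meth"] + records["count_unmeth"]


def filter_by_coverage(records: pd.DataFrame, min_cov: int = 10,
                       cap_percentile: float = 99.99) -> pd.DataFrame:
    """Drop low-coverage sites and presumed PCR artifacts.

    Sites with coverage below ``min_cov`` are removed, as are sites above
    the per-sample ``cap_percentile`` coverage (nearest-rank definition,
    computed over all covered sites with contexts pooled).
    """
    if len(records) == 0:
        warnings.warn("coverage filter on empty input", stacklevel=2)
        return records
    cov = _coverage(records)
    covered = cov[cov > 0].to_numpy()
    if len(covered) == 0:
        return records.iloc[0:0]
    # nearest-rank percentile: smallest value with at least p% of data <= it
    rank = int(np.ceil(cap_percentile / 100.0 * len(covered)))
    cap = np.partition(covered, rank - 1)[rank - 1]
    return records[(cov >= min_cov) & (cov <= cap)]


def conversion_rate(control_records: pd.DataFrame) -> ConversionStats:
    """Bisulfite conversion efficiency from an unmethylated control genome.

    conversion rate = converted cytosines / analyzed cytosines x 100,
    where every unmethylated call is a successful conversion.
    """
    converted = int(control_records["count_unmeth"].sum())
    analyzed = int(_coverage(control_records).sum())
    if analyzed == 0:
        raise ValueError("no analyzed cytosines on the control genome")
    rate = converted / analyzed * 100.0
    return ConversionStats(converted=converted, analyzed=analyzed,
                           conversion_rate=rate,
                           nonconversion_rate=1.0 - rate / 100.0)


def site_level(record) -> float:
    """Per-site methylated fraction meth / (meth + unmeth)."""
    cov = record.count_meth + record.count_unmeth
    return record.count_meth / cov if cov else float("nan")


def _summary(records: pd.DataFrame, min_cov: int) -> SiteSummary:
    context = records["context"].iloc[0] if len(records) else "NA"
    if records["context"].nunique() > 1:
        context = "mixed"
    cov = _coverage(records)
    keep = records[cov >= min_cov]
    cov = cov[cov >= min_cov]
    n = len(keep)
    if n == 0:
        return SiteSummary(context, 0, float("nan"), float("nan"), 0, 0)
    total_meth = int(keep["count_meth"].sum())
    total_cov = int(cov.sum())
    mean_level = float((keep["count_meth"] / cov).mean())
    return SiteSummary(context, n, mean_level, total_meth / total_cov,
                       total_meth, total_cov)


def mean_methylation_level(records: pd.DataFrame, min_cov: int = 10) -> SiteSummary:
    """Unweighted average of per-site fractions over sites with >= min_cov."""
    return _summary(records, min_cov)


def weighted_methylation_level(records: pd.DataFrame, min_cov: int = 3) -> SiteSummary:
    """Coverage-weighted level: sum(meth)/sum(cov) over sites with >= min_cov."""
    return _summary(records, min_cov)


def assign_regions(records: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Attach the enclosing target region to every cytosine record.

    Interval membership uses the half-open rule start <= pos-1 < end on the
    region's 0-based coordinates.  Regions must be non-overlapping within a
    chromosome.  Records outside every region get region_idx -1.
    """
    out = records.copy()
    out["region_idx"] = -1
    out["gene_id"] = pd.NA
    for chrom, reg in regions.groupby("chrom", sort=False):
        sel = out["chrom"] == chrom
        if not sel.any():
            continue
        reg = reg.sort_values("start")
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        pos0 = out.loc[sel, "pos"].to_numpy() - 1
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, None)])
        region_idx = np.where(inside, reg.index.to_numpy()[np.clip(idx, 0, None)], -1)
        out.loc[sel, "region_idx"] = region_idx
        gene_ids = reg["gene_id"].to_numpy()
        genes = np.where(inside, gene_ids[np.clip(idx, 0, None)], None)
        out.loc[sel, "gene_id"] = genes
    return out


def region_methylation(records: pd.DataFrame, regions: pd.DataFrame,
                       context: str | None = None, min_cov: int = 3) -> pd.DataFrame:
    """Per-region weighted methylation level.

    Returns one row per (region, context) with the weighted level over
    in-region sites at the coverage floor, the number of contributing
    cytosines and the total coverage.  Regions with no covered cytosine in
    a context are emitted with n_covered_cytosines = 0 and NaN level.
    """
    recs = records if context is None else records[records["context"] == context]
    assigned = assign_regions(recs, regions)
    cov = _coverage(assigned)
    assigned = assigned[(assigned["region_idx"] >= 0) & (cov >= min_cov)]
    contexts = [context] if context else ["CpG", "CHG", "CHH"]
    grouped = (
        assigned.groupby(["region_idx", "context"], observed=True)
        .agg(total_meth=("count_meth", "sum"),
             total_unmeth=("count_unmeth", "sum"),
             n_covered_cytosines=("count_meth", "size"))
        .reset_index()
    )
    grouped["total_cov"] = grouped["total_meth"] + grouped["total_unmeth"]
    full = pd.MultiIndex.from_product([regions.index, contexts],
                                      names=["region_idx", "context"]).to_frame(index=False)
    out = full.merge(grouped, on=["region_idx", "context"], how="left")
    out["n_covered_cytosines"] = out["n_covered_cytosines"].fillna(0).astype(int)
    out["total_meth"] = out["total_meth"].fillna(0).astype(int)
    out["total_cov"] = out["total_cov"].fillna(0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["weighted_level"] = out["total_meth"] / out["total_cov"]
    meta = regions[["gene_id", "anchor_type", "chrom", "start", "end"]]
    out = out.merge(meta, left_on="region_idx", right_index=True)
    cols = ["region_idx", "gene_id", "anchor_type", "chrom", "start", "end",
            "context", "weighted_level", "n_covered_cytosines", "total_meth",
            "total_cov"]
    return out[cols].sort_values(["region_idx", "context"]).reset_index(drop=True)


def chh_significance(records: pd.DataFrame, nonconversion: float,
                     alpha: float = 0.05, min_cov: int = 10,
                     method: str = "midp", adjust: bool = False) -> pd.DataFrame:
    """One-sided binomial screen of CHH methylation against non-conversion.

    Each CHH site with coverage >= ``min_cov`` is tested for a methylated
    count exceeding Binomial(coverage, nonconversion).  The default p-value
    is the Lancaster mid-p (``method="midp"``), which restores near-nominal
    size at capture coverages where the exact tail p is conservative;
    ``method="exact"`` gives the classical tail probability.  Setting
    ``adjust`` applies Benjamini-Hochberg across sites.

    Returns the per-site table with ``p`` and ``significant`` columns; the
    overall significant fraction is ``out["significant"].mean()``.
    """
    if not 0.0 < nonconversion < 1.0:
        raise ValueError("nonconversion rate must be in (0, 1)")
    chh = records[records["context"] == "CHH"].copy()
    cov = _coverage(chh)
    chh = chh[cov >= min_cov].copy()
    cov = cov[cov >= min_cov].to_numpy()
    m = chh["count_meth"].to_numpy()
    tail = stats.binom.sf(m - 1, cov, nonconversion)  # P(X >= m)
    if method == "exact":
        p = tail
    elif method == "midp":
        p = tail - 0.5 * stats.binom.pmf(m, cov, nonconversion)
    else:
        raise ValueError(f"unknown method {method!r}")
    chh["p"] = p
    if adjust:
        from statsmodels.stats.multitest import multipletests

        chh["q"] = multipletests(p, method="fdr_bh")[1] if len(p) else p
        chh["significant"] = chh.get("q", pd.Series(dtype=float)) < alpha
    else:
        chh["significant"] = chh["p"] < alpha
    return chh
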