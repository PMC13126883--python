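"""Homeolog-triad expression contributions and their methylation context.

A triad is the set of three homeologous gene copies on the A, B and D
subgenomes of hexaploid wheat.  Each homeolog's contribution is its TPM
divided by the triad total; on the ternary plot a contribution between
1/6 and 2/3 (inclusive) is *balanced*, below 1/6 *suppressed* and above
2/3 *dominant*.  The thresholds are stored as exact fractions and only
displayed as 16.7 % / 66.7 %.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import CorrelationResult, _pearson

__all__ = ["compute_contributions", "classify_homeologs",
           "contribution_methylation_association", "variance_association",
           "triad_methylation", "SUPPRESSED_MAX", "DOMINANT_MIN"]

SUPPRESSED_MAX = 1.0 / 6.0
DOMINANT_MIN = 2.0 / 3.0


def classify_homeologs(contribs) -> np.ndarray:
    """Category per contribution: suppressed (<1/6), balanced, dominant (>2/3).

    Boundaries are inclusive in the balanced class.
    """
    c = np.asarray(contribs, dtype=float)
    return np.where(c < SUPPRESSED_MAX, "suppressed",
                    np.where(c > DOMINANT_MIN, "dominant", "balanced"))


def compute_contributions(expression: pd.Series, triad_map: pd.DataFrame,
                          floor: float = 0.5) -> pd.DataFrame:
    """Per-triad homeolog contributions from a gene -> TPM mapping.

    Triads whose summed TPM does not exceed ``floor`` (or with a missing
    homeolog) are excluded (``included=False`` with a reason).
    """
    rows = []
    for t in triad_map.itertuples(index=False):
        tpms = [expression.get(g, np.nan) for g in (t.gene_A, t.gene_B, t.gene_D)]
        row = {"triad_id": t.triad_id, "tpm_A": tpms[0], "tpm_B": tpms[1],
               "tpm_D": tpms[2]}
        if any(pd.isna(x) for x in tpms):
            row.update(included=False, reason="missing homeolog")
        elif sum(tpms) <= floor:
            row.update(included=False, reason="below expression floor")
        else:
            total = sum(tpms)
            contribs = [x / total for x in tpms]
            cats = classify_homeologs(contribs)
            row.update(included=True, reason="",
                       contrib_A=contribs[0], contrib_B=contribs[1],
                       contrib_D=contribs[2], cat_A=cats[0], cat_B=cats[1],
                       cat_D=cats[2])
        rows.append(row)
    cols = ["triad_id", "tpm_A", "tpm_B", "tpm_D", "included", "reason",
            "contrib_A", "contrib_B", "contrib_D", "cat_A", "cat_B", "cat_D"]
    out = pd.DataFrame(rows)
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    return out[cols]


def triad_methylation(region_meth: pd.DataFrame, triad_map: pd.DataFrame,
                      context: str) -> pd.DataFrame:
    """Per-homeolog weighted region levels and their within-triad SD.

    Defined only for triads where all three homeologs have region
    methylation data in the requested context.
    """
    meth = region_meth[(region_meth["context"] == context)
                       & (region_meth["n_covered_cytosines"] > 0)]
    levels = meth.set_index("gene_id")["weighted_level"]
    rows = []
    for t in triad_map.itertuples(index=False):
        vals = [levels.get(g, np.nan) for g in (t.gene_A, t.gene_B, t.gene_D)]
        if any(pd.isna(v) for v in vals):
            continue
        rows.append({"triad_id": t.triad_id, "level_A": vals[0],
                     "level_B": vals[1], "level_D": vals[2],
                     "level_sd": float(np.std(vals, ddof=1))})
    return pd.DataFrame(rows, columns=["triad_id", "level_A", "level_B",
                                       "level_D", "level_sd"])


def _melt_homeologs(triad_expr: pd.DataFrame, triad_meth: pd.DataFrame) -> pd.DataFrame:
    expr = triad_expr[triad_expr["included"] == True]  # noqa: E712
    merged = expr.merge(triad_meth, on="triad_id", how="inner")
    frames = []
    for sg in ("A", "B", "D"):
        frames.append(pd.DataFrame({
            "triad_id": merged["triad_id"],
            "subgenome": sg,
            "contribution": merged[f"contrib_{sg}"],
            "category": merged[f"cat_{sg}"],
            "level": merged[f"level_{sg}"],
        }))
    return pd.concat(frames, ignore_index=True)


def contribution_methylation_association(triad_expr: pd.DataFrame,
                                         triad_meth: pd.DataFrame,
                                         min_group: int = 3) -> dict:
    """Relation between homeolog expression contribution and methylation.

    Returns the Pearson correlation of contribution vs region level across
    homeologs, per-category level distributions, and pairwise
    between-category tests (Wilcoxon rank-sum alongside a Welch t-test,
    since both appear in the ternary-plot literature).
    """
    data = _melt_homeologs(triad_expr, triad_meth)
    corr = _pearson(data["contribution"], data["level"])
    groups = {cat: grp["level"].to_numpy()
              for cat, grp in data.groupby("category")}
    tests = []
    for a, b in (("suppressed", "balanced"), ("suppressed", "dominant"),
                 ("balanced", "dominant")):
        if a not in groups or b not in groups or \
                min(len(groups[a]), len(groups[b])) < min_group:
            tests.append({"pair": f"{a}-{b}", "wilcoxon_p": np.nan,
                          "ttest_p": np.nan, "skipped": True})
            continue
        w = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        t = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        tests.append({"pair": f"{a}-{b}", "wilcoxon_p": float(w.pvalue),
                      "ttest_p": float(t.pvalue), "skipped": False})
    return {"correlation": corr, "data": data,
            "category_levels": {k: v for k, v in groups.items()},
            "tests": pd.DataFrame(tests)}


def variance_association(triad_expr: pd.DataFrame, triad_meth: pd.DataFrame,
                         min_triads: int = 10) -> CorrelationResult:
    """Correlation of within-triad SD(contributions) vs SD(levels).

    Tests whether imbalanced triads carry more variable homeolog
    methylation, independent of the direction of any effect.
    """
    expr = triad_expr[triad_expr["included"] == True].copy()  # noqa: E712
    expr["contrib_sd"] = expr[["contrib_A", "contrib_B", "contrib_D"]].std(
        axis=1, ddof=1)
    merged = expr.merge(triad_meth[["triad_id", "level_sd"]], on="triad_id")
    if len(merged) < min_triads:
        warnings.warn("too few triads for variance association", stacklevel=2)
        return CorrelationResult(np.nan, np.nan, np.nan, len(merged))
    return _pearson(merged["contrib_sd"], merged["level_sd"])
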