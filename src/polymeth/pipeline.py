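"""End-to-end orchestration of the analysis from a single configuration.

``run_pipeline`` executes the requested stages in dependency order on a
cohort directory (as produced by :mod:`polymeth.synthetic_cohort` or laid
out the same way from real data), writes every output as TSV and records
a manifest with parameter provenance and file hashes so that a rerun with
the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffmeth, formats_io, landscape, methcore, triads

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("polymeth")

STAGES = ("summarize", "scan", "pca", "metaprofile", "correlate", "triads",
          "dmc", "dmr", "overlap", "density")

_DEPENDS = {
    "dmr": (),
    "overlap": ("dmr",),
    "density": ("dmc",),
}


@dataclass
class RunConfig:
    """Paths and analysis parameters for one pipeline run."""

    cohort_dir: str
    outdir: str
    min_cov_site: int = 10  # PCA / DMC floor
    min_cov_region: int = 3  # region-based floor
    cap_percentile: float = 99.99
    diff_threshold: float = 25.0
    q_cutoff: float = 0.01
    use_q: bool = True
    window: int = 2_000_000
    step: int = 1_000_000
    bin_size: int = 10
    min_cpg_per_segment: int = 3
    triad_floor: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_stages(stages) -> list:
    requested = list(STAGES) if stages is None else list(stages)
    for s in requested:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        for dep in _DEPENDS.get(s, ()):
            if dep not in requested:
                raise RuntimeError(
                    f"stage {s!r} requires stage {dep!r}, which was not requested")
    return [s for s in STAGES if s in requested]


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Run the requested stages and return the output manifest."""
    stages = _resolve_stages(stages)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _load_inputs(config)
    artifacts: list[Path] = []

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        artifacts.append(path)
        log.info("wrote %s (%d rows)", path, len(df))

    filtered = {
        key: methcore.filter_by_coverage(df, min_cov=1,
                                         cap_percentile=config.cap_percentile)
        for key, df in cohort["methylomes"].items()
    }
    libname = {key: f"{key[0]}_rep{key[1]}" for key in filtered}
    regions = cohort["regions"]

    if "summarize" in stages:
        rows = []
        for key, df in filtered.items():
            for ctx, grp in df.groupby("context"):
                mean = methcore.mean_methylation_level(grp, config.min_cov_site)
                weighted = methcore.weighted_methylation_level(
                    grp, config.min_cov_region)
                rows.append({"library": libname[key], "context": ctx,
                             "n_sites_mean": mean.n_sites,
                             "mean_level": mean.mean_level,
                             "n_sites_weighted": weighted.n_sites,
                             "weighted_level": weighted.weighted_level})
            ctrl = cohort["chloroplast"].get(key)
            if ctrl is not None and len(ctrl):
                conv = methcore.conversion_rate(ctrl)
                rows.append({"library": libname[key], "context": "chloroplast",
                             "mean_level": np.nan,
                             "weighted_level": 1 - conv.conversion_rate / 100,
                             "n_sites_mean": conv.analyzed,
                             "n_sites_weighted": conv.converted})
        save(pd.DataFrame(rows), "site_summaries.tsv")

    region_meth = {}
    if {"correlate", "triads", "metaprofile"} & set(stages):
        for key, df in filtered.items():
            region_meth[key] = methcore.region_methylation(
                df, regions, min_cov=config.min_cov_region)

    if "scan" in stages:
        tracks = {}
        chrom_lengths = dict(zip(cohort["centromeres"]["chrom"],
                                 cohort["centromeres"]["chrom_length"]))
        for key, df in filtered.items():
            track = landscape.chromosome_scan(
                df, regions, chrom_lengths, window=config.window,
                step=config.step, min_cov=config.min_cov_region)
            track["library"] = libname[key]
            tracks[libname[key]] = track
        save(pd.concat(tracks.values(), ignore_index=True), "scan_tracks.tsv")
        r_mat, p_mat = landscape.track_similarity(tracks)
        r_mat.to_csv(out / "track_pearson.tsv", sep="\t")
        p_mat.to_csv(out / "track_wilcoxon.tsv", sep="\t")
        artifacts += [out / "track_pearson.tsv", out / "track_wilcoxon.tsv"]

    if "pca" in stages:
        for partition, subgenomes in (("AB", ("A", "B")), ("D", ("D",))):
            chroms = {c for c in regions["chrom"].unique()
                      if c[-1] in subgenomes}
            subset = {}
            for key, df in filtered.items():
                sub = df[df["chrom"].isin(chroms)]
                if len(sub):
                    subset[libname[key]] = sub
            if len(subset) < 3:
                continue
            matrix = landscape.build_methylation_matrix(
                subset, min_cov=config.min_cov_site)
            coords, var = landscape.pca_methylomes(matrix)
            coords = coords.reset_index(names="library")
            coords["partition"] = partition
            save(coords, f"pca_{partition}.tsv")
            pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(var))],
                          "variance_explained": var}).pipe(
                save, f"pca_{partition}_variance.tsv")

    expression = cohort["expression"]
    expr_class = landscape.classify_expression_status(expression)

    if "metaprofile" in stages:
        profile, _ = landscape.metaprofile(
            {libname[k]: df for k, df in filtered.items()}, regions,
            expr_class, bin_size=config.bin_size,
            min_cov=config.min_cov_region)
        save(profile, "metaprofile.tsv")

    if "correlate" in stages:
        rows = []
        for key, rm in region_meth.items():
            sample = key[0]
            tpm = (expression[expression["sample_id"] == sample]
                   .groupby("gene_id")["tpm"].mean())
            if len(tpm) == 0:
                continue
            for ctx in ("CpG", "CHG", "CHH"):
                res = landscape.methylation_expression_correlations(
                    rm, tpm, cohort["centromeres"], ctx)
                for pair in ("meth_expression", "meth_distance",
                             "expression_distance"):
                    c = res[pair]
                    rows.append({"library": libname[key], "context": ctx,
                                 "pair": pair, "r": c.r, "r2": c.r2,
                                 "p": c.p, "n": c.n})
        save(pd.DataFrame(rows), "correlations.tsv")

    if "triads" in stages:
        triad_map = cohort["triads"]
        rows = []
        hexaploids = [s.sample_id for s in cohort["sample_sheet"]
                      if s.role in ("synthetic", "natural")]
        for key, rm in region_meth.items():
            sample = key[0]
            if sample not in hexaploids or key[1] != 1:
                continue
            tpm = (expression[expression["sample_id"] == sample]
                   .groupby("gene_id")["tpm"].mean())
            contrib = triads.compute_contributions(tpm, triad_map,
                                                   floor=config.triad_floor)
            for ctx in ("CpG", "CHG", "CHH"):
                tm = triads.triad_methylation(rm, triad_map, ctx)
                if len(tm) < 3:
                    continue
                assoc = triads.contribution_methylation_association(contrib, tm)
                var = triads.variance_association(contrib, tm)
                rows.append({"sample": sample, "context": ctx,
                             "contrib_r": assoc["correlation"].r,
                             "contrib_r2": assoc["correlation"].r2,
                             "contrib_p": assoc["correlation"].p,
                             "variance_r": var.r, "variance_r2": var.r2,
                             "variance_p": var.p, "n_triads": var.n})
        save(pd.DataFrame(rows), "triad_associations.tsv")

    comparisons = _parent_synthetic_pairs(cohort["sample_sheet"])

    def _parent_group(parents):
        ab = [filtered[k] for k in sorted(filtered) if k[0] == parents[0]]
        d = [filtered[k] for k in sorted(filtered) if k[0] == parents[1]]
        return diffmeth.combine_parents(ab, d)

    dmc_results = {}
    if "dmc" in stages:
        for synth, parents in comparisons.items():
            g1 = _parent_group(parents)
            g2 = [filtered[k] for k in filtered if k[0] == synth]
            res = diffmeth.dmc_test(g1, g2, min_cov=config.min_cov_site,
                                    diff_threshold=config.diff_threshold,
                                    q_cutoff=config.q_cutoff,
                                    use_q=config.use_q)
            res["synthetic"] = synth
            dmc_results[synth] = res
            save(res, f"dmc_{synth}.tsv")

    dmr_results = {}
    if "dmr" in stages:
        for synth, parents in comparisons.items():
            g1 = _parent_group(parents)
            g2 = [filtered[k] for k in filtered if k[0] == synth]
            fixed = diffmeth.dmr_fixed_windows(
                g1, g2, regions, min_cov=config.min_cov_site,
                diff_threshold=config.diff_threshold,
                q_cutoff=config.q_cutoff, use_q=config.use_q)
            fixed["method"] = "windows"
            segs = diffmeth.segment_parents(
                [filtered[k] for k in filtered if k[0] == parents[0]],
                [filtered[k] for k in filtered if k[0] == parents[1]],
                regions, min_cpg=config.min_cpg_per_segment,
                min_cov=config.min_cov_site)
            seg_res = diffmeth.dmr_segments(
                g1, g2, segs, min_cov=config.min_cov_site,
                diff_threshold=config.diff_threshold,
                q_cutoff=config.q_cutoff, use_q=config.use_q)
            seg_res["method"] = "segments"
            both = pd.concat([fixed, seg_res], ignore_index=True)
            both["synthetic"] = synth
            dmr_results[synth] = both
            save(both, f"dmr_{synth}.tsv")

    if "overlap" in stages:
        rows = []
        universe = regions["gene_id"].nunique()
        calls = {s: set(r.loc[r["status"] != "ns", "gene_id"])
                 for s, r in dmr_results.items()}
        names = sorted(calls)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                res = diffmeth.overlap_test(calls[a], calls[b], universe)
                rows.append({"set1": a, "set2": b, "n1": res.n1, "n2": res.n2,
                             "observed": res.observed,
                             "expected": res.expected, "p": res.p})
        # DEG vs DMR overlap per synthetic
        for synth, r in dmr_results.items():
            degs = cohort["deg_lists"].get(synth)
            if degs is None:
                continue
            res = diffmeth.overlap_test(calls[synth], set(degs["gene_id"]),
                                        universe)
            rows.append({"set1": f"DMR_{synth}", "set2": f"DEG_{synth}",
                         "n1": res.n1, "n2": res.n2,
                         "observed": res.observed, "expected": res.expected,
                         "p": res.p})
        save(pd.DataFrame(rows), "overlaps.tsv")

    if "density" in stages:
        rows = []
        for synth, res in dmc_results.items():
            degs = cohort["deg_lists"].get(synth)
            if degs is None or len(res) == 0:
                continue
            d = diffmeth.dmc_density(res, regions, set(degs["gene_id"]))
            d["synthetic"] = synth
            rows.append(d)
        save(pd.DataFrame(rows), "dmc_density.tsv")

    manifest = {
        "stages": stages,
        "config": config.to_dict(),
        "artifacts": [{"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                      for p in artifacts],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _parent_synthetic_pairs(sheet) -> dict:
    pairs = {}
    for s in sheet:
        if s.role == "synthetic" and s.parent_ab and s.parent_d:
            parent_ids = {x.sample_id for x in sheet}
            if s.parent_ab in parent_ids and s.parent_d in parent_ids:
                pairs[s.sample_id] = (s.parent_ab, s.parent_d)
    return pairs


def _load_inputs(config: RunConfig) -> dict:
    from .synthetic_cohort import load_cohort

    return load_cohort(config.cohort_dir)
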