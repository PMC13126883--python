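"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV with a header line.  Internal coordinates
are 0-based half-open; the cytosine-report dialect keeps the Bismark
convention of 1-based positions, and the conversion happens only here, at
the I/O boundary.

Formats
-------
* cytosine report  -- one strand-specific cytosine per row with methylated /
  unmethylated read counts, sequence context (CpG/CHG/CHH) and trinucleotide.
* regions BED      -- BED6 plus two extra columns (``anchor_type``,
  ``multi_utr``); every region is a 300 bp window anchored on a TSS or SC.
* expression TSV   -- long table of per-library TPM values.
* triad TSV        -- one row per homeolog triad with A/B/D gene ids.
* gene-set TSV     -- named gene lists (e.g. DEGs), optionally with an
  up/down direction column.
* sample sheet     -- YAML inventory of samples, roles and file paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CytosineRecord",
    "TargetRegion",
    "ExpressionRecord",
    "SampleSheet",
    "SampleEntry",
    "FormatError",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_regions_bed",
    "write_regions_bed",
    "read_expression",
    "write_expression",
    "read_triads",
    "write_triads",
    "read_gene_sets",
    "write_gene_set",
    "read_sample_sheet",
    "write_sample_sheet",
    "destrand_cpg",
    "REGION_LENGTH",
]

REGION_LENGTH = 300

CONTEXTS = ("CpG", "CHG", "CHH")

CYTOSINE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "count_meth",
    "count_unmeth",
    "context",
    "trinucleotide",
]

REGION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "anchor_type",
    "multi_utr",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented dialect."""


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-specific cytosine with its read counts."""

    chrom: str
    pos: int  # 1-based, Bismark convention
    strand: str
    count_meth: int
    count_unmeth: int
    context: str
    trinucleotide: str = ""

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass(frozen=True)
class TargetRegion:
    """A 300 bp capture window anchored on the TSS or SC of one gene."""

    gene_id: str
    anchor_type: str  # "TSS" or "SC"
    chrom: str
    start: int  # 0-based half-open
    end: int
    subgenome: str
    strand: str = "+"
    multi_utr: bool = False


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    sample_id: str
    library: int
    tpm: float


@dataclass
class SampleEntry:
    sample_id: str
    genotype: str
    role: str  # parent_AB | parent_D | synthetic | natural
    replicates: list = field(default_factory=list)
    parent_ab: str | None = None
    parent_d: str | None = None


@dataclass
class SampleSheet:
    samples: list

    def __iter__(self):
        return iter(self.samples)

    def __len__(self):
        return len(self.samples)

    def by_role(self, role: str) -> list:
        return [s for s in self.samples if s.role == role]

    def get(self, sample_id: str) -> SampleEntry:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def _first_bad_line(mask: pd.Series) -> int:
    # +2: header line plus 1-based numbering
    return int(np.flatnonzero(mask.to_numpy())[0]) + 2


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a cytosine report into a validated DataFrame.

    Positions stay 1-based as in the file.  Any malformed row aborts the
    read with a :class:`FormatError` naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "trinucleotide": str})
    missing = [c for c in CYTOSINE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return df[CYTOSINE_COLUMNS].astype(
            {"pos": np.int64, "count_meth": np.int64, "count_unmeth": np.int64}
        )
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna() | (pos < 1) | (pos != pos.astype("Int64").astype(float))
    if bad.any():
        raise FormatError(f"{path}: malformed position at line {_first_bad_line(bad)}")
    for col in ("count_meth", "count_unmeth"):
        counts = pd.to_numeric(df[col], errors="coerce")
        bad = counts.isna() | (counts < 0)
        if bad.any():
            raise FormatError(
                f"{path}: negative or malformed {col} at line {_first_bad_line(bad)}"
            )
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise FormatError(
            f"{path}: unknown context {df['context'][bad].iloc[0]!r} "
            f"at line {_first_bad_line(bad)}"
        )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(f"{path}: bad strand at line {_first_bad_line(bad)}")
    df = df.astype({"pos": np.int64, "count_meth": np.int64, "count_unmeth": np.int64})
    return df[CYTOSINE_COLUMNS]


def write_cytosine_report(records: pd.DataFrame, path) -> None:
    records[CYTOSINE_COLUMNS].to_csv(path, sep="\t", index=False)


def _subgenome_from_chrom(chrom: str) -> str:
    if chrom and chrom[-1] in "ABD":
        return chrom[-1]
    return "unknown"


def read_regions_bed(path, allow_any_length: bool = False) -> pd.DataFrame:
    """Read target regions from BED6+2 (0-based half-open coordinates).

    The subgenome is inferred from the chromosome name suffix (...A/B/D);
    anything else maps to ``"unknown"`` with a warning.  Window length must
    equal 300 bp unless ``allow_any_length`` is set.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=REGION_COLUMNS,
                     dtype={"chrom": str, "name": str})
    if len(df) == 0:
        df["gene_id"] = []
        df["subgenome"] = []
        return df
    lengths = df["end"] - df["start"]
    if not allow_any_length and (lengths != REGION_LENGTH).any():
        i = int(np.flatnonzero((lengths != REGION_LENGTH).to_numpy())[0]) + 1
        raise FormatError(
            f"{path}: region of length {int(lengths.iloc[i - 1])} "
            f"(expected {REGION_LENGTH}) at line {i}"
        )
    if (df["start"] < 0).any():
        raise FormatError(f"{path}: negative start coordinate")
    df["gene_id"] = df["name"].str.split("|").str[0]
    df["subgenome"] = df["chrom"].map(_subgenome_from_chrom)
    if (df["subgenome"] == "unknown").any():
        warnings.warn("regions on chromosomes without an A/B/D suffix: "
                      "subgenome set to 'unknown'", stacklevel=2)
    df["multi_utr"] = df["multi_utr"].astype(int).astype(bool)
    return df


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    out = regions.copy()
    if "name" not in out.columns:
        out["name"] = out["gene_id"] + "|" + out["anchor_type"]
    if "score" not in out.columns:
        out["score"] = 0
    out["multi_utr"] = out["multi_utr"].astype(int)
    out[REGION_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "sample_id": str})
    for col in ("gene_id", "sample_id", "library", "tpm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if (df["tpm"] < 0).any():
        raise FormatError(f"{path}: negative TPM value")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr[["gene_id", "sample_id", "library", "tpm"]].to_csv(path, sep="\t", index=False)


def read_triads(path, regions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read the triad table (one row per triad: triad_id, gene_A/B/D).

    A gene appearing in two triads is an integrity error.  When a region
    table is supplied, triad genes absent from it trigger a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("triad_id", "gene_A", "gene_B", "gene_D"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    genes = pd.concat([df["gene_A"], df["gene_B"], df["gene_D"]])
    dup = genes[genes.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: gene {dup.iloc[0]!r} assigned to two triads")
    if regions is not None:
        known = set(regions["gene_id"])
        unknown = set(genes) - known
        if unknown:
            warnings.warn(f"{len(unknown)} triad genes absent from the region table",
                          stacklevel=2)
    return df


def write_triads(triads: pd.DataFrame, path) -> None:
    triads[["triad_id", "gene_A", "gene_B", "gene_D"]].to_csv(path, sep="\t", index=False)


def read_gene_sets(path, known_genes=None) -> pd.DataFrame:
    """Read a gene list (columns: gene_id, optional direction).

    Unknown genes are retained with a warning so that lists from a richer
    annotation survive a desk-scale run.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'gene_id'")
    if "direction" not in df.columns:
        df["direction"] = "na"
    if known_genes is not None:
        unknown = ~df["gene_id"].isin(set(known_genes))
        if unknown.any():
            warnings.warn(f"{int(unknown.sum())} genes in {path} are not in the "
                          "annotation; retained", stacklevel=2)
    return df


def write_gene_set(genes: pd.DataFrame, path) -> None:
    cols = ["gene_id"] + (["direction"] if "direction" in genes.columns else [])
    genes[cols].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path, check_paths: bool = True) -> SampleSheet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = Path(path).parent
    samples = []
    for entry in doc["samples"]:
        reps = entry.get("replicates", [])
        if not reps:
            raise FormatError(f"sample {entry['sample_id']}: no replicates listed")
        resolved = []
        for rep in reps:
            rep = dict(rep)
            for key in ("cytosine_report", "chloroplast_report"):
                if rep.get(key):
                    p = base / rep[key]
                    if check_paths and not p.exists():
                        raise FormatError(f"sample {entry['sample_id']}: "
                                          f"missing file {p}")
                    rep[key] = str(p)
            resolved.append(rep)
        samples.append(SampleEntry(
            sample_id=entry["sample_id"],
            genotype=entry.get("genotype", entry["sample_id"]),
            role=entry["role"],
            replicates=resolved,
            parent_ab=entry.get("parent_ab"),
            parent_d=entry.get("parent_d"),
        ))
    return SampleSheet(samples=samples)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    doc = {"samples": []}
    for s in sheet.samples:
        entry = {
            "sample_id": s.sample_id,
            "genotype": s.genotype,
            "role": s.role,
            "replicates": s.replicates,
        }
        if s.parent_ab:
            entry["parent_ab"] = s.parent_ab
        if s.parent_d:
            entry["parent_d"] = s.parent_d
        doc["samples"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def destrand_cpg(records: pd.DataFrame) -> pd.DataFrame:
    """Merge symmetric CpG pairs by summing counts onto the plus-strand C.

    A minus-strand CpG at position p pairs with the plus-strand CpG at
    p - 1.  Non-CpG records and unpaired CpGs pass through unchanged.
    """
    cpg = records["context"] == "CpG"
    out = records.loc[~cpg].copy()
    c = records.loc[cpg].copy()
    c["pair_pos"] = np.where(c["strand"] == "+", c["pos"], c["pos"] - 1)
    grouped = (
        c.groupby(["chrom", "pair_pos"], as_index=False, sort=False)
        .agg(count_meth=("count_meth", "sum"),
             count_unmeth=("count_unmeth", "sum"),
             trinucleotide=("trinucleotide", "first"))
    )
    grouped = grouped.rename(columns={"pair_pos": "pos"})
    grouped["strand"] = "+"
    grouped["context"] = "CpG"
    merged = pd.concat([out, grouped[CYTOSINE_COLUMNS]], ignore_index=True)
    return merged.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
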