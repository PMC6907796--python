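"""Per-sample microsatellite genotype tables.

A genotype call is an unordered diploid pair of repeat-array lengths (bp) for
one sample at one locus, together with the number of reads supporting it.
Calls below the read-depth threshold are discarded; missing calls are absent
rows, so per-locus sample availability is implicit (exome capture makes this
heterogeneous across gene regions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: 1000 Genomes super-population labels (configurable in all readers).
POPULATIONS = ("AFR", "EUR", "AMR", "EAS", "SAS")

GENOTYPE_COLUMNS = ["sample_id", "population", "locus_id",
                    "allele_a", "allele_b", "read_depth"]


@dataclass(frozen=True)
class FilterConfig:
    """Call-level filters: minimum supporting reads and minimum samples
    per population for a locus to enter a pairwise screen."""

    min_reads: int = 6
    min_samples_per_pop: int = 1

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.min_samples_per_pop < 1:
            raise ValueError("min_samples_per_pop must be >= 1")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    population: str
    locus_id: str
    allele_a: int  # canonical: allele_a <= allele_b
    allele_b: int
    read_depth: int


@dataclass
class LocusGenotypeSummary:
    """Per-locus genotype-category counts by population and the allele set."""

    locus_id: str
    category_counts: dict[str, Counter]  # population -> {"a/b": n}
    allele_set: set[int]

    @property
    def allele_count(self) -> int:
        return len(self.allele_set)

    @property
    def n_calls(self) -> int:
        return sum(sum(c.values()) for c in self.category_counts.values())


def genotype_category(allele_a: int, allele_b: int) -> str:
    """Canonical genotype label ``a/b`` with a <= b."""
    a, b = sorted((int(allele_a), int(allele_b)))
    return f"{a}/{b}"


def read_genotype_table(
    path: str | Path,
    populations: Sequence[str] = POPULATIONS,
) -> pd.DataFrame:
    """Read and validate a genotype-call TSV.

    Expects columns sample_id, population, locus_id, allele_a, allele_b,
    read_depth.  Allele pairs are canonicalized to allele_a <= allele_b.
    Malformed rows raise with the (1-based, header included) line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[GENOTYPE_COLUMNS].copy()
    return validate_calls(df, populations=populations)


def validate_calls(
    df: pd.DataFrame,
    populations: Sequence[str] = POPULATIONS,
) -> pd.DataFrame:
    """Validate and canonicalize an in-memory call table."""
    df = df.copy()
    popset = set(populations)
    bad_pop = ~df["population"].isin(popset)
    if bad_pop.any():
        i = int(np.flatnonzero(bad_pop.to_numpy())[0])
        raise ValueError(
            f"line {i + 2}: unknown population label "
            f"{df['population'].iloc[i]!r} (expected one of {sorted(popset)})")
    for col, minimum in (("allele_a", 1), ("allele_b", 1), ("read_depth", 0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < minimum)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"line {i + 2}: invalid {col} value {df[col].iloc[i]!r}")
        df[col] = vals.astype(int)
    a = np.minimum(df["allele_a"], df["allele_b"])
    b = np.maximum(df["allele_a"], df["allele_b"])
    df["allele_a"], df["allele_b"] = a, b
    return df.reset_index(drop=True)


def write_genotype_table(df: pd.DataFrame, path: str | Path) -> None:
    df[GENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def depth_filter(df: pd.DataFrame, cfg: FilterConfig | None = None,
                 logger=None) -> pd.DataFrame:
    """Drop calls supported by fewer than ``cfg.min_reads`` reads."""
    cfg = cfg or FilterConfig()
    keep = df["read_depth"] >= cfg.min_reads
    if logger is not None:
        logger.info("depth filter: removed %d of %d calls (min_reads=%d)",
                    int((~keep).sum()), len(df), cfg.min_reads)
    return df[keep].reset_index(drop=True)


def add_category(df: pd.DataFrame) -> pd.DataFrame:
    """Append the canonical genotype-category column."""
    df = df.copy()
    df["category"] = (df["allele_a"].astype(str) + "/" + df["allele_b"].astype(str))
    return df


def summarize_locus(calls: pd.DataFrame, locus_id: str | None = None) -> LocusGenotypeSummary:
    """Summarize depth-filtered calls at one locus.

    The allele count is the number of distinct array lengths over both
    alleles of all retained calls (the standard per-locus allele tally).
    """
    if locus_id is None:
        ids = calls["locus_id"].unique()
        locus_id = ids[0] if len(ids) else ""
    cat_counts: dict[str, Counter] = {}
    for pop, grp in calls.groupby("population", sort=True):
        cat_counts[pop] = Counter(
            genotype_category(a, b)
            for a, b in zip(grp["allele_a"], grp["allele_b"]))
    alleles = set(calls["allele_a"]) | set(calls["allele_b"])
    return LocusGenotypeSummary(locus_id=str(locus_id),
                                category_counts=cat_counts,
                                allele_set={int(a) for a in alleles})


def summarize_cohort(calls: pd.DataFrame) -> dict[str, LocusGenotypeSummary]:
    """Per-locus summaries for a whole (depth-filtered) call table."""
    return {str(locus): summarize_locus(grp, str(locus))
            for locus, grp in calls.groupby("locus_id", sort=True)}


def cohort_allele_total(calls: pd.DataFrame) -> int:
    """Sum over loci of the per-locus distinct-allele count."""
    melted = pd.concat([
        calls[["locus_id", "allele_a"]].rename(columns={"allele_a": "allele"}),
        calls[["locus_id", "allele_b"]].rename(columns={"allele_b": "allele"}),
    ])
    return int(melted.groupby("locus_id")["allele"].nunique().sum())


def locus_sample_counts(calls: pd.DataFrame) -> pd.Series:
    """Available-sample count per locus (retained calls over all populations);
    the stratification variable for the coverage-robustness series."""
    return calls.groupby("locus_id")["sample_id"].nunique()
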