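"""Downstream enrichment statistics for EBML sets.

2x2 chi-square tests of independence with odds ratios, Woolf confidence
intervals and Pearson residuals, applied to category enrichments (eSTR,
matrisome, selective-sweep, repeat-unit length, amino-acid class) and to
pairwise EBML overlap; plus the two coverage-stratified robustness series and
the two-sample Kolmogorov-Smirnov comparison of allele counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

REGIONS = ("intron", "exon", "cds", "utr5", "utr3")


@dataclass
class TwoByTwo:
    """2x2 contingency table; cell ``a`` counts the both-positive class."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("positive", "negative")
    col_labels: tuple[str, str] = ("positive", "negative")

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class EnrichmentResult:
    table: TwoByTwo
    chi2: float
    p_value: float
    dof: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    residuals: np.ndarray | None  # 2x2 Pearson residuals (uncorrected)
    direction: str  # over | under | none
    note: str = ""

    @property
    def is_na(self) -> bool:
        return math.isnan(self.p_value)

    def signed_logp(self, base: float = math.e) -> float:
        """-log(p) when over-represented, +log(p) when under (plots below
        the axis); natural log by default."""
        if self.is_na:
            return math.nan
        p = max(self.p_value, 1e-300)
        mag = -math.log(p) / math.log(base)
        return mag if self.direction != "under" else -mag


def _na_result(table: TwoByTwo, note: str) -> EnrichmentResult:
    return EnrichmentResult(table, math.nan, math.nan, 1, math.nan, math.nan,
                            math.nan, None, "none", note=note)


def chi2_2x2(table: TwoByTwo, yates: bool = False) -> EnrichmentResult:
    """Chi-square test of independence on a 2x2 table.

    Uncorrected statistic: N(ad - bc)^2 / (R1 R2 C1 C2); Yates subtracts
    N/2 from |ad - bc| (floored at zero) when enabled.  Pearson residuals
    (O - E)/sqrt(E) are always the uncorrected ones, so their squares sum to
    the uncorrected statistic.  Any zero margin yields an NA result.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return _na_result(table, "zero margin")
    det = a * d - b * c
    denom = float(r1) * r2 * c1 * c2
    if yates:
        adj = max(abs(det) - n / 2.0, 0.0)
        chi2 = n * adj * adj / denom
    else:
        chi2 = n * float(det) ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    expected = np.outer([r1, r2], [c1, c2]) / n
    residuals = (table.as_array() - expected) / np.sqrt(expected)
    if a > expected[0, 0]:
        direction = "over"
    elif a < expected[0, 0]:
        direction = "under"
    else:
        direction = "none"
    or_, lo, hi = odds_ratio_ci(table)
    return EnrichmentResult(table, float(chi2), p, 1, or_, lo, hi,
                            residuals, direction)


def odds_ratio_ci(table: TwoByTwo, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio with the Woolf log-interval.

    When any cell is zero all four cells receive the Haldane-Anscombe +0.5
    before both the ratio and the interval are computed.
    """
    cells = [float(x) for x in (table.a, table.b, table.c, table.d)]
    if min(cells) == 0:
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(stats.norm.ppf(0.5 + level / 2))
    return or_, or_ * math.exp(-z * se), or_ * math.exp(z * se)


def category_enrichment(
    ebml_flags: pd.Series,
    category_flags: pd.Series,
    universe=None,
    yates: bool = False,
) -> EnrichmentResult:
    """Association between EBML status and a locus category over a universe.

    ``ebml_flags`` and ``category_flags`` are boolean Series indexed by
    locus; the universe defaults to the intersection of their indexes.
    Cell ``a`` counts loci that are both EBML and in the category.
    """
    if universe is None:
        universe = ebml_flags.index.intersection(category_flags.index)
    universe = pd.Index(universe)
    if len(universe) == 0:
        raise ValueError("universe is empty")
    e = ebml_flags.reindex(universe, fill_value=False).astype(bool)
    c = category_flags.reindex(universe, fill_value=False).astype(bool)
    table = TwoByTwo(
        int((e & c).sum()), int((e & ~c).sum()),
        int((~e & c).sum()), int((~e & ~c).sum()),
        row_labels=("EBML", "not EBML"),
        col_labels=("in category", "not in category"))
    return chi2_2x2(table, yates=yates)


def pairwise_overlap_tests(
    ebml_sets: dict[str, set[str]],
    yates: bool = False,
) -> pd.DataFrame:
    """One 2x2 test per unordered population pair over the EBML union.

    For each pair the table classifies every union locus as in-both /
    first-only / second-only / neither.  Returns a tidy DataFrame with a
    signed -log(p) column (negative = under-represented overlap).
    """
    import itertools

    pops = sorted(ebml_sets)
    if len(pops) < 2:
        raise ValueError("need at least two EBML sets")
    union = sorted(set().union(*ebml_sets.values()))
    rows = []
    for pa, pb in itertools.combinations(pops, 2):
        in_a = pd.Series([l in ebml_sets[pa] for l in union], index=union)
        in_b = pd.Series([l in ebml_sets[pb] for l in union], index=union)
        res = category_enrichment(in_a, in_b, universe=union, yates=yates)
        rows.append({"pop_a": pa, "pop_b": pb, "a_both": res.table.a,
                     "chi2": res.chi2, "p_value": res.p_value,
                     "odds_ratio": res.odds_ratio, "direction": res.direction,
                     "signed_logp": res.signed_logp()})
    return pd.DataFrame(rows)


@dataclass
class StratifiedSeries:
    """Coverage-robustness series of per-region enrichment tests.

    ``threshold`` mode forms nested strata (iteration 1 keeps every locus,
    iteration i >= 2 keeps loci with more than 2**i available samples);
    ``window`` mode forms disjoint strata of loci with available-sample
    counts in [2**i, 2**(i+1) - 1] for i = 1..n_iter.
    """

    mode: str
    iterations: list[dict]  # {"iteration", "stratum", "n_loci", region -> result}
    regions: tuple[str, ...] = REGIONS

    def signed_logp_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.iterations:
            row = {"iteration": it["iteration"], "stratum": it["stratum"],
                   "n_loci": it["n_loci"]}
            for region in self.regions:
                res = it[region]
                row[region] = res.signed_logp() if res is not None else math.nan
            rows.append(row)
        return pd.DataFrame(rows)


def stratified_series(
    sample_counts: pd.Series,
    ebml_flags: pd.Series,
    region_flags: pd.DataFrame,
    mode: str = "threshold",
    n_iter: int = 10,
    yates: bool = False,
) -> StratifiedSeries:
    """Per-region enrichment tests across sample-availability strata.

    ``sample_counts`` — available samples per locus; ``ebml_flags`` — boolean
    per locus; ``region_flags`` — boolean DataFrame with one column per gene
    region.  Strata with a zero margin for a region yield None for that cell.
    """
    if mode not in ("threshold", "window"):
        raise ValueError("mode must be 'threshold' or 'window'")
    universe = sample_counts.index
    ebml = ebml_flags.reindex(universe, fill_value=False).astype(bool)
    iterations = []
    for i in range(1, n_iter + 1):
        if mode == "threshold":
            if i == 1:
                mask = pd.Series(True, index=universe)
                stratum = "all"
            else:
                cut = 2 ** i
                mask = sample_counts > cut
                stratum = f">{cut}"
        else:
            lo, hi = 2 ** i, 2 ** (i + 1) - 1
            mask = (sample_counts >= lo) & (sample_counts <= hi)
            stratum = f"[{lo},{hi}]"
        idx = universe[mask]
        entry: dict = {"iteration": i, "stratum": stratum, "n_loci": len(idx)}
        for region in REGIONS:
            if region not in region_flags.columns or len(idx) == 0:
                entry[region] = None
                continue
            flags = region_flags[region].reindex(idx, fill_value=False).astype(bool)
            try:
                res = category_enrichment(ebml.loc[idx], flags, universe=idx,
                                          yates=yates)
            except ValueError:
                entry[region] = None
                continue
            entry[region] = None if res.is_na else res
        iterations.append(entry)
    return StratifiedSeries(mode=mode, iterations=iterations)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample KS test on allele-count distributions.

    D is the supremum ECDF distance; the p-value uses the asymptotic KS
    distribution with the standard effective-n scaling.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
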