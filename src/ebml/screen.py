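"""Discovery of ethnically biased microsatellite loci (EBML).

For each unordered pair of super-populations, every shared locus yields a 2xN
contingency table (populations x genotype categories) tested with Fisher's
exact test; the Benjamini-Hochberg step-up correction is applied within each
pairwise screen.  A locus is biased in population P when the null (no
difference in genotype distribution) is rejected in *all four* screens that
pair P with another population.

The top-level interface follows the model/results idiom::

    model = EBMLScreen(calls, config=ScreenConfig(alpha=0.05, seed=7))
    res = model.fit()
    res.ebml_sets["AFR"]       # loci biased in AFR
    print(res.summary())
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fisher import FisherResult, fisher_exact_2xn
from .genotypes import (FilterConfig, POPULATIONS, add_category, depth_filter,
                        validate_calls)

SCREEN_COLUMNS = ["locus_id", "pair", "n_categories", "p_value", "q_value",
                  "reject", "method"]


@dataclass(frozen=True)
class ScreenConfig:
    """Screening parameters.

    alpha
        FDR level of the per-screen Benjamini-Hochberg correction.  The
        level is a package choice (0.05) and is echoed in every report.
    max_exact_total / max_exact_n / max_exact_tables
        Outer caps and workload gate for exact enumeration (see
        :mod:`ebml.fisher`).
    mc_reps / mc_batch / mc_early_stop
        Monte-Carlo replicate budget, batch size, and sequential early-stop
        threshold for tables beyond the exact gate.
    """

    alpha: float = 0.05
    max_exact_total: int = 200
    max_exact_n: int = 12
    max_exact_tables: int = 10_000
    mc_reps: int = 100_000
    mc_batch: int = 2048
    mc_early_stop: float | None = None  # None = use alpha
    seed: int = 0
    min_samples_per_pop: int = 1

    @property
    def effective_early_stop(self) -> float:
        return self.alpha if self.mc_early_stop is None else self.mc_early_stop

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.mc_reps < 10_000:
            raise ValueError("mc_reps must be >= 10000")


@dataclass
class ContingencyTable:
    locus_id: str
    pop_a: str
    pop_b: str
    categories: list[str]
    counts: np.ndarray  # shape (2, N)

    @property
    def pair(self) -> str:
        return f"{self.pop_a}-{self.pop_b}"


@dataclass(frozen=True)
class ScreenResult:
    locus_id: str
    pair: str
    p_value: float
    q_value: float
    reject: bool
    method: str


@dataclass
class EBMLRecord:
    locus_id: str
    biased_in: set[str]
    pair_q: dict[str, float]


def _pair_counts(counts: pd.DataFrame, pop_a: str, pop_b: str) -> pd.DataFrame:
    """Wide per-locus category counts restricted to one population pair."""
    sub = counts[counts["population"].isin([pop_a, pop_b])]
    return sub.pivot_table(index=["locus_id", "category"],
                           columns="population", values="n",
                           aggfunc="sum", fill_value=0)


def build_contingency(
    summary,
    pop_a: str,
    pop_b: str,
    cfg: ScreenConfig | None = None,
) -> ContingencyTable | str:
    """2xN table for one locus and population pair, or a skip reason.

    Columns are the union of genotype categories observed in either
    population, in canonical sorted order.  The locus is skipped when either
    population has fewer than ``cfg.min_samples_per_pop`` retained samples.
    """
    cfg = cfg or ScreenConfig()
    ca = summary.category_counts.get(pop_a, {})
    cb = summary.category_counts.get(pop_b, {})
    cats = sorted(set(ca) | set(cb), key=_category_sort_key)
    if not cats:
        return "insufficient samples"
    counts = np.array([[ca.get(c, 0) for c in cats],
                       [cb.get(c, 0) for c in cats]], dtype=np.int64)
    if counts[0].sum() < cfg.min_samples_per_pop or \
            counts[1].sum() < cfg.min_samples_per_pop:
        return "insufficient samples"
    return ContingencyTable(summary.locus_id, pop_a, pop_b, cats, counts)


def _category_sort_key(cat: str):
    try:
        a, b = cat.split("/")
        return (int(a), int(b))
    except ValueError:
        return (1 << 30, cat)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and rejection flags.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; reject every p up to
    the largest i with p_(i) <= i * alpha / m.  Stable sort breaks ties.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    passed = ranked <= np.arange(1, m + 1) * alpha / m
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.max(np.flatnonzero(passed)))
        reject[order[: k + 1]] = True
    return q, reject


def _locus_rng(seed: int, pair: str, locus_id: str) -> np.random.Generator:
    """Deterministic per-(seed, pair, locus) generator, independent of
    iteration order."""
    h = zlib.crc32(f"{pair}|{locus_id}".encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, h])


def _locus_count_matrices(counts: pd.DataFrame, populations) -> dict:
    """Per-locus (n_pops x N_categories) count matrices, built once and
    sliced for every pairwise screen."""
    pop_index = {p: i for i, p in enumerate(populations)}
    out: dict[str, np.ndarray] = {}
    pop_codes = counts["population"].map(pop_index).to_numpy()
    n_arr = counts["n"].to_numpy()
    grouped = counts.groupby("locus_id", sort=True)
    for locus, idx in grouped.indices.items():
        cats = counts["category"].to_numpy()[idx]
        uniq, cat_codes = np.unique(cats, return_inverse=True)
        M = np.zeros((len(pop_index), len(uniq)), dtype=np.int64)
        np.add.at(M, (pop_codes[idx], cat_codes), n_arr[idx])
        out[str(locus)] = M
    return out


def _screen_pair(matrices: dict, populations, pop_a: str, pop_b: str,
                 cfg: ScreenConfig, logger=None):
    pair = f"{pop_a}-{pop_b}"
    ia, ib = list(populations).index(pop_a), list(populations).index(pop_b)
    rows: list[tuple] = []
    skipped: list[tuple[str, str]] = []
    for locus in matrices:
        M = matrices[locus]
        tab = M[[ia, ib]]
        keep = tab.sum(axis=0) > 0
        tab = tab[:, keep]
        if tab[0].sum() < cfg.min_samples_per_pop or \
                tab[1].sum() < cfg.min_samples_per_pop:
            skipped.append((locus, "insufficient samples"))
            continue
        res = fisher_exact_2xn(
            tab,
            max_exact_tables=cfg.max_exact_tables,
            max_exact_total=cfg.max_exact_total,
            max_exact_n=cfg.max_exact_n,
            mc_reps=cfg.mc_reps,
            mc_batch=cfg.mc_batch,
            mc_early_stop=cfg.effective_early_stop,
            rng=_locus_rng(cfg.seed, pair, locus),
        )
        rows.append((locus, pair, tab.shape[1], res.p_value, res.method))
    df = pd.DataFrame(rows, columns=["locus_id", "pair", "n_categories",
                                     "p_value", "method"])
    q, reject = bh_adjust(df["p_value"].to_numpy(), cfg.alpha)
    df["q_value"], df["reject"] = q, reject
    df = df[SCREEN_COLUMNS]
    if logger is not None:
        logger.info("screen %s: tested %d loci, rejected %d, skipped %d",
                    pair, len(df), int(df["reject"].sum()), len(skipped))
    return df, skipped


def pairwise_screen(
    counts: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    cfg: ScreenConfig | None = None,
    logger=None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Fisher-test every shared locus for one population pair and apply BH.

    ``counts`` has columns locus_id, population, category, n (long form).
    Returns (results DataFrame, skipped [(locus, reason), ...]).  BH is
    applied across exactly the loci tested in this screen.
    """
    cfg = cfg or ScreenConfig()
    pops = sorted(counts["population"].unique())
    for p in (pop_a, pop_b):
        if p not in pops:
            pops.append(p)
    matrices = _locus_count_matrices(counts, pops)
    return _screen_pair(matrices, pops, pop_a, pop_b, cfg, logger=logger)


def converge_ebml(screens: dict[str, pd.DataFrame], population: str) -> set[str]:
    """Loci rejected in all four screens pairing ``population``.

    A locus skipped (absent) in any of the four screens cannot converge.
    Raises if a required pair is missing.
    """
    pops = sorted({p for pair in screens for p in pair.split("-")})
    required = [f"{min(population, o)}-{max(population, o)}"
                for o in pops if o != population]
    missing = [pair for pair in required if pair not in screens]
    if missing:
        raise KeyError(f"missing screen(s) for {population}: {missing}")
    sets = []
    for pair in required:
        df = screens[pair]
        sets.append(set(df.loc[df["reject"], "locus_id"]))
    return set.intersection(*sets) if sets else set()


def summarize_overlap(ebml_sets: dict[str, set[str]]) -> tuple[pd.DataFrame, pd.Series]:
    """Per-locus membership matrix and exclusive-region counts.

    Returns (membership DataFrame indexed by locus with one boolean column
    per population, counts Series keyed by the '+'-joined member tuple).
    Region counts partition the union, so they sum to its size.
    """
    pops = sorted(ebml_sets)
    union = sorted(set().union(*ebml_sets.values())) if ebml_sets else []
    member = pd.DataFrame(
        {pop: [l in ebml_sets[pop] for l in union] for pop in pops},
        index=pd.Index(union, name="locus_id"), dtype=bool)
    if len(member):
        labels = member.apply(
            lambda row: "+".join(p for p in pops if row[p]), axis=1)
        counts = labels.value_counts().sort_index()
    else:
        counts = pd.Series(dtype=int)
    return member, counts


class EBMLScreen:
    """Pairwise Fisher screening model over a multi-population cohort.

    Parameters
    ----------
    calls
        Genotype-call table (columns sample_id, population, locus_id,
        allele_a, allele_b, read_depth), not yet depth-filtered.
    populations
        Label set; defaults to the five super-populations.
    filter_config, config
        Read-depth filter and screening parameters.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        populations=POPULATIONS,
        filter_config: FilterConfig | None = None,
        config: ScreenConfig | None = None,
    ) -> None:
        self.populations = tuple(populations)
        self.filter_config = filter_config or FilterConfig()
        self.config = config or ScreenConfig()
        self.calls = validate_calls(calls, populations=self.populations)

    @classmethod
    def from_table(cls, path, **kwargs) -> "EBMLScreen":
        from .genotypes import read_genotype_table
        populations = kwargs.get("populations", POPULATIONS)
        return cls(read_genotype_table(path, populations=populations), **kwargs)

    def fit(self, logger=None) -> "EBMLScreenResults":
        filtered = depth_filter(self.calls, self.filter_config, logger=logger)
        counts = (add_category(filtered)
                  .groupby(["locus_id", "population", "category"], sort=True)
                  .size().rename("n").reset_index())
        pops = sorted(self.populations)
        matrices = _locus_count_matrices(counts, pops)
        screens: dict[str, pd.DataFrame] = {}
        skipped: dict[str, list] = {}
        for pop_a, pop_b in itertools.combinations(pops, 2):
            pair = f"{pop_a}-{pop_b}"
            screens[pair], skipped[pair] = _screen_pair(
                matrices, pops, pop_a, pop_b, self.config, logger=logger)
        ebml_sets = {p: converge_ebml(screens, p) for p in self.populations}
        return EBMLScreenResults(self, filtered, screens, skipped, ebml_sets)


class EBMLScreenResults:
    """Fitted screen: per-pair results, converged EBML sets, overlap."""

    def __init__(self, model, filtered_calls, screens, skipped, ebml_sets):
        self.model = model
        self.config = model.config
        self.filtered_calls = filtered_calls
        self.screens = screens
        self.skipped = skipped
        self.ebml_sets = ebml_sets
        self.membership, self.region_counts = summarize_overlap(ebml_sets)

    @property
    def ebml_union(self) -> set[str]:
        return set(self.membership.index)

    def ebml_records(self) -> pd.DataFrame:
        """One row per EBML locus: membership bitmask and per-pair q."""
        pops = sorted(self.model.populations)
        qmaps = {pair: df.set_index("locus_id")["q_value"]
                 for pair, df in self.screens.items()}
        rows = []
        for locus in self.membership.index:
            row = {"locus_id": locus,
                   "biased_in": "+".join(p for p in pops
                                         if self.membership.loc[locus, p])}
            for pair, qmap in qmaps.items():
                row[f"q_{pair}"] = qmap.get(locus, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def screen_table(self) -> pd.DataFrame:
        """All per-pair results concatenated (Fig-style tested/passing log)."""
        return pd.concat(self.screens.values(), ignore_index=True)

    def summary(self) -> str:
        lines = [
            "EBML pairwise Fisher screen",
            f"  populations: {', '.join(sorted(self.model.populations))}",
            f"  FDR level (BH, per screen): {self.config.alpha}",
            f"  seed: {self.config.seed}",
            "  screen            tested  rejected  skipped",
        ]
        for pair in sorted(self.screens):
            df = self.screens[pair]
            lines.append(f"  {pair:<16} {len(df):>7} {int(df['reject'].sum()):>9} "
                         f"{len(self.skipped[pair]):>8}")
        lines.append("  population  EBML")
        for pop in sorted(self.ebml_sets):
            lines.append(f"  {pop:<10} {len(self.ebml_sets[pop]):>5}")
        lines.append(f"  EBML union: {len(self.ebml_union)}")
        return "\n".join(lines)

    def to_tsv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.screen_table().to_csv(out / "screens.tsv", sep="\t", index=False)
        self.ebml_records().to_csv(out / "ebml.tsv", sep="\t", index=False)
        self.region_counts.rename("n_loci").to_csv(out / "overlap_regions.tsv",
                                                   sep="\t")
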