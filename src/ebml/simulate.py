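"""Synthetic cohorts and reference sequences with known ground truth.

The cohort generator emulates the study conditions of the real survey: five
labelled super-populations at the 1000 Genomes Phase 3 exome sample sizes,
multi-allelic array-length genotypes drawn under Hardy-Weinberg equilibrium
from Dirichlet allele frequencies shared across populations, a configurable
number of planted biased loci whose target population's frequency vector is
shifted by a stated total-variation distance, exome-like per-locus sample
availability (Beta-Binomial with a region-dependent mean), and per-call read
depths so the depth filter removes a controllable fraction of calls.

The reference generator plants pure, imperfect, split, compound and
hash-colliding repeats on a repeat-free background so the catalog stage has
an exact expected output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import CatalogConfig, find_pure_repeats
from .genotypes import GENOTYPE_COLUMNS, POPULATIONS

#: 1000 Genomes Phase 3 exome-index sample sizes per super-population
DEFAULT_POP_SIZES = {"AFR": 667, "EUR": 502, "AMR": 352, "EAS": 514, "SAS": 494}

#: mean fraction of samples with a usable call, by gene region — coding and
#: exonic loci are well covered by exome capture, intronic/intergenic poorly
DEFAULT_COVERAGE_MEANS = {
    "cds": 0.9, "exon": 0.9, "utr5": 0.6, "utr3": 0.6,
    "intron": 0.35, "intergenic": 0.25,
}

DEFAULT_REGION_PROBS = {
    "intron": 0.45, "cds": 0.10, "utr5": 0.07, "utr3": 0.08,
    "exon": 0.05, "intergenic": 0.25,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters; the defaults are the emulated study conditions."""

    pop_sizes: dict = field(default_factory=lambda: dict(DEFAULT_POP_SIZES))
    n_loci: int = 2000
    alleles_per_locus: int = 4
    dirichlet_concentration: float = 1.0
    n_biased: int = 200
    effect_tv: float = 0.4
    coverage_means: dict | None = None   # None = every sample available
    coverage_rho: float = 0.1            # Beta-Binomial overdispersion
    region_probs: dict = field(default_factory=lambda: dict(DEFAULT_REGION_PROBS))
    depth_mean: float = 12.0             # Poisson read depth
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.pop_sizes.values()):
            raise ValueError("population sizes must be positive")
        if not 0 <= self.effect_tv <= 1:
            raise ValueError("effect_tv must be in [0, 1]")
        if self.n_biased > self.n_loci:
            raise ValueError("n_biased cannot exceed n_loci")
        if self.alleles_per_locus < 1:
            raise ValueError("alleles_per_locus must be >= 1")


@dataclass
class TruthTable:
    """Ground truth for a simulated cohort."""

    table: pd.DataFrame           # locus_id, region, biased, target_pop
    shared_freqs: dict            # locus_id -> frequency vector
    planted_freqs: dict           # locus_id -> target population's vector
    allele_lengths: dict          # locus_id -> array lengths (bp)

    @property
    def biased_loci(self) -> set[str]:
        return set(self.table.loc[self.table["biased"], "locus_id"])


def simulate_allele_freqs(
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> tuple[dict, dict]:
    """Shared per-locus allele lengths and Dirichlet frequency vectors.

    Allele lengths are K distinct array lengths stepped by the motif length
    around a locus-specific mean.  Reproducible under a fixed seed.
    """
    if spec.alleles_per_locus < 1:
        raise ValueError("need at least one allele per locus")
    rng = rng or np.random.default_rng(spec.seed)
    K = spec.alleles_per_locus
    lengths: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}
    for i in range(spec.n_loci):
        locus = f"L{i:05d}"
        unit_len = int(rng.integers(1, 7))
        base = int(rng.integers(10, 41))
        lengths[locus] = base + unit_len * np.arange(K)
        freqs[locus] = rng.dirichlet([spec.dirichlet_concentration] * K)
    return lengths, freqs


def plant_bias(freq: np.ndarray, effect_tv: float) -> np.ndarray:
    """Shift a frequency vector by exactly ``effect_tv`` in total variation.

    Mass is removed from the most-frequent alleles (in descending order) and
    given to the least-frequent allele, so the donor and recipient sets are
    disjoint and the realized TV distance equals the moved mass.
    """
    p = np.asarray(freq, dtype=float)
    if not 0 <= effect_tv <= 1:
        raise ValueError("effect_tv must be in [0, 1]")
    if effect_tv == 0:
        return p.copy()
    if p.size < 2:
        raise ValueError("cannot plant bias on a monomorphic locus")
    order = np.argsort(p, kind="stable")        # ascending
    recipient = order[0]
    donors = order[1:][::-1]                    # most frequent first
    max_tv = float(p[donors].sum())
    if effect_tv > max_tv + 1e-12:
        raise ValueError(
            f"effect_tv {effect_tv} unreachable; max achievable is {max_tv:.6f}")
    q = p.copy()
    need = effect_tv
    for d in donors:
        take = min(q[d], need)
        q[d] -= take
        need -= take
        if need <= 1e-15:
            break
    q[recipient] += effect_tv
    return q / q.sum()


def _beta_binomial(rng: np.random.Generator, n: int, mean: float, rho: float) -> int:
    """One Beta-Binomial draw with mean ``n*mean`` and intra-class
    correlation ``rho``."""
    if rho <= 0:
        return int(rng.binomial(n, mean))
    conc = (1 - rho) / rho
    a, b = mean * conc, (1 - mean) * conc
    return int(rng.binomial(n, rng.beta(a, b)))


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, TruthTable]:
    """Generate a genotype-call table and its ground truth.

    Per locus and population the available samples each draw two alleles
    independently from that population's frequency vector (HWE); read depth
    is Poisson.  Biased loci have their target population's vector shifted
    by ``spec.effect_tv`` total variation.
    """
    rng = np.random.default_rng(spec.seed)
    lengths, shared = simulate_allele_freqs(spec, rng)
    loci = sorted(lengths)
    pops = sorted(spec.pop_sizes)
    regions = sorted(spec.region_probs)
    region_p = np.array([spec.region_probs[r] for r in regions], dtype=float)
    region_p /= region_p.sum()
    locus_region = {l: regions[int(i)] for l, i in
                    zip(loci, rng.choice(len(regions), size=len(loci), p=region_p))}
    biased = set(rng.choice(loci, size=spec.n_biased, replace=False)) \
        if spec.n_biased else set()
    target_pop = {l: pops[int(i)] for l, i in
                  zip(sorted(biased), rng.integers(0, len(pops), size=len(biased)))}
    planted: dict[str, np.ndarray] = {}

    sample_ids = {pop: [f"{pop}{i:04d}" for i in range(n)]
                  for pop, n in spec.pop_sizes.items()}
    col_sample, col_pop, col_locus = [], [], []
    col_a, col_b, col_depth = [], [], []
    truth_rows = []
    for locus in loci:
        alen = lengths[locus]
        base_freq = shared[locus]
        region = locus_region[locus]
        is_biased = locus in biased
        if is_biased:
            planted[locus] = plant_bias(base_freq, spec.effect_tv)
        truth_rows.append({"locus_id": locus, "region": region,
                           "biased": is_biased,
                           "target_pop": target_pop.get(locus, "")})
        for pop in pops:
            n_pop = spec.pop_sizes[pop]
            if spec.coverage_means is None:
                avail = n_pop
            else:
                mean = spec.coverage_means.get(region, 0.5)
                avail = _beta_binomial(rng, n_pop, mean, spec.coverage_rho)
            if avail == 0:
                continue
            chosen = rng.choice(n_pop, size=avail, replace=False)
            freq = planted[locus] if (is_biased and pop == target_pop[locus]) \
                else base_freq
            pairs = rng.choice(len(alen), size=(avail, 2), p=freq)
            a = alen[pairs.min(axis=1)]
            b = alen[pairs.max(axis=1)]
            depth = rng.poisson(spec.depth_mean, size=avail)
            col_sample.extend(sample_ids[pop][i] for i in chosen)
            col_pop.extend([pop] * avail)
            col_locus.extend([locus] * avail)
            col_a.extend(a.tolist())
            col_b.extend(b.tolist())
            col_depth.extend(depth.tolist())
    calls = pd.DataFrame({
        "sample_id": col_sample, "population": col_pop, "locus_id": col_locus,
        "allele_a": col_a, "allele_b": col_b, "read_depth": col_depth,
    })[GENOTYPE_COLUMNS]
    truth = TruthTable(pd.DataFrame(truth_rows), shared, planted, lengths)
    return calls, truth


# ---------------------------------------------------------------------------
# reference simulation


def square_free_word(n: int) -> str:
    """First ``n`` characters of a square-free word over {A, C, G}.

    Uses the classic substitution a -> abc, b -> ac, c -> b, whose fixed
    point contains no square (no two consecutive copies of any substring) —
    hence no tandem repeat of any unit at all.  Ideal background for
    planting repeats with exactly known coordinates.
    """
    word = "a"
    rules = {"a": "abc", "b": "ac", "c": "b"}
    while len(word) < n:
        word = "".join(rules[ch] for ch in word)
    return word[:n].translate(str.maketrans("abc", "ACG"))


def simulate_reference(
    n_repeats: int,
    contig_length: int,
    cfg: CatalogConfig | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant repeats of five structural types on a tandem-free background.

    Types cycle through: pure; imperfect (two same-unit runs, gap <=
    merge_gap, one merged locus); split (gap > merge_gap, two loci);
    compound (two different units, gap <= merge_gap, one compound locus);
    and hash-collision pairs (two pure arrays of different lengths sharing
    flanks + unit, both expected to be removed by deduplication).

    The background is a square-free word (no tandem structure) over A/C/G;
    planted arrays avoid T, and single ``T`` guard bases separate every
    array from the background so that no run can extend across a junction.
    A per-plant serial tag upstream makes uniqueness keys distinct except
    for the intentional collision pairs.  The assembled reference is
    verified against the expected catalog before it is returned.

    Returns ``({contig: sequence}, truth)`` where ``truth`` is a BED-like
    frame of every planted locus with an ``expect_removed`` flag.
    """
    from .catalog import deduplicate_catalog, merge_and_filter, min_rotation

    cfg = cfg or CatalogConfig()
    rng = np.random.default_rng(seed)
    word = square_free_word(max(contig_length, 200_000) * 2)
    spacing = max(3 * cfg.merge_gap, 30) + 2 * cfg.flank_len

    pieces: list[str] = []
    truth_rows: list[dict] = []
    pos = 0
    n_serial = 0
    contig = "chrSim1"

    def emit(piece: str) -> None:
        nonlocal pos
        pieces.append(piece)
        pos += len(piece)

    def bg(n: int) -> str:
        return word[pos:pos + n]

    def serial() -> str:
        """4-char base-3 plant tag over A/C/G; makes upstream flanks unique."""
        nonlocal n_serial
        digits = np.base_repr(n_serial, base=3).rjust(4, "0")[-4:]
        n_serial += 1
        return digits.translate(str.maketrans("012", "ACG"))

    def gap_fill(n: int) -> str:
        if n <= 2:
            return "T" * n
        return "T" + word[pos + 1:pos + n - 1] + "T"

    def gap_fill_tagged(n: int) -> str:
        # for gaps that precede a separately catalogued locus: end with a
        # guarded serial tag so that locus's upstream flank is unique too
        assert n >= 8
        return "T" + word[pos + 1:pos + n - 7] + "T" + serial() + "T"

    def plant(arrays: list[tuple[str, int]], gaps: list[int], expect: str) -> None:
        emit(bg(spacing))
        emit("T" + serial() + "T")
        seg_spans = []
        for idx, (unit, copies) in enumerate(arrays):
            if idx:
                fill = gap_fill_tagged if expect == "two" else gap_fill
                emit(fill(gaps[idx - 1]))
            s = pos
            emit(unit * copies)
            seg_spans.append((s, pos, unit))
        emit("T")
        if expect == "two":
            for s, e, u in seg_spans:
                truth_rows.append({"chrom": contig, "start": s, "end": e,
                                   "unit": min_rotation(u),
                                   "expect_removed": False})
        else:
            longest = max(seg_spans, key=lambda t: (t[1] - t[0], -t[0]))
            truth_rows.append({"chrom": contig, "start": seg_spans[0][0],
                               "end": seg_spans[-1][1],
                               "unit": min_rotation(longest[2]),
                               "expect_removed": False})

    kinds = ["pure", "imperfect", "split", "compound", "collision"]
    i = 0
    planted = 0
    while planted < n_repeats:
        kind = kinds[i % len(kinds)]
        i += 1
        if kind == "pure":
            unit = ["A", "AC", "AAG", "AG"][i % 4]
            copies = int(rng.integers(9, 16)) if len(unit) == 1 \
                else int(rng.integers(4, 8))
            plant([(unit, copies)], [], expect="one")
            planted += 1
        elif kind == "imperfect":
            gap = int(rng.integers(1, cfg.merge_gap + 1))
            plant([("AC", 5), ("AC", 4)], [gap], expect="one")
            planted += 1
        elif kind == "split":
            gap = cfg.merge_gap + int(rng.integers(3, 9))
            plant([("AG", 5), ("AG", 4)], [gap], expect="two")
            planted += 2
        elif kind == "compound":
            gap = int(rng.integers(1, cfg.merge_gap + 1))
            plant([("A", 8), ("AG", 5)], [gap], expect="one")
            planted += 1
        else:  # collision: identical flank+unit+flank keys, both removed
            up, down = "GCTGC", "CTTAG"
            for copies in (34, 15):
                emit(bg(spacing))
                emit("T" + up)
                s = pos
                emit("A" * copies)
                truth_rows.append({"chrom": contig, "start": s, "end": pos,
                                   "unit": "A", "expect_removed": True})
                emit(down + "T")
            planted += 2
    emit(bg(spacing))
    seq = "".join(pieces)
    if len(seq) > contig_length:
        raise ValueError(
            f"contig_length {contig_length} too short; need {len(seq)} bp")
    seq += word[len(seq):contig_length]
    truth = (pd.DataFrame(truth_rows)
             .sort_values(["chrom", "start"]).reset_index(drop=True))
    _verify_reference(seq, truth, cfg, contig)
    return {contig: seq}, truth


def _verify_reference(seq: str, truth: pd.DataFrame, cfg: CatalogConfig,
                      contig: str) -> None:
    """Assert the assembled reference yields exactly the expected catalog."""
    from .catalog import deduplicate_catalog, merge_and_filter

    runs = find_pure_repeats(seq, cfg)
    loci = merge_and_filter(runs, cfg, seq, chrom=contig)
    retained, removed = deduplicate_catalog(loci, cfg)
    got = sorted((l.start, l.end, l.unit) for l in retained)
    want = sorted((int(r.start), int(r.end), r.unit)
                  for r in truth.itertuples() if not r.expect_removed)
    got_removed = sorted((l.start, l.end) for l in removed)
    want_removed = sorted((int(r.start), int(r.end))
                          for r in truth.itertuples() if r.expect_removed)
    if got != want or got_removed != want_removed:
        raise RuntimeError(
            "reference assembly does not reproduce its planted catalog; "
            f"{len(got)} vs {len(want)} retained, "
            f"{len(got_removed)} vs {len(want_removed)} removed")


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
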