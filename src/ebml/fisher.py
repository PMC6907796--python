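"""Fisher's exact test for 2xN contingency tables.

The null conditions on both margins: row 1 counts follow a multivariate
hypergeometric distribution over the column totals.  The two-sided p-value is
the total probability of all tables at least as extreme as — i.e. no more
probable than — the observed one.

Two evaluation paths are provided and recorded per table:

* ``exact`` — depth-first enumeration over column fills with two prunings:
  a subtree whose best achievable probability is already in the tail is added
  wholesale via the Vandermonde identity (the completions' conditional
  probabilities sum to a closed form), and a subtree whose partial probability
  already exceeds the tail threshold is skipped.  Chosen when a cheap dynamic
  -programming count of margin-compatible tables is below a workload gate.
* ``montecarlo`` — seeded sampling of row-1 fills from the multivariate
  hypergeometric null, with the add-one estimator
  ``p = (1 + #{prob <= observed}) / (reps + 1)`` and an optional sequential
  early stop for clearly non-significant tables.

Probability comparisons use a relative tolerance so that tied tables are
counted in the tail despite floating-point log-factorial evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

#: relative tolerance on the "probability <= observed" comparison
TIE_REL_TOL = 1e-7
_LOG_TIE = math.log1p(TIE_REL_TOL)


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str          # "exact" | "montecarlo"
    reps: int = 0        # Monte-Carlo draws actually used


_LGAMMA = gammaln(np.arange(1024, dtype=float))


def _lgamma_cache(size: int) -> np.ndarray:
    global _LGAMMA
    if size > _LGAMMA.size:
        _LGAMMA = gammaln(np.arange(max(size, 2 * _LGAMMA.size), dtype=float))
    return _LGAMMA


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _log_binom_row(n: int) -> np.ndarray:
    """log C(n, k) for k = 0..n, from the cached log-gamma table."""
    lg = _lgamma_cache(n + 2)
    k = np.arange(n + 1)
    return lg[n + 1] - lg[k + 1] - lg[n - k + 1]


def _check_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2xN")
    if (t < 0).any():
        raise ValueError("table counts must be non-negative")
    return t


def count_tables(col_sums: np.ndarray, r1: int, cap: int) -> int:
    """Number of 2xN tables with the given margins, capped at ``cap + 1``.

    Iterated capped convolution over columns; cost O(N * r1 * 1) via numpy.
    """
    ways = np.zeros(r1 + 1, dtype=np.int64)
    ways[0] = 1
    for c in col_sums:
        kernel = np.ones(min(int(c), r1) + 1, dtype=np.int64)
        ways = np.convolve(ways, kernel)[: r1 + 1]
        np.minimum(ways, cap + 1, out=ways)
    return int(ways[r1])


def _exact_p(col_sums: np.ndarray, r1: int, x_obs: np.ndarray) -> float:
    """Exact two-sided p by pruned depth-first enumeration."""
    c = col_sums.astype(np.int64)
    n = int(c.sum())
    N = len(c)
    log_c = [_log_binom_row(int(cj)) for cj in c]
    lg = _lgamma_cache(n + 2)
    denom = float(lg[n + 1] - lg[r1 + 1] - lg[n - r1 + 1])
    logw_obs = float(sum(log_c[j][int(x_obs[j])] for j in range(N)))
    thresh = logw_obs + _LOG_TIE
    # suffix quantities for bounds and wholesale addition
    suffix_tot = np.concatenate((np.cumsum(c[::-1])[::-1], [0]))  # len N+1
    suffix_max = np.zeros(N + 1)
    for j in range(N - 1, -1, -1):
        suffix_max[j] = suffix_max[j + 1] + float(log_c[j].max())

    total = 0.0
    stack = [(0, r1, 0.0)]  # (column index, remaining row-1 mass, partial logw)
    while stack:
        j, r_rem, logw = stack.pop()
        if logw > thresh:
            continue  # no completion can lower logw
        if j == N:
            total += math.exp(logw - denom)
            continue
        rest = int(suffix_tot[j])
        if logw + suffix_max[j] <= thresh:
            # every completion is in the tail: add the whole subtree mass
            lbin = float(lg[rest + 1] - lg[r_rem + 1] - lg[rest - r_rem + 1])
            total += math.exp(logw + lbin - denom)
            continue
        cj = int(c[j])
        lo = max(0, r_rem - (rest - cj))
        hi = min(cj, r_rem)
        for x in range(lo, hi + 1):
            stack.append((j + 1, r_rem - x, logw + float(log_c[j][x])))
    return min(total, 1.0)


def _montecarlo_p(
    col_sums: np.ndarray,
    r1: int,
    x_obs: np.ndarray,
    rng: np.random.Generator,
    mc_reps: int,
    batch: int = 2048,
    early_stop_p: float | None = 0.05,
) -> tuple[float, int]:
    """Seeded Monte-Carlo p with sequential early stopping.

    Draws escalate through checkpoints (512, 2048, ..., mc_reps); sampling
    stops once the 3-sigma lower confidence bound of the running estimate
    exceeds ``early_stop_p``.  A p-value whose lower bound exceeds the FDR
    level can never be rejected by the BH step-up (whose largest threshold
    is alpha), so stopping there cannot change a screening decision.
    """
    c = col_sums.astype(np.int64)
    N = len(c)
    log_c = [_log_binom_row(int(cj)) for cj in c]
    logw_obs = float(sum(log_c[j][int(x_obs[j])] for j in range(N)))
    thresh = logw_obs + _LOG_TIE
    checkpoints = []
    cp = min(512, batch)
    while cp < mc_reps:
        checkpoints.append(cp)
        cp *= 4
    checkpoints.append(mc_reps)
    hits = 0
    done = 0
    for cp in checkpoints:
        size = cp - done
        if size <= 0:
            continue
        draws = rng.multivariate_hypergeometric(c, r1, size=size)
        logw = np.zeros(size)
        for j in range(N):
            logw += log_c[j][draws[:, j]]
        hits += int((logw <= thresh).sum())
        done = cp
        if early_stop_p is not None:
            p_hat = (1 + hits) / (1 + done)
            lcb = p_hat - 3.0 * math.sqrt(p_hat * (1 - p_hat) / done)
            if lcb > early_stop_p:
                break
    return (1 + hits) / (1 + done), done


def fisher_exact_2xn(
    table,
    *,
    max_exact_tables: int = 10_000,
    max_exact_total: int = 200,
    max_exact_n: int = 12,
    mc_reps: int = 100_000,
    mc_batch: int = 2048,
    mc_early_stop: float | None = 0.05,
    rng: np.random.Generator | int | None = None,
) -> FisherResult:
    """Two-sided Fisher's exact test on a 2xN table.

    The exact path is used when the table is within the outer size cap
    (``max_exact_total`` total count, ``max_exact_n`` columns) and the number
    of margin-compatible tables is at most ``max_exact_tables``; otherwise a
    seeded Monte-Carlo estimate is returned.  A 2x1 table (no variation)
    has p = 1 by construction.
    """
    t = _check_table(table)
    col_sums = t.sum(axis=0)
    keep = col_sums > 0
    t = t[:, keep]
    col_sums = col_sums[keep]
    N = t.shape[1]
    r1 = int(t[0].sum())
    r2 = int(t[1].sum())
    if N <= 1 or r1 == 0 or r2 == 0:
        return FisherResult(1.0, "exact")
    total = r1 + r2
    if N <= max_exact_n and total <= max_exact_total:
        # cheap bracket before the DP count: the product of per-column
        # choices bounds the table count from above
        log_ub = float(np.log(np.minimum(col_sums, r1) + 1).sum())
        if log_ub <= math.log(max_exact_tables):
            return FisherResult(_exact_p(col_sums, r1, t[0]), "exact")
        if log_ub <= math.log(1000.0 * max_exact_tables):
            n_tables = count_tables(col_sums, r1, max_exact_tables)
            if n_tables <= max_exact_tables:
                return FisherResult(_exact_p(col_sums, r1, t[0]), "exact")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p, done = _montecarlo_p(col_sums, r1, t[0], rng, int(mc_reps),
                            batch=mc_batch, early_stop_p=mc_early_stop)
    return FisherResult(p, "montecarlo", reps=done)


def brute_force_p(table) -> float:
    """Independent oracle: full enumeration of all tables with both margins
    fixed, no pruning.  Intended for small tables only."""
    t = _check_table(table)
    col_sums = t.sum(axis=0)
    keep = col_sums > 0
    t = t[:, keep]
    col_sums = col_sums[keep]
    r1 = int(t[0].sum())
    if t.shape[1] <= 1 or r1 == 0 or int(t[1].sum()) == 0:
        return 1.0
    N = t.shape[1]
    n = int(col_sums.sum())
    denom = float(_log_binom(n, r1))
    logw_obs = float(sum(_log_binom(int(col_sums[j]), int(t[0, j]))
                         for j in range(N)))
    thresh = logw_obs + _LOG_TIE

    def rec(j: int, r_rem: int, logw: float) -> float:
        if j == N:
            if r_rem == 0 and logw <= thresh:
                return math.exp(logw - denom)
            return 0.0
        acc = 0.0
        for x in range(0, min(int(col_sums[j]), r_rem) + 1):
            acc += rec(j + 1, r_rem - x, logw + float(_log_binom(int(col_sums[j]), x)))
        return acc

    return min(rec(0, r1, 0.0), 1.0)
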