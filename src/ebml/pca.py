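"""Patterson-normalized principal component analysis of microsatellite
genotypes.

Genotypes are encoded per locus on a [0, 2] dosage scale, each locus (row)
is mean-centered and divided by sqrt(p(1-p)) with the shrunk frequency
estimator p = (1 + sum_n X_mn) / (2 + 2N), and the individual-by-individual
covariance matrix C = X'X / m is eigendecomposed.  This is the conventional
normalization for genotype PCA, under which eigenvalues of unstructured data
concentrate near a common scale.

Two encodings are provided because a multi-allelic repeat genotype has no
canonical dosage:

* ``length-sum`` (default) — the summed diploid array length, min-max
  rescaled per locus to [0, 2]; uses the full multi-allelic information.
* ``major-dosage`` — count of the locus's modal allele in {0, 1, 2};
  the biallelic-marker convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import POPULATIONS


@dataclass
class DosageMatrix:
    X: np.ndarray             # m loci x n individuals, NaN = missing
    locus_ids: list[str]
    sample_ids: list[str]
    populations: list[str]
    encoding: str

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.locus_ids), len(self.sample_ids)):
            raise ValueError("matrix dimensions do not match labels")


@dataclass
class PCAResult:
    components: np.ndarray       # n individuals x k
    eigenvalues: np.ndarray      # descending
    variance_fractions: np.ndarray
    sample_ids: list[str]
    populations: list[str]
    encoding: str = ""

    def coordinates(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.components,
            columns=[f"PC{i + 1}" for i in range(self.components.shape[1])])
        df.insert(0, "population", self.populations)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def summary(self) -> str:
        lines = [f"Patterson-normalized PCA ({self.encoding} encoding)",
                 f"  individuals: {len(self.sample_ids)}",
                 "  component  eigenvalue  variance fraction"]
        for i, (ev, vf) in enumerate(zip(self.eigenvalues, self.variance_fractions)):
            lines.append(f"  PC{i + 1:<8} {ev:>10.4f} {vf:>14.4f}")
        return "\n".join(lines)


def encode_dosage(
    calls: pd.DataFrame,
    encoding: str = "length-sum",
    logger=None,
) -> DosageMatrix:
    """Build the loci x individuals dosage matrix from depth-filtered calls.

    Monomorphic loci (no dosage variation) are dropped; missing calls are
    NaN.  Sample population labels ride along for downstream plotting.
    """
    if encoding not in ("length-sum", "major-dosage"):
        raise ValueError("encoding must be 'length-sum' or 'major-dosage'")
    samples = calls[["sample_id", "population"]].drop_duplicates("sample_id")
    samples = samples.sort_values("sample_id", kind="stable")
    sample_ids = samples["sample_id"].tolist()
    pops = samples["population"].tolist()
    if encoding == "length-sum":
        value = calls["allele_a"] + calls["allele_b"]
    else:
        # modal allele per locus over both chromosomes
        melted = pd.concat([
            calls[["locus_id", "allele_a"]].rename(columns={"allele_a": "al"}),
            calls[["locus_id", "allele_b"]].rename(columns={"allele_b": "al"})])
        modal = (melted.groupby("locus_id")["al"]
                 .agg(lambda s: s.value_counts().sort_index().idxmax()))
        major = calls["locus_id"].map(modal)
        value = ((calls["allele_a"] == major).astype(int)
                 + (calls["allele_b"] == major).astype(int))
    wide = (calls.assign(value=value)
            .pivot_table(index="locus_id", columns="sample_id",
                         values="value", aggfunc="first")
            .reindex(columns=sample_ids))
    X = wide.to_numpy(dtype=float)
    if encoding == "length-sum":
        lo = np.nanmin(X, axis=1, keepdims=True)
        hi = np.nanmax(X, axis=1, keepdims=True)
        span = hi - lo
        keep = span[:, 0] > 0
        X = (X[keep] - lo[keep]) / span[keep] * 2.0
        wide = wide[keep]
    else:
        keep = np.nanmax(X, axis=1) != np.nanmin(X, axis=1)
        X = X[keep]
        wide = wide[keep]
    if logger is not None:
        logger.info("dosage encoding %s: %d loci kept, %d monomorphic dropped",
                    encoding, int(keep.sum()), int((~keep).sum()))
    return DosageMatrix(X, [str(i) for i in wide.index], sample_ids, pops,
                        encoding)


def patterson_normalize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-center and scale a [0, 2] dosage matrix; NaNs become 0 afterwards.

    Per row: mu over observed entries; p = (1 + sum over observed) /
    (2 + 2 * n_observed); divisor sqrt(p(1-p)).  Rows that are entirely
    missing or have a zero divisor are dropped.  Returns (normalized matrix,
    boolean mask of kept rows).
    """
    X = np.asarray(X, dtype=float)
    obs = ~np.isnan(X)
    n_obs = obs.sum(axis=1)
    keep = n_obs > 0
    with np.errstate(invalid="ignore"):
        row_sum = np.nansum(X, axis=1)
        mu = np.where(keep, row_sum / np.maximum(n_obs, 1), 0.0)
        p = (1.0 + row_sum) / (2.0 + 2.0 * np.maximum(n_obs, 1))
        var = p * (1.0 - p)
    keep &= var > 0
    Xn = (X[keep] - mu[keep, None]) / np.sqrt(var[keep, None])
    Xn[np.isnan(Xn)] = 0.0
    return Xn, keep


def principal_components(Xn: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenpairs of the individual covariance C = X'X / m.

    Eigenvector signs are fixed by making each component's largest-magnitude
    loading positive.  Returns (components n x k, eigenvalues descending).
    """
    m, n = Xn.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of individuals ({n})")
    C = Xn.T @ Xn / m
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:k]
    evals = evals[order]
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return evecs, evals


class MicrosatellitePCA:
    """PCA model over a genotype-call table (depth-filtered upstream)."""

    def __init__(self, calls: pd.DataFrame, encoding: str = "length-sum"):
        self.calls = calls
        self.encoding = encoding

    def fit(self, k: int = 10, logger=None) -> PCAResult:
        dm = encode_dosage(self.calls, encoding=self.encoding, logger=logger)
        Xn, kept = patterson_normalize(dm.X)
        k = min(k, len(dm.sample_ids))
        comps, evals = principal_components(Xn, k)
        trace = float(np.trace(Xn.T @ Xn / Xn.shape[0]))
        fractions = evals / trace if trace > 0 else np.zeros_like(evals)
        return PCAResult(comps, evals, fractions, dm.sample_ids,
                         dm.populations, encoding=self.encoding)
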