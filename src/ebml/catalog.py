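"""Microsatellite catalog construction from a reference genome.

A microsatellite is a tandem array of a short motif (1-6 bp).  The catalog is
built in three passes:

1. detect *pure* repeat runs — maximal stretches of exact tandem repetition,
   no impurities tolerated;
2. merge nearby runs — interruptions up to ``merge_gap`` bp are tolerated
   inside a single (imperfect) locus, and runs of different motifs closer than
   ``merge_gap`` form a *compound* locus;
3. remove loci whose mapping context is ambiguous: each locus receives a
   uniqueness key (upstream flank + motif + downstream flank) and every key
   occurring more than once is removed, all copies, because short reads cannot
   be placed uniquely at such loci.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_VALID_BASES = frozenset("ACGTN")

CATALOG_COLUMNS = [
    "chrom", "start", "end", "unit", "unit_length", "n_segments",
    "is_compound", "upstream_flank", "downstream_flank", "key",
]


@dataclass(frozen=True)
class CatalogConfig:
    """Detection and filtering thresholds for catalog construction.

    merge_gap
        Maximum interruption (bp) between pure runs that still belong to one
        locus.  Runs separated by more than this are distinct loci.
    flank_len
        Length (bp) of the flanking sequences used for the uniqueness key.
    min_pure_copies_mono / min_pure_copies
        Minimum number of complete tandem copies for a pure run of a 1-bp
        motif / a 2-6 bp motif.
    min_array_len
        Minimum total span (bp) of a locus after merging.
    """

    merge_gap: int = 10
    flank_len: int = 5
    min_unit: int = 1
    max_unit: int = 6
    min_pure_copies_mono: int = 6
    min_pure_copies: int = 3
    min_array_len: int = 8

    def __post_init__(self) -> None:
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if not (1 <= self.min_unit <= self.max_unit <= 6):
            raise ValueError("unit lengths must satisfy 1 <= min_unit <= max_unit <= 6")
        for name in ("flank_len", "min_pure_copies_mono", "min_pure_copies",
                     "min_array_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def min_copies(self, unit_length: int) -> int:
        return self.min_pure_copies_mono if unit_length == 1 else self.min_pure_copies


@dataclass(frozen=True)
class PureRun:
    """A maximal stretch of exact tandem repetition of a primitive motif."""

    start: int
    end: int
    unit: str          # lexicographically minimal rotation
    phase: str = ""    # motif as written at `start` (observed phase)

    def __iter__(self):
        return iter((self.start, self.end, self.unit))


@dataclass
class RepeatLocus:
    """One catalogued microsatellite."""

    locus_id: str
    chrom: str
    start: int
    end: int
    unit: str
    unit_length: int
    array_seq: str
    segments: list[tuple[int, int, str]]
    is_compound: bool
    upstream_flank: str
    downstream_flank: str
    edge_truncated: bool = False

    @property
    def hashable(self) -> bool:
        """True when both flanks are full-length and unambiguous."""
        if self.edge_truncated:
            return False
        return "N" not in self.upstream_flank and "N" not in self.downstream_flank


def min_rotation(s: str) -> str:
    """Lexicographically minimal rotation of ``s``."""
    return min(s[i:] + s[:i] for i in range(len(s)))


def _is_primitive(unit: str) -> bool:
    """True unless ``unit`` is itself a repetition of a shorter motif."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    return seq


def find_pure_repeats(seq: str, cfg: CatalogConfig | None = None) -> list[PureRun]:
    """Detect maximal pure tandem runs in ``seq``.

    A run for period ``p`` is a maximal interval in which every base equals
    the base ``p`` positions earlier, the leading ``p``-mer is primitive
    (not itself a repetition of a shorter motif), and the interval contains
    at least ``cfg.min_copies(p)`` complete motif copies.  Ambiguous bases
    (N) terminate runs.  Runs of different motifs may overlap.
    """
    cfg = cfg or CatalogConfig()
    seq = _validate_sequence(seq)
    n = len(seq)
    if n == 0:
        return []
    arr = np.frombuffer(seq.encode(), dtype="S1")
    not_n = arr != b"N"
    runs: list[PureRun] = []
    for p in range(cfg.min_unit, cfg.max_unit + 1):
        if n <= p:
            break
        eq = (arr[p:] == arr[:-p]) & not_n[p:] & not_n[:-p]
        if not eq.any():
            continue
        # maximal stretches of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # eq-index one past last True
        for a, b in zip(starts, ends):
            run_start, run_end = int(a), int(b) + p  # sequence coordinates
            if (run_end - run_start) // p < cfg.min_copies(p):
                continue
            phase = seq[run_start:run_start + p]
            if not _is_primitive(phase):
                continue  # covered by a smaller period
            runs.append(PureRun(run_start, run_end, min_rotation(phase), phase))
    runs.sort(key=lambda r: (r.start, r.end, r.unit))
    return runs


def merge_and_filter(
    runs: Sequence[PureRun],
    cfg: CatalogConfig,
    seq: str,
    chrom: str = "seq",
) -> list[RepeatLocus]:
    """Merge pure runs separated by at most ``cfg.merge_gap`` bp into loci.

    Runs of the same motif merge into an imperfect locus; runs of different
    motifs merge into a compound locus.  Loci spanning fewer than
    ``cfg.min_array_len`` bp are dropped.  Flanks are extracted from ``seq``;
    loci within ``flank_len`` of a contig edge are flagged ``edge_truncated``.
    """
    seq = _validate_sequence(seq)
    ordered = sorted(runs, key=lambda r: (r.start, r.end))
    groups: list[list[PureRun]] = []
    cur_end = -(10**9)
    for run in ordered:
        if groups and run.start - cur_end <= cfg.merge_gap:
            groups[-1].append(run)
        else:
            groups.append([run])
        cur_end = max(cur_end, run.end)
    loci: list[RepeatLocus] = []
    for group in groups:
        start = group[0].start
        end = max(r.end for r in group)
        if end - start < cfg.min_array_len:
            continue
        units = [r.unit for r in group]
        # representative motif: that of the longest segment (ties: leftmost)
        longest = max(group, key=lambda r: (r.end - r.start, -r.start))
        up = seq[max(0, start - cfg.flank_len):start]
        down = seq[end:end + cfg.flank_len]
        # clip any overlap between consecutive segments so they stay ordered
        segments: list[tuple[int, int, str]] = []
        for r in group:
            s = max(r.start, segments[-1][1]) if segments else r.start
            if s < r.end:
                segments.append((s, r.end, r.unit))
        loci.append(RepeatLocus(
            locus_id=f"{chrom}:{start}-{end}",
            chrom=chrom,
            start=start,
            end=end,
            unit=longest.unit,
            unit_length=len(longest.unit),
            array_seq=seq[start:end],
            segments=segments,
            is_compound=len(set(units)) > 1,
            upstream_flank=up,
            downstream_flank=down,
            edge_truncated=(len(up) < cfg.flank_len or len(down) < cfg.flank_len),
        ))
    return loci


def uniqueness_key(locus: RepeatLocus, cfg: CatalogConfig | None = None) -> str:
    """Mapping-ambiguity key: upstream flank + motif + downstream flank.

    The key is independent of array length, so loci differing only in repeat
    copy number — which short reads cannot distinguish once mismapped —
    collide.
    """
    if not locus.hashable:
        raise ValueError(f"locus {locus.locus_id} lacks full unambiguous flanks")
    return locus.upstream_flank + locus.unit + locus.downstream_flank


def deduplicate_catalog(
    loci: Iterable[RepeatLocus],
    cfg: CatalogConfig | None = None,
) -> tuple[list[RepeatLocus], list[RepeatLocus]]:
    """Remove every locus whose uniqueness key occurs more than once.

    All copies of a colliding key are removed (not all-but-one).  Loci
    without a hashable flank context are excluded from key counting and from
    the retained list; callers see them via the original input.
    Returns ``(retained, removed)``.
    """
    loci = list(loci)
    hashable = [l for l in loci if l.hashable]
    counts = Counter(uniqueness_key(l) for l in hashable)
    retained = [l for l in hashable if counts[uniqueness_key(l)] == 1]
    removed = [l for l in hashable if counts[uniqueness_key(l)] > 1]
    return retained, removed


def _read_fasta(path: str | Path):
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def catalog_to_frame(loci: Sequence[RepeatLocus], cfg: CatalogConfig) -> pd.DataFrame:
    rows = []
    for l in loci:
        rows.append({
            "chrom": l.chrom, "start": l.start, "end": l.end, "unit": l.unit,
            "unit_length": l.unit_length, "n_segments": len(l.segments),
            "is_compound": l.is_compound, "upstream_flank": l.upstream_flank,
            "downstream_flank": l.downstream_flank,
            "key": uniqueness_key(l, cfg) if l.hashable else "",
        })
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def scan_reference(
    fasta_path: str | Path,
    cfg: CatalogConfig | None = None,
    out_path: str | Path | None = None,
    logger=None,
) -> pd.DataFrame:
    """Build the deduplicated catalog for every contig of a FASTA file.

    Returns the catalog as a DataFrame (TSV written to ``out_path`` when
    given).  Output is deterministic for fixed input.
    """
    cfg = cfg or CatalogConfig()
    all_loci: list[RepeatLocus] = []
    n_contigs = 0
    for name, seq in _read_fasta(fasta_path):
        n_contigs += 1
        runs = find_pure_repeats(seq, cfg)
        loci = merge_and_filter(runs, cfg, seq, chrom=name)
        if logger is not None:
            logger.info("contig %s: %d pure runs, %d loci", name, len(runs), len(loci))
        all_loci.extend(loci)
    if n_contigs == 0:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    retained, removed = deduplicate_catalog(all_loci, cfg)
    if logger is not None:
        logger.info("catalog: %d loci retained, %d removed as ambiguous, %d edge-truncated",
                    len(retained), len(removed),
                    sum(not l.hashable for l in all_loci))
    df = catalog_to_frame(retained, cfg)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def catalog_to_bed(df: pd.DataFrame, out_path: str | Path) -> None:
    """Plain 6-column BED export (name = motif, score = unit length)."""
    bed = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df["unit"], "score": df["unit_length"],
        "strand": ".",
    })
    bed.to_csv(out_path, sep="\t", index=False, header=False)
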