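"""Gene-region annotation and coding-repeat translation.

Loci are assigned region flags (intron/exon/cds/utr5/utr3) by any-overlap
(>= 1 bp) with gene features; CDS or UTR overlap implies the exon flag.
Coding repeats are translated in the reading frame implied by the CDS start,
phase and strand, and summarized as amino-acid runs classified by
hydrophobicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

REGION_KINDS = ("intron", "exon", "cds", "utr5", "utr3")

_GFF_KIND_MAP = {
    "exon": "exon",
    "cds": "cds",
    "intron": "intron",
    "five_prime_utr": "utr5",
    "three_prime_utr": "utr3",
    "5utr": "utr5",
    "3utr": "utr3",
}

#: three-way hydrophobicity partition (configurable; charged/polar residues
#: hydrophilic, aliphatic/aromatic hydrophobic, small/ambivalent neutral)
DEFAULT_RESIDUE_CLASSES = {
    **{aa: "hydrophilic" for aa in "RKDEQNH"},
    **{aa: "hydrophobic" for aa in "AVLIMFWC"},
    **{aa: "neutral" for aa in "GSTYP"},
}


@dataclass(frozen=True)
class GeneFeature:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    kind: str   # intron | exon | cds | utr5 | utr3
    gene_id: str
    phase: int | None = None  # CDS only

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("feature start must be < end")
        if self.kind == "cds" and self.phase not in (0, 1, 2):
            raise ValueError("cds features require phase 0, 1 or 2")
        if self.kind != "cds" and self.phase is not None:
            raise ValueError("phase only applies to cds features")


@dataclass
class CodingRepeatCall:
    locus_id: str
    gene_id: str
    peptide_unit: str
    run_lengths: list[int]
    residue_class: str
    frameshifting: bool = False


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_features(path: str | Path, derive_introns: bool = True) -> list[GeneFeature]:
    """Read gene features from GFF3 (1-based inclusive, converted to 0-based
    half-open).  Unrecognized feature types are ignored.  When no intron
    features are present they are derived as exon complements within each
    transcript (Parent) span."""
    feats: list[GeneFeature] = []
    exons_by_parent: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, phase, attrs = cols[:9]
            kind = _GFF_KIND_MAP.get(ftype.lower())
            if kind is None:
                continue
            a = _parse_gff_attributes(attrs)
            gene = a.get("gene_id") or a.get("gene") or a.get("Parent") or a.get("ID") or ""
            s, e = int(start) - 1, int(end)
            feats.append(GeneFeature(
                chrom, s, e, strand, kind, gene,
                phase=int(phase) if kind == "cds" and phase in "012" else
                (0 if kind == "cds" else None)))
            if kind == "exon":
                parent = a.get("Parent") or gene
                exons_by_parent.setdefault((chrom, strand, parent), []).append((s, e))
    if derive_introns and not any(f.kind == "intron" for f in feats):
        for (chrom, strand, parent), exons in exons_by_parent.items():
            exons = sorted(exons)
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 > e1:
                    feats.append(GeneFeature(chrom, e1, s2, strand, "intron", parent))
    return feats


def assign_regions(loci: pd.DataFrame, features: list[GeneFeature]) -> pd.DataFrame:
    """Boolean region flags per locus by any-overlap (>= 1 bp).

    ``loci`` needs columns locus_id, chrom, start, end.  Flags are the union
    over transcripts; cds/utr overlap implies exon.  Loci on contigs absent
    from the features are flagged ``unannotated``.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    feature_chroms = set()
    for f in features:
        feature_chroms.add(f.chrom)
        trees.setdefault((f.chrom, f.kind), IntervalTree()).addi(f.start, f.end, f)
    rows = []
    for rec in loci.itertuples():
        flags = {k: False for k in REGION_KINDS}
        chrom, start, end = rec.chrom, int(rec.start), int(rec.end)
        unannot = chrom not in feature_chroms
        if not unannot:
            for kind in REGION_KINDS:
                tree = trees.get((chrom, kind))
                if tree is not None and tree.overlap(start, end):
                    flags[kind] = True
        if flags["cds"] or flags["utr5"] or flags["utr3"]:
            flags["exon"] = True
        rows.append({"locus_id": rec.locus_id, **flags, "unannotated": unannot})
    return pd.DataFrame(rows).set_index("locus_id")


def overlapping_genes(loci: pd.DataFrame, features: list[GeneFeature]) -> pd.DataFrame:
    """Locus -> gene assignments (any feature overlap); for gene-list export."""
    tree_by_chrom: dict[str, IntervalTree] = {}
    for f in features:
        tree_by_chrom.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f.gene_id)
    rows = []
    for rec in loci.itertuples():
        tree = tree_by_chrom.get(rec.chrom)
        genes = sorted({iv.data for iv in tree.overlap(int(rec.start), int(rec.end))}) \
            if tree is not None else []
        for g in genes:
            rows.append({"locus_id": rec.locus_id, "gene_id": g})
    return pd.DataFrame(rows, columns=["locus_id", "gene_id"])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _max_residue_run(peptide: str, lo: int, hi: int) -> tuple[str, int, int, int]:
    """Longest period-1 or period-2 residue run overlapping peptide[lo:hi).

    Returns (unit, run_start, run_end, run_length_in_residues).
    """
    best = ("", 0, 0, 0)
    n = len(peptide)
    for period in (1, 2):
        i = 0
        while i < n - period:
            j = i + period
            while j < n and peptide[j] == peptide[j - period]:
                j += 1
            run_len = j - i
            if run_len > period and j > lo and i < hi:
                unit = peptide[i:i + period]
                if period == 2 and unit[0] == unit[1]:
                    i += 1
                    continue
                n_res = run_len
                if n_res > best[3]:
                    best = (unit, i, j, n_res)
            i = max(i + 1, j - period + 1)
    return best


def translate_coding_repeat(
    locus,
    cds: GeneFeature,
    genome_seq: str,
    allele_lengths: list[int] | None = None,
    residue_classes: dict[str, str] | None = None,
) -> CodingRepeatCall:
    """Translate the CDS window covering a repeat and report its residue run.

    ``locus`` needs attributes chrom/start/end (reference coordinates);
    ``genome_seq`` is the full contig sequence.  The reading frame starts at
    the CDS start plus its phase (strand-aware; minus-strand CDS is
    reverse-complemented before translation).  ``allele_lengths`` are
    observed array lengths (bp); a length change that is not a multiple of 3
    marks the call frameshifting and excludes it from residue-run reporting.
    """
    from Bio.Seq import Seq

    classes = residue_classes or DEFAULT_RESIDUE_CLASSES
    if cds.strand == "+":
        coding_start = cds.start + (cds.phase or 0)
        cds_seq = genome_seq[coding_start:cds.end]
        rep_lo = max(locus.start, coding_start) - coding_start
        rep_hi = min(locus.end, cds.end) - coding_start
    else:
        coding_end = cds.end - (cds.phase or 0)
        cds_seq = _revcomp(genome_seq[cds.start:coding_end])
        rep_lo = coding_end - min(locus.end, coding_end)
        rep_hi = coding_end - max(locus.start, cds.start)
    if rep_hi <= rep_lo:
        raise ValueError("locus does not overlap the coding frame of this CDS")
    usable = len(cds_seq) - len(cds_seq) % 3
    peptide = str(Seq(cds_seq[:usable]).translate())
    aa_lo, aa_hi = rep_lo // 3, (rep_hi + 2) // 3
    unit, _, _, run_len = _max_residue_run(peptide, aa_lo, aa_hi)
    ref_len = locus.end - locus.start
    frameshifting = False
    run_lengths = []
    if allele_lengths:
        for alen in allele_lengths:
            delta = alen - ref_len
            if delta % 3 != 0:
                frameshifting = True
            else:
                run_lengths.append(run_len + delta // 3)
    else:
        run_lengths = [run_len]
    residue_class = classify_residue(unit[0], classes) if unit else "neutral"
    return CodingRepeatCall(
        locus_id=getattr(locus, "locus_id", f"{locus.chrom}:{locus.start}-{locus.end}"),
        gene_id=cds.gene_id,
        peptide_unit=unit,
        run_lengths=run_lengths if not frameshifting else [],
        residue_class=residue_class,
        frameshifting=frameshifting)


def classify_residue(aa: str, scheme: dict[str, str] | None = None) -> str:
    """Hydrophobicity class of a one-letter residue code."""
    scheme = scheme or DEFAULT_RESIDUE_CLASSES
    aa = aa.upper()
    if aa not in scheme:
        raise ValueError(f"unknown amino-acid code {aa!r}")
    return scheme[aa]
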