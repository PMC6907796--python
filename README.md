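# ebml — population-biased microsatellite discovery

Microsatellites (short tandem repeats, STRs) are 1–6 bp motifs repeated in
tandem; their array lengths mutate fast and can modulate nearby gene
expression. `ebml` is a pipeline for finding **ethnically biased
microsatellite loci (EBML)** in multi-population cohorts: loci where at
least one super-population's genotype distribution differs significantly
from each of the other populations. It is aimed at population geneticists
working with repeat genotypes called from short-read data (e.g. RepeatSeq
output on 1000 Genomes-style cohorts).

## What it computes

For each unordered pair of populations *(A, B)* and each locus, the samples
are tallied into a 2×N contingency table over the N observed diploid
genotype categories (unordered array-length pairs `a/b`). The null — no
difference in genotype distribution — is tested with **Fisher's exact
test**, which conditions on both margins: row-1 counts follow a
multivariate hypergeometric law over the column totals, and the two-sided
p-value is the total probability of all tables no more probable than the
observed one. Exact enumeration is used when the margin-compatible table
count is small; beyond that a seeded Monte-Carlo estimate with the add-one
estimator `p = (1 + #{P(T) ≤ P(obs)}) / (reps + 1)` is used, and the method
is recorded per locus. Within each of the `C(5,2) = 10` pairwise screens,
the **Benjamini–Hochberg** step-up controls the FDR at level α (default
0.05). A locus is biased in population *P* when the null is rejected in
**all four** screens pairing *P* — the EBML convergence rule.

Around this core the package provides:

* **repeat catalog** — pure-run detection in a reference FASTA, merging of
  interrupted/compound repeats under a `merge_gap` (default 10 bp), and
  removal of mapping-ambiguous loci via flank+motif+flank uniqueness keys
  (e.g. `GCTGC(A)^34 CTTAG → "GCTGCACTTAG"`; all loci sharing a key are
  dropped);
* **genotype I/O** — tabular per-sample calls with a ≥ 6-read depth filter
  and per-locus allele/category summaries;
* **enrichment statistics** — 2×2 χ² tests with odds ratios, Woolf
  confidence intervals and Pearson residuals for locus categories (eSTR,
  matrisome, selective sweeps, unit length, amino-acid class), pairwise
  EBML-overlap tests, two coverage-stratified robustness series, and a
  two-sample Kolmogorov–Smirnov comparison of allele counts;
* **annotation** — intron/exon/CDS/UTR flags by interval overlap and
  strand-aware translation of coding repeats into residue runs;
* **PCA** — Patterson normalization (row-centred, scaled by
  `sqrt(p(1−p))` with `p = (1 + Σ X)/(2 + 2N)`) and eigendecomposition of
  the individual covariance matrix;
* **synthetic data** — cohorts with Dirichlet allele frequencies under
  Hardy–Weinberg equilibrium, planted bias of a stated total-variation
  effect size, exome-like coverage, and reference sequences with planted
  repeats and exact truth.

## Worked example

```python
from ebml import CohortSpec, EBMLScreen, ScreenConfig, simulate_cohort

spec = CohortSpec(pop_sizes={p: 100 for p in ("AFR", "EUR", "AMR", "EAS", "SAS")},
                  n_loci=300, n_biased=30, effect_tv=0.4,
                  coverage_means=None, seed=7)
calls, truth = simulate_cohort(spec)
res = EBMLScreen(calls, config=ScreenConfig(alpha=0.05, seed=7,
                                            mc_reps=10_000)).fit()
print(res.summary())
```

prints (abridged):

```
EBML pairwise Fisher screen
  populations: AFR, AMR, EAS, EUR, SAS
  FDR level (BH, per screen): 0.05
  seed: 7
  screen            tested  rejected  skipped
  AFR-AMR              300        11        0
  AFR-EAS              300        12        0
  ...
  population  EBML
  AFR            7
  AMR            5
  EAS            6
  EUR            5
  SAS            7
  EBML union: 30
```

Each pairwise row reports how many loci entered that screen and how many
rejected the null after BH correction; the per-population counts are the
loci rejected in all four of that population's screens, and here the union
recovers the 30 planted biased loci. `res.ebml_sets["AFR"]` holds the locus
ids, `res.screen_table()` the per-pair p/q-values, and
`res.membership`/`res.region_counts` the overlap structure between the five
EBML sets.

A command-line interface mirrors the stages
(`ebml scan | genotypes | screen | enrich | annotate | pca | simulate | run`).

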