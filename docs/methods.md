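# Methods

## The discovery model

A cohort is a set of diploid samples, each labelled with one of five
super-populations, genotyped at a shared catalog of microsatellite loci. A
genotype is the unordered pair of repeat-array lengths in bp; the category
label `a/b` (a ≤ b) is the unit of all counting. The screen asks, per locus
and per population pair, whether the two populations draw their genotypes
from the same distribution.

Conditioning on both margins of the 2×N table removes the nuisance
parameters: under the null the row-1 counts **x** follow the multivariate
hypergeometric distribution over column totals **c**,
`P(x) = Π_j C(c_j, x_j) / C(n, r_1)`. The two-sided p-value sums `P(T)`
over all margin-compatible tables with `P(T) ≤ P(obs)`. Fisher's exact test
was chosen over χ²/G because the genotype tables are often sparse — many
categories with one or two samples — where asymptotic tests are invalid.

Per pairwise screen, Benjamini–Hochberg is applied across exactly the loci
tested in that screen (not jointly across the ten screens); a locus is
declared biased in population *P* only when rejected in all four screens
pairing *P*. Loci with a single observed category receive p = 1 and count
toward the BH family, so the "tested" totals reflect every locus that met
the sample requirement. A locus skipped (fewer than `min_samples_per_pop`
retained samples) in any of a population's four screens cannot converge for
that population; ignoring missing screens instead would declare bias from
incomplete evidence.

### Exact vs Monte-Carlo evaluation

Exact enumeration is depth-first over column fills with two prunings: when
the maximum achievable completion probability of a partial assignment is
already within the tail, the whole subtree's mass is added in closed form
(Vandermonde: the completions' conditional weights sum to
`C(n_rest, r_rest)`); when the partial weight already exceeds the
threshold, the subtree is skipped. Enumeration is attempted only when the
table is within an outer size cap (total ≤ 200, N ≤ 12) *and* a capped
dynamic-programming count of margin-compatible tables is at most
`max_exact_tables` (default 10,000). The count gate, rather than a raw size
cap, is what decides: a 2×10 table with margins of 100 has > 10¹² valid
tables and must be sampled, while a sparse 2×12 table with small margins
enumerates in microseconds.

The Monte-Carlo path samples row-1 fills directly from the multivariate
hypergeometric null and uses the add-one estimator
`p = (1 + hits)/(reps + 1)` (never zero, conservatively biased). Draws
escalate through checkpoints (512, 2048, …, `mc_reps`); sampling stops
early once the 3σ lower confidence bound of the running estimate exceeds
the screen's FDR level α, because the BH step-up's largest possible
rejection threshold is α — a p-value confidently above it cannot change any
decision. Each (seed, pair, locus) triple gets its own generator derived by
hashing, so results are independent of iteration order and reproducible.
`mc_reps` defaults to 10⁵; the simulation studies in the test suite and
acceptance script use 10⁴, which bounds the smallest reportable p at
~10⁻⁴ — sufficient for BH decisions in families of ~2,000 tests with tens
to hundreds of true signals.

Probability comparisons use a relative tie tolerance of 10⁻⁷ so that
tables tied with the observed one (up to log-factorial rounding) are
counted in the tail; without it the exact p is unstable at machine
precision.

## Catalog construction

Pure runs are maximal intervals in which every base equals the base *p*
positions earlier (p = 1..6), with a primitive leading motif and at least 6
(mononucleotide) or 3 (longer motifs) complete copies; N terminates runs.
Runs separated by at most `merge_gap` (10 bp) merge into one locus —
same-motif merges are "imperfect", mixed-motif merges "compound" (motif of
the longest segment represents the locus). Loci spanning < 8 bp are
dropped. These two copy/length thresholds are package defaults (the
detection literature varies) chosen to keep mononucleotide noise out while
retaining short informative arrays; both are configurable.

The uniqueness key is upstream-flank + motif + downstream-flank (5 bp
flanks), written in sequence order; every locus whose key occurs more than
once is removed — all copies — because reads from such loci cannot be
mapped uniquely. Loci lacking a full N-free flank are flagged and excluded
from hashing rather than silently dropped. Motifs are canonicalized to the
lexicographically minimal rotation on the given strand; reverse-complement
classes are deliberately not folded (A and T runs are biologically and
mutationally distinct on a fixed reference strand).

## Enrichment statistics

All category tests are 2×2 χ² tests of independence, uncorrected by
default: the closed form `N(ad−bc)²/(R₁R₂C₁C₂)` equals the sum of squared
Pearson residuals `(O−E)/√E`, an identity the tests verify and the
fourfold-style displays rely on; Yates' correction is available behind a
flag but breaks that identity by design. Odds ratios use the Woolf
log-interval, with Haldane–Anscombe +0.5 on all cells when any cell is
zero (for the ratio and interval only — a zero-margin χ² is reported NA,
not corrected). Signed log-p series use natural log, positive when the
first category is over-represented.

The two coverage-stratified series address exome-capture confounding: the
number of samples with a usable call is region-dependent (coding high,
intron/UTR low), so a single pooled test of region enrichment is biased.
Threshold mode repeats the test on nested subsets (all loci, then > 4,
> 8, > 16, … available samples, doubling for 10 iterations); window mode
uses disjoint strata [2,3], [4,7], [8,15], … . Concordant directions
across populated strata in both modes indicate the enrichment is not a
coverage artifact. "Available samples" counts retained (depth-filtered)
calls summed over populations.

The allele-count comparison uses the asymptotic two-sample KS test; group
sizes in the intended applications are dozens to thousands, where the
asymptotic p is adequate and the exact permutation version is not needed.

## PCA

There is no canonical dosage for a multi-allelic repeat genotype, so two
encodings are offered and recorded in output metadata: `length-sum` (the
summed diploid array length, min-max rescaled to [0,2] per locus; default,
uses the full multi-allelic information) and `major-dosage` (count of the
locus's modal allele, the biallelic convention). Rows are centred and
scaled by `sqrt(p(1−p))` with the shrunk estimator
`p = (1 + Σ_n X_mn)/(2 + 2N)`, which keeps a finite divisor for rows at the
scale boundary; missing entries are mean-imputed (zero after centring),
which is unbiased for the covariance in expectation. The covariance
`C = XᵀX/m` over individuals is eigendecomposed; eigenvector signs are
fixed by making the largest-magnitude loading positive.

## Synthetic data: what it emulates and what it does not

The cohort generator reproduces the study conditions the pipeline is meant
for: five populations at the 1000 Genomes Phase 3 exome sizes (AFR 667,
EUR 502, AMR 352, EAS 514, SAS 494) by default; per-locus allele-length
ladders stepped by the motif length; shared allele frequencies drawn from a
symmetric Dirichlet (concentration 1); Hardy–Weinberg sampling within
populations; Beta-Binomial per-locus sample availability with
region-dependent means (coding ≈ 0.9, UTR ≈ 0.6, intron ≈ 0.35) emulating
exome capture; and Poisson read depths (mean 12) so the ≥ 6-read filter
removes a realistic few percent of calls. Planted bias shifts the target
population's frequency vector by an exact total-variation distance
(mass moved from the most-frequent to the least-frequent allele), an
interpretable effect size that bounds the genotype-distribution shift under
HWE. The power study uses effect TV 0.4 with 100 samples per population,
K = 4 alleles and 2,000 loci (200 biased) over 20 seeds — sized so a
desk-scale run completes in minutes while leaving the detection problem
non-trivial.

Not emulated: linkage disequilibrium between loci, stepwise mutation
structure within populations, genotyping error, allele dropout, and
population substructure below the super-population labels. Passing tests
therefore demonstrate correctness of the statistics and the recovery of
frequency-shift signals under HWE independence — not robustness to
real-data artifacts such as stutter noise or cryptic relatedness.

The reference generator plants repeats on a background built from a
square-free ternary word (no two consecutive copies of any substring, hence
no tandem structure at all), with single `T` guard bases isolating each
planted array and per-plant serial tags making flank keys unique except for
the intentional hash-collision pairs. This makes the expected catalog exact
by construction; the generator verifies the assembled sequence against its
own truth before returning it.

## Numerical and design choices

* FDR level α = 0.05 by default; it is printed in every summary and
  manifest because downstream counts are meaningless without it.
* BH is implemented directly (ten lines, step-up with stable ties) and
  cross-checked against statsmodels in the tests.
* 2×1 tables get p = 1 rather than exclusion, keeping the BH family size
  equal to the number of loci meeting the sample rule.
* Merge monotonicity (larger `merge_gap` never yields more merged groups)
  holds for the merge itself; the min-array-length filter can rescue short
  runs into a newly merged locus, so the invariant is stated pre-filter.
* Residue hydrophobicity classes default to hydrophilic {R,K,D,E,Q,N,H},
  hydrophobic {A,V,L,I,M,F,W,C}, neutral {G,S,T,Y,P}; the partition is
  configurable since conventions differ at the margins (notably serine).
* Degenerate inputs: empty sequences yield empty catalogs; loci with no
  retained calls are dropped with a log entry; all-missing PCA rows are
  dropped; an empty p-value vector BH-adjusts to empty.

## Known limitations

* The Monte-Carlo p-floor (`1/(reps+1)`) limits BH resolution when true
  signals are few and the family is large; raise `mc_reps` for such
  designs.
* Exact enumeration cost is gated by a table count, so pathological tables
  just under the gate can take tens of milliseconds.
* GFF3 parsing covers the exon/CDS/UTR/intron subset with `Parent`-based
  intron derivation; full genome annotation edge cases (trans-splicing,
  multi-parent features) are out of scope.
* Coding-repeat translation reports the maximal period-1/2 residue run in
  the repeat window of the overlapping CDS; repeats spanning splice
  junctions are not stitched across CDS features.
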