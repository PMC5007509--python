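# Methods

This note documents the statistical conventions, numerical choices and
simulation models behind the package, and what the test suite does and
does not establish.

## Forensic parameters

All per-locus statistics operate on one locus of a genotype table (or,
where possible, a frequency table) with pairwise deletion: the sample
size *n* at a locus is the number of individuals with a non-missing
call there, and frequencies are counts over the 2*n* gene copies.

- **Expected heterozygosity** uses Nei's small-sample correction,
  *H*exp = (2*n*/(2*n*−1))(1 − Σ*p*ᵢ²). The uncorrected variant is
  available via `unbiased=False`. The correction matters at the third
  decimal for *n* ≈ 100, which is exactly the precision at which
  published tables print it.
- **PIC** is the Botstein index 1 − Σ*p*ᵢ² − (Σ*p*ᵢ²)² + Σ*p*ᵢ⁴.
- **Matching probability** follows the PowerStats convention: the sum
  of squared *observed* genotype-class frequencies, not the
  Hardy–Weinberg product expectation. The two differ noticeably (at
  TPOX in the packaged panel: 0.157 observed vs ≈0.168 expected);
  `expected_match_probability` provides the HWE variant for
  frequency-only input and is labelled as such.
- **PE and PI** are functions of observed heterozygosity *h* only:
  PE = *h*²(1 − 2*h*(1−*h*)²), PI = 1/(2(1−*h*)). PI diverges as
  *h* → 1 and is an error there.
- **Combined statistics** assume independent loci:
  CPD/CPE = 1 − Π(1 − per-locus value); mean Pm is arithmetic.

### Reproducing printed tables

Published tables round to 2–3 decimals, which sets the comparison
tolerances in `reproduce_gorkha` (±0.005 for frequency-derived Hexp and
PIC, ±0.002/±0.01 for PE/PI, ±0.001 for mean Pm, ±1e-7 for CPE, exact
for counts). Because a printed *H*obs is really a heterozygote count
over *n* individuals, the reproduction path first recovers the exact
proportion round(*h*·*n*)/*n* before applying PE/PI — PI's division by
1 − *h* amplifies third-decimal rounding enough to matter (printed
0.867 at *n* = 98 is 85/98 = 0.86735; PI is 3.769 from the count but
3.759 from the rounded decimal).

Four columns of the packaged table carry printed summary values that
are arithmetically inconsistent with their own printed frequencies or
*H*obs (expected heterozygosity at D21S11, TH01, D19S433 and FGA; PE/PI
at D21S11, TH01 and D19S433 — the D21S11/D19S433 PE/PI pair is a
verbatim duplicate, suggesting transcription duplication in the
source). These columns are excluded from the per-locus pass/fail
comparisons and the exclusion lists are module constants. The printed
combined PD is likewise not derivable from the printed per-locus PD row
(the product saturates IEEE doubles), so CPD is reported without a
pass/fail verdict. The package also reports 1/mean Pm as the "one in
N" figure computed from its own mean, without attempting to match
secondary derived phrasings.

## Exact Hardy–Weinberg test

The test conditions on observed allele counts *m*₁…*m*ₖ. A genotype
array with heterozygote counts {*n*ᵢⱼ} has probability

P = *n*! · 2^h · Π*m*ᵢ! / (Π_{i≤j} *n*ᵢⱼ! · (2*n*)!),

*h* the number of heterozygous individuals. The two-sided probability
test sums P over all arrays with P ≤ P(observed); ties are included
with a 1e-9 tolerance on log-probabilities (array probabilities are far
better separated than that in practice).

- **Enumeration** recurses over the heterozygote counts *n*ᵢⱼ (i < j)
  in lexicographic order with capacity pruning; diagonal counts follow
  by parity. Auto-dispatch enumerates when the locus has ≤4 observed
  alleles and *n* ≤ 200 — but the 4-allele array space grows
  combinatorially in *n*, so auto-dispatch additionally abandons any
  enumeration exceeding 200,000 arrays and falls back to Monte Carlo.
  An explicit `method="enumerate"` runs without the budget.
- **Monte Carlo** shuffles the 2*n* gene copies, re-pairs consecutive
  copies and recomputes the array probability, fully vectorized across
  replicates; the estimator is (1 + hits)/(1 + reps), so p is never 0.
  Defaults: 100,000 replicates, seed 1, both recorded in the result.
- Monomorphic loci return p = 1 (only one array is possible).
- Bonferroni correction divides the working level by the number of
  loci at full precision (0.05/15 = 0.00333…, displayed 0.003).

The exact test's p-values are discrete and conservative: under the
null their distribution is stochastically larger than uniform, which
is what the calibration test asserts (empirical CDF at a grid of
levels, with binomial and Monte Carlo noise margins).

## Distances and differentiation

**Nei's DA** between populations is 1 − (1/L)ΣₗΣᵢ√(xᵢyᵢ) over L shared
loci, with allele domains unioned per locus (absent alleles contribute
0). It lives in [0, 1] and is 0 iff the frequency vectors coincide.

**Weir–Cockerham θ** is computed from variance components a (between
populations), b (between individuals within) and c (within
individuals), summed over alleles and loci before the ratio
θ = Σa / Σ(a+b+c); estimates can be slightly negative and are reported
as computed. Inputs here are frequency tables, the situation of
published compilations, so copy counts are reconstructed as
round(freq·2*n*) and the within-individual heterozygosity entering b
and c uses its random-mating expectation 2*p*(1−*p*). This
frequency-only approximation is exact in expectation under HWE but
cannot see genotypic disequilibrium; with raw genotypes a future
version could use observed heterozygote counts instead.

**Permutation test**: the pooled 2*n*A+2*n*B gene copies are reshuffled
into the original group sizes; p = (1 + #{θ* ≥ θobs})/(1 + reps),
one-sided because differentiation only inflates θ. Default 10,000
replicates, seeded. This gene-copy scheme is a documented stand-in for
whatever pseudo-individual reconstruction the original Fst software
used on frequency-only data; it is property-tested (null behaviour,
fixed-difference minimum, power under drift), not value-matched to any
published p-value.

## Neighbor-Joining and bootstrap

The Saitou–Nei criterion Q(i,j) = (r−2)d(i,j) − Rᵢ − Rⱼ is minimized
at each step; two details the standard description leaves open are
pinned down for reproducibility:

- ties in Q are broken by the lexicographically lowest index pair of
  the current node list;
- a negative branch-length estimate is clamped to 0 with the deficit
  transferred to its sibling branch, preserving the path length
  through the new node; the raw estimate is kept on the node as
  `raw_length`.

The final three nodes join at a basal trifurcation, which is also the
(arbitrary but stable) rooting used for Newick serialization. NJ is
exact on additive matrices — topology and all path lengths — and the
suite verifies this on random trees of 4–12 leaves, plus agreement
with an independent NJ implementation on non-additive matrices.

Bootstrap follows the published pipeline: the resampling unit is the
locus (with replacement), the distance matrix and tree are rebuilt per
replicate, and each internal edge of the full-data tree (not a
consensus tree) is labelled with the percentage of replicates
containing its bipartition. Bipartitions are canonicalized by the side
not containing the alphabetically first leaf, making the encoding
invariant to leaf order and rooting.

On the packaged 16-population matrix, the nearest leaf to the study
population by tree path length is one of the two Nepali reference
samples: the printed matrix has them at 0.015 and 0.016, a near-tie
that NJ's re-estimated branch lengths can order either way since the
matrix (being rounded to 3 decimals) is not additive.

## Ordination

`pcoa` performs classical scaling (double-centred −D²/2,
eigendecomposition, coordinates scaled by √eigenvalue) via scikit-bio,
then drops non-positive eigenvalue axes, warning when that truncates
the request. `pca_frequencies` builds the populations × (locus, allele)
matrix, mean-centres columns and takes the SVD. Both fix axis signs by
making each component's largest-magnitude entry positive, so repeated
runs agree exactly. Both routes are exposed because published STR
ordinations are made from either a distance matrix or the raw
frequency table; neither is value-matched to any published plot, whose
axes and signs are software-specific.

## Simulators

- `sample_hwe_population`: two independent draws per individual from
  the locus frequencies (the null of the exact test).
- `sample_inbred_population`: with probability *F*is an individual is a
  forced homozygote (one draw duplicated); expected
  *H*obs = (1−*F*is)(1−Σ*p*²). This is the simplest mixture model with
  the correct first moment, adequate for power tests; it is not a
  pedigree model.
- `sample_balding_nichols`: per locus, each population's frequency
  vector is drawn from Dirichlet(p·(1−F)/F) around the ancestral
  vector p, then genotypes are random-mating draws within populations.
  The parameterization gives E[Fst] ≈ F, which is what makes estimator
  recovery a quantitative benchmark (mean θ within 30% of F at the
  scales tested). F = 0 copies the ancestor exactly.

Defaults mirror the study the fixtures come from: 15 loci whose
per-locus allele counts match the published panel (summing to 138),
98 individuals per population, ancestral frequencies from a symmetric
Dirichlet(1) when not given explicitly. All generators are pure
functions of (parameters, seed).

What the simulations do *not* emulate: stepwise mutation, linkage
between loci, genotyping dropout/stutter, population admixture. Tests
passing on these generators show the estimators and tests behave
correctly under their own model assumptions; they are silent about
robustness to those real-data features.

## Problem sizes used in the test suite

Deterministic fixture checks run on the full packaged tables. The
stochastic properties use: 500 simulated loci at *n* = 98 (HWE null
calibration, Monte Carlo at 1,000 replicates per locus); 150 paired
null/inbred samples (power); 6 replicate Balding–Nichols simulations
per F at 20 loci × 200 individuals (θ recovery); 200 bootstrap
replicates over 12 loci for the deep-split support check; exhaustive
HWE oracles at ≤3 alleles up to *n* = 5 (perfect-matching enumeration)
and *n* = 8 (independent flat enumeration). These sizes were chosen so
each property is tested with comfortable statistical margins while the
whole suite stays quick to run.
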