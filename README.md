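# strpop

Population-genetic and forensic analysis of autosomal short-tandem-repeat
(STR) panels: the statistics a forensic lab reports for a typed
population sample, and the between-population analyses used to place
that sample among published reference populations.

The package grew out of reanalyzing a 15-locus Identifiler panel typed
in 98 individuals, for which it ships the published allele-frequency
table and the 16-population Nei genetic-distance matrix as fixtures, but
every component works on any STR genotype or frequency data.

## What it computes

**Per-locus forensic parameters** from a genotype table or frequency
table, in the PowerStats convention:

- observed heterozygosity *H*obs and Nei's unbiased expected
  heterozygosity *H*exp = (2*n*/(2*n*−1))·(1 − Σ*p*ᵢ²);
- polymorphism information content
  PIC = 1 − Σ*p*ᵢ² − (Σ*p*ᵢ²)² + Σ*p*ᵢ⁴ (Botstein);
- matching probability Pm = Σ (observed genotype-class frequency)² and
  power of discrimination PD = 1 − Pm;
- power of exclusion PE = *h*²(1 − 2*h*(1−*h*)²) and typical paternity
  index PI = 1/(2(1−*h*)) with *h* = *H*obs;
- panel-wide combinations CPD/CPE = 1 − Π(1 − per-locus value) and mean
  Pm.

**Exact Hardy–Weinberg test** conditional on allele counts (probability
test, two-sided), by exhaustive enumeration of genotype arrays for
few-allele loci and seeded Monte Carlo gene-copy shuffling otherwise,
with Bonferroni correction across a panel.

**Population structure**: Nei's DA distance
(1 − mean over loci of Σ√(*x*ᵢ*y*ᵢ)), Weir–Cockerham θ (Fst) from
variance components with locus-wise permutation p-values,
Saitou–Nei Neighbor-Joining trees with bootstrap-over-loci supports,
and ordination (PCoA of a distance matrix or PCA of frequency tables).

**Simulators** for testing it all without raw data: random-mating
genotype sampling, inbred sampling with a target *F*is, and
Balding–Nichols drifted population sets with expected Fst equal to the
drift parameter.

## Worked example

```python
import numpy as np
import strpop as sp

table = sp.load_gorkha_frequencies()      # 15 loci, n = 98, 138 alleles
h = sp.expected_heterozygosity(table.freqs["TPOX"], table.n["TPOX"])
p = sp.pic(table.freqs["TPOX"])
print(f"TPOX: Hexp = {h:.3f}, PIC = {p:.3f}")

pub = table.published                     # the table's own summary rows
pe = np.array([pub["pe"][locus] for locus in table.loci])
print(f"combined PE = {1 - np.prod(1 - pe):.10f}")

tree = sp.neighbor_joining(sp.load_nei_da_matrix())
print(sp.write_newick(tree)[:60], "...")
```

prints

```
TPOX: Hexp = 0.668, PIC = 0.609
combined PE = 0.9999993441
(Tamil:0.006895996093750001,((Gorkha:0.008996093749999998,(Ne ...
```

TPOX is the least informative locus of the panel (lowest PIC), yet the
fifteen loci jointly exclude a non-parent with probability 0.9999993;
the tree groups the highland/East-Asian populations together and puts
the six lowlander Indian populations on the other side of an internal
edge. The scripts under `examples/` walk through each capability
(forensic summary, HWE testing, distances and trees, ordination,
estimator recovery) and print a line explaining their numbers.

A thin CLI mirrors the library:

```sh
strpop summarize --genotypes g.csv --out report.csv
strpop hwe --genotypes g.csv --reps 100000 --seed 1 --out hwe.csv
strpop tree --pops pops.csv --bootstrap 1000 --seed 1 --out tree.nwk
strpop reproduce-gorkha
```

`strpop reproduce-gorkha` recomputes every statistic of the packaged
study tables, diffs against the printed values and exits nonzero on any
failure.

## File formats

Genotype CSV (`sample,<locus>,...` with `a/b`, homozygote shorthand
`a`, empty = missing); frequency CSV in published-table layout (allele
rows, optional summary rows, `n` row); distance matrices as labelled
CSV or PHYLIP square; population sets as long CSV
(`population,locus,allele,frequency,n`); trees as Newick with integer
bootstrap supports on internal nodes.
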