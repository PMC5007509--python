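"""Exact Hardy-Weinberg testing on simulated genotype samples.

Draws one population under random mating and one with inbreeding
(F_is = 0.3) at the same allele frequencies, runs the exact test on
both, and applies the Bonferroni-corrected significance level a
15-locus panel would use.
"""

import strpop as sp
from strpop.str_data import AlleleLabel

freqs = {AlleleLabel(8): 0.4, AlleleLabel(9): 0.35, AlleleLabel(10): 0.25}
null_pop = sp.sample_hwe_population({"L": freqs}, n=98, seed=1)
inbred_pop = sp.sample_inbred_population({"L": freqs}, n=98, f_is=0.3, seed=1)

alpha = sp.bonferroni_alpha(0.05, 15)
print(f"Bonferroni-corrected level for 15 loci: {alpha:.3f}\n")

for name, pop in [("random mating", null_pop), ("inbred F=0.3", inbred_pop)]:
    res = sp.hwe_exact(pop, "L", seed=1)
    h = sp.observed_heterozygosity(pop, "L")
    verdict = "rejects HWE" if res.p_value < alpha else "consistent with HWE"
    print(f"{name:15s} Hobs = {h:.3f}  p = {res.p_value:.4f} "
          f"({res.method})  -> {verdict}")

print("\nThe inbred sample shows the heterozygote deficit the exact test "
      "is designed to detect; the random-mating sample should not be "
      "flagged at the corrected level.")
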