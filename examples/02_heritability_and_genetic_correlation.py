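"""Recover generating heritability and genetic correlation.

Simulates an unrelated cohort with a polygenic trait (h2 = 15.6%) and
a second cohort with two traits sharing genetic correlation 0.55, then
re-estimates both quantities by Haseman-Elston regression on the
genetic relationship matrix.
"""

from tpewas import (
    GeneticArchitecture,
    genetic_correlation_he,
    heritability_he,
    simulate_cohort,
)

arch = GeneticArchitecture(n_individuals=4000, n_variants=2000, h2=0.156, seed=1)
cohort, traits = simulate_cohort(arch)
est = heritability_he(cohort, traits["trait_a"].to_numpy())
print(f"generating h2 = 15.6% -> HE estimate {100 * est.h2:.1f}% "
      f"(jackknife SE {100 * est.se:.1f} points)")

arch2 = GeneticArchitecture(
    n_individuals=4000, n_variants=2000, h2=0.10, rg=0.55, seed=2
)
cohort2, traits2 = simulate_cohort(arch2)
rg = genetic_correlation_he(
    cohort2, traits2["trait_a"].to_numpy(), traits2["trait_b"].to_numpy()
)
print(f"generating rg = 0.55  -> bivariate HE estimate {rg.rg:.2f} "
      f"(jackknife SE {rg.se:.2f})")
print("\nBoth estimates sit within their sampling error of the generating "
      "values;\nthe SE reflects the desk-scale cohort (4,000 individuals).")
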