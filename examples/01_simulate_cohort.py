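"""Generate a synthetic biobank-style cohort with known causal structure.

The generator draws biallelic genotypes, builds BMI from a true variant
score plus a shared unobserved confounder, and discretises a latent
well-being index (linear or quadratic in BMI) onto an ordinal scale at
empirical quantile cutpoints.
"""

from mrwell import SimConfig, simulate_cohort

config = SimConfig(n_individuals=10_000, n_variants=20, seed=1)
geno, pheno, truth = simulate_cohort(config)

df = pheno.data
print(f"cohort: {len(df)} individuals x {geno.n_variants} variants")
print(f"BMI mean (SD): {df.bmi.mean():.1f} ({df.bmi.std():.1f}) kg/m^2")
print(f"female: {(df.sex == 'female').mean():.1%}, urban: {df.urban.mean():.1%}, "
      f"related: {df.related.mean():.1%}")
print("well-being category proportions:",
      df.wellbeing.value_counts(normalize=True).sort_index().round(3).tolist())
print(f"true causal effect: {truth.beta_linear} per BMI SD "
      f"(quadratic {truth.beta_quadratic}); per-allele effects {truth.beta_g[0]:.2f} SD")
# The category proportions track the configured prevalences (11.6/44.3/27.0/17.1%),
# and the printed truth is what the downstream estimators should recover.
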