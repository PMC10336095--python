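"""One-sample Mendelian randomisation against a confounded observational fit.

The cohort is generated with a true causal effect of 0.3 per BMI SD and a
shared confounder loading 0.5 on both BMI and well-being: ordinary
regression overstates the effect, TSLS with the genetic score recovers it.
Stratified estimates are then pooled by fixed-effects meta-analysis.
"""

from mrwell import (
    SimConfig,
    meta_fixed,
    observational_fit,
    simulate_cohort,
    tsls_fit,
)

geno, pheno, truth = simulate_cohort(
    SimConfig(n_individuals=20_000, beta_linear=0.3, seed=3)
)
g = geno.dosages @ truth.beta_g  # true-weight score for a clean comparison
x = pheno.data.bmi.to_numpy()
y = pheno.data.latent_wellbeing.to_numpy()

ols = observational_fit(x, y)
iv = tsls_fit(g, x, y)
print(f"truth: {truth.beta_linear} per BMI SD")
print(f"observational: {ols.beta:.3f} (95% CI {ols.ci[0]:.3f}, {ols.ci[1]:.3f})")
print(f"TSLS:          {iv.beta:.3f} (95% CI {iv.ci[0]:.3f}, {iv.ci[1]:.3f})")

# per-sex estimates pooled with inverse-variance weights
per_sex = []
for sex in ("male", "female"):
    m = (pheno.data.sex == sex).to_numpy()
    per_sex.append(tsls_fit(g[m], x[m], y[m], labels=dict(sex=sex)))
meta = meta_fixed(per_sex)
print(f"meta over sexes: {meta.beta:.3f} +- {meta.se:.3f}, "
      f"Q = {meta.q:.2f}, I^2 = {meta.i2:.1f}%")
# The observational slope sits well above the truth (confounding), the TSLS
# CI covers 0.3, and I^2 near zero reflects the designed homogeneity.
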