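"""Build a block jack-knifed genetic risk score and check instrument strength.

Variants are MAF-filtered, oriented to the trait-increasing allele using
per-sex regressions of rank-inverse-normal-transformed BMI, and weighted by
leave-one-block-out regressions so nobody's phenotype informs their own
score. Related individuals receive full-unrelated-sample weights.
"""

from mrwell import (
    SimConfig,
    align_effect_alleles,
    compute_grs,
    instrument_strength,
    jackknife_weights,
    maf_filter,
    simulate_cohort,
)

geno, pheno, truth = simulate_cohort(SimConfig(n_individuals=15_000, seed=2))

geno = maf_filter(geno, threshold=0.01)
oriented, _ = align_effect_alleles(geno, pheno)
weights = jackknife_weights(oriented, pheno, n_blocks=50, seed=2)
grs = compute_grs(oriented, weights, pheno)

print(f"{grs.n_variants} variants scored, weights: {grs.provenance}")
print(f"flipped variants: {int(oriented.oriented.sum())} "
      "(none expected: all simulated effects are trait-increasing)")
for sex, d in instrument_strength(grs, pheno).items():
    print(f"{sex}: GRS explains {d.r_squared:.2%} of BMI variance "
          f"(F = {d.f_statistic:.1f}, n = {d.n})")
# An F comfortably above 10 in each sex means the score is a usable
# instrument; the variance explained is in the 1-3% range typical of
# BMI risk scores in large cohorts.
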