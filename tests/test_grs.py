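"""Genetic risk scores: RINT, allele orientation, weights, jack-knife,
the score identity, and instrument strength."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrwell.geno_io import GenotypeMatrix, PhenotypeTable, VariantWeightSet
from mrwell.grs import (
    DegeneracyError,
    EmptyInstrumentError,
    align_effect_alleles,
    compute_grs,
    estimate_weights,
    instrument_strength,
    jackknife_weights,
    maf_filter,
    rint,
)


class TestRint:
    def test_blom_offsets_three_values(self):
        out = rint([5.0, 1.0, 9.0])
        np.testing.assert_allclose(out, [0.0, -0.869, 0.869], atol=5e-4)

    def test_rank_preserving(self, rng):
        x = rng.standard_normal(50)
        order = np.argsort(x)
        assert (np.diff(rint(x)[order]) > 0).all()

    def test_ties_get_equal_values(self):
        out = rint([3.0, 3.0, 7.0, 9.0])
        assert out[0] == out[1]

    def test_missing_propagates(self):
        out = rint([1.0, np.nan, 2.0])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    def test_constant_input_rejected(self):
        with pytest.raises(DegeneracyError):
            rint([2.0, 2.0, 2.0])


def _mk_geno(dosages):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(n)],
        variant_ids=[f"v{k}" for k in range(m)],
        dosages=dosages,
        effect_allele=["A"] * m,
        other_allele=["G"] * m,
    )


def _mk_pheno(geno, bmi, sex=None, **cols):
    n = geno.n_individuals
    df = pd.DataFrame(
        {
            "individual_id": geno.individual_ids,
            "sex": sex if sex is not None else ["male", "female"] * (n // 2),
            "bmi": bmi,
        }
    )
    for k, v in cols.items():
        df[k] = v
    return PhenotypeTable(df)


class TestAlignEffectAlleles:
    def _sexed_cohort(self, slope_male, slope_female, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        sex = np.where(np.arange(n) % 2 == 0, "male", "female")
        slope = np.where(sex == "male", slope_male, slope_female)
        bmi = 24 + slope * d[:, 0] + rng.normal(0, 0.5, n)
        geno = _mk_geno(d)
        return geno, _mk_pheno(geno, bmi, sex=list(sex))

    def test_negative_both_sexes_flips(self):
        geno, pheno = self._sexed_cohort(-0.5, -0.5)
        oriented, wset = align_effect_alleles(geno, pheno)
        np.testing.assert_array_equal(oriented.dosages[:, 0], 2 - geno.dosages[:, 0])
        assert oriented.effect_allele[0] == "G"  # alleles swapped
        assert wset.weights["male"][0] > 0 and wset.weights["female"][0] > 0

    def test_sign_conflict_resolved_by_larger_effect(self):
        # male effect -0.2, female +0.5: the female orientation wins, so
        # dosages stay unflipped and the recorded male effect stays negative
        geno, pheno = self._sexed_cohort(-0.2, 0.5)
        oriented, wset = align_effect_alleles(geno, pheno)
        np.testing.assert_array_equal(oriented.dosages, geno.dosages)
        assert wset.weights["female"][0] > 0
        assert wset.weights["male"][0] < 0

    def test_no_flips_when_truth_positive(self, small_cohort):
        geno, pheno, truth = small_cohort
        assert (truth.beta_g > 0).all()
        oriented, _ = align_effect_alleles(geno, pheno)
        assert not oriented.oriented.any()

    def test_single_sex_rejected(self):
        geno, pheno = self._sexed_cohort(0.3, 0.3)
        pheno.data["sex"] = "male"
        with pytest.raises(DegeneracyError):
            align_effect_alleles(geno, pheno)


class TestMafFilter:
    def _with_maf(self, mafs, multiallelic=None):
        # column j holds 2s in the first round(200*maf) rows: p = maf exactly
        n = 100
        cols = []
        for maf in mafs:
            c = np.zeros(n)
            c[: int(round(n * maf))] = 2.0
            cols.append(c)
        g = _mk_geno(np.column_stack(cols))
        if multiallelic is not None:
            g.multiallelic = np.asarray(multiallelic)
        return g

    def test_below_threshold_removed(self):
        g = self._with_maf([0.005, 0.2])
        kept = maf_filter(g)
        assert kept.variant_ids == ["v1"]

    def test_boundary_maf_retained(self):
        g = self._with_maf([0.01, 0.2])
        assert maf_filter(g).n_variants == 2

    def test_multiallelic_removed(self):
        g = self._with_maf([0.2, 0.2, 0.2], multiallelic=[False, True, False])
        assert maf_filter(g).n_variants == 2

    def test_all_removed_raises(self):
        g = self._with_maf([0.005])
        with pytest.raises(EmptyInstrumentError):
            maf_filter(g)


def _weightset(geno, w):
    return VariantWeightSet(
        variant_ids=list(geno.variant_ids),
        effect_allele=list(geno.effect_allele),
        other_allele=list(geno.other_allele),
        weights={"male": np.asarray(w, dtype=float)},
        source="external",
    )


class TestComputeGrs:
    def test_single_variant_direct(self):
        g = _mk_geno([[2.0]])
        res = compute_grs(g, _weightset(g, [1.0]))
        assert res.grs_w[0] == 2.0
        assert res.grs_s[0] == 2.0

    def test_two_variant_hand_arithmetic(self):
        g = _mk_geno([[1.0, 2.0]])
        res = compute_grs(g, _weightset(g, [0.5, 0.5]))
        assert res.grs_w[0] == pytest.approx(1.5)
        assert res.grs_s[0] == pytest.approx(3.0)  # 2 * 1.5 / 1.0

    def test_uniform_dosage_weight_free(self, rng):
        m = 5
        w = rng.uniform(0.1, 1.0, m)
        for d in (0.0, 1.0, 2.0):
            g = _mk_geno(np.full((1, m), d))
            res = compute_grs(g, _weightset(g, w))
            assert res.grs_s[0] == pytest.approx(m * d)

    def test_zero_weight_sum_rejected(self):
        g = _mk_geno([[1.0, 1.0]])
        with pytest.raises(ZeroDivisionError):
            compute_grs(g, _weightset(g, [0.5, -0.5]))

    @given(
        st.integers(2, 6),
        st.integers(1, 5),
        st.integers(0, 2**31 - 1),
    )
    def test_standardisation_identity(self, m, n, seed):
        # GRS_s * sum(beta) == n_variants * GRS_w for every individual
        r = np.random.default_rng(seed)
        g = _mk_geno(r.integers(0, 3, size=(n, m)).astype(float))
        w = r.uniform(0.05, 1.0, m)
        res = compute_grs(g, _weightset(g, w))
        np.testing.assert_allclose(res.grs_s * w.sum(), m * res.grs_w, rtol=1e-12)

    def test_allele_flip_shifts_score_by_constant(self, rng):
        m, n = 4, 30
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        w = rng.uniform(0.1, 0.5, m)
        g = _mk_geno(d)
        base = compute_grs(g, _weightset(g, w)).grs_w
        d2 = d.copy()
        d2[:, 0] = 2 - d2[:, 0]
        w2 = w.copy()
        w2[0] = -w2[0]
        flipped = compute_grs(_mk_geno(d2), _weightset(_mk_geno(d2), w2)).grs_w
        np.testing.assert_allclose(flipped - base, -2 * w[0], atol=1e-12)


class TestEstimateWeights:
    def test_single_variant_reduces_to_simple_slope(self, rng):
        n = 400
        d = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        bmi = 25 + 0.4 * d[:, 0] + rng.normal(0, 1, n)
        geno = _mk_geno(d)
        pheno = _mk_pheno(geno, bmi)
        w = estimate_weights(geno, pheno, n_pcs=0, sex="male")
        mask = pheno.data["sex"] == "male"
        slope = np.polyfit(d[mask, 0], bmi[mask], 1)[0]
        assert w[0] == pytest.approx(slope, rel=1e-10)

    def test_recovers_generative_effects(self, small_cohort):
        geno, pheno, truth = small_cohort
        # weights act on the raw BMI scale: exposure_scale * beta_g
        expected = 3.5 * truth.beta_g
        w = estimate_weights(geno, pheno, n_pcs=3, sex="female")
        D = geno.dosages
        resid_var = np.var(pheno.data["bmi"])
        se_approx = np.sqrt(resid_var / (len(pheno.data) * 2 * 0.05 * 0.95))
        np.testing.assert_allclose(w, expected, atol=3 * se_approx)

    def test_orthogonal_pcs_leave_weights_unchanged(self, small_cohort):
        geno, pheno, _ = small_cohort
        w0 = estimate_weights(geno, pheno, n_pcs=0, sex="male")
        w3 = estimate_weights(geno, pheno, n_pcs=3, sex="male")
        np.testing.assert_allclose(w0, w3, atol=0.02)

    def test_too_many_pcs_rejected(self, small_cohort):
        geno, pheno, _ = small_cohort
        with pytest.raises(ValueError, match="pc"):
            estimate_weights(geno, pheno, n_pcs=50, sex="male")


@pytest.fixture(scope="module")
def jk(small_cohort):
    geno, pheno, _ = small_cohort
    return jackknife_weights(geno, pheno, n_blocks=5, seed=1, n_pcs=3)


class TestJackknife:

    def test_leave_block_out_by_reconstruction(self, small_cohort, jk):
        # re-estimating weights with block 2's members excluded reproduces
        # the stored row exactly
        geno, pheno, _ = small_cohort
        members = [i for i, iid in enumerate(geno.individual_ids) if jk.block_of[iid] == 2]
        mask = np.ones(geno.n_individuals, dtype=bool)
        mask[members] = False
        w = estimate_weights(geno, pheno, n_pcs=3, sex="female", mask=mask)
        np.testing.assert_allclose(jk.weights["female"][2], w, rtol=1e-10)

    def test_own_phenotype_never_enters_own_weights(self, small_cohort, jk):
        # perturbing one unrelated individual's BMI must leave their own
        # assigned weight vector untouched
        geno, pheno, _ = small_cohort
        df = pheno.data.copy()
        target = df.index[(df["related"] == 0)][0]
        iid = df.loc[target, "individual_id"]
        sex = df.loc[target, "sex"]
        df.loc[target, "bmi"] += 10.0
        jk2 = jackknife_weights(
            geno, PhenotypeTable(df), n_blocks=5, seed=1, n_pcs=3
        )
        b = jk.block_of[iid]
        assert b == jk2.block_of[iid]
        np.testing.assert_allclose(
            jk.weights[sex][b], jk2.weights[sex][b], rtol=1e-10
        )

    def test_related_assigned_full_sample_row(self, small_cohort, jk):
        geno, pheno, _ = small_cohort
        related_ids = pheno.data.loc[pheno.data["related"] == 1, "individual_id"]
        for iid in related_ids.head(3):
            assert jk.block_of[iid] == -1
            np.testing.assert_array_equal(
                jk.weights_for("male", iid), jk.weights["male"][-1]
            )

    def test_two_blocks_agree_in_homogeneous_data(self, small_cohort):
        geno, pheno, _ = small_cohort
        jk2 = jackknife_weights(geno, pheno, n_blocks=2, seed=3, n_pcs=3)
        w0, w1 = jk2.weights["female"][0], jk2.weights["female"][1]
        # both halves estimate the same truth; agreement within 3 joint SEs
        se = np.sqrt(2) * 3.5 / np.sqrt(0.5 * 2000 * 2 * 0.05 * 0.95)
        np.testing.assert_allclose(w0, w1, atol=3 * se)

    def test_too_few_blocks_rejected(self, small_cohort):
        geno, pheno, _ = small_cohort
        with pytest.raises(ValueError):
            jackknife_weights(geno, pheno, n_blocks=1)


class TestInstrumentStrength:
    def test_f_r2_identity_one_regressor(self, small_cohort):
        geno, pheno, truth = small_cohort
        wset = _weightset(geno, truth.beta_g)
        wset.weights["female"] = wset.weights["male"]
        res = compute_grs(geno, wset, pheno)
        d = instrument_strength(res, pheno, sex="female")
        n, k = d.n, 1
        f_from_r2 = d.r_squared * (n - k - 1) / (1 - d.r_squared)
        assert d.f_statistic == pytest.approx(f_from_r2, rel=1e-9)

    def test_null_instrument_explains_nothing(self, small_cohort, rng):
        geno, pheno, _ = small_cohort
        from mrwell.grs import GRSResult

        noise = rng.standard_normal(geno.n_individuals)
        fake = GRSResult(
            individual_ids=list(geno.individual_ids),
            grs_w=noise,
            grs_s=noise,
            n_variants=0,
            provenance="null",
        )
        d = instrument_strength(fake, pheno, sex="male")
        assert d.r_squared < 0.005
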