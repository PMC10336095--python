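"""Genetic risk score construction and instrument diagnostics.

Implements the weighted score GRS_w = sum_i beta_i * d_i and its
standardised form GRS_s = n * GRS_w / sum_i beta_i, with the weighting
scheme used for one-sample MR in a cohort containing related individuals:

1. allele orientation — per sex, rank-inverse-normal-transformed (RINT) BMI
   is regressed jointly on all variants; each variant's dosage is flipped to
   count the trait-increasing allele, and when the sexes disagree on the
   sign the sex with the larger absolute effect decides;
2. block jack-knife weights — the unrelated subset is split into near-equal
   blocks; each block receives weights estimated with that block excluded,
   so no individual's phenotype informs their own score; related individuals
   receive weights estimated on the full unrelated subset;
3. instrument strength — incremental R^2 and F for adding the score to a
   covariate-only model of the exposure, per sex.

Variants that are multiallelic or have minor-allele frequency below 1% are
excluded before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .geno_io import GenotypeMatrix, PhenotypeTable, VariantWeightSet

__all__ = [
    "GRSResult",
    "InstrumentDiagnostics",
    "rint",
    "align_effect_alleles",
    "estimate_weights",
    "jackknife_weights",
    "maf_filter",
    "compute_grs",
    "instrument_strength",
]

log = logging.getLogger(__name__)


class EmptyInstrumentError(ValueError):
    """Every variant was filtered out."""


class DegeneracyError(ValueError):
    pass


@dataclass
class GRSResult:
    """Per-individual weighted and standardised genetic risk scores."""

    individual_ids: list[str]
    grs_w: np.ndarray
    grs_s: np.ndarray
    n_variants: int
    provenance: str  # "external" | "full-sample" | "jackknife"
    weight_sums: np.ndarray | None = None  # per-individual sum of beta_i


@dataclass
class InstrumentDiagnostics:
    r_squared: float
    f_statistic: float
    sex: str
    n: int


def rint(values) -> np.ndarray:
    """Rank-based inverse normal transform with Blom's offset.

    Transformed value = Phi^{-1}((rank - 3/8) / (n + 1/4)) with average
    ranks for ties; missing values propagate as NaN.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 2:
        raise DegeneracyError("need at least 2 non-missing values")
    if np.unique(x[ok]).size == 1:
        raise DegeneracyError("all values identical; RINT undefined")
    ranks = rankdata(x[ok], method="average")
    out[ok] = norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return out


def _ols_coefs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient joint regression; consider pruning collinear variants"
        )
    return coef


def _per_sex_variant_betas(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    response: np.ndarray,
    joint: bool = True,
) -> dict[str, np.ndarray]:
    """Regress *response* on all variants, separately in each sex."""
    df = pheno.aligned_to(geno).data
    betas: dict[str, np.ndarray] = {}
    for sex in ("male", "female"):
        mask = (df["sex"] == sex).to_numpy() & ~np.isnan(response)
        if mask.sum() < geno.n_variants + 2:
            raise DegeneracyError(f"too few {sex} individuals for joint regression")
        D = geno.dosages[mask]
        y = response[mask]
        if joint:
            X = np.column_stack([np.ones(mask.sum()), D])
            betas[sex] = _ols_coefs(X, y)[1:]
        else:
            b = np.empty(geno.n_variants)
            for j in range(geno.n_variants):
                X = np.column_stack([np.ones(mask.sum()), D[:, j]])
                b[j] = _ols_coefs(X, y)[1]
            betas[sex] = b
    return betas


def align_effect_alleles(
    geno: GenotypeMatrix, pheno: PhenotypeTable, joint: bool = True
) -> tuple[GenotypeMatrix, VariantWeightSet]:
    """Orient every variant's dosage to count the trait-increasing allele.

    Per sex, RINT-transformed BMI is regressed on all variants (jointly by
    default). A variant whose estimated effect is negative in both sexes is
    flipped (d -> 2 - d, alleles swapped); when the sexes disagree in sign,
    the orientation follows the sex with the larger absolute effect.
    Returns the oriented matrix and the per-sex effects on the oriented
    allele.
    """
    df = pheno.aligned_to(geno).data
    sexes = set(df["sex"].dropna())
    if sexes != {"male", "female"}:
        raise DegeneracyError("both sexes must be present for allele alignment")
    rint_bmi = rint(df["bmi"].to_numpy(dtype=float))
    betas = _per_sex_variant_betas(geno, pheno, rint_bmi, joint=joint)
    bm, bf = betas["male"], betas["female"]
    # sign of the deciding sex: agreement keeps the common sign, otherwise
    # the larger |effect| wins
    deciding = np.where(np.abs(bf) >= np.abs(bm), np.sign(bf), np.sign(bm))
    agree = np.sign(bm) == np.sign(bf)
    orient_sign = np.where(agree, np.sign(bm), deciding)
    orient_sign[orient_sign == 0] = 1.0
    flip = orient_sign < 0

    dosages = geno.dosages.copy()
    dosages[:, flip] = 2.0 - dosages[:, flip]
    effect = [
        geno.other_allele[j] if flip[j] else geno.effect_allele[j]
        for j in range(geno.n_variants)
    ]
    other = [
        geno.effect_allele[j] if flip[j] else geno.other_allele[j]
        for j in range(geno.n_variants)
    ]
    oriented = GenotypeMatrix(
        individual_ids=list(geno.individual_ids),
        variant_ids=list(geno.variant_ids),
        dosages=dosages,
        effect_allele=effect,
        other_allele=other,
        multiallelic=geno.multiallelic.copy(),
        oriented=flip.copy(),
    )
    weights = VariantWeightSet(
        variant_ids=list(geno.variant_ids),
        effect_allele=effect,
        other_allele=other,
        weights={"male": bm * orient_sign, "female": bf * orient_sign},
        source="alignment-rint",
    )
    return oriented, weights


def estimate_weights(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    n_pcs: int = 12,
    sex: str | None = None,
    joint: bool = True,
    mask: np.ndarray | None = None,
) -> np.ndarray | dict[str, np.ndarray]:
    """Estimate variant weights by regressing BMI on all oriented variants.

    The regression is joint over variants with *n_pcs* principal components
    as covariates, fitted on the unrelated subset. With ``sex=None`` a dict
    of per-sex weight vectors is returned.
    """
    if sex is None:
        return {
            s: estimate_weights(geno, pheno, n_pcs, s, joint, mask)
            for s in ("male", "female")
        }
    df = pheno.aligned_to(geno).data
    pc_cols = [f"pc{j + 1}" for j in range(n_pcs)]
    missing = [c for c in pc_cols if c not in df.columns]
    if missing:
        raise ValueError(f"requested {n_pcs} PCs but columns missing: {missing}")
    sel = (df["sex"] == sex).to_numpy()
    if "related" in df.columns:
        sel &= df["related"].to_numpy() == 0
    if mask is not None:
        sel &= mask
    D = geno.dosages[sel]
    y = df.loc[sel, "bmi"].to_numpy(dtype=float)
    C = df.loc[sel, pc_cols].to_numpy(dtype=float)
    if joint:
        X = np.column_stack([np.ones(sel.sum()), D, C])
        return _ols_coefs(X, y)[1 : 1 + geno.n_variants]
    b = np.empty(geno.n_variants)
    for j in range(geno.n_variants):
        X = np.column_stack([np.ones(sel.sum()), D[:, j], C])
        b[j] = _ols_coefs(X, y)[1]
    return b


def jackknife_weights(
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    n_blocks: int = 100,
    seed: int = 0,
    n_pcs: int = 12,
    joint: bool = True,
) -> VariantWeightSet:
    """Block jack-knife weight estimation on the unrelated subset.

    Unrelated individuals are partitioned into *n_blocks* near-equal blocks
    by a seeded shuffle. For each block, per-sex weights are estimated on
    all unrelated individuals outside the block and assigned to the block's
    members, so nobody's phenotype enters their own weights. Related
    individuals are assigned the weights estimated on the whole unrelated
    subset.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    df = pheno.aligned_to(geno).data
    unrelated = df["related"].to_numpy() == 0 if "related" in df.columns else np.ones(
        len(df), dtype=bool
    )
    n_unrel = int(unrelated.sum())
    if n_unrel < 2 * n_blocks:
        raise ValueError(f"unrelated n={n_unrel} too small for {n_blocks} blocks")

    rng = np.random.default_rng(seed)
    unrel_idx = np.flatnonzero(unrelated)
    perm = rng.permutation(unrel_idx)
    blocks = np.array_split(perm, n_blocks)

    weight_rows = {s: np.empty((n_blocks + 1, geno.n_variants)) for s in ("male", "female")}
    for b, block in enumerate(blocks):
        mask = np.ones(len(df), dtype=bool)
        mask[block] = False
        w = estimate_weights(geno, pheno, n_pcs=n_pcs, joint=joint, mask=mask)
        for s in ("male", "female"):
            weight_rows[s][b] = w[s]
    w_full = estimate_weights(geno, pheno, n_pcs=n_pcs, joint=joint)
    for s in ("male", "female"):
        weight_rows[s][n_blocks] = w_full[s]

    block_of = {i: -1 for i in geno.individual_ids}
    for b, block in enumerate(blocks):
        for i in block:
            block_of[geno.individual_ids[i]] = b

    return VariantWeightSet(
        variant_ids=list(geno.variant_ids),
        effect_allele=list(geno.effect_allele),
        other_allele=list(geno.other_allele),
        weights=weight_rows,
        source="jackknife",
        block_of=block_of,
        n_blocks=n_blocks,
    )


def maf_filter(geno: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Drop multiallelic variants and those with MAF strictly below *threshold*."""
    keep = (geno.maf >= threshold) & ~geno.multiallelic
    dropped = [v for v, k in zip(geno.variant_ids, keep) if not k]
    if dropped:
        log.info("maf_filter removed %d variant(s): %s", len(dropped), dropped)
    if not keep.any():
        raise EmptyInstrumentError("all variants removed by MAF/multiallelic filter")
    return geno.subset_variants(keep)


def compute_grs(
    geno: GenotypeMatrix, weights: VariantWeightSet, pheno: PhenotypeTable | None = None
) -> GRSResult:
    """Score every individual: GRS_w = sum beta_i d_i, GRS_s = n GRS_w / sum beta_i.

    With jack-knifed (per-sex, per-block) weights, each individual is scored
    with the weight vector assigned to their sex and block; *pheno* supplies
    the sex labels and is required in that case.
    """
    if list(weights.variant_ids) != list(geno.variant_ids):
        raise ValueError("weight set does not cover the genotype matrix's variants")
    m = geno.n_variants
    per_sex = any(np.asarray(w).ndim > 1 for w in weights.weights.values()) or len(
        weights.weights
    ) > 1
    if per_sex and pheno is None:
        raise ValueError("per-sex weights require a phenotype table for sex labels")

    grs_w = np.empty(geno.n_individuals)
    wsum = np.empty(geno.n_individuals)
    if pheno is not None:
        sex = pheno.aligned_to(geno).data["sex"].to_numpy()
    else:
        sex = np.array([next(iter(weights.weights))] * geno.n_individuals)
    for i, iid in enumerate(geno.individual_ids):
        w = weights.weights_for(sex[i], iid)
        grs_w[i] = geno.dosages[i] @ w
        wsum[i] = w.sum()
    if np.any(wsum == 0):
        raise ZeroDivisionError("sum of weights is zero; standardised GRS undefined")
    grs_s = m * grs_w / wsum
    return GRSResult(
        individual_ids=list(geno.individual_ids),
        grs_w=grs_w,
        grs_s=grs_s,
        n_variants=m,
        provenance=weights.source,
        weight_sums=wsum,
    )


def instrument_strength(
    grs: GRSResult,
    pheno: PhenotypeTable,
    covariates: list[str] | None = None,
    sex: str | None = None,
    exposure: str = "bmi",
) -> InstrumentDiagnostics | dict[str, InstrumentDiagnostics]:
    """Incremental R^2 and F for adding the standardised score to a covariate
    model of the exposure.

    For a single added regressor the two are linked by
    F = dR^2 (n - k - 1) / (1 - R^2_full)."""
    if sex is None:
        return {
            s: instrument_strength(grs, pheno, covariates, s, exposure)
            for s in ("male", "female")
        }
    covariates = covariates or []
    df = pheno.data.set_index("individual_id").loc[grs.individual_ids]
    mask = (df["sex"] == sex).to_numpy()
    y = df.loc[mask, exposure].to_numpy(dtype=float)
    C = df.loc[mask, covariates].to_numpy(dtype=float) if covariates else np.empty(
        (mask.sum(), 0)
    )
    g = grs.grs_s[mask]
    n = int(mask.sum())
    ones = np.ones(n)
    X0 = np.column_stack([ones, C])
    X1 = np.column_stack([ones, C, g])
    if n <= X1.shape[1] + 1:
        raise DegeneracyError("too few individuals for instrument diagnostics")
    rss0 = _rss(X0, y)
    rss1 = _rss(X1, y)
    tss = ((y - y.mean()) ** 2).sum()
    r2 = (rss0 - rss1) / tss
    k = X1.shape[1] - 1  # slopes counted, not intercept
    f = (rss0 - rss1) / (rss1 / (n - k - 1))
    return InstrumentDiagnostics(r_squared=float(r2), f_statistic=float(f), sex=sex, n=n)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)
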