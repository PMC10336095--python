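"""End-to-end study orchestration.

Drives the full design from a single configuration: allele orientation and
jack-knife weighting, genetic-risk-score construction, observational and
TSLS fits per (sex x recruitment region) stratum, fixed-effects
meta-analysis to all/urban/rural/sex summaries with I^2, fractional
polynomial screening, control-function non-linear MR, sensitivity region
exclusions, and cross-cohort Fisher z comparisons.

Two cohort styles are supported: ``region-stratified-meta`` (fit each sex x
region stratum with region-specific covariates, then meta-analyse — the
design used for a multi-region cohort with related individuals) and
``joint`` (single fits over all/sex/urban/rural subsets with external or
full-sample weights — the design used for a single-centre cohort).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .geno_io import GenotypeMatrix, PhenotypeTable, VariantWeightSet
from .grs import (
    GRSResult,
    align_effect_alleles,
    compute_grs,
    instrument_strength,
    jackknife_weights,
    maf_filter,
)
from .mr_core import (
    DiffTest,
    MetaResult,
    StratumEstimate,
    fisher_z_diff,
    meta_fixed,
    observational_fit,
    tsls_fit,
)
from .nonlinear import CFResult, FPModel, compare_nonlinear, control_function, fp1_search, fp2_search, fit_quadratic

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "exclude_regions",
    "compare_cohorts",
    "prevalence_screen",
    "estimate_from_printed",
]

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Configuration of one cohort analysis."""

    style: str = "region-stratified-meta"  # or "joint"
    cohort: str = "synthetic"
    outcomes: tuple[str, ...] = ("wellbeing",)
    exposure: str = "bmi"
    n_pcs: int = 12
    covariates: tuple[str, ...] = ("age",)  # PCs appended automatically
    region_exclusions: tuple[str, ...] = ()
    min_stratum_n: int = 50
    maf_threshold: float = 0.01
    n_blocks: int = 100
    weights: str = "jackknife"  # "jackknife" | "full" | "external"
    run_observational: bool = True
    run_tsls: bool = True
    run_fp: bool = False
    run_cf: bool = False
    cf_bootstrap: int = 500
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """Everything one `run_study` call produced, with provenance."""

    estimates: list[StratumEstimate] = field(default_factory=list)
    metas: list[MetaResult] = field(default_factory=list)
    fp_models: list[FPModel] = field(default_factory=list)
    cf_results: list[CFResult] = field(default_factory=list)
    instrument: dict = field(default_factory=dict)
    skipped_strata: list[str] = field(default_factory=list)
    prevalence_flags: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def genetic_estimate(self, sex: str = "all", region: str = "all", outcome: str | None = None):
        """The TSLS (meta or direct) estimate for a stratum summary."""
        for m in self.metas:
            if m.model == "tsls" and m.sex == sex and m.region == region and (
                outcome is None or m.outcome == outcome
            ):
                return m
        for e in self.estimates:
            if e.model == "tsls" and e.sex == sex and e.region == region and (
                outcome is None or e.outcome == outcome
            ):
                return e
        raise KeyError(f"no genetic estimate for sex={sex!r}, region={region!r}")

    def cf_result(self, label_contains: str = "") -> CFResult:
        for r in self.cf_results:
            if label_contains in r.label:
                return r
        raise KeyError(f"no control-function result matching {label_contains!r}")


def exclude_regions(pheno: PhenotypeTable, regions) -> PhenotypeTable:
    """Drop all individuals from the named recruitment regions."""
    regions = list(regions)
    present = set(pheno.data["region"])
    missing = sorted(set(regions) - present)
    if missing:
        raise KeyError(f"region label(s) not present: {missing}")
    keep = ~pheno.data["region"].isin(regions)
    if not keep.any():
        raise ValueError("excluding these regions empties the cohort")
    dropped = int((~keep).sum())
    log.info("excluded %d individual(s) from regions %s", dropped, regions)
    return PhenotypeTable(pheno.data.loc[keep].reset_index(drop=True))


def prevalence_screen(
    pheno: PhenotypeTable, outcome: str, threshold: float = 0.01
) -> dict[str, bool]:
    """Flag regions where any outcome category's prevalence is below *threshold*.

    Flags are advisory (for reviewer attention); nothing is auto-excluded.
    """
    flags: dict[str, bool] = {}
    df = pheno.data
    categories = sorted(df[outcome].dropna().unique())
    for region, sub in df.groupby("region"):
        vals = sub[outcome].dropna()
        props = vals.value_counts(normalize=True).reindex(categories, fill_value=0.0)
        flags[str(region)] = bool((props < threshold).any()) if threshold > 0 else False
    return flags


def _covariate_matrix(df: pd.DataFrame, config: StudyConfig, drop_sex: bool) -> np.ndarray:
    cols = [c for c in config.covariates if not (drop_sex and c == "sex")]
    blocks = []
    for c in cols:
        if c == "sex":
            blocks.append((df["sex"] == "female").to_numpy(dtype=float))
        else:
            blocks.append(df[c].to_numpy(dtype=float))
    for j in range(config.n_pcs):
        col = f"pc{j + 1}"
        if col in df.columns:
            blocks.append(df[col].to_numpy(dtype=float))
    if not blocks:
        return np.empty((len(df), 0))
    return np.column_stack(blocks)


def _prepare_instrument(
    config: StudyConfig,
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    external_weights: VariantWeightSet | None,
) -> tuple[GRSResult, GenotypeMatrix]:
    geno = maf_filter(geno, config.maf_threshold)
    if config.weights == "external":
        if external_weights is None:
            raise ValueError("weights='external' requires an external VariantWeightSet")
        return compute_grs(geno, external_weights, pheno), geno
    oriented, _ = align_effect_alleles(geno, pheno)
    if config.weights == "jackknife":
        wset = jackknife_weights(
            oriented, pheno, n_blocks=config.n_blocks, seed=config.seed, n_pcs=config.n_pcs
        )
    else:  # full-sample weights
        from .grs import estimate_weights

        w = estimate_weights(oriented, pheno, n_pcs=config.n_pcs)
        wset = VariantWeightSet(
            variant_ids=list(oriented.variant_ids),
            effect_allele=list(oriented.effect_allele),
            other_allele=list(oriented.other_allele),
            weights=w,
            source="full-sample",
        )
    return compute_grs(oriented, wset, pheno), oriented


def run_study(
    config: StudyConfig,
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    external_weights: VariantWeightSet | None = None,
) -> StudyReport:
    """Run the configured analysis end to end and return a full report."""
    report = StudyReport()
    if config.region_exclusions:
        pheno = exclude_regions(pheno, config.region_exclusions)
        keep = np.isin(geno.individual_ids, pheno.data["individual_id"].to_numpy())
        geno = geno.subset_individuals(keep)

    grs, geno = _prepare_instrument(config, geno, pheno, external_weights)
    df = pheno.aligned_to(geno).data
    pc_cols = [f"pc{j+1}" for j in range(config.n_pcs) if f"pc{j+1}" in df.columns]
    report.instrument = {
        s: d.__dict__
        for s, d in instrument_strength(grs, pheno, covariates=pc_cols or None).items()
    }

    for outcome in config.outcomes:
        report.prevalence_flags[outcome] = prevalence_screen(pheno, outcome)
        if config.style == "region-stratified-meta":
            _run_stratified(config, report, df, grs, outcome)
        elif config.style == "joint":
            _run_joint(config, report, df, grs, outcome)
        else:
            raise ValueError(f"unknown cohort style {config.style!r}")
        if config.run_fp or config.run_cf:
            _run_nonlinear(config, report, df, grs, outcome)

    report.provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "n_individuals": len(df),
        "n_variants": grs.n_variants,
        "weights": grs.provenance,
    }
    return report


def _fit_stratum(config, df, grs, outcome, mask, sex_label, region_label, drop_sex):
    sub = df.loc[mask]
    C = _covariate_matrix(sub, config, drop_sex=drop_sex)
    x = sub[config.exposure].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    g = grs.grs_s[mask.to_numpy() if hasattr(mask, "to_numpy") else mask]
    labels = dict(sex=sex_label, region=region_label, cohort=config.cohort, outcome=outcome)
    out = []
    if config.run_observational:
        out.append(observational_fit(x, y, C, labels=labels))
    if config.run_tsls:
        out.append(tsls_fit(g, x, y, C, labels=labels))
    return out


def _run_stratified(config, report, df, grs, outcome):
    """Per (sex x region) fits, then fixed-effects meta to summaries."""
    stratum_estimates: list[StratumEstimate] = []
    regions = sorted(df["region"].unique())
    for sex in ("male", "female"):
        for region in regions:
            mask = (df["sex"] == sex) & (df["region"] == region)
            if int(mask.sum()) < config.min_stratum_n:
                report.skipped_strata.append(f"{outcome}:{sex}:{region}")
                log.warning("skipping stratum %s/%s (n=%d)", sex, region, mask.sum())
                continue
            ests = _fit_stratum(config, df, grs, outcome, mask, sex, region, drop_sex=True)
            stratum_estimates.extend(ests)
    report.estimates.extend(stratum_estimates)

    urban_of = df.drop_duplicates("region").set_index("region")["urban"].to_dict()
    groups = {
        "all": lambda r: True,
        "urban": lambda r: bool(urban_of.get(r, 0)),
        "rural": lambda r: not bool(urban_of.get(r, 0)),
    }
    for model in ("observational", "tsls"):
        pool = [e for e in stratum_estimates if e.model == model]
        if not pool:
            continue
        for sex in ("all", "male", "female"):
            for gname, member in groups.items():
                sel = [
                    e
                    for e in pool
                    if (sex == "all" or e.sex == sex) and member(e.region)
                ]
                if not sel:
                    continue
                meta = meta_fixed(sel)
                meta.sex, meta.region, meta.model = sex, gname, model
                report.metas.append(meta)


def _run_joint(config, report, df, grs, outcome):
    """Direct fits over all/sex/urban/rural subsets (no meta-analysis)."""
    subsets = {
        ("all", "all"): np.ones(len(df), dtype=bool),
        ("male", "all"): (df["sex"] == "male").to_numpy(),
        ("female", "all"): (df["sex"] == "female").to_numpy(),
        ("all", "urban"): df["urban"].to_numpy(dtype=bool),
        ("all", "rural"): ~df["urban"].to_numpy(dtype=bool),
    }
    for (sex, region), mask in subsets.items():
        if int(mask.sum()) < config.min_stratum_n:
            report.skipped_strata.append(f"{outcome}:{sex}:{region}")
            continue
        ests = _fit_stratum(
            config, df, grs, outcome, mask, sex, region, drop_sex=(sex != "all")
        )
        report.estimates.extend(ests)


def _run_nonlinear(config, report, df, grs, outcome):
    x = df[config.exposure].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    C = _covariate_matrix(df, config, drop_sex=False)
    if config.run_fp:
        quad = fit_quadratic(x, y, C, label=f"{outcome}:quadratic")
        fp1 = fp1_search(x, y, C)
        fp2 = fp2_search(x, y, C)
        fp1.label, fp2.label = f"{outcome}:FP1", f"{outcome}:FP2"
        report.fp_models.extend([quad, fp1, fp2])
    if config.run_cf:
        cf = control_function(
            grs,
            x,
            y,
            C,
            n_bootstrap=config.cf_bootstrap,
            seed=config.seed,
            label=f"{outcome}:all",
        )
        report.cf_results.append(cf)


def compare_cohorts(
    report_a: StudyReport,
    report_b: StudyReport,
    strata: list[tuple[str, str]] | None = None,
    outcome: str | None = None,
) -> list[DiffTest]:
    """Stratum-wise Fisher z tests between two cohorts' genetic estimates.

    Linear TSLS (or meta) estimates are compared per stratum; when both
    reports carry control-function results, the quadratic coefficients are
    compared too. Strata missing on either side are skipped with a warning.
    """
    strata = strata or [("all", "all"), ("male", "all"), ("female", "all"),
                        ("all", "urban"), ("all", "rural")]
    tests: list[DiffTest] = []
    for sex, region in strata:
        try:
            ea = report_a.genetic_estimate(sex, region, outcome)
            eb = report_b.genetic_estimate(sex, region, outcome)
        except KeyError:
            log.warning("stratum (%s, %s) missing on one side; skipped", sex, region)
            continue
        tests.append(fisher_z_diff(ea, eb, label=f"linear:{sex}:{region}"))
    for ca in report_a.cf_results:
        for cb in report_b.cf_results:
            if ca.label.split(":", 1)[-1] == cb.label.split(":", 1)[-1]:
                t = compare_nonlinear(ca, cb, label=f"quadratic:{ca.label}")
                tests.append(t)
    return tests


def estimate_from_printed(
    beta: float, ci_lower: float, ci_upper: float, **labels
) -> StratumEstimate:
    """Build a StratumEstimate from a published beta and 95% CI.

    Lets cross-cohort comparisons run on printed summary values alone,
    without individual-level data.
    """
    from .mr_core import ci_to_se

    return StratumEstimate(
        beta=beta, se=ci_to_se(ci_lower, ci_upper), n=0, model="tsls", **labels
    )
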