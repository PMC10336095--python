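"""File formats, schema validation, and outcome recoding.

The pipeline exchanges four kinds of files, all plain text:

* dosage TSV — individuals in rows (joinable on individual id), variants in
  columns, entries in [0, 2]; or a dosage-bearing VCF,
* phenotype TSV — one row per individual with sex, age, region, urban flag,
  principal components, BMI, ordinal outcomes and a relatedness flag;
  missing cells written as ``NA``,
* variant-weight TSV — per-variant effect allele and per-sex effect sizes,
* results TSV/JSON — one row per fitted estimate with beta, SE, 95% CI, P, n.

Outcome recoding maps questionnaire labels onto ordinal scales: the 4-level
health item (Poor..Excellent -> 0..3), the 4-level life-satisfaction item
with the two lowest categories merged, and the 6-level happiness item where
"Do not know" / "Prefer not to answer" become missing.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "VariantWeightSet",
    "SchemaError",
    "read_dosage_matrix",
    "read_phenotype_table",
    "recode_outcome",
    "write_results",
    "write_dosage_tsv",
    "ci_from_beta_se",
]

Z95 = 1.96  # normal 95% CI multiplier

RECODING_SCHEMES: dict[str, dict[str, float]] = {
    "health4": {"Poor": 0, "Fair": 1, "Good": 2, "Excellent": 3},
    "life4_merged": {
        "Very unsatisfied": 0,
        "Unsatisfied": 0,
        "Neither satisfied nor dissatisfied": 1,
        "Satisfied": 2,
        "Very satisfied": 3,
    },
    "happiness6": {
        "Extremely unhappy": 0,
        "Very unhappy": 1,
        "Moderately unhappy": 2,
        "Moderately happy": 3,
        "Very happy": 4,
        "Extremely happy": 5,
        "Do not know": math.nan,
        "Prefer not to answer": math.nan,
    },
}


class SchemaError(ValueError):
    """A file or table violates the expected schema."""


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with allele metadata.

    ``maf`` is computed from the dosages as min(p, 1-p) with
    p = mean(dosage)/2 unless supplied. ``oriented`` marks variants whose
    dosage has been flipped to count the trait-increasing allele.
    """

    individual_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    effect_allele: list[str]
    other_allele: list[str]
    multiallelic: np.ndarray | None = None
    maf: np.ndarray | None = None
    oriented: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.variant_ids):
            raise SchemaError("dosage matrix shape does not match id lists")
        if len(set(self.individual_ids)) != n:
            raise SchemaError("individual ids are not unique")
        if len(set(self.variant_ids)) != m:
            raise SchemaError("variant ids are not unique")
        bad = np.argwhere((self.dosages < 0) | (self.dosages > 2))
        if bad.size:
            i, j = bad[0]
            raise SchemaError(
                f"dosage out of [0, 2] at individual {self.individual_ids[i]!r}, "
                f"variant {self.variant_ids[j]!r}: {self.dosages[i, j]}"
            )
        if self.multiallelic is None:
            self.multiallelic = np.zeros(m, dtype=bool)
        if self.maf is None:
            p = self.dosages.mean(axis=0) / 2.0
            self.maf = np.minimum(p, 1.0 - p)
        if self.oriented is None:
            self.oriented = np.zeros(m, dtype=bool)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            variant_ids=[self.variant_ids[j] for j in idx],
            dosages=self.dosages[:, idx],
            effect_allele=[self.effect_allele[j] for j in idx],
            other_allele=[self.other_allele[j] for j in idx],
            multiallelic=self.multiallelic[idx],
            maf=self.maf[idx],
            oriented=self.oriented[idx],
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in idx],
            variant_ids=list(self.variant_ids),
            dosages=self.dosages[idx, :],
            effect_allele=list(self.effect_allele),
            other_allele=list(self.other_allele),
            multiallelic=self.multiallelic.copy(),
            maf=None,  # recompute within the subset
            oriented=self.oriented.copy(),
        )


@dataclass
class PhenotypeTable:
    """Per-individual phenotypes and covariates as a validated DataFrame."""

    data: pd.DataFrame

    REQUIRED = ("individual_id", "sex")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise SchemaError(f"phenotype table missing column {col!r}")
        if self.data["individual_id"].duplicated().any():
            raise SchemaError("duplicate individual ids in phenotype table")
        if "bmi" in self.data.columns:
            bmi = self.data["bmi"].dropna()
            if (bmi <= 0).any():
                raise SchemaError("BMI must be > 0 where present")
        bad_sex = set(self.data["sex"].dropna()) - {"male", "female"}
        if bad_sex:
            raise SchemaError(f"unknown sex labels: {sorted(bad_sex)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("pc") and c[2:].isdigit()]

    def aligned_to(self, geno: GenotypeMatrix) -> "PhenotypeTable":
        """Reorder rows to match the genotype matrix's individual order."""
        df = self.data.set_index("individual_id").loc[geno.individual_ids].reset_index()
        return PhenotypeTable(df)


@dataclass
class VariantWeightSet:
    """Per-variant, per-sex effect sizes on the oriented effect allele.

    ``weights[sex]`` holds either a single vector (full-sample or external
    weights) or an array of ``n_blocks + 1`` vectors where row ``b`` was
    estimated with block ``b`` left out and the final row on the whole
    unrelated sample (used for related individuals). ``block_of`` maps an
    individual id to their jack-knife block, or -1 when the individual uses
    the full-sample row.
    """

    variant_ids: list[str]
    effect_allele: list[str]
    other_allele: list[str]
    weights: dict[str, np.ndarray]
    source: str = "internal"
    block_of: dict[str, int] | None = None
    n_blocks: int = 0

    def __post_init__(self) -> None:
        for sex, w in self.weights.items():
            w = np.asarray(w, dtype=float)
            if not np.isfinite(w).all():
                raise SchemaError(f"non-finite weight for sex {sex!r}")
            self.weights[sex] = w

    def weights_for(self, sex: str, individual_id: str | None = None) -> np.ndarray:
        w = self.weights[sex]
        if w.ndim == 1:
            return w
        block = -1 if self.block_of is None else self.block_of.get(individual_id, -1)
        return w[block] if block >= 0 else w[-1]


# ---------------------------------------------------------------------------
# readers


def read_dosage_matrix(
    path: str | Path, format: str = "tsv", dosage_field: str = "DS", strict: bool = False
) -> GenotypeMatrix:
    """Read a dosage matrix from a TSV (individuals in rows) or a VCF.

    For VCF input the per-sample dosage is taken from *dosage_field*
    (conventionally ``DS``); if that field is absent and *strict* is off,
    genotype hard-calls are summed to a dosage. Records with more than one
    ALT allele are flagged multiallelic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return GenotypeMatrix(
            individual_ids=[str(i) for i in df.index],
            variant_ids=[str(c) for c in df.columns],
            dosages=df.to_numpy(dtype=float),
            effect_allele=["A"] * df.shape[1],
            other_allele=["G"] * df.shape[1],
        )
    if format == "vcf":
        return _read_vcf_dosages(path, dosage_field, strict)
    raise SchemaError(f"unknown dosage format {format!r}")


def _read_vcf_dosages(path: Path, dosage_field: str, strict: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids, effect, other, multi, columns = [], [], [], [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        alts = rec.ALT or []
        multi.append(len(alts) > 1)
        effect.append(alts[0] if alts else rec.REF)
        other.append(rec.REF)
        variant_ids.append(vid)
        ds = None
        try:
            ds = rec.format(dosage_field)
        except KeyError:
            ds = None
        if ds is not None:
            columns.append(np.asarray(ds, dtype=float).reshape(-1))
        elif strict:
            raise SchemaError(
                f"VCF record {vid} lacks dosage field {dosage_field!r} (strict mode)"
            )
        else:
            gt = np.asarray(rec.genotype.array())[:, :2]
            columns.append((gt > 0).sum(axis=1).astype(float))
    if not columns:
        raise SchemaError(f"no usable records in {path}")
    return GenotypeMatrix(
        individual_ids=samples,
        variant_ids=variant_ids,
        dosages=np.column_stack(columns),
        effect_allele=effect,
        other_allele=other,
        multiallelic=np.asarray(multi),
    )


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["individual_id"] = df["individual_id"].astype(str)
    return PhenotypeTable(df)


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path, precision: int = 6) -> None:
    df = pd.DataFrame(
        np.round(geno.dosages, precision),
        index=pd.Index(geno.individual_ids, name="individual_id"),
        columns=geno.variant_ids,
    )
    df.to_csv(path, sep="\t", float_format=f"%.{precision}f")


def write_phenotype_tsv(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.data.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# outcome recoding


def recode_outcome(raw, scheme: str) -> pd.Series:
    """Map questionnaire labels to an ordinal scale (NaN for missing).

    Schemes: ``health4`` (Poor=0 .. Excellent=3), ``life4_merged`` (Very
    unsatisfied merged with Unsatisfied=0 .. Very satisfied=3),
    ``happiness6`` (Extremely unhappy=0 .. Extremely happy=5 with
    "Do not know"/"Prefer not to answer" set to missing). Labels outside the
    scheme's vocabulary raise :class:`SchemaError`.
    """
    if scheme not in RECODING_SCHEMES:
        raise SchemaError(
            f"unknown scheme {scheme!r}; choose from {sorted(RECODING_SCHEMES)}"
        )
    mapping = RECODING_SCHEMES[scheme]
    raw = pd.Series(raw)
    unknown = sorted(set(raw.dropna()) - set(mapping))
    if unknown:
        raise SchemaError(f"labels not in scheme {scheme!r}: {unknown}")
    return raw.map(mapping).astype(float)


# ---------------------------------------------------------------------------
# results writing


def ci_from_beta_se(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    return beta - z * se, beta + z * se


def _estimate_row(est) -> dict:
    d = dataclasses.asdict(est) if dataclasses.is_dataclass(est) else dict(est)
    row = {"kind": type(est).__name__}
    for key, val in d.items():
        if isinstance(val, (str, int, float, bool)) or val is None:
            row[key] = val
        elif isinstance(val, np.ndarray) and val.size <= 8:
            row[key] = ";".join(f"{v:g}" for v in val.ravel())
    if "beta" in row and "se" in row and row.get("se") is not None:
        lo, hi = row["beta"] - Z95 * row["se"], row["beta"] + Z95 * row["se"]
        row["ci_lower"], row["ci_upper"] = lo, hi
    return row


def write_results(estimates, path: str | Path) -> pd.DataFrame:
    """Write a collection of fitted estimates as TSV plus a JSON mirror.

    Each row carries the stratum labels and model tag of one estimate with
    beta, SE, the 95% CI (beta +/- 1.96 SE), P and n where defined. An empty
    collection produces a header-only TSV.
    """
    path = Path(path)
    rows = [_estimate_row(e) for e in estimates]
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(
            columns=["kind", "beta", "se", "ci_lower", "ci_upper", "p", "n"]
        )
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(
            df.replace({np.nan: None}).to_dict(orient="records"), fh, indent=1
        )
    return df
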