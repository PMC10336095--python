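"""Observational and two-stage least-squares causal models, fixed-effects
meta-analysis with I-squared, and the Fisher z difference test.

The causal estimator is one-sample TSLS: stage 1 regresses the exposure on
the genetic risk score plus covariates; stage 2 regresses the outcome on the
stage-1 fitted exposure plus the same covariates. Standard errors use the
proper instrumental-variable variance, with the residual computed against
the observed (not fitted) exposure — naive stage-2 OLS standard errors are
anticonservative and are not offered. Effects are reported per cohort SD of
the exposure; ordinal well-being outcomes are modelled as numeric responses
in linear models.

Stratum estimates are pooled by inverse-variance fixed-effects
meta-analysis with Cochran's Q and I^2 = max(0, (Q - df)/Q) * 100, and two
independent estimates are compared by z = (b1 - b2) / sqrt(SE1^2 + SE2^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm

from .grs import GRSResult

__all__ = [
    "StratumEstimate",
    "MetaResult",
    "DiffTest",
    "WeakInstrumentWarning",
    "observational_fit",
    "tsls_fit",
    "meta_fixed",
    "i_squared",
    "ci_to_se",
    "fisher_z_diff",
]


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass
class StratumEstimate:
    """One fitted slope: outcome units per SD of the exposure."""

    beta: float
    se: float
    n: int
    model: str = "observational"  # "observational" | "tsls"
    sex: str = "all"
    region: str = "all"
    cohort: str = ""
    outcome: str = ""
    covariate_set: str = ""
    p: float = field(init=False)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("SE must be > 0")
        self.p = float(2 * norm.sf(abs(self.beta / self.se)))

    @property
    def ci(self) -> tuple[float, float]:
        return self.beta - 1.96 * self.se, self.beta + 1.96 * self.se


@dataclass
class MetaResult:
    beta: float
    se: float
    q: float
    df: int
    i2: float
    p_heterogeneity: float
    n: int = 0
    sex: str = "all"
    region: str = "all"
    cohort: str = ""
    outcome: str = ""
    model: str = ""

    @property
    def p(self) -> float:
        return float(2 * norm.sf(abs(self.beta / self.se)))


@dataclass
class DiffTest:
    z: float
    p: float
    beta1: float
    beta2: float
    se1: float
    se2: float
    label: str = ""


def _design(n: int, *cols: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(n), *cols])


def _check_full_rank(X: np.ndarray, context: str) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design in {context}: rank {rank} < {X.shape[1]} columns"
        )


def _complete_cases(*arrays: np.ndarray) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        ok &= ~np.isnan(a).any(axis=1) if a.ndim == 2 else ~np.isnan(a)
    return ok


def observational_fit(
    exposure: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    exposure_sd: float | None = None,
    labels: dict | None = None,
) -> StratumEstimate:
    """OLS of the outcome on the exposure in SD units plus covariates.

    The exposure SD is computed within the analysis (complete-case) sample
    unless a fixed external SD is supplied via *exposure_sd*.
    """
    exposure = np.asarray(exposure, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    C = _as_cov(covariates, len(exposure))
    ok = _complete_cases(exposure, outcome, C)
    x, y, C = exposure[ok], outcome[ok], C[ok]
    n = len(x)
    if n < C.shape[1] + 3:
        raise ValueError("too few complete cases")
    sd = exposure_sd if exposure_sd is not None else x.std(ddof=1)
    xs = (x - x.mean()) / sd
    X = _design(n, xs, C)
    _check_full_rank(X, "observational_fit")
    beta, se = _ols_beta_se(X, y, slope_index=1)
    return StratumEstimate(beta=beta, se=se, n=n, model="observational", **(labels or {}))


def tsls_fit(
    grs: GRSResult | np.ndarray,
    exposure: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    exposure_sd: float | None = None,
    weak_f_threshold: float = 10.0,
    labels: dict | None = None,
) -> StratumEstimate:
    """Two-stage least squares with a single genetic-score instrument.

    Stage 1: exposure (in SD units) on the standardised score and
    covariates. Stage 2: outcome on stage-1 fitted exposure and the same
    covariates. The reported SE uses residuals formed with the observed
    exposure, the correct IV variance for the generated regressor. A
    stage-1 F below *weak_f_threshold* triggers a weak-instrument warning.
    """
    g = grs.grs_s if isinstance(grs, GRSResult) else np.asarray(grs, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    C = _as_cov(covariates, len(exposure))
    ok = _complete_cases(g, exposure, outcome, C)
    g, x, y, C = g[ok], exposure[ok], outcome[ok], C[ok]
    n = len(x)
    sd = exposure_sd if exposure_sd is not None else x.std(ddof=1)
    xs = (x - x.mean()) / sd

    X1 = _design(n, g, C)
    _check_full_rank(X1, "tsls stage 1")
    coef1, _, _, _ = np.linalg.lstsq(X1, xs, rcond=None)
    fitted = X1 @ coef1
    r1 = xs - fitted
    rss1 = r1 @ r1
    tss1_partial = ((xs - _design(n, C) @ np.linalg.lstsq(_design(n, C), xs, rcond=None)[0]) ** 2).sum()
    k1 = X1.shape[1]
    f_stage1 = ((tss1_partial - rss1) / 1) / (rss1 / (n - k1))
    if f_stage1 < weak_f_threshold:
        warnings.warn(
            f"weak instrument: stage-1 F = {f_stage1:.2f} < {weak_f_threshold}",
            WeakInstrumentWarning,
            stacklevel=2,
        )

    Xhat = _design(n, fitted, C)
    XtX = Xhat.T @ Xhat
    coef2 = np.linalg.solve(XtX, Xhat.T @ y)
    # IV variance: residuals against the observed exposure
    Xobs = _design(n, xs, C)
    resid = y - Xobs @ coef2
    sigma2 = (resid @ resid) / (n - Xhat.shape[1])
    cov = sigma2 * np.linalg.inv(XtX)
    est = StratumEstimate(
        beta=float(coef2[1]),
        se=float(np.sqrt(cov[1, 1])),
        n=n,
        model="tsls",
        **(labels or {}),
    )
    est.f_stage1 = float(f_stage1)
    return est


def _as_cov(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    C = np.asarray(covariates, dtype=float)
    return C.reshape(n, -1)


def _ols_beta_se(X: np.ndarray, y: np.ndarray, slope_index: int) -> tuple[float, float]:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = (resid @ resid) / (len(y) - X.shape[1])
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return float(coef[slope_index]), float(np.sqrt(cov[slope_index, slope_index]))


def meta_fixed(estimates) -> MetaResult:
    """Inverse-variance fixed-effects pooling with Cochran's Q.

    w_i = 1/SE_i^2; pooled beta = sum(w b)/sum(w); pooled SE = 1/sqrt(sum w);
    Q = sum w (b - pooled)^2 on k-1 degrees of freedom.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("meta_fixed requires at least one estimate")
    b = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    if (se <= 0).any():
        raise ValueError("all SEs must be > 0")
    w = 1.0 / se**2
    pooled = float((w * b).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    q = float((w * (b - pooled) ** 2).sum())
    df = len(b) - 1
    p_het = float(chi2.sf(q, df)) if df >= 1 else 1.0
    meta = MetaResult(
        beta=pooled,
        se=pooled_se,
        q=q,
        df=df,
        i2=0.0,
        p_heterogeneity=p_het,
        n=int(sum(e.n for e in estimates)),
        model=estimates[0].model,
        outcome=estimates[0].outcome,
        cohort=estimates[0].cohort,
    )
    meta.i2 = i_squared(meta)
    return meta


def i_squared(meta: MetaResult) -> float:
    """I^2 = max(0, (Q - df)/Q) x 100, in percent; 0 when Q = 0."""
    if meta.q <= 0:
        return 0.0
    return float(max(0.0, (meta.q - meta.df) / meta.q) * 100.0)


def ci_to_se(lower: float, upper: float, level: float = 0.95) -> float:
    """Recover a standard error from a printed symmetric confidence interval."""
    if not (np.isfinite(lower) and np.isfinite(upper)):
        raise ValueError("CI bounds must be finite")
    if upper <= lower:
        raise ValueError("upper bound must exceed lower bound")
    z = norm.ppf(0.5 + level / 2) if level != 0.95 else 1.96
    return (upper - lower) / (2 * z)


def fisher_z_diff(est1, est2, label: str = "") -> DiffTest:
    """Fisher z test for a difference between two independent estimates.

    z = (b1 - b2)/sqrt(SE1^2 + SE2^2); the two-sided P uses the normal
    survival function and stays accurate for extremely small values.
    """
    b1, s1 = est1.beta, est1.se
    b2, s2 = est2.beta, est2.se
    if s1 <= 0 or s2 <= 0:
        raise ValueError("both SEs must be > 0")
    z = (b1 - b2) / np.hypot(s1, s2)
    p = float(2 * norm.sf(abs(z)))
    return DiffTest(z=float(z), p=p, beta1=b1, beta2=b2, se1=s1, se2=s2, label=label)
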