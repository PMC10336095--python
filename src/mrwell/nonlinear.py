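"""Non-linearity screening and control-function non-linear MR.

Observational screening compares linear, quadratic, and fractional
polynomial (FP) models by AIC. FP1 fits the eight single-power transforms
X^p with p drawn from S = (-2, -1, -0.5, 0, 0.5, 1, 2, 3) (p = 0 meaning
log X); FP2 fits the 36 power combinations — the 28 distinct unordered
pairs plus the 8 repeated powers, a repeated power p contributing the pair
(X^p, X^p log X). The exposure is divided by its sample mean before
powering, which guarantees positivity for BMI; p1 = 1, p2 = 2 reproduces
the quadratic model exactly.

The causal analogue is a control-function estimator: stage 1 regresses the
exposure on the genetic score and covariates and keeps the residuals; stage
2 regresses the outcome on the exposure, its square, the covariates, and
the stage-1 residual, whose inclusion absorbs the unmeasured confounding.
The stage-2 coefficients on the exposure terms are the causal estimates.
Standard errors come from a nonparametric bootstrap over individuals that
re-runs both stages (the generated stage-1 residual invalidates naive OLS
standard errors); a fast naive mode exists for exploratory runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .grs import GRSResult
from .mr_core import DiffTest, WeakInstrumentWarning, fisher_z_diff

__all__ = [
    "FP_POWERS",
    "FPModel",
    "CFResult",
    "fit_quadratic",
    "fp_transform",
    "fp1_search",
    "fp2_search",
    "select_by_aic",
    "control_function",
    "compare_nonlinear",
]

log = logging.getLogger(__name__)

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass
class FPModel:
    """A fitted fractional-polynomial (or plain linear/quadratic) model."""

    degree: int
    powers: tuple[float, ...]
    coefficients: np.ndarray
    intercept: float
    aic: float
    loglik: float
    scale: float = 1.0  # exposure divided by this before powering
    center: float = 0.0  # subtracted before squaring (quadratic fits)
    n: int = 0
    label: str = ""
    collapsed: bool = False  # FP2 with p1 == p2
    aic_table: dict[tuple[float, ...], float] = field(default_factory=dict)
    fitted: np.ndarray | None = None
    y_checksum: float = 0.0


@dataclass
class CFResult:
    """Control-function estimates: causal linear and quadratic coefficients."""

    beta_linear: float
    beta_quadratic: float
    beta_residual: float
    se_linear: float
    se_quadratic: float
    se_residual: float
    p_quadratic: float
    n: int
    f_stage1: float
    n_bootstrap: int = 0
    covariate_set: str = ""
    label: str = ""


def _gaussian_aic(rss: float, n: int, k: int) -> tuple[float, float]:
    """AIC with the error variance profiled at its MLE.

    k counts the intercept and slope terms, not the variance parameter.
    """
    sigma2 = rss / n
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return 2 * k - 2 * loglik, loglik


def _fit_linear_model(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("singular design")
    resid = y - X @ coef
    return coef, float(resid @ resid)


def _cov_block(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    return np.asarray(covariates, dtype=float).reshape(n, -1)


def fit_quadratic(
    x: np.ndarray, y: np.ndarray, covariates=None, label: str = ""
) -> FPModel:
    """Linear model with linear and quadratic exposure terms.

    The exposure is centred before squaring to reduce collinearity;
    coefficients are reported on the centred scale with the centre stored.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    C = _cov_block(covariates, n)
    c = x.mean()
    xc = x - c
    X = np.column_stack([np.ones(n), xc, xc**2, C])
    coef, rss = _fit_linear_model(X, y)
    k = X.shape[1]
    aic, ll = _gaussian_aic(rss, n, k)
    return FPModel(
        degree=2,
        powers=(1.0, 2.0),
        coefficients=coef[1:3],
        intercept=float(coef[0]),
        aic=aic,
        loglik=ll,
        center=c,
        n=n,
        label=label or "quadratic",
        fitted=X @ coef,
        y_checksum=float(np.sum(y)),
    )


def fp_transform(x: np.ndarray, p: float) -> np.ndarray:
    """The FP basis transform: x^p, with p = 0 meaning the natural log."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fractional polynomials require strictly positive x")
    return np.log(x) if p == 0 else x**p


def _fp_design(xs: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """FP design columns; a repeated power p contributes (x^p, x^p log x)."""
    if len(powers) == 2 and powers[0] == powers[1]:
        base = fp_transform(xs, powers[0])
        return np.column_stack([base, base * np.log(xs)])
    return np.column_stack([fp_transform(xs, p) for p in powers])


def _fp_fit(
    x: np.ndarray, y: np.ndarray, powers: tuple[float, ...], covariates
) -> FPModel:
    n = len(x)
    scale = float(np.mean(x))
    xs = x / scale
    if np.any(xs <= 0):
        raise ValueError("exposure not strictly positive after mean scaling")
    C = _cov_block(covariates, n)
    B = _fp_design(xs, powers)
    X = np.column_stack([np.ones(n), B, C])
    coef, rss = _fit_linear_model(X, y)
    aic, ll = _gaussian_aic(rss, n, X.shape[1])
    return FPModel(
        degree=len(powers),
        powers=powers,
        coefficients=coef[1 : 1 + B.shape[1]],
        intercept=float(coef[0]),
        aic=aic,
        loglik=ll,
        scale=scale,
        n=n,
        label=f"FP{len(powers)}{powers}",
        collapsed=len(powers) == 2 and powers[0] == powers[1],
        fitted=X @ coef,
        y_checksum=float(np.sum(y)),
    )


def _fp_search(x, y, covariates, candidates: list[tuple[float, ...]]) -> FPModel:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    table: dict[tuple[float, ...], float] = {}
    fits: list[FPModel] = []
    for powers in candidates:
        try:
            m = _fp_fit(x, y, powers, covariates)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            log.warning("FP fit at powers %s failed: %s", powers, exc)
            continue
        table[powers] = m.aic
        fits.append(m)
    if not fits:
        raise RuntimeError("every fractional-polynomial candidate fit failed")
    best = min(fits, key=lambda m: m.aic)
    best.aic_table = table
    return best


def fp1_search(x, y, covariates=None) -> FPModel:
    """Fit all 8 single-power FP models; return the minimum-AIC fit."""
    return _fp_search(x, y, covariates, [(p,) for p in FP_POWERS])


def fp2_search(x, y, covariates=None) -> FPModel:
    """Fit all 36 FP2 power combinations; return the minimum-AIC fit.

    Candidates are the 28 unordered distinct pairs plus the 8 repeated
    powers; a winning repeated-power model is flagged ``collapsed``.
    """
    candidates = [
        (p1, p2)
        for i, p1 in enumerate(FP_POWERS)
        for p2 in FP_POWERS[i:]
    ]
    assert len(candidates) == 36
    return _fp_search(x, y, covariates, candidates)


def select_by_aic(models) -> tuple[FPModel, list[tuple[str, float]]]:
    """Pick the minimum-AIC model from fits on identical data.

    Ties break toward fewer parameters, then lower powers. Models fitted on
    differing samples are not comparable and raise ``ValueError``.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    ref = models[0]
    for m in models[1:]:
        if m.n != ref.n or abs(m.y_checksum - ref.y_checksum) > 1e-8 * max(
            1.0, abs(ref.y_checksum)
        ):
            raise ValueError("models were fitted on differing samples")
    best = min(
        models,
        key=lambda m: (round(m.aic, 10), len(m.coefficients), m.powers),
    )
    table = [(m.label or str(m.powers), m.aic) for m in models]
    return best, table


def _cf_point(
    g: np.ndarray, xs: np.ndarray, y: np.ndarray, C: np.ndarray, degree: int = 2
) -> tuple[np.ndarray, float, np.ndarray]:
    """One control-function fit; returns (b_lin, b_quad, b_resid), F1, cov.

    With ``degree=1`` the quadratic column is omitted and its slots in the
    returned coefficient vector and covariance are zero.
    """
    n = len(xs)
    X1 = np.column_stack([np.ones(n), g, C])
    coef1, rss1 = _fit_linear_model(X1, xs)
    r = xs - X1 @ coef1
    X0 = np.column_stack([np.ones(n), C])
    _, rss0 = _fit_linear_model(X0, xs)
    f1 = (rss0 - rss1) / (rss1 / (n - X1.shape[1]))
    poly = [xs, xs**2] if degree == 2 else [xs]
    X2 = np.column_stack([np.ones(n), *poly, C, r])
    coef2, rss2 = _fit_linear_model(X2, y)
    sigma2 = rss2 / (n - X2.shape[1])
    cov = sigma2 * np.linalg.inv(X2.T @ X2)
    idx = [1, 2, X2.shape[1] - 1] if degree == 2 else [1, X2.shape[1] - 1]
    out = coef2[idx]
    cv = cov[np.ix_(idx, idx)]
    if degree == 1:
        out = np.array([out[0], 0.0, out[1]])
        cv_full = np.zeros((3, 3))
        cv_full[np.ix_([0, 2], [0, 2])] = cv
        cv = cv_full
    return out, float(f1), cv


def control_function(
    grs: GRSResult | np.ndarray,
    exposure: np.ndarray,
    outcome: np.ndarray,
    covariates=None,
    degree: int = 2,
    n_bootstrap: int = 500,
    seed: int = 0,
    weak_f_threshold: float = 10.0,
    naive_se: bool = False,
    label: str = "",
) -> CFResult:
    """Control-function non-linear IV fit with quadratic exposure terms.

    Stage 1: exposure (standardised to sample SD) on the genetic score plus
    covariates, residuals retained. Stage 2: outcome on exposure, exposure
    squared, covariates, and the stage-1 residual. SEs are bootstrap
    (resampling individuals and re-running both stages, seeded) unless
    ``naive_se`` requests plain stage-2 OLS SEs. The two-sided P for the
    quadratic term uses a normal reference.
    """
    g = grs.grs_s if isinstance(grs, GRSResult) else np.asarray(grs, dtype=float)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(x)
    C = _cov_block(covariates, n)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    xs = (x - x.mean()) / x.std(ddof=1)

    point, f1, cov = _cf_point(g, xs, y, C, degree)
    if f1 < weak_f_threshold:
        warnings.warn(
            f"weak instrument: stage-1 F = {f1:.2f} < {weak_f_threshold}",
            WeakInstrumentWarning,
            stacklevel=2,
        )

    if naive_se or n_bootstrap == 0:
        with np.errstate(invalid="ignore"):
            ses = np.sqrt(np.diag(cov))
        used = 0
    else:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_bootstrap, 3))
        failures = 0
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            try:
                xb = x[idx]
                xsb = (xb - xb.mean()) / xb.std(ddof=1)
                reps[b], _, _ = _cf_point(g[idx], xsb, y[idx], C[idx], degree)
            except np.linalg.LinAlgError:
                reps[b] = np.nan
                failures += 1
        if failures > 0.05 * n_bootstrap:
            raise RuntimeError(
                f"bootstrap failure rate {failures / n_bootstrap:.1%} exceeds 5%"
            )
        ses = np.nanstd(reps, axis=0, ddof=1)
        used = n_bootstrap

    p_quad = float(2 * norm.sf(abs(point[1] / ses[1]))) if degree == 2 else float("nan")
    return CFResult(
        beta_linear=float(point[0]),
        beta_quadratic=float(point[1]),
        beta_residual=float(point[2]),
        se_linear=float(ses[0]),
        se_quadratic=float(ses[1]),
        se_residual=float(ses[2]),
        p_quadratic=p_quad,
        n=n,
        f_stage1=f1,
        n_bootstrap=used,
        label=label,
    )


def compare_nonlinear(cf1: CFResult, cf2: CFResult, label: str = "") -> DiffTest:
    """Fisher z test applied to the two quadratic causal coefficients."""

    class _E:
        def __init__(self, beta, se):
            self.beta, self.se = beta, se

    return fisher_z_diff(
        _E(cf1.beta_quadratic, cf1.se_quadratic),
        _E(cf2.beta_quadratic, cf2.se_quadratic),
        label=label,
    )
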