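"""Summary-statistic Mendelian randomization with correlated instruments.

Three estimators over per-SNP exposure (``bx``) and outcome (``by``)
effects with an inter-instrument correlation matrix ``rho``:

* ``ivw_correlated`` — generalized-least-squares slope through the origin
  with weight matrix ``Omega_ij = byse_i * byse_j * rho_ij``; the random
  model inflates the SE by ``max(1, sqrt(Q / (J - 1)))``.
* ``maxlik_correlated`` — joint normal likelihood of (bx, by) with means
  (xi, theta * xi), profiled over the per-SNP exposure means.
* ``egger_correlated`` — the same GLS regression with a free intercept; a
  nonzero intercept indicates average directional pleiotropy.

Plus Benjamini-Hochberg FDR adjustment and report finalization (per-250bp
rescaling, FDR family, power join).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    ConvergenceFailure,
    InsufficientData,
    SingularWeightMatrix,
    ValidationError,
)
from .panel import DEFAULT_SCALING, ScalingConstants, bp_rescale, nearest_psd_correlation

log = logging.getLogger(__name__)

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass
class MRInput:
    """Per-SNP summary statistics feeding one MR fit."""

    bx: np.ndarray
    bxse: np.ndarray
    by: np.ndarray
    byse: np.ndarray
    rho: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bx = np.atleast_1d(np.asarray(self.bx, dtype=float))
        self.bxse = np.atleast_1d(np.asarray(self.bxse, dtype=float))
        self.by = np.atleast_1d(np.asarray(self.by, dtype=float))
        self.byse = np.atleast_1d(np.asarray(self.byse, dtype=float))
        J = self.bx.size
        if not (self.bxse.size == self.by.size == self.byse.size == J):
            raise ValidationError("bx, bxse, by, byse must have equal length")
        if J == 0:
            raise InsufficientData("no instruments")
        if np.any(self.bxse <= 0) or np.any(self.byse <= 0):
            raise ValidationError("standard errors must be positive")
        if self.rho is None:
            self.rho = np.eye(J)
        else:
            self.rho = np.asarray(self.rho, dtype=float)
            if self.rho.shape != (J, J):
                raise ValidationError("rho has wrong shape")
            if not np.allclose(self.rho, self.rho.T, atol=1e-10):
                raise ValidationError("rho must be symmetric")

    @property
    def J(self) -> int:
        return self.bx.size


@dataclass
class MRResult:
    """One causal estimate: effect of one SD of telomere length on the outcome."""

    method: str
    theta: float
    se: float
    ci95: tuple[float, float]
    p: float
    Q: float = float("nan")
    egger_intercept: float = float("nan")
    egger_intercept_se: float = float("nan")
    egger_intercept_p: float = float("nan")
    theta_250bp: float = float("nan")
    or_250bp: float = float("nan")
    p_fdr: float = float("nan")

    def rescaled(self, target_bp: float = 250.0, scaling: ScalingConstants = DEFAULT_SCALING) -> "MRResult":
        self.theta_250bp = bp_rescale(self.theta, target_bp, scaling)
        self.or_250bp = math.exp(self.theta_250bp)
        return self


def _omega(input: MRInput) -> np.ndarray:
    omega = np.outer(input.byse, input.byse) * input.rho
    try:
        np.linalg.cholesky(omega)
        return omega
    except np.linalg.LinAlgError:
        log.warning("weight matrix not positive definite; eigen-clipping")
        repaired = nearest_psd_correlation(input.rho)
        omega = np.outer(input.byse, input.byse) * repaired
        try:
            np.linalg.cholesky(omega + 1e-14 * np.eye(input.J))
            return omega
        except np.linalg.LinAlgError as exc:
            raise SingularWeightMatrix("weight matrix singular after PSD repair") from exc


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _wald_ratio(input: MRInput, method: str) -> MRResult:
    bx, by = float(input.bx[0]), float(input.by[0])
    bxse, byse = float(input.bxse[0]), float(input.byse[0])
    if bx == 0:
        raise ValidationError("Wald ratio undefined for bx = 0")
    theta = by / bx
    se = math.sqrt(byse**2 / bx**2 + by**2 * bxse**2 / bx**4)  # delta method
    ci = (theta - Z95 * se, theta + Z95 * se)
    return MRResult(method, theta, se, ci, _normal_p(theta / se), Q=0.0)


def ivw_correlated(input: MRInput, model: str = "random") -> MRResult:
    """GLS inverse-variance weighted estimate through the origin."""
    if model not in ("fixed", "random"):
        raise ValidationError(f"unknown model {model!r}")
    if input.J == 1:
        return _wald_ratio(input, "ivw")
    omega = _omega(input)
    oi_bx = np.linalg.solve(omega, input.bx)
    denom = float(input.bx @ oi_bx)
    if denom <= 0:
        raise SingularWeightMatrix("degenerate exposure effects")
    theta = float(input.by @ oi_bx) / denom
    se_fixed = math.sqrt(1.0 / denom)
    resid = input.by - theta * input.bx
    Q = float(resid @ np.linalg.solve(omega, resid))
    se = se_fixed
    if model == "random" and input.J > 1:
        se *= max(1.0, math.sqrt(Q / (input.J - 1)))
    ci = (theta - Z95 * se, theta + Z95 * se)
    return MRResult("ivw", theta, se, ci, _normal_p(theta / se), Q=Q)


def egger_correlated(input: MRInput, model: str = "random") -> MRResult:
    """GLS regression of by on bx with a free pleiotropy intercept.

    Requires bx oriented non-negative (effect alleles lengthen telomeres);
    slope is the causal estimate, intercept the average directional
    pleiotropy tested against zero.
    """
    if input.J < 3:
        raise InsufficientData(f"MR-Egger needs >= 3 instruments, got {input.J}")
    if np.any(input.bx < 0):
        raise ValidationError("bx must be oriented non-negative for MR-Egger")
    omega = _omega(input)
    X = np.column_stack([np.ones(input.J), input.bx])
    oi_X = np.linalg.solve(omega, X)
    xtx = X.T @ oi_X
    coef = np.linalg.solve(xtx, oi_X.T @ input.by)
    resid = input.by - X @ coef
    Q = float(resid @ np.linalg.solve(omega, resid))
    cov = np.linalg.inv(xtx)
    inflation = 1.0
    if model == "random" and input.J > 2:
        inflation = max(1.0, math.sqrt(Q / (input.J - 2)))
    se_int = math.sqrt(cov[0, 0]) * inflation
    se_slope = math.sqrt(cov[1, 1]) * inflation
    theta = float(coef[1])
    intercept = float(coef[0])
    ci = (theta - Z95 * se_slope, theta + Z95 * se_slope)
    return MRResult(
        "egger",
        theta,
        se_slope,
        ci,
        _normal_p(theta / se_slope),
        Q=Q,
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_p=_normal_p(intercept / se_int),
    )


def _maxlik_neg2ll(theta: float, input: MRInput, sx: np.ndarray, sy: np.ndarray,
                   psi: float) -> tuple[float, np.ndarray]:
    """Profile -2logL (up to a constant) at theta, with xi profiled out by GLS."""
    J = input.J
    top = np.concatenate([input.bx, input.by])
    if psi == 0.0:
        xi = np.linalg.solve(
            np.linalg.inv(sx) + theta**2 * np.linalg.inv(sy),
            np.linalg.solve(sx, input.bx) + theta * np.linalg.solve(sy, input.by),
        )
        rx = input.bx - xi
        ry = input.by - theta * xi
        val = float(rx @ np.linalg.solve(sx, rx) + ry @ np.linalg.solve(sy, ry))
        return val, xi
    cross = psi * np.outer(input.bxse, input.byse) * input.rho
    sigma = np.block([[sx, cross], [cross.T, sy]])
    sigma_inv = np.linalg.inv(sigma)
    G = np.vstack([np.eye(J), theta * np.eye(J)])
    A = G.T @ sigma_inv @ G
    xi = np.linalg.solve(A, G.T @ sigma_inv @ top)
    r = top - G @ xi
    return float(r @ sigma_inv @ r), xi


def maxlik_correlated(
    input: MRInput,
    psi: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> MRResult:
    """Likelihood-based estimate: joint normal model for (bx, by).

    ``psi`` is the exposure-outcome estimate correlation (0 for
    non-overlapping two-sample designs).  Initialized at the IVW solution;
    the profile log-likelihood is maximized over theta and the SE taken from
    the curvature of the profile at the optimum.
    """
    if input.J == 1:
        return _wald_ratio(input, "maxlik")
    sx = np.outer(input.bxse, input.bxse) * input.rho
    sy = np.outer(input.byse, input.byse) * input.rho
    theta0 = ivw_correlated(input, model="fixed").theta

    def objective(theta: float) -> float:
        return _maxlik_neg2ll(theta, input, sx, sy, psi)[0]

    span = 10.0 * max(abs(theta0), 1.0)
    res = optimize.minimize_scalar(
        objective,
        bracket=(theta0 - 0.1 * span, theta0, theta0 + 0.1 * span),
        method="brent",
        options={"xtol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise ConvergenceFailure(f"maxlik failed to converge: {res.message}")
    theta = float(res.x)
    # SE from the profile curvature (Schur complement of the full information).
    h = 1e-5 * max(abs(theta), 1.0)
    f0 = objective(theta)
    fp = objective(theta + h)
    fm = objective(theta - h)
    d2 = (fp - 2.0 * f0 + fm) / h**2
    if d2 <= 0:
        raise ConvergenceFailure("non-positive profile curvature at the optimum")
    se = math.sqrt(2.0 / d2)  # objective is -2 logL
    ci = (theta - Z95 * se, theta + Z95 * se)
    _, xi = _maxlik_neg2ll(theta, input, sx, sy, psi)
    ry = input.by - theta * xi
    Q = float(ry @ np.linalg.solve(sy, ry))
    return MRResult("maxlik", theta, se, ci, _normal_p(theta / se), Q=Q)


METHODS = {
    "ivw": ivw_correlated,
    "maxlik": maxlik_correlated,
    "egger": egger_correlated,
}


def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def run_methods(
    input: MRInput,
    methods: tuple[str, ...] = ("ivw", "maxlik", "egger"),
    scaling: ScalingConstants = DEFAULT_SCALING,
    target_bp: float = 250.0,
) -> dict[str, MRResult]:
    out = {}
    for m in methods:
        try:
            out[m] = METHODS[m](input).rescaled(target_bp, scaling)
        except InsufficientData:
            log.info("skipping %s (insufficient instruments, J=%d)", m, input.J)
    return out


def finalize(
    results: pd.DataFrame,
    scaling: ScalingConstants = DEFAULT_SCALING,
    target_bp: float = 250.0,
    fdr_method: str = "maxlik",
    fdr_stratum: str = "60+/all",
    power_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach rescaled effects, the FDR column, and power flags to MR results.

    ``results`` needs columns outcome, stratum, method, theta, se, p.  FDR is
    computed across outcomes within the primary-analysis family: one p-value
    per outcome, ``fdr_method`` estimates in the ``fdr_stratum`` stratum.
    CIs are rescaled deterministically from the per-SD normal-theory CI.
    """
    df = results.copy()
    factor = target_bp / scaling.bp_per_sd
    df["theta_250bp"] = df["theta"] * factor
    df["or_250bp"] = np.exp(df["theta_250bp"])
    df["ci_low_250bp"] = (df["theta"] - Z95 * df["se"]) * factor
    df["ci_high_250bp"] = (df["theta"] + Z95 * df["se"]) * factor
    df["or_ci_low_250bp"] = np.exp(df["ci_low_250bp"])
    df["or_ci_high_250bp"] = np.exp(df["ci_high_250bp"])

    df["p_fdr"] = np.nan
    family = (df["method"] == fdr_method) & (df["stratum"] == fdr_stratum)
    if family.any():
        df.loc[family, "p_fdr"] = fdr_bh(df.loc[family, "p"].to_numpy())

    if power_table is not None:
        df = df.merge(power_table[["outcome", "power", "low_power"]], on="outcome", how="left")
    return df
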