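"""Per-SNP association estimation: the SNP-outcome inputs to MR.

Betas are per copy of the telomere-lengthening allele: log-odds for binary
outcomes (logistic regression by IRLS) and SD units for standardized
continuous outcomes (OLS with classical standard errors).  Individuals with
missing outcome or covariates are dropped listwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import DegenerateGenotype, InsufficientData, ValidationError
from .panel import SNPPanel
from .phenotypes import DerivedOutcome

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "center", "array_type", "pc1", "pc2", "pc3", "pc4", "pc5")
_CATEGORICAL = {"sex", "center", "array_type"}

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 50


@dataclass
class AssocResult:
    rsid: str
    outcome: str
    beta: float
    se: float
    n: int
    n_cases: int | None = None
    converged: bool = True
    stratum: str = "all"


def design_matrix(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Intercept plus covariates, categoricals dummy-coded (first level dropped)."""
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1))
    cols = [np.ones(n)]
    for name in covariates.columns:
        col = covariates[name]
        if name in _CATEGORICAL or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy())
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def linear_assoc(
    y: np.ndarray,
    g: np.ndarray,
    covariates: pd.DataFrame | None = None,
    rsid: str = "",
    outcome: str = "",
) -> AssocResult:
    """OLS slope on the dosage with classical (non-robust) standard error."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    if covariates is not None:
        keep &= ~covariates.isna().any(axis=1).to_numpy()
        covariates = covariates.loc[keep]
    y, g = y[keep], g[keep]
    if np.ptp(g) == 0:
        raise DegenerateGenotype(f"{rsid}: constant dosage")
    X = np.column_stack([g, design_matrix(covariates, len(y))])
    n, p = X.shape
    if n <= p:
        raise InsufficientData(f"{rsid}/{outcome}: n={n} <= p={p}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[0, 0], 0.0)))
    return AssocResult(rsid=rsid, outcome=outcome, beta=float(coef[0]), se=se, n=n)


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic ML via iteratively reweighted least squares.

    Returns (coefficients, standard errors from observed information,
    converged flag).  Convergence: |change in log-likelihood| < 1e-8.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = np.clip(y.mean(), 1e-10, 1 - 1e-10)
    beta[-1] = logit(ybar)  # intercept column is appended last by callers
    ll_old = -np.inf
    converged = False
    for _ in range(IRLS_MAX_ITER):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        eta = X @ beta
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if abs(ll - ll_old) < IRLS_TOL:
            converged = True
            break
        ll_old = ll
    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    # quasi-separation: coefficients diverging (log-odds this large are not
    # attainable from real case-control contrasts)
    if np.abs(beta).max() > 15:
        converged = False
    return beta, se, converged


def logistic_assoc(
    y: np.ndarray,
    g: np.ndarray,
    covariates: pd.DataFrame | None = None,
    rsid: str = "",
    outcome: str = "",
) -> AssocResult:
    """Logistic regression log-odds per allele; excluded (NaN) codes dropped."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    if covariates is not None:
        keep &= ~covariates.isna().any(axis=1).to_numpy()
        covariates = covariates.loc[keep]
    y, g = y[keep], g[keep]
    classes = np.unique(y)
    if classes.size < 2:
        raise InsufficientData(f"{rsid}/{outcome}: single-class outcome")
    if np.ptp(g) == 0:
        raise DegenerateGenotype(f"{rsid}: constant dosage")
    X = np.column_stack([g, design_matrix(covariates, len(y))])
    if X.shape[0] <= X.shape[1]:
        raise InsufficientData(f"{rsid}/{outcome}: n <= p")
    # move intercept last so _irls can initialize it
    X = np.column_stack([X[:, 0], X[:, 2:], X[:, 1]])
    coef, se, converged = _irls(X, y)
    if not converged:
        log.warning("%s/%s: logistic fit did not converge (possible separation)", rsid, outcome)
    return AssocResult(
        rsid=rsid,
        outcome=outcome,
        beta=float(coef[0]),
        se=float(se[0]),
        n=len(y),
        n_cases=int(y.sum()),
        converged=converged,
    )


def linear_scan(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized marginal OLS (intercept + dosage) across all SNPs at once."""
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    var_g = (gc**2).sum(axis=0)
    beta = gc.T @ yc / var_g
    rss = (yc**2).sum() - beta**2 * var_g
    se = np.sqrt(np.clip(rss / (n - 2), 0.0, None) / var_g)
    return beta, se


def logistic_scan(
    y: np.ndarray, G: np.ndarray, tol: float = 1e-10, max_iter: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized marginal logistic fits (intercept + dosage) across SNPs.

    Newton iterations run jointly for all J two-parameter models; used by
    simulation studies where thousands of marginal fits are needed.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    n, J = G.shape
    a = np.full(J, logit(np.clip(y.mean(), 1e-10, 1 - 1e-10)))
    b = np.zeros(J)
    for _ in range(max_iter):
        eta = a[None, :] + G * b[None, :]
        mu = expit(eta)
        w = mu * (1 - mu)
        r = y[:, None] - mu
        s0 = w.sum(axis=0)
        s1 = (w * G).sum(axis=0)
        s2 = (w * G * G).sum(axis=0)
        u0 = r.sum(axis=0)
        u1 = (r * G).sum(axis=0)
        det = s0 * s2 - s1 * s1
        da = (s2 * u0 - s1 * u1) / det
        db = (s0 * u1 - s1 * u0) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    eta = a[None, :] + G * b[None, :]
    w = expit(eta) * (1 - expit(eta))
    s0 = w.sum(axis=0)
    s1 = (w * G).sum(axis=0)
    s2 = (w * G * G).sum(axis=0)
    se_b = np.sqrt(s0 / (s0 * s2 - s1 * s1))
    return b, se_b


def stratum_mask(cohort: pd.DataFrame, age_stratum: str, sex_stratum: str) -> np.ndarray:
    age = cohort["age"].to_numpy(dtype=float)
    if age_stratum == "all":
        m = np.ones(len(cohort), dtype=bool)
    elif age_stratum == "40-60":
        m = (age >= 40) & (age < 60)
    elif age_stratum == "60+":
        m = age >= 60
    else:
        raise ValidationError(f"unknown age stratum {age_stratum!r}")
    if sex_stratum == "all":
        pass
    elif sex_stratum in ("male", "female"):
        m &= (cohort["sex"] == ("M" if sex_stratum == "male" else "F")).to_numpy()
    else:
        raise ValidationError(f"unknown sex stratum {sex_stratum!r}")
    return m


def scan(
    panel: SNPPanel,
    cohort: pd.DataFrame,
    outcomes: Mapping[str, DerivedOutcome],
    age_stratum: str = "all",
    sex_stratum: str = "all",
    covariates: Sequence[str] | None = DEFAULT_COVARIATES,
    outcome_sex: Mapping[str, str] | None = None,
) -> list[AssocResult]:
    """One association per SNP per outcome within the requested stratum.

    ``outcome_sex`` marks sex-restricted outcomes ("female"/"male"); entries
    conflicting with the stratum are skipped with a logged notice.
    """
    mask = stratum_mask(cohort, age_stratum, sex_stratum)
    if not mask.any():
        raise InsufficientData(f"empty stratum {age_stratum}/{sex_stratum}")
    sub = cohort.loc[mask]
    cov = sub[list(covariates)] if covariates else None
    if cov is not None and sex_stratum != "all" and "sex" in cov.columns:
        cov = cov.drop(columns="sex")  # constant within a sex stratum
    stratum_label = f"{age_stratum}/{sex_stratum}"
    results: list[AssocResult] = []
    for name, outcome in outcomes.items():
        restriction = (outcome_sex or {}).get(name)
        if restriction is not None and sex_stratum not in ("all", restriction):
            log.info("skipping %s in %s stratum (restricted to %s)", name, sex_stratum, restriction)
            continue
        y = outcome.values[mask]
        if restriction is not None and sex_stratum == "all":
            sex_ok = (sub["sex"] == ("F" if restriction == "female" else "M")).to_numpy()
            y = np.where(sex_ok, y, np.nan)
        fit = logistic_assoc if outcome.kind == "binary" else linear_assoc
        fits: list[AssocResult] = []
        try:
            for rsid in panel.rsids:
                g = sub[f"g_{rsid}"].to_numpy(dtype=float)
                res = fit(y, g, cov, rsid=rsid, outcome=name)
                res.stratum = stratum_label
                fits.append(res)
        except (InsufficientData, DegenerateGenotype) as exc:
            log.warning("skipping %s in %s: %s", name, stratum_label, exc)
            continue
        results.extend(fits)
    return results


def results_table(results: list[AssocResult], panel: SNPPanel) -> pd.DataFrame:
    """GWAS-summary-style table of scan results."""
    alleles = {s.rsid: (s.effect_allele, s.other_allele) for s in panel.snps}
    rows = []
    for r in results:
        ea, oa = alleles.get(r.rsid, ("", ""))
        rows.append(
            {
                "rsid": r.rsid, "effect_allele": ea, "other_allele": oa,
                "beta": r.beta, "se": r.se, "n": r.n, "n_cases": r.n_cases,
                "outcome": r.outcome, "stratum": r.stratum, "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)
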