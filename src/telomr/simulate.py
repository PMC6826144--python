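"""Synthetic biobank-style cohort generation.

Generates individual-level data with the statistical structure the MR
analysis assumes: LD-correlated genotype dosages under Hardy-Weinberg, a
latent standardized telomere-length exposure explaining a target fraction
of variance (2.23% by default), logistic binary outcomes calibrated to a
marginal prevalence, continuous outcomes with unit variance, parental
attained ages, and the raw survey/measurement fields the phenotype
derivations consume.

Genotypes come from a Gaussian copula: two independent haplotypes per
individual, each a thresholded latent multivariate normal whose pairwise
latent correlation is calibrated numerically so the *dosage* correlation
matches the panel's r matrix.  All stages draw from per-stage RNG streams
derived from one master seed by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, ndtri

from .errors import ValidationError
from .panel import SNPPanel, nearest_psd_correlation

# Fixed per-stage offsets mixed with the master seed so stages are independent.
_STREAMS = {
    "genotypes": 11,
    "telomere": 23,
    "covariates": 37,
    "outcomes": 41,
    "parental": 53,
    "raw": 67,
    "confounder": 71,
}

#: Father's / mother's age-at-death defaults (years): mean, SD.
FATHER_AGE = (72.22, 11.05)
MOTHER_AGE = (77.37, 9.83)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stage]])


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cohort.

    ``causal_effects`` maps outcome name to the effect of one SD of telomere
    length: log-odds for binary outcomes (those listed in ``prevalences``),
    SD change for continuous ones.  ``pleiotropy`` maps outcome name to a
    per-SNP vector of direct (non-exposure-mediated) allele effects.
    """

    n: int
    seed: int
    panel: SNPPanel
    target_r2: float = 0.0223
    causal_effects: dict[str, float] = field(default_factory=dict)
    prevalences: dict[str, float] = field(default_factory=dict)
    pleiotropy: dict[str, np.ndarray] = field(default_factory=dict)
    confounder_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("n must be at least 2")
        if not 0 <= self.target_r2 < 1:
            raise ValidationError(f"target_r2 {self.target_r2} outside [0, 1)")
        for name, k in self.prevalences.items():
            if not 0 < k < 1:
                raise ValidationError(f"prevalence for {name} must be in (0,1)")


def _pair_dosage_corr(rho: float, z_i: float, z_j: float, p_i: float, p_j: float) -> float:
    """Correlation of two thresholded-Gaussian haplotype indicators."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    joint = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([z_i, z_j])
    return (joint - p_i * p_j) / np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))


@lru_cache(maxsize=32)
def _latent_correlation_cached(eaf_key: tuple, r_key: bytes, shape: int) -> np.ndarray:
    eaf = np.asarray(eaf_key)
    r = np.frombuffer(r_key).reshape(shape, shape)
    z = ndtri(eaf)
    latent = np.eye(shape)
    for i in range(shape):
        for j in range(i + 1, shape):
            target = r[i, j]
            if abs(target) < 1e-12:
                continue
            if target >= 1.0 - 1e-12:
                latent[i, j] = latent[j, i] = 1.0
                continue
            f = lambda rho: _pair_dosage_corr(rho, z[i], z[j], eaf[i], eaf[j]) - target
            hi = 0.999999
            if f(hi) < 0:  # target beyond the Frechet bound for these frequencies
                latent[i, j] = latent[j, i] = hi
                continue
            latent[i, j] = latent[j, i] = optimize.brentq(f, -0.999, hi, xtol=1e-10)
    if np.linalg.eigvalsh(latent).min() < 1e-10:
        latent = nearest_psd_correlation(latent)
    return latent


def latent_correlation(panel: SNPPanel) -> np.ndarray:
    """Latent-Gaussian correlation calibrated so dosage correlation matches panel.r."""
    return _latent_correlation_cached(
        tuple(panel.eaf), np.ascontiguousarray(panel.r).tobytes(), panel.J
    )


def simulate_genotypes(spec: SimulationSpec) -> np.ndarray:
    """n x J dosage matrix (0/1/2 effect-allele counts) under HWE with LD."""
    rng = stage_rng(spec.seed, "genotypes")
    panel = spec.panel
    chol = np.linalg.cholesky(latent_correlation(panel))
    z = ndtri(panel.eaf)
    dosage = np.zeros((spec.n, panel.J))
    for _ in range(2):  # two independent haplotypes
        latent = rng.standard_normal((spec.n, panel.J)) @ chol.T
        dosage += latent < z
    return dosage


@dataclass
class TelomereSim:
    """Latent exposure plus the marginal per-allele effects it realizes."""

    telomere_sd: np.ndarray
    marginal_beta: np.ndarray
    scale: float


def simulate_telomere(dosages: np.ndarray, spec: SimulationSpec) -> TelomereSim:
    """Standardized telomere length with genetic R² equal to ``target_r2``.

    The genetic score uses conditional weights ``w = Sigma^-1 D beta`` fit to
    the realized genotype covariance, so the in-sample *marginal* per-allele
    regression slope on each SNP equals (a common rescaling of) the panel
    beta — matching how GWAS summary effects are defined.
    """
    rng = stage_rng(spec.seed, "telomere")
    n = dosages.shape[0]
    if spec.target_r2 == 0:
        return TelomereSim(rng.standard_normal(n), np.zeros(dosages.shape[1]), 0.0)
    beta = spec.panel.beta_sd
    gc = dosages - dosages.mean(axis=0)
    sigma = gc.T @ gc / n
    dvar = np.diag(sigma)
    if np.any(dvar <= 0):
        raise ValidationError("constant dosage column; cannot calibrate exposure")
    w = np.linalg.solve(sigma, dvar * beta)
    q = float(beta @ (dvar * np.linalg.solve(sigma, dvar * beta)))
    if q <= 0:
        raise ValidationError("panel betas explain zero variance; target_r2 unreachable")
    scale = np.sqrt(spec.target_r2 / q)
    score = gc @ (w * scale)
    noise = rng.standard_normal(n) * np.sqrt(1.0 - spec.target_r2)
    return TelomereSim(score + noise, beta * scale, float(scale))


def simulate_covariates(n: int, seed: int) -> pd.DataFrame:
    """Baseline covariates: age, sex, center, array type, five PC scores."""
    rng = stage_rng(seed, "covariates")
    df = pd.DataFrame(
        {
            "age": rng.uniform(40.0, 70.0, n),
            "sex": np.where(rng.random(n) < 0.54, "F", "M"),
            "center": rng.integers(0, 22, n),
            "array_type": np.where(rng.random(n) < 0.10, "bileve", "axiom"),
        }
    )
    for k in range(1, 6):
        df[f"pc{k}"] = rng.standard_normal(n)
    return df


def solve_logistic_intercept(lp: np.ndarray, prevalence: float, tol: float = 1e-6) -> float:
    """Intercept a with mean(expit(a + lp)) = prevalence, by bracketed root-finding."""
    if not 0 < prevalence < 1:
        raise ValidationError(f"prevalence {prevalence} unreachable")
    f = lambda a: float(np.mean(expit(a + lp))) - prevalence
    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValidationError(f"prevalence {prevalence} unreachable for given effects")
    return optimize.brentq(f, lo, hi, xtol=tol)


def simulate_outcomes(cohort: pd.DataFrame, spec: SimulationSpec) -> pd.DataFrame:
    """Append one column per entry of ``spec.causal_effects``.

    Binary outcomes (named in ``spec.prevalences``) follow a logistic model
    with the intercept solved numerically for the requested marginal
    prevalence; continuous outcomes are scaled to unit total variance.
    """
    rng = stage_rng(spec.seed, "outcomes")
    n = len(cohort)
    tel = cohort["telomere_sd"].to_numpy()
    gcols = [c for c in cohort.columns if c.startswith("g_")]
    gc = cohort[gcols].to_numpy() - cohort[gcols].to_numpy().mean(axis=0)
    conf = cohort["confounder"].to_numpy() if "confounder" in cohort else 0.0
    out = cohort.copy()
    for name, theta in spec.causal_effects.items():
        alpha = np.asarray(spec.pleiotropy.get(name, np.zeros(len(gcols))), dtype=float)
        if alpha.shape != (len(gcols),):
            raise ValidationError(f"pleiotropy vector for {name} has wrong length")
        lp = theta * tel + gc @ alpha + spec.confounder_strength * conf
        if name in spec.prevalences:
            a = solve_logistic_intercept(lp, spec.prevalences[name])
            out[name] = (rng.random(n) < expit(a + lp)).astype(int)
        else:
            var_sig = float(np.var(lp))
            if var_sig >= 1.0:
                raise ValidationError(
                    f"{name}: signal variance {var_sig:.3f} exceeds unit total variance"
                )
            out[name] = lp + rng.standard_normal(n) * np.sqrt(1.0 - var_sig)
    return out


def simulate_parental_ages(
    n: int,
    seed: int,
    father: tuple[float, float] = FATHER_AGE,
    mother: tuple[float, float] = MOTHER_AGE,
    truncate_at: float = 20.0,
    premature_frac: float = 0.0,
    premature: tuple[float, float] = (45.0, 5.0),
    father_dead_frac: float = 0.70,
    mother_dead_frac: float = 0.54,
) -> pd.DataFrame:
    """Parental attained ages plus death flags.

    Ages are normal (truncated at ``truncate_at``), optionally mixed with a
    premature-death component for exercising the early-death cutoff.  Dead
    parents' ages are ages at death; living parents' are current ages.
    """
    rng = stage_rng(seed, "parental")

    def draw(mean: float, sd: float) -> np.ndarray:
        a = (truncate_at - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)

    fa, ma = draw(*father), draw(*mother)
    if premature_frac > 0:
        mask_f = rng.random(n) < premature_frac
        mask_m = rng.random(n) < premature_frac
        fa[mask_f] = draw(*premature)[mask_f]
        ma[mask_m] = draw(*premature)[mask_m]
    return pd.DataFrame(
        {
            "father_age": fa,
            "mother_age": ma,
            "father_dead": rng.random(n) < father_dead_frac,
            "mother_dead": rng.random(n) < mother_dead_frac,
        }
    )


_DEPRESSION_LEVELS = ["Not at all", "Several days", "More than half the days",
                      "Nearly every day", "Do not know"]
_PAIN_LEVELS = ["No", "Yes", "Do not know", "Prefer not to answer"]
_FALL_LEVELS = ["No falls", "Only one fall", "More than one fall", "Prefer not to answer"]
_PACE_LEVELS = ["Slow pace", "Steady average pace", "Brisk pace"]

N_DEFICIT_ITEMS = 49


def simulate_raw_phenotypes(cohort: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Raw survey/measurement fields consumed by the phenotype derivations.

    Distributional choices here are calibration conveniences for testing the
    derivation rules, not claims about any real cohort.
    """
    rng = stage_rng(seed, "raw")
    n = len(cohort)
    age = cohort["age"].to_numpy()
    male = (cohort["sex"] == "M").to_numpy()
    out = cohort.copy()

    # 49 binary deficit items, mildly age-dependent; last two are the
    # cancer-related items dropped for the 47-item index.
    base = rng.uniform(0.01, 0.12, N_DEFICIT_ITEMS)
    for i in range(N_DEFICIT_ITEMS):
        p = np.clip(base[i] + 0.003 * (age - 55.0), 0.002, 0.6)
        out[f"deficit_{i + 1:02d}"] = (rng.random(n) < p).astype(float)

    grip = np.where(male, 41.0, 25.0) - 0.25 * (age - 55.0) + rng.standard_normal(n) * np.where(male, 8.0, 6.0)
    out["grip_max_kg"] = np.clip(grip, 1.0, None)
    smi = np.where(male, 9.8, 7.2) - 0.02 * (age - 55.0) + rng.standard_normal(n) * np.where(male, 1.2, 1.0)
    out["smi_kg_m2"] = np.clip(smi, 2.0, None)

    out["reaction_time_ms"] = np.exp(rng.normal(np.log(540.0) + 0.003 * (age - 55.0), 0.18, n))
    out["visual_memory_errors"] = rng.poisson(4.0, n).astype(float)

    out["depression_response"] = rng.choice(_DEPRESSION_LEVELS, n, p=[0.72, 0.18, 0.04, 0.02, 0.04])
    for pain in ("back", "hip", "knee"):
        out[f"{pain}_pain_response"] = rng.choice(_PAIN_LEVELS, n, p=[0.78, 0.18, 0.02, 0.02])
    out["falls_response"] = rng.choice(_FALL_LEVELS, n, p=[0.78, 0.14, 0.06, 0.02])

    out["weight_loss"] = (rng.random(n) < 0.05).astype(float)
    out["exhaustion"] = (rng.random(n) < 0.12).astype(float)
    out["walking_pace"] = rng.choice(_PACE_LEVELS, n, p=[0.08, 0.52, 0.40])
    out["activity_met_min"] = np.clip(rng.gamma(2.0, 900.0, n), 0.0, None)

    out["systolic_bp"] = 132.0 + 0.45 * (age - 55.0) + rng.standard_normal(n) * 18.0
    return out


def simulate_cohort(spec: SimulationSpec, raw_phenotypes: bool = True) -> pd.DataFrame:
    """Full cohort table: dosages, exposure, covariates, outcomes, raw fields."""
    dosages = simulate_genotypes(spec)
    tel = simulate_telomere(dosages, spec)
    df = simulate_covariates(spec.n, spec.seed)
    for j, rsid in enumerate(spec.panel.rsids):
        df[f"g_{rsid}"] = dosages[:, j]
    df["telomere_sd"] = tel.telomere_sd
    df["confounder"] = stage_rng(spec.seed, "confounder").standard_normal(spec.n)
    df = pd.concat([df, simulate_parental_ages(spec.n, spec.seed)], axis=1)
    if raw_phenotypes:
        df = simulate_raw_phenotypes(df, spec.seed)
    df = simulate_outcomes(df, spec)
    return df
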