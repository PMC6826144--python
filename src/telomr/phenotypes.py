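"""Derivation of analysis outcomes from raw cohort fields.

Each derivation returns a :class:`DerivedOutcome` whose ``values`` encode a
three-state binary coding (1 case, 0 control, NaN excluded) or a continuous
value (NaN missing/excluded).  Continuous outcomes are z-transformed over
the analyzed subsample before association analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDistribution, SchemaError, ValidationError

# Parental survival contrasts (years).
TOP10_FATHER, TOP10_MOTHER = 87.0, 90.0
TOP10_CONTROL_BEFORE = 80.0
CENT_FATHER, CENT_MOTHER = 96.0, 100.0
CENT_CONTROL_FATHER, CENT_CONTROL_MOTHER = 90.0, 95.0

# EWGSOP sarcopenia cutoffs (strict "<"), by sex.
GRIP_CUTOFF = {"M": 30.0, "F": 20.0}
SMI_CUTOFF = {"M": 8.87, "F": 6.42}

N_FRAILTY_ITEMS = 49
FRIED_QUANTILE = 0.20


@dataclass
class DerivedOutcome:
    """A coded analysis outcome plus its derivation audit trail."""

    name: str
    kind: str  # "binary" | "continuous"
    values: np.ndarray
    transform_log: list[str] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    @property
    def n_cases(self) -> int | None:
        if self.kind != "binary":
            return None
        return int(np.nansum(self.values))

    def counts(self) -> tuple[int, int, int]:
        """(cases, controls, excluded) for a binary outcome."""
        v = self.values
        return int(np.nansum(v == 1)), int(np.nansum(v == 0)), int(np.isnan(v).sum())


@dataclass
class CutoffEstimate:
    """Early-death cutoff: modal age at death minus one standard deviation."""

    modal_age: float
    sd: float
    cutoff: float


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize over non-missing entries (population SD)."""
    x = np.asarray(x, dtype=float)
    m = ~np.isnan(x)
    mu, sd = x[m].mean(), x[m].std()
    if sd == 0:
        raise DegenerateDistribution("cannot z-score a constant vector")
    out = np.full_like(x, np.nan)
    out[m] = (x[m] - mu) / sd
    return out


def early_death_cutoff(
    ages: np.ndarray, method: str = "kde_halfnormal", grid_step: float = 0.1
) -> CutoffEstimate:
    """Estimate the premature-death cutoff from ages at death.

    ``kde_halfnormal``: the modal age is the maximizer of a Gaussian-kernel
    density (Silverman bandwidth) on a ``grid_step``-year grid, and the SD is
    a half-normal fit to the ages at or above the mode (reflected about it) —
    robust to a premature-death left tail.  ``gaussian_ml``: plain normal fit
    (mode = mean).  Cutoff = mode - SD.
    """
    ages = np.asarray(ages, dtype=float)
    ages = ages[~np.isnan(ages)]
    if ages.size < 100:
        raise ValidationError(f"need >= 100 ages at death, got {ages.size}")
    if np.ptp(ages) == 0:
        raise DegenerateDistribution("constant ages at death")
    if method == "gaussian_ml":
        mode, sd = float(ages.mean()), float(ages.std())
    elif method == "kde_halfnormal":
        kde = stats.gaussian_kde(ages, bw_method="silverman")
        grid = np.arange(ages.min(), ages.max() + grid_step, grid_step)
        mode = float(grid[np.argmax(kde(grid))])
        upper = ages[ages >= mode]
        sd = float(np.sqrt(np.mean((upper - mode) ** 2)))
    else:
        raise ValidationError(f"unknown cutoff method {method!r}")
    if sd <= 0:
        raise DegenerateDistribution("zero spread above the mode")
    return CutoffEstimate(modal_age=mode, sd=sd, cutoff=mode - sd)


def apply_early_death_cutoff(ages: np.ndarray, dead: np.ndarray, cutoff: float) -> np.ndarray:
    """Set dead parents' ages below ``cutoff`` to missing (premature deaths)."""
    ages = np.asarray(ages, dtype=float).copy()
    premature = np.asarray(dead, dtype=bool) & (ages < cutoff)
    ages[premature] = np.nan
    return ages


def parental_lifespan_z(
    father_age: np.ndarray,
    mother_age: np.ndarray,
    father_dead: np.ndarray,
    mother_dead: np.ndarray,
) -> DerivedOutcome:
    """Average of the two parents' sex-specific z-scored ages at death.

    Only participants with both parents dead (and ages present, i.e. not
    flagged premature) contribute; z-transforms are computed per parent over
    that analysis subsample.
    """
    fa = np.asarray(father_age, dtype=float)
    ma = np.asarray(mother_age, dtype=float)
    both = (
        np.asarray(father_dead, dtype=bool)
        & np.asarray(mother_dead, dtype=bool)
        & ~np.isnan(fa)
        & ~np.isnan(ma)
    )
    values = np.full(fa.shape, np.nan)
    if both.any():
        zf = (fa[both] - fa[both].mean()) / fa[both].std()
        zm = (ma[both] - ma[both].mean()) / ma[both].std()
        values[both] = (zf + zm) / 2.0
    return DerivedOutcome(
        name="parents_age_at_death",
        kind="continuous",
        values=values,
        transform_log=["zscore_by_parent", "average"],
        n_excluded=int((~both).sum()),
    )


def top10_survival(
    father_age: np.ndarray,
    mother_age: np.ndarray,
    father_dead: np.ndarray,
    mother_dead: np.ndarray,
) -> DerivedOutcome:
    """Both parents in the top decile of survival vs both dead before 80.

    Case: father reached >= 87 and mother reached >= 90, regardless of death
    status.  Control: both parents dead before 80.  Everyone else excluded.
    """
    fa = np.asarray(father_age, dtype=float)
    ma = np.asarray(mother_age, dtype=float)
    fd = np.asarray(father_dead, dtype=bool)
    md = np.asarray(mother_dead, dtype=bool)
    with np.errstate(invalid="ignore"):
        case = (fa >= TOP10_FATHER) & (ma >= TOP10_MOTHER)
        control = fd & md & (fa < TOP10_CONTROL_BEFORE) & (ma < TOP10_CONTROL_BEFORE)
    values = np.full(fa.shape, np.nan)
    values[control] = 0.0
    values[case] = 1.0
    return DerivedOutcome(
        name="parents_top10_survival",
        kind="binary",
        values=values,
        n_excluded=int(np.isnan(values).sum()),
    )


def centenarian_status(
    father_age: np.ndarray,
    mother_age: np.ndarray,
    father_dead: np.ndarray,
    mother_dead: np.ndarray,
) -> DerivedOutcome:
    """Near-centenarian parents (father >= 96 or mother >= 100) vs both dead young.

    Controls: father died < 90 and mother died < 95.  Others excluded.
    """
    fa = np.asarray(father_age, dtype=float)
    ma = np.asarray(mother_age, dtype=float)
    fd = np.asarray(father_dead, dtype=bool)
    md = np.asarray(mother_dead, dtype=bool)
    with np.errstate(invalid="ignore"):
        case = (fa >= CENT_FATHER) | (ma >= CENT_MOTHER)
        control = fd & md & (fa < CENT_CONTROL_FATHER) & (ma < CENT_CONTROL_MOTHER)
    values = np.full(fa.shape, np.nan)
    values[control] = 0.0
    values[case] = 1.0
    return DerivedOutcome(
        name="parents_centenarian",
        kind="binary",
        values=values,
        n_excluded=int(np.isnan(values).sum()),
    )


def frailty_index(
    items: pd.DataFrame,
    exclude_cancer: bool = False,
    cancer_items: tuple[str, str] | None = None,
    standardize: bool = True,
) -> DerivedOutcome:
    """Deficit-accumulation frailty index: sum of 49 items, log(x+1), z-score.

    ``exclude_cancer`` drops the two cancer-related items (47-item variant).
    Any missing item excludes the individual.
    """
    if items.shape[1] != N_FRAILTY_ITEMS:
        raise SchemaError(f"expected {N_FRAILTY_ITEMS} deficit items, got {items.shape[1]}")
    complete = ~items.isna().any(axis=1).to_numpy()
    cols = list(items.columns)
    if exclude_cancer:
        drop = list(cancer_items) if cancer_items is not None else cols[-2:]
        cols = [c for c in cols if c not in drop]
    total = items[cols].sum(axis=1).to_numpy(dtype=float)
    values = np.full(len(items), np.nan)
    values[complete] = np.log1p(total[complete])
    log_steps = ["sum_items", "log1p"]
    if standardize:
        values = zscore(values)
        log_steps.append("zscore")
    return DerivedOutcome(
        name="frailty_index_47" if exclude_cancer else "frailty_index_49",
        kind="continuous",
        values=values,
        transform_log=log_steps,
        n_excluded=int((~complete).sum()),
    )


def cognitive_transforms(
    reaction_time_ms: np.ndarray,
    visual_memory_errors: np.ndarray,
    standardize: bool = True,
) -> tuple[DerivedOutcome, DerivedOutcome]:
    """Log-transformed reaction time and log(x+1) visual memory errors, z-scored."""
    rt = np.asarray(reaction_time_ms, dtype=float)
    vm = np.asarray(visual_memory_errors, dtype=float)
    if np.any(rt[~np.isnan(rt)] <= 0):
        raise ValidationError("reaction time must be positive")
    if np.any(vm[~np.isnan(vm)] < 0):
        raise ValidationError("visual memory errors must be non-negative")
    rt_vals, vm_vals = np.log(rt), np.log1p(vm)
    rt_steps, vm_steps = ["log"], ["log1p"]
    if standardize:
        rt_vals, vm_vals = zscore(rt_vals), zscore(vm_vals)
        rt_steps.append("zscore")
        vm_steps.append("zscore")
    rt_out = DerivedOutcome(
        "reaction_time", "continuous", rt_vals,
        transform_log=rt_steps, n_excluded=int(np.isnan(rt).sum()),
    )
    vm_out = DerivedOutcome(
        "visual_memory_errors", "continuous", vm_vals,
        transform_log=vm_steps, n_excluded=int(np.isnan(vm).sum()),
    )
    return rt_out, vm_out


def _sex_cutoff(sex: np.ndarray, cutoffs: dict[str, float]) -> np.ndarray:
    sex = np.asarray(sex, dtype=object)
    unknown = set(np.unique(sex)) - set(cutoffs)
    if unknown:
        raise ValidationError(f"unknown sex code(s): {sorted(map(str, unknown))}")
    return np.array([cutoffs[s] for s in sex], dtype=float)


def sarcopenia(
    grip_max_kg: np.ndarray, smi_kg_m2: np.ndarray, sex: np.ndarray
) -> dict[str, DerivedOutcome]:
    """EWGSOP sarcopenia: low grip strength AND low skeletal muscle mass index.

    Sex-specific strict cutoffs: grip < 30/20 kg, SMI < 8.87/6.42 kg/m²
    (men/women).  Returns the composite plus both components.
    """
    grip = np.asarray(grip_max_kg, dtype=float)
    smi = np.asarray(smi_kg_m2, dtype=float)
    grip_cut = _sex_cutoff(sex, GRIP_CUTOFF)
    smi_cut = _sex_cutoff(sex, SMI_CUTOFF)

    def binarize(name: str, metric: np.ndarray, cut: np.ndarray) -> DerivedOutcome:
        values = np.where(np.isnan(metric), np.nan, (metric < cut).astype(float))
        return DerivedOutcome(name, "binary", values, n_excluded=int(np.isnan(values).sum()))

    low_grip = binarize("low_grip", grip, grip_cut)
    low_muscle = binarize("low_muscle", smi, smi_cut)
    both = low_grip.values * low_muscle.values  # NaN propagates
    sarc = DerivedOutcome(
        "sarcopenia", "binary", both, n_excluded=int(np.isnan(both).sum())
    )
    return {"sarcopenia": sarc, "low_grip": low_grip, "low_muscle": low_muscle}


def fried_frailty(
    weight_loss: np.ndarray,
    exhaustion: np.ndarray,
    slow_pace: np.ndarray,
    grip_max_kg: np.ndarray,
    activity: np.ndarray,
    sex: np.ndarray,
) -> DerivedOutcome:
    """Fried phenotype: frail if >= 3 of 5 criteria.

    Grip and activity criteria are the lowest 20% by sex within the analysis
    sample (all five elements observed); any missing element excludes the
    individual.
    """
    wl = np.asarray(weight_loss, dtype=float)
    ex = np.asarray(exhaustion, dtype=float)
    sp = np.asarray(slow_pace, dtype=float)
    grip = np.asarray(grip_max_kg, dtype=float)
    act = np.asarray(activity, dtype=float)
    sex = np.asarray(sex, dtype=object)
    complete = ~(np.isnan(wl) | np.isnan(ex) | np.isnan(sp) | np.isnan(grip) | np.isnan(act))

    low_grip = np.zeros(len(wl), dtype=bool)
    low_act = np.zeros(len(wl), dtype=bool)
    for s in np.unique(sex):
        m = (sex == s) & complete
        if not m.any():
            continue
        low_grip[m] = grip[m] < np.quantile(grip[m], FRIED_QUANTILE)
        low_act[m] = act[m] < np.quantile(act[m], FRIED_QUANTILE)

    n_crit = wl + ex + sp + low_grip + low_act
    values = np.where(complete, (n_crit >= 3).astype(float), np.nan)
    return DerivedOutcome(
        "fried_frailty", "binary", values, n_excluded=int((~complete).sum())
    )


_DEPRESSION_CONTROL = {"Not at all"}
_DEPRESSION_CASE = {"Several days", "More than half the days", "Nearly every day"}
_DEPRESSION_EXCLUDE = {"Do not know"}
_PAIN_MAP = {"Yes": 1.0, "No": 0.0, "Do not know": np.nan, "Prefer not to answer": np.nan}
_FALLS_MAP = {
    "No falls": 0.0,
    "Only one fall": 1.0,
    "More than one fall": 1.0,
    "Prefer not to answer": np.nan,
}


def _code_responses(responses: np.ndarray, mapping: dict[str, float], name: str) -> np.ndarray:
    values = np.full(len(responses), np.nan)
    for i, resp in enumerate(responses):
        if resp is None or (isinstance(resp, float) and np.isnan(resp)):
            continue  # no response -> excluded
        if resp not in mapping:
            raise ValidationError(f"{name}: unknown response label {resp!r}")
        values[i] = mapping[resp]
    return values


def depression_coding(responses: np.ndarray) -> DerivedOutcome:
    """Any depressed mood ('Not at all' vs everything else; 'Do not know' excluded)."""
    mapping = {r: 1.0 for r in _DEPRESSION_CASE}
    mapping.update({r: 0.0 for r in _DEPRESSION_CONTROL})
    mapping.update({r: np.nan for r in _DEPRESSION_EXCLUDE})
    values = _code_responses(np.asarray(responses, dtype=object), mapping, "depression")
    return DerivedOutcome("depressed", "binary", values, n_excluded=int(np.isnan(values).sum()))


def pain_coding(responses: np.ndarray, site: str = "pain") -> DerivedOutcome:
    values = _code_responses(np.asarray(responses, dtype=object), _PAIN_MAP, site)
    return DerivedOutcome(f"{site}_3mo", "binary", values, n_excluded=int(np.isnan(values).sum()))


def falls_coding(responses: np.ndarray) -> DerivedOutcome:
    """Any fall in the last year ('>= 1 falls' vs 'No falls')."""
    values = _code_responses(np.asarray(responses, dtype=object), _FALLS_MAP, "falls")
    return DerivedOutcome("any_fall", "binary", values, n_excluded=int(np.isnan(values).sum()))
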