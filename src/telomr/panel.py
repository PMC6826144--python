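"""Instrument panel I/O, LD handling, and telomere-length unit conversions.

The exposure is leukocyte telomere length on a standardized (SD) scale.
One SD corresponds to roughly 650 base pairs; adult attrition runs at about
25 bp per year, so 250 bp is approximately one decade of aging.  All
conversions between those scales live here so that every downstream module
rescales identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DuplicateInstrument, SchemaError, ValidationError

log = logging.getLogger(__name__)

PANEL_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta_sd", "se_sd", "locus",
]

_VALID_ALLELES = frozenset("ACGT")

#: Panel exclusion rule: instruments with minor allele frequency < 0.05 are rejected.
MIN_MAF = 0.05


@dataclass(frozen=True)
class ScalingConstants:
    """Conversion constants between SD of telomere length, base pairs and years."""

    bp_per_sd: float = 650.0
    bp_per_year: float = 25.0
    bp_per_decade: float = 250.0

    def __post_init__(self) -> None:
        if min(self.bp_per_sd, self.bp_per_year, self.bp_per_decade) <= 0:
            raise ValidationError("scaling constants must be positive")


DEFAULT_SCALING = ScalingConstants()


@dataclass
class SNPRecord:
    """One instrument: per-allele effect on telomere length in SD units."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta_sd: float
    se_sd: float
    locus: str = ""

    def validate(self) -> None:
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValidationError(f"{self.rsid}: alleles must be single A/C/G/T bases")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele identical")
        if not (MIN_MAF <= self.eaf <= 1 - MIN_MAF):
            raise ValidationError(
                f"{self.rsid}: eaf {self.eaf} outside [{MIN_MAF}, {1 - MIN_MAF}]"
            )
        if not self.se_sd > 0:
            raise ValidationError(f"{self.rsid}: non-positive standard error {self.se_sd}")

    def oriented(self) -> "SNPRecord":
        """Return a copy with the effect allele set to the telomere-lengthening allele."""
        if self.beta_sd >= 0:
            return replace(self)
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta_sd=-self.beta_sd,
        )


@dataclass
class SNPPanel:
    """Ordered instrument set plus the inter-instrument correlation structure.

    ``r2`` holds squared LD correlations; ``r`` its elementwise square root
    with all signs fixed positive (the analysis convention: every effect
    allele lengthens telomeres, so positive correlation is coherent).
    """

    snps: list[SNPRecord]
    r2: np.ndarray
    r: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.r is None:
            self.r = ld_from_r2(self.r2)

    @property
    def J(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    @property
    def eaf(self) -> np.ndarray:
        return np.array([s.eaf for s in self.snps])

    @property
    def beta_sd(self) -> np.ndarray:
        return np.array([s.beta_sd for s in self.snps])

    @property
    def se_sd(self) -> np.ndarray:
        return np.array([s.se_sd for s in self.snps])

    def subset(self, keep: list[int]) -> "SNPPanel":
        idx = np.asarray(keep, dtype=int)
        return SNPPanel(
            snps=[self.snps[i] for i in idx],
            r2=self.r2[np.ix_(idx, idx)].copy(),
            r=self.r[np.ix_(idx, idx)].copy(),
        )


def _check_square_ld(m: np.ndarray, *, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"{name} must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValidationError(f"{name} must be symmetric")
    if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
        raise ValidationError(f"{name} entries must lie in [0, 1]")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ValidationError(f"{name} diagonal must be 1")
    return m


def nearest_psd_correlation(m: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigen-clip a symmetric matrix at ``floor`` and rescale to unit diagonal."""
    w, v = np.linalg.eigh(m)
    w = np.clip(w, floor, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    return (repaired + repaired.T) / 2.0


def ld_from_r2(r2_matrix: np.ndarray) -> np.ndarray:
    """Elementwise square root of an r² matrix, repaired to PSD if needed."""
    r2 = _check_square_ld(r2_matrix, name="r2 matrix")
    r = np.sqrt(np.clip(r2, 0.0, 1.0))
    eig_min = np.linalg.eigvalsh(r).min()
    if eig_min < -1e-10:
        log.warning(
            "sqrt(r2) correlation matrix not PSD (min eigenvalue %.3g); eigen-clipping",
            eig_min,
        )
        r = nearest_psd_correlation(r)
    return r


def load_panel(
    path: str | Path,
    ld_path: str | Path | None = None,
    scaling: ScalingConstants = DEFAULT_SCALING,
) -> SNPPanel:
    """Read a tab-separated instrument table (and optional r² matrix).

    Alleles are flipped on load so every effect allele is the
    telomere-lengthening allele: a negative ``beta_sd`` row is stored with
    swapped alleles, negated beta and complemented frequency.  With no LD
    file the instruments are treated as uncorrelated (identity r²).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty panel file") from exc
    missing = [c for c in PANEL_COLUMNS if c not in df.columns and c != "locus"]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if "locus" not in df.columns:
        df["locus"] = ""
    if df["rsid"].duplicated().any():
        dups = sorted(df.loc[df["rsid"].duplicated(), "rsid"])
        raise DuplicateInstrument(f"duplicate rsid(s): {dups}")

    snps = []
    for row in df.itertuples(index=False):
        rec = SNPRecord(
            rsid=str(row.rsid),
            chrom=str(row.chrom),
            pos=int(row.pos),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            eaf=float(row.eaf),
            beta_sd=float(row.beta_sd),
            se_sd=float(row.se_sd),
            locus=str(row.locus),
        )
        rec = rec.oriented()
        rec.validate()
        snps.append(rec)

    if ld_path is None:
        r2 = np.eye(len(snps))
    else:
        r2 = load_ld_matrix(ld_path, [s.rsid for s in snps])
    return SNPPanel(snps=snps, r2=r2)


def load_ld_matrix(path: str | Path, rsids: list[str]) -> np.ndarray:
    """Read a square r² matrix keyed by rsid, reordered to match ``rsids``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [rs for rs in rsids if rs not in df.index or rs not in df.columns]
    if missing:
        raise SchemaError(f"{path}: LD matrix missing rsids {missing}")
    m = df.loc[rsids, rsids].to_numpy(dtype=float)
    return _check_square_ld(m, name="LD matrix")


def write_panel(panel: SNPPanel, path: str | Path) -> None:
    """Write the panel back out in the canonical tab-separated layout."""
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for s in panel.snps:
            fh.write(
                f"{s.rsid}\t{s.chrom}\t{s.pos}\t{s.effect_allele}\t{s.other_allele}\t"
                f"{float(s.eaf)}\t{float(s.beta_sd)}\t{float(s.se_sd)}\t{s.locus}\n"
            )


def write_ld_matrix(panel: SNPPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rsid\t" + "\t".join(panel.rsids) + "\n")
        for rs, row in zip(panel.rsids, panel.r2):
            fh.write(rs + "\t" + "\t".join(str(float(v)) for v in row) + "\n")


def prune_perfect_ld(panel: SNPPanel, tol: float = 1e-12) -> SNPPanel:
    """Drop the later-listed instrument of every pair in perfect LD (r² = 1)."""
    keep: list[int] = []
    for j in range(panel.J):
        redundant = any(abs(panel.r2[i, j] - 1.0) <= tol for i in keep)
        if redundant:
            prior = [panel.rsids[i] for i in keep if abs(panel.r2[i, j] - 1.0) <= tol]
            log.info("dropping %s: perfect LD with %s", panel.rsids[j], prior[0])
        else:
            keep.append(j)
    if len(keep) == panel.J:
        return panel
    return panel.subset(keep)


def default_panel() -> SNPPanel:
    """The shipped 13-instrument fixture panel with its r² matrix.

    Per-SNP betas/SEs/frequencies are synthetic placeholders calibrated so
    the uncorrelated variance explained totals 2.23%; they are not
    transcriptions of any published supplement.
    """
    data = resources.files("telomr.data")
    with resources.as_file(data / "panel_13snp.tsv") as p, resources.as_file(
        data / "ld_13snp.tsv"
    ) as ld:
        return load_panel(p, ld)


def bp_rescale(
    effect: float,
    target_bp: float,
    scaling: ScalingConstants = DEFAULT_SCALING,
    *,
    odds_ratio: bool = False,
    source_bp: float | None = None,
) -> float:
    """Rescale a per-SD effect to a per-``target_bp`` effect.

    Log-scale effects (log-odds, or SD change of the outcome) multiply by
    ``target_bp / source_bp``; odds ratios exponentiate with the same
    factor.  ``source_bp`` defaults to one SD of telomere length.
    """
    if target_bp <= 0:
        raise ValidationError(f"target_bp must be positive, got {target_bp}")
    src = scaling.bp_per_sd if source_bp is None else source_bp
    if src <= 0:
        raise ValidationError(f"source_bp must be positive, got {src}")
    factor = target_bp / src
    if odds_ratio:
        if effect <= 0:
            raise ValidationError("odds ratios must be positive")
        return float(effect**factor)
    return float(effect * factor)


def years_equivalent(bp: float, scaling: ScalingConstants = DEFAULT_SCALING) -> float:
    """Years of adult telomere attrition equivalent to ``bp`` base pairs."""
    return float(bp / scaling.bp_per_year)


def natural_units(effect_sd: float, outcome_sd: float) -> float:
    """Convert a standardized effect back to the outcome's measurement units.

    E.g. a 0.031 SD change in systolic blood pressure with SD 19.77 mm Hg
    is 0.61 mm Hg.
    """
    if outcome_sd <= 0:
        raise ValidationError("outcome SD must be positive")
    return float(effect_sd * outcome_sd)
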