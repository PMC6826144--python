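"""Pipeline orchestration: simulate -> derive -> scan -> MR -> power -> report.

Stages communicate through plain tab-separated files so each can be rerun
independently; a JSON manifest records the config hash, seed, library
versions and per-stage row counts.  Identical config + seed yields
byte-identical result tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, mr, phenotypes, power
from .errors import ValidationError
from .panel import DEFAULT_SCALING, SNPPanel, ScalingConstants, default_panel, load_panel
from .simulate import SimulationSpec, simulate_cohort

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 1,
    "n": 20000,
    "panel": "default",
    "ld": None,
    "target_r2": 0.0223,
    "causal_effects": {"cancer": 0.10, "chd": -0.05, "biomarker": 0.05},
    "prevalences": {"cancer": 0.14, "chd": 0.08},
    "strata": [["all", "all"], ["40-60", "all"], ["60+", "all"]],
    "methods": ["ivw", "maxlik", "egger"],
    "fdr_alpha": 0.05,
    "fdr_method": "maxlik",
    "fdr_stratum": "60+/all",
    "target_bp": 250.0,
    "power_alpha": 0.01,
    "power_or": 1.2,
    "power_beta": 0.1,
    "cutoff_method": "kde_halfnormal",
    "covariates": list(assoc.DEFAULT_COVARIATES),
}


def load_config(path: str | Path | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg.update(user)
    if cfg.get("seed") is None:
        raise ValidationError("a seed is mandatory for simulation runs")
    return cfg


def config_hash(cfg: dict) -> str:
    canonical = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def resolve_panel(cfg: dict) -> SNPPanel:
    if cfg.get("panel") in (None, "default"):
        return default_panel()
    path = Path(cfg["panel"])
    if not path.exists():
        raise ValidationError(f"panel file not found: {path}")
    ld = cfg.get("ld")
    if ld is not None and not Path(ld).exists():
        raise ValidationError(f"LD file not found: {ld}")
    return load_panel(path, ld)


def simulation_spec(cfg: dict, panel: SNPPanel) -> SimulationSpec:
    return SimulationSpec(
        n=int(cfg["n"]),
        seed=int(cfg["seed"]),
        panel=panel,
        target_r2=float(cfg["target_r2"]),
        causal_effects={k: float(v) for k, v in cfg["causal_effects"].items()},
        prevalences={k: float(v) for k, v in cfg["prevalences"].items()},
    )


def derive_outcomes(
    cohort: pd.DataFrame, cfg: dict | None = None
) -> dict[str, phenotypes.DerivedOutcome]:
    """The default outcome registry applied to a simulated cohort."""
    cfg = cfg or DEFAULT_CONFIG
    out: dict[str, phenotypes.DerivedOutcome] = {}

    for name in cfg["causal_effects"]:
        values = cohort[name].to_numpy(dtype=float)
        if name in cfg["prevalences"]:
            out[name] = phenotypes.DerivedOutcome(name, "binary", values)
        else:
            out[name] = phenotypes.DerivedOutcome(
                name, "continuous", phenotypes.zscore(values), transform_log=["zscore"]
            )

    fa = cohort["father_age"].to_numpy(dtype=float)
    ma = cohort["mother_age"].to_numpy(dtype=float)
    fd = cohort["father_dead"].to_numpy(dtype=bool)
    md = cohort["mother_dead"].to_numpy(dtype=bool)
    method = cfg.get("cutoff_method", "kde_halfnormal")
    fa_cut = phenotypes.early_death_cutoff(fa[fd], method=method)
    ma_cut = phenotypes.early_death_cutoff(ma[md], method=method)
    fa_adj = phenotypes.apply_early_death_cutoff(fa, fd, fa_cut.cutoff)
    ma_adj = phenotypes.apply_early_death_cutoff(ma, md, ma_cut.cutoff)
    out["parents_age_at_death"] = phenotypes.parental_lifespan_z(fa_adj, ma_adj, fd, md)
    out["parents_top10_survival"] = phenotypes.top10_survival(fa_adj, ma_adj, fd, md)
    out["parents_centenarian"] = phenotypes.centenarian_status(fa_adj, ma_adj, fd, md)

    deficits = cohort[[c for c in cohort.columns if c.startswith("deficit_")]]
    out["frailty_index_49"] = phenotypes.frailty_index(deficits, exclude_cancer=False)
    out["frailty_index_47"] = phenotypes.frailty_index(deficits, exclude_cancer=True)

    rt, vm = phenotypes.cognitive_transforms(
        cohort["reaction_time_ms"].to_numpy(), cohort["visual_memory_errors"].to_numpy()
    )
    out["reaction_time"] = rt
    out["visual_memory_errors"] = vm

    sex = cohort["sex"].to_numpy()
    out.update(
        phenotypes.sarcopenia(
            cohort["grip_max_kg"].to_numpy(), cohort["smi_kg_m2"].to_numpy(), sex
        )
    )
    slow = (cohort["walking_pace"] == "Slow pace").astype(float).to_numpy()
    out["fried_frailty"] = phenotypes.fried_frailty(
        cohort["weight_loss"].to_numpy(),
        cohort["exhaustion"].to_numpy(),
        slow,
        cohort["grip_max_kg"].to_numpy(),
        cohort["activity_met_min"].to_numpy(),
        sex,
    )

    out["depressed"] = phenotypes.depression_coding(cohort["depression_response"].to_numpy())
    for site in ("back", "hip", "knee"):
        out[f"{site}_pain"] = phenotypes.pain_coding(
            cohort[f"{site}_pain_response"].to_numpy(), site=f"{site}_pain"
        )
    out["any_fall"] = phenotypes.falls_coding(cohort["falls_response"].to_numpy())
    out["systolic_bp"] = phenotypes.DerivedOutcome(
        "systolic_bp",
        "continuous",
        phenotypes.zscore(cohort["systolic_bp"].to_numpy(dtype=float)),
        transform_log=["zscore"],
    )
    return out


def mr_from_scan(
    panel: SNPPanel,
    scan_table: pd.DataFrame,
    methods: tuple[str, ...] = ("ivw", "maxlik", "egger"),
    scaling: ScalingConstants = DEFAULT_SCALING,
    target_bp: float = 250.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run MR per outcome/stratum from a scan results table.

    Returns (MR results table, Egger scatter export of per-SNP points).
    """
    rows, scatter = [], []
    for (outcome, stratum), grp in scan_table.groupby(["outcome", "stratum"], sort=True):
        grp = grp.set_index("rsid").loc[panel.rsids]
        inp = mr.MRInput(
            bx=panel.beta_sd,
            bxse=panel.se_sd,
            by=grp["beta"].to_numpy(),
            byse=grp["se"].to_numpy(),
            rho=panel.r,
            labels=panel.rsids,
        )
        fits = mr.run_methods(inp, methods, scaling, target_bp)
        for name, res in fits.items():
            rows.append(
                {
                    "outcome": outcome,
                    "stratum": stratum,
                    "method": name,
                    "theta": res.theta,
                    "se": res.se,
                    "p": res.p,
                    "q": res.Q,
                    "egger_intercept": res.egger_intercept,
                    "egger_intercept_p": res.egger_intercept_p,
                    "n": int(grp["n"].iloc[0]),
                    "n_cases": grp["n_cases"].iloc[0],
                }
            )
        if "egger" in fits:
            e = fits["egger"]
            for rsid, bx, by in zip(panel.rsids, panel.beta_sd, grp["beta"]):
                scatter.append(
                    {
                        "outcome": outcome,
                        "stratum": stratum,
                        "rsid": rsid,
                        "bx": bx,
                        "by": by,
                        "fitted": e.egger_intercept + e.theta * bx,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(scatter)


def power_table(
    mr_results: pd.DataFrame,
    outcomes: dict[str, phenotypes.DerivedOutcome],
    cfg: dict,
    stratum: str | None = None,
) -> pd.DataFrame:
    """Analytic power per outcome at the design effect sizes (OR 1.2 / 0.1 SD)."""
    stratum = stratum or cfg["fdr_stratum"]
    sub = mr_results[mr_results["stratum"] == stratum]
    rows = []
    for outcome, grp in sub.groupby("outcome"):
        n = int(grp["n"].iloc[0])
        kind = outcomes[outcome].kind
        if kind == "binary":
            k = float(grp["n_cases"].iloc[0]) / n
            spec = power.PowerSpec(
                n=n, r2=cfg["target_r2"], effect=cfg["power_or"],
                alpha=cfg["power_alpha"], case_fraction=k,
            )
            pw = power.power_binary(spec)
        else:
            spec = power.PowerSpec(
                n=n, r2=cfg["target_r2"], effect=cfg["power_beta"], alpha=cfg["power_alpha"]
            )
            pw = power.power_continuous(spec)
        rows.append({"outcome": outcome, "n": n, "power": pw,
                     "low_power": power.flag_low_power(pw)})
    return pd.DataFrame(rows)


def report_forest(results: pd.DataFrame, fdr_alpha: float = 0.05,
                  method: str = "maxlik") -> pd.DataFrame:
    """Per-outcome, per-stratum forest table: OR/beta per 250 bp with CIs.

    ``bold`` flags rows whose FDR-adjusted p is strictly below ``fdr_alpha``.
    """
    cols = ["outcome", "stratum", "or_250bp", "or_ci_low_250bp", "or_ci_high_250bp",
            "theta_250bp", "ci_low_250bp", "ci_high_250bp", "p", "p_fdr"]
    if results.empty:
        return pd.DataFrame(columns=cols + ["bold"])
    sub = results[results["method"] == method][cols].copy()
    sub["bold"] = sub["p_fdr"] < fdr_alpha
    sub.loc[sub["p_fdr"].isna(), "bold"] = False
    return sub.reset_index(drop=True)


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run(cfg: dict, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = resolve_panel(cfg)
    spec = simulation_spec(cfg, panel)

    log.info("simulating cohort: n=%d seed=%d", spec.n, spec.seed)
    cohort = simulate_cohort(spec)
    write_tsv(cohort, outdir / "cohort.tsv")

    outcomes = derive_outcomes(cohort, cfg)
    derived = pd.DataFrame({name: o.values for name, o in outcomes.items()})
    write_tsv(derived, outdir / "derived_outcomes.tsv")

    scan_frames = []
    for age_s, sex_s in cfg["strata"]:
        results = assoc.scan(
            panel, cohort, outcomes, age_stratum=age_s, sex_stratum=sex_s,
            covariates=cfg["covariates"],
        )
        scan_frames.append(assoc.results_table(results, panel))
    scan_table = pd.concat(scan_frames, ignore_index=True)
    write_tsv(scan_table, outdir / "assoc.tsv")

    scaling = DEFAULT_SCALING
    mr_results, scatter = mr_from_scan(
        panel, scan_table, tuple(cfg["methods"]), scaling, cfg["target_bp"]
    )
    pw = power_table(mr_results, outcomes, cfg)
    final = mr.finalize(
        mr_results, scaling, cfg["target_bp"],
        fdr_method=cfg["fdr_method"], fdr_stratum=cfg["fdr_stratum"], power_table=pw,
    )
    write_tsv(final, outdir / "mr_results.tsv")
    write_tsv(scatter, outdir / "egger_scatter.tsv")
    write_tsv(pw, outdir / "power.tsv")
    forest = report_forest(final, cfg["fdr_alpha"], cfg["fdr_method"])
    write_tsv(forest, outdir / "forest.tsv")

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "versions": {
            "telomr": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "rows": {
            "cohort": len(cohort),
            "assoc": len(scan_table),
            "mr_results": len(final),
            "power": len(pw),
        },
        "exclusions": {
            name: {"analyzed": o.n, "excluded": int(math.fsum([o.n_excluded]))}
            for name, o in outcomes.items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
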