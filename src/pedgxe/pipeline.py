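"""Panel orchestration: preprocess -> stage-1/2/3 inference across a trait
panel from a single configuration, with table- and figure-ready exports.

A per-trait failure is quarantined (recorded in the bundle's ``errors``)
rather than aborting the panel, mirroring a real multi-trait screen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as prep
from .covariance import function_grid
from .inference import TestResult, adjust_pvalues, test_gxe_components, test_gxe_joint, test_heritability
from .likelihood import FitResult, LikelihoodData, prepare_data
from .pedigree import Pedigree, read_pedigree

__all__ = ["RunConfig", "PanelResult", "run_panel", "export_tables",
           "export_function_grids", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One panel run: inputs, per-trait covariates, and model options."""

    pedigree_path: str = ""
    phenotype_path: str = ""
    traits: dict[str, list[str]] = field(default_factory=dict)  # trait -> covariates
    exclusion_flags: list[str] = field(default_factory=lambda: list(prep.DEFAULT_EXCLUSION_FLAGS))
    sei_column: str = "sei"
    education_column: str = "education"
    zses_column: str = "zses"        # used directly if present in the file
    zses_sample: str = "post-exclusion"  # or "recruited"
    alpha: float = 0.05
    adjust_method: str = "bonferroni"
    stage3_m: int = 1                    # adjustment multiplier per stage-3 test
    n_starts: int = 5
    seed: int = 0
    grid: tuple[float, float, float] = (-3.0, 3.0, 0.1)
    outdir: str = "pedgxe_out"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.zses_sample not in ("post-exclusion", "recruited"):
            raise ValueError("zses_sample must be 'post-exclusion' or 'recruited'")

    def validate_against(self, frame: pd.DataFrame) -> None:
        if not self.traits:
            raise ValueError("config lists no traits")
        missing = [
            c for t, covs in self.traits.items() for c in [t, *covs]
            if c not in frame.columns
        ]
        if missing:
            raise ValueError(f"config references absent columns: {sorted(set(missing))}")


def load_config(path) -> RunConfig:
    """Read a YAML config file into a RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "grid" in raw:
        raw["grid"] = tuple(raw["grid"])
    return RunConfig(**raw)


@dataclass
class TraitResult:
    trait: str
    n: int
    r_squared: float
    chosen_model: int
    fits: dict[str, FitResult]
    stage1: list[TestResult]
    stage2: TestResult | None = None
    stage3: list[TestResult] = field(default_factory=list)
    gxe_fit: FitResult | None = None
    data: LikelihoodData | None = None


@dataclass
class PanelResult:
    traits: dict[str, TraitResult]
    errors: dict[str, str]
    config: RunConfig
    manifest: dict


def run_panel(
    config: RunConfig,
    ped: Pedigree | None = None,
    frame: pd.DataFrame | None = None,
) -> PanelResult:
    """Run the full three-stage screen over the configured trait panel.

    ``ped`` and ``frame`` may be passed directly (e.g. from the simulator);
    otherwise they are read from the configured paths.
    """
    if ped is None:
        ped = read_pedigree(config.pedigree_path)
    if frame is None:
        frame = pd.read_csv(config.phenotype_path, sep=None, engine="python",
                            na_values=["NA"])
    frame = frame.copy()
    frame["id"] = frame["id"].astype(str)
    config.validate_against(frame)

    if config.zses_column in frame.columns:
        frame["zses"] = frame[config.zses_column].astype(float)
    else:
        # standardize within the analysis sample by default: excluded rows
        # neither shape the mean/SD nor receive a score
        sei = frame[config.sei_column].to_numpy(dtype=float)
        edu = frame[config.education_column].to_numpy(dtype=float)
        if config.zses_sample == "post-exclusion":
            kept_ids = set(prep.apply_exclusions(frame, config.exclusion_flags)["id"])
            mask = frame["id"].isin(kept_ids).to_numpy()
            sei = np.where(mask, sei, np.nan)
            edu = np.where(mask, edu, np.nan)
        frame["zses"] = prep.zses_score(sei, edu)

    fit_kw = dict(seed=config.seed, n_starts=config.n_starts)
    results: dict[str, TraitResult] = {}
    errors: dict[str, str] = {}
    for trait, covariates in config.traits.items():
        try:
            table = prep.preprocess_trait(frame, trait, covariates,
                                          exclusion_flags=config.exclusion_flags)
            data = prepare_data(ped, table)
            log.info("trait %s: n=%d complete cases in %d blocks",
                     trait, data.n, data.n_blocks)
            chosen, fits, stage1 = test_heritability(data, alpha=config.alpha, **fit_kw)
            results[trait] = TraitResult(
                trait=trait, n=data.n, r_squared=table.attrs.get("r_squared", 0.0),
                chosen_model=chosen, fits=fits, stage1=stage1, data=data,
            )
        except Exception as err:  # noqa: BLE001 - quarantine the trait
            log.error("trait %s failed at stage 1: %s", trait, err)
            errors[trait] = str(err)

    # stage 2 on heritable traits, adjusted across the configured panel size
    m_panel = len(config.traits)
    stage2_traits = [
        t for t, r in results.items()
        if r.stage1[0].p < config.alpha
    ]
    raw_ps = []
    for trait in stage2_traits:
        r = results[trait]
        base = r.fits["model2"] if r.chosen_model == 2 else r.fits["model1"]
        try:
            r.stage2 = test_gxe_joint(r.data, base_model=r.chosen_model,
                                      base_fit=base, **fit_kw)
            r.gxe_fit = r.stage2.fit_full
            raw_ps.append(r.stage2.p)
        except Exception as err:  # noqa: BLE001
            log.error("trait %s failed at stage 2: %s", trait, err)
            errors[trait] = str(err)
            raw_ps.append(np.nan)
    if raw_ps:
        ok = ~np.isnan(raw_ps)
        adj = np.full(len(raw_ps), np.nan)
        adj[ok] = adjust_pvalues(np.asarray(raw_ps)[ok], m=m_panel,
                                 method=config.adjust_method)
        for trait, a in zip(stage2_traits, adj):
            if results[trait].stage2 is not None and np.isfinite(a):
                results[trait].stage2.p_adjusted = float(a)

    # stage 3 only on stage-2 survivors (gatekeeping)
    for trait in stage2_traits:
        r = results[trait]
        if r.stage2 is None or not (r.stage2.p_adjusted < config.alpha):
            continue
        try:
            r.stage3 = test_gxe_components(
                r.data, base_model=r.chosen_model, full_fit=r.gxe_fit,
                m_adjust=config.stage3_m, **fit_kw)
        except Exception as err:  # noqa: BLE001
            log.error("trait %s failed at stage 3: %s", trait, err)
            errors[trait] = str(err)

    manifest = {
        "seed": config.seed,
        "alpha": config.alpha,
        "adjust_method": config.adjust_method,
        "n_starts": config.n_starts,
        "panel_size": m_panel,
        "traits": {
            t: {
                "n": r.n,
                "chosen_model": r.chosen_model,
                "stage2_run": r.stage2 is not None,
                "stage3_run": bool(r.stage3),
            }
            for t, r in results.items()
        },
        "errors": errors,
    }
    return PanelResult(traits=results, errors=errors, config=config, manifest=manifest)


_MISSING = "-----"  # marker for components absent from a trait's model


def export_tables(bundle: PanelResult, outdir) -> dict[str, Path]:
    """Write the three result tables.

    ``heritability.csv``: per-trait N, h^2 (SE) and its p, c^2 (SE) and its
    p for model-2 traits, covariate variance share.  ``gxe_joint.csv``: the
    panel-adjusted joint GxE p-value per heritable trait.
    ``gxe_components.csv``: the five component-test p-values per stage-3
    trait, with the missing marker for household columns of model-1 traits.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows1, rows2, rows3 = [], [], []
    for trait, r in bundle.traits.items():
        fit = r.fits["model2"] if r.chosen_model == 2 else r.fits["model1"]
        h2, c2 = fit.heritability()
        h2_se = fit.h2_se(r.data) if r.data is not None else float("nan")
        herit_p = r.stage1[0].p
        house = next((t for t in r.stage1 if t.name == "household_variance_zero"), None)
        if r.chosen_model == 2:
            c2_se = fit.c2_se(r.data) if r.data is not None else float("nan")
            c2_cell = f"{c2:.2f} ({c2_se:.2f})"
            c2_p = f"{house.p:.3g}" if house else _MISSING
        else:
            c2_cell, c2_p = _MISSING, _MISSING
        rows1.append({
            "trait": trait, "n": r.n,
            "h2": round(h2, 4), "h2_se": round(h2_se, 4), "h2_p": herit_p,
            "c2": c2_cell, "c2_p": c2_p,
            "covariate_variance_share": round(r.r_squared, 4),
        })
        if r.stage2 is not None:
            rows2.append({"trait": trait, "p_adjusted": f"{r.stage2.p_adjusted:.5f}",
                          "stat": round(r.stage2.stat, 4), "df": r.stage2.df})
        if r.stage3:
            by_name = {t.name: t for t in r.stage3}
            row = {"trait": trait}
            for _, label, _null in (
                ("gamma_g", "homogeneous_genetic_variance", None),
                ("gamma_e", "homogeneous_residual_variance", None),
                ("gamma_c", "homogeneous_household_variance", None),
                ("lambda_g", "genetic_correlation_equals_1", None),
                ("lambda_c", "household_correlation_equals_1", None),
            ):
                t = by_name.get(label)
                row[label] = f"{t.p_adjusted:.5f}" if t is not None else _MISSING
            rows3.append(row)
    # per-trait fit report: estimates, SEs, loglik, convergence flags
    fit_rows = []
    for trait, r in bundle.traits.items():
        labelled = [("model2" if r.chosen_model == 2 else "model1",
                     r.fits["model2"] if r.chosen_model == 2 else r.fits["model1"])]
        if r.gxe_fit is not None:
            labelled.append(("gxe", r.gxe_fit))
        for label, fit in labelled:
            base = {"trait": trait, "model": label,
                    "loglik": round(fit.loglik, 6), "status": fit.status,
                    "n": fit.n, "n_blocks": fit.n_blocks}
            for pname in fit.free_names:
                fit_rows.append({**base, "parameter": pname,
                                 "estimate": round(getattr(fit.params, pname), 6),
                                 "se": round(fit.se[pname], 6)
                                 if np.isfinite(fit.se[pname]) else "",
                                 "boundary": fit.boundary.get(pname, False)})
            for xname, b in zip(fit.x_names, fit.params.beta):
                fit_rows.append({**base, "parameter": f"beta_{xname}",
                                 "estimate": round(b, 6),
                                 "se": round(fit.beta_se[xname], 6)
                                 if np.isfinite(fit.beta_se.get(xname, np.nan)) else "",
                                 "boundary": False})
    paths = {}
    for name, rows in (("heritability", rows1), ("gxe_joint", rows2),
                       ("gxe_components", rows3), ("fit_params", fit_rows)):
        path = outdir / f"{name}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        paths[name] = path
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = outdir / "manifest.json"
    return paths


def export_function_grids(bundle: PanelResult, outdir, z_range=None, step=None) -> dict[str, Path]:
    """Per fitted-GxE trait: component-variance curves over the z grid and
    the genetic-covariance surface over (z_i, z_j)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lo, hi, st = bundle.config.grid
    if z_range is not None:
        lo, hi = z_range
    if step is not None:
        st = step
    grid = np.round(np.arange(lo, hi + st / 2, st), 10)
    paths = {}
    for trait, r in bundle.traits.items():
        if r.gxe_fit is None:
            continue
        tabs = function_grid(r.gxe_fit.params, r.gxe_fit.spec, grid)
        comp_path = outdir / f"{trait}_functions.csv"
        surf_path = outdir / f"{trait}_surface.csv"
        tabs["components"].to_csv(comp_path, index=False, float_format="%.10g")
        tabs["surface"].to_csv(surf_path, index=False, float_format="%.10g")
        paths[f"{trait}_functions"] = comp_path
        paths[f"{trait}_surface"] = surf_path
    return paths
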