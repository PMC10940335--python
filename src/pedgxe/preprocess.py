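"""Trait preprocessing: zSES construction, exclusion filters, covariate
residualization, rank-based inverse-normal transformation, the SES mediation
screen, and a metabolic-syndrome criteria classifier.

Missing values are never imputed; every operation propagates missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "zses_score",
    "apply_exclusions",
    "residualize",
    "inverse_normalize",
    "mediation_screen",
    "ms_classify",
    "preprocess_trait",
]

log = logging.getLogger(__name__)

#: default exclusion-flag columns: disease or medication altering metabolism
DEFAULT_EXCLUSION_FLAGS = ("diabetes", "diabetes_meds", "htn_meds", "dyslipidemia_meds")


def _standardize(x: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with the n-1 denominator, NaN-propagating."""
    m = np.nanmean(x)
    s = np.nanstd(x, ddof=1)
    if not np.isfinite(s) or s == 0:
        raise ValueError("cannot standardize a zero-variance vector")
    return (x - m) / s


def zses_score(sei, education) -> np.ndarray:
    """Standardized socioeconomic score: standardize(standardize(SEI) +
    standardize(education)).

    Entries with either input missing are missing; the output has sample mean
    0 and SD 1 over the non-missing entries.  Invariant to affine rescaling of
    either input, so SEI may come in any units.
    """
    sei = np.asarray(sei, dtype=float)
    edu = np.asarray(education, dtype=float)
    if sei.shape != edu.shape:
        raise ValueError("SEI and education vectors differ in length")
    if np.sum(np.isfinite(sei)) < 2 or np.sum(np.isfinite(edu)) < 2:
        raise ValueError("need at least 2 non-missing values in each input")
    total = _standardize(sei) + _standardize(edu)
    return _standardize(total)


def apply_exclusions(table: pd.DataFrame, flags=DEFAULT_EXCLUSION_FLAGS) -> pd.DataFrame:
    """Drop rows with any exclusion flag set (missing flag = not excluded).

    Pure filter: retained rows are returned unaltered.
    """
    present = [c for c in flags if c in table.columns]
    if not present:
        return table.copy()
    flagged = table[present].fillna(0).astype(float).gt(0).any(axis=1)
    log.info("exclusion filter removed %d of %d rows", int(flagged.sum()), len(table))
    return table.loc[~flagged].copy()


def residualize(trait, covariates: pd.DataFrame | None = None) -> tuple[np.ndarray, float]:
    """OLS residuals of the trait on an intercept plus the covariate columns.

    Only complete cases (trait and all covariates observed) get residuals;
    other entries are NaN.  Returns ``(residuals, r_squared)`` where the R^2
    is the proportion of trait variance accounted for by the covariates
    (0.0 when there are none).
    """
    y = np.asarray(trait, dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        ok = np.isfinite(y)
        if not ok.any():
            raise ValueError("no complete cases: trait entirely missing")
        out = np.full(y.shape, np.nan)
        out[ok] = y[ok] - y[ok].mean()
        return out, 0.0
    x = np.asarray(covariates, dtype=float)
    ok = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
    if not ok.any():
        raise ValueError("no complete cases for trait and covariates")
    design = sm.add_constant(x[ok], has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which columns are linearly dependent on the preceding ones
        bad = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) == np.linalg.matrix_rank(design[:, :j]):
                bad.append(covariates.columns[j - 1])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y[ok], design).fit()
    out = np.full(y.shape, np.nan)
    out[ok] = fit.resid
    return out, float(fit.rsquared)


def inverse_normalize(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offset by default).

    Maps value with (tie-averaged) rank r among n observed values to
    ``Phi^-1((r - c) / (n - 2c + 1))`` with c the offset (Blom: 3/8, giving
    the familiar (r - 3/8)/(n + 1/4)).  Strictly rank-preserving on distinct
    values; missing entries stay missing.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.nanstd(x) == 0:
        raise ValueError("all values identical; rank transform undefined")
    ranks = stats.rankdata(x[ok])
    out = np.full(x.shape, np.nan)
    out[ok] = stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))
    return out


def mediation_screen(zses, covariate, m: int = 1) -> tuple[float, float]:
    """Screen one covariate as a potential mediator of the SES score.

    Simple linear regression with zSES as the dependent variable and the
    covariate as the predictor; returns the two-sided t-test p-value for the
    slope, raw and Bonferroni-adjusted for ``m`` screens (min(1, m*p)).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    z = np.asarray(zses, dtype=float)
    c = np.asarray(covariate, dtype=float)
    ok = np.isfinite(z) & np.isfinite(c)
    if np.std(c[ok]) == 0:
        raise ValueError("zero-variance covariate")
    res = stats.linregress(c[ok], z[ok])
    p = float(res.pvalue)
    return p, min(1.0, m * p)


def mediation_report(frame: pd.DataFrame, covariates: list[str],
                     zses: str = "zses") -> pd.DataFrame:
    """Screen several candidate mediators of the SES score at once.

    One simple regression per covariate with zSES as the outcome; the
    Bonferroni multiplier is the number of covariates screened.  Returns a
    frame with columns covariate, slope, p_raw, p_adjusted.
    """
    m = len(covariates)
    rows = []
    z = frame[zses].to_numpy(dtype=float)
    for name in covariates:
        c = frame[name].to_numpy(dtype=float)
        ok = np.isfinite(z) & np.isfinite(c)
        res = stats.linregress(c[ok], z[ok])
        rows.append({"covariate": name, "slope": res.slope,
                     "p_raw": res.pvalue,
                     "p_adjusted": min(1.0, m * res.pvalue)})
    return pd.DataFrame(rows)


#: metabolic-syndrome criteria (trait units: mg/dL, mmHg)
MS_THRESHOLDS = {
    "triglycerides": 150.0,   # TG above this flags
    "hdl_male": 40.0,         # HDL below this flags (men)
    "hdl_female": 50.0,       # HDL below this flags (women)
    "sbp": 135.0,             # either blood-pressure bound at/above flags
    "dbp": 85.0,
    "fasting_glucose": 100.0, # FG above this flags
}


def ms_classify(
    traits: pd.DataFrame,
    sex,
    threshold: int = 3,
    bp_at_or_above: bool = True,
) -> pd.Series:
    """Metabolic-syndrome status from four criteria flags.

    Expects columns ``triglycerides``, ``hdl``, ``sbp``, ``dbp``,
    ``fasting_glucose`` in mg/dL / mmHg and a sex vector ("male"/"female" or
    M/F/1/2).  Flags: TG > 150; HDL < 40 (men) / < 50 (women); blood pressure
    >= 135/85 on either bound; fasting glucose > 100.  Status is positive
    when at least ``threshold`` flags are set; a missing component leaves its
    flag missing, and the status is missing when the observed flags cannot
    determine it either way.
    """
    sex_norm = pd.Series(sex, index=traits.index).map(
        {"male": "male", "female": "female", "M": "male", "F": "female",
         1: "male", 2: "female", "1": "male", "2": "female"}
    )
    if sex_norm.isna().any():
        bad = pd.Series(sex, index=traits.index)[sex_norm.isna()].unique()
        raise ValueError(f"unknown sex code(s): {list(bad)}")

    t = traits
    flags = pd.DataFrame(index=traits.index, dtype=float)
    flags["tg"] = (t["triglycerides"] > MS_THRESHOLDS["triglycerides"]).where(
        t["triglycerides"].notna()
    )
    hdl_cut = sex_norm.map({"male": MS_THRESHOLDS["hdl_male"], "female": MS_THRESHOLDS["hdl_female"]})
    flags["hdl"] = (t["hdl"] < hdl_cut).where(t["hdl"].notna())
    if bp_at_or_above:
        bp = (t["sbp"] >= MS_THRESHOLDS["sbp"]) | (t["dbp"] >= MS_THRESHOLDS["dbp"])
    else:
        bp = (t["sbp"] < MS_THRESHOLDS["sbp"]) | (t["dbp"] < MS_THRESHOLDS["dbp"])
    flags["bp"] = bp.where(t["sbp"].notna() & t["dbp"].notna())
    flags["fg"] = (t["fasting_glucose"] > MS_THRESHOLDS["fasting_glucose"]).where(
        t["fasting_glucose"].notna()
    )

    set_count = flags.sum(axis=1, skipna=True)
    n_missing = flags.isna().sum(axis=1)
    status = pd.Series(np.nan, index=traits.index, dtype=float)
    status[set_count >= threshold] = 1.0
    status[(set_count + n_missing) < threshold] = 0.0
    return status


def preprocess_trait(
    table: pd.DataFrame,
    trait: str,
    covariates: list[str] | None = None,
    exclusion_flags=DEFAULT_EXCLUSION_FLAGS,
    inverse_normal: bool = True,
) -> pd.DataFrame:
    """Standard per-trait pipeline: exclusions, residualization on the listed
    covariates, then rank-based inverse normalization.

    Returns a frame with columns ``id``, ``y`` (the analysis-ready trait) and
    ``zses`` (carried through), with an ``r_squared`` attribute recording the
    covariate variance share.
    """
    kept = apply_exclusions(table, exclusion_flags)
    cov = kept[covariates] if covariates else None
    resid, r2 = residualize(kept[trait], cov)
    y = inverse_normalize(resid) if inverse_normal else resid
    out = pd.DataFrame({"id": kept["id"].astype(str), "y": y})
    if "zses" in kept.columns:
        out["zses"] = kept["zses"].to_numpy()
    out.attrs["r_squared"] = r2
    out.attrs["n_excluded"] = len(table) - len(kept)
    return out
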