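"""Likelihood-ratio testing: heritability/household screening, the joint
GxE test, component-wise GxE tests, and multiple-testing adjustment.

Null distributions are boundary-aware.  A variance component or a decay
rate is constrained to the edge of its space under the null, so the LRT
statistic is asymptotically an equal mixture of a point mass at 0 and a
chi-square with 1 df; the resulting p-value is ``0.5 * P(chi2_1 >= stat)``
and is exactly 0.5 when the estimate itself sits on the boundary.  Slope
parameters (the gammas) are interior and use a plain chi2(1).  The joint
GxE test uses chi2 with df equal to the number of freed parameters (3
against model 1, 5 against model 2); because the freed lambdas sit on a
boundary this reference is conservative.

The three-stage gatekeeping procedure:

1. screen each trait for heritability (sigma_g^2 = 0) and a household
   component (sigma_c^2 = 0), choosing model 1 or model 2;
2. for heritable traits, test the full GxE model against the chosen base,
   adjusting across the trait panel;
3. for joint survivors, test each GxE parameter (gamma_g, lambda_g,
   gamma_e, and for model-2 traits gamma_c, lambda_c) one at a time
   against the full fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .covariance import ModelSpec, gxe_spec, model1_spec, model2_spec, sporadic_spec
from .likelihood import BOUNDARY_TOL, FitResult, LikelihoodData, constrained_fit, fit_ml

__all__ = ["TestResult", "lrt_p", "lrt_statistic", "adjust_pvalues",
           "test_heritability", "test_gxe_joint", "test_gxe_components"]

log = logging.getLogger(__name__)

#: negative LRT values larger than this in magnitude are reported before clipping
CLIP_TOL = 1e-6


@dataclass
class TestResult:
    """One likelihood-ratio test."""

    name: str
    stat: float
    null: str                  # "chi2(k)" or "halfmix" (0.5*chi2_0 + 0.5*chi2_1)
    p: float
    p_adjusted: float
    stage: int
    fit_full: FitResult | None = None
    fit_null: FitResult | None = None

    @property
    def df(self) -> int | None:
        if self.null.startswith("chi2"):
            return int(self.null[5:-1])
        return None


def lrt_statistic(loglik_full: float, loglik_null: float) -> float:
    """2 * (l_full - l_null), clipped to 0 when optimizer noise makes it
    slightly negative (clipping beyond CLIP_TOL is logged)."""
    stat = 2.0 * (loglik_full - loglik_null)
    if stat < 0.0:
        if stat < -CLIP_TOL:
            log.warning("negative LRT statistic %.3g clipped to 0", stat)
        stat = 0.0
    return stat


def lrt_p(stat: float, null: str) -> float:
    """Tail probability of the LRT statistic under the stated null.

    ``"chi2(k)"``: P(chi2_k >= stat).  ``"halfmix"``: the boundary mixture
    0.5 * delta_0 + 0.5 * chi2_1, giving 0.5 * P(chi2_1 >= stat) — exactly
    0.5 at stat = 0.  A general mixture ``"mix:w0,w1,..."`` weights
    chi2_0, chi2_1, ... tails.
    """
    if stat < 0:
        raise ValueError("LRT statistic must be >= 0")
    if null == "halfmix":
        return float(0.5 * stats.chi2.sf(stat, 1)) if stat > 0 else 0.5
    if null.startswith("chi2(") and null.endswith(")"):
        df = int(null[5:-1])
        return float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    if null.startswith("mix:"):
        weights = [float(w) for w in null[4:].split(",")]
        p = 0.0
        for df, w in enumerate(weights):
            if df == 0:
                p += w * (0.0 if stat > 0 else 1.0)
            else:
                p += w * float(stats.chi2.sf(stat, df))
        return p
    raise ValueError(f"unknown null distribution spec {null!r}")


def adjust_pvalues(p, m: int | None = None, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment over a panel.

    Bonferroni (default): min(1, m * p) with ``m`` the panel size (defaults
    to len(p)).  ``holm`` and ``bh`` (Benjamini-Hochberg) are available via
    statsmodels for the within-vector case.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        mm = len(p) if m is None else m
        if mm < 1:
            raise ValueError("m must be >= 1")
        return np.minimum(1.0, mm * p)
    from statsmodels.stats.multitest import multipletests
    mapped = {"holm": "holm", "bh": "fdr_bh"}[method]
    return multipletests(p, method=mapped)[1]


# -- stage 1 ----------------------------------------------------------------

def test_heritability(
    data: LikelihoodData,
    alpha: float = 0.05,
    has_household: bool | None = None,
    **fit_kw,
) -> tuple[int, dict[str, FitResult], list[TestResult]]:
    """Stage-1 screen: is the trait heritable, and is there a household
    component?

    Tests sigma_g^2 = 0 and sigma_c^2 = 0 by boundary (half-mixture) LRTs.
    Returns ``(chosen_model, fits, tests)`` where chosen_model is 1 when the
    household component is non-significant at ``alpha`` and 2 otherwise, and
    heritability should be read from ``fits["model1"]`` / ``fits["model2"]``
    accordingly.
    """
    if has_household is None:
        has_household = any(b.hh.any() for b in data.blocks)

    fits = {
        "sporadic": fit_ml(data, sporadic_spec(), **fit_kw),
        "model1": fit_ml(data, model1_spec(), **fit_kw),
    }
    tests = []
    if has_household:
        fits["model2"] = fit_ml(data, model2_spec(), **fit_kw)
        fits["household_only"] = fit_ml(data, sporadic_spec(household=True), **fit_kw)
        stat_c = lrt_statistic(fits["model2"].loglik, fits["model1"].loglik)
        p_c = lrt_p(stat_c, "halfmix")
        tests.append(TestResult("household_variance_zero", stat_c, "halfmix",
                                p_c, p_c, stage=1,
                                fit_full=fits["model2"], fit_null=fits["model1"]))
        chosen = 2 if p_c < alpha else 1
    else:
        chosen = 1

    if chosen == 2:
        stat_g = lrt_statistic(fits["model2"].loglik, fits["household_only"].loglik)
        full, nullfit = fits["model2"], fits["household_only"]
    else:
        stat_g = lrt_statistic(fits["model1"].loglik, fits["sporadic"].loglik)
        full, nullfit = fits["model1"], fits["sporadic"]
    p_g = lrt_p(stat_g, "halfmix")
    tests.insert(0, TestResult("heritability_zero", stat_g, "halfmix",
                               p_g, p_g, stage=1, fit_full=full, fit_null=nullfit))
    return chosen, fits, tests


# -- stage 2 ----------------------------------------------------------------

def test_gxe_joint(
    data: LikelihoodData,
    base_model: int = 1,
    base_fit: FitResult | None = None,
    **fit_kw,
) -> TestResult:
    """Joint test of the full GxE model against model 1 or model 2.

    Frees gamma_g, lambda_g, gamma_e (and gamma_c, lambda_c when the base
    carries a household component); chi2 reference with df = number of freed
    parameters, conservative because the lambdas sit on a boundary under the
    null.  The adjusted p is filled in by the panel driver.
    """
    if base_model not in (1, 2):
        raise ValueError("base_model must be 1 or 2")
    household = base_model == 2
    spec = gxe_spec(household=household)
    if base_fit is None:
        base_fit = fit_ml(data, model2_spec() if household else model1_spec(), **fit_kw)
    # warm-start the full model at the base-model optimum (gammas/lambdas 0)
    full_fit = fit_ml(data, spec, start=base_fit.params, **fit_kw)
    df = len(spec.free)
    stat = lrt_statistic(full_fit.loglik, base_fit.loglik)
    p = lrt_p(stat, f"chi2({df})")
    return TestResult(f"gxe_joint_vs_model{base_model}", stat, f"chi2({df})",
                      p, p, stage=2, fit_full=full_fit, fit_null=base_fit)


# -- stage 3 ----------------------------------------------------------------

#: component tests in reporting order, with their null references
_COMPONENT_TESTS = (
    ("gamma_g", "homogeneous_genetic_variance", "chi2(1)"),
    ("gamma_e", "homogeneous_residual_variance", "chi2(1)"),
    ("gamma_c", "homogeneous_household_variance", "chi2(1)"),
    ("lambda_g", "genetic_correlation_equals_1", "halfmix"),
    ("lambda_c", "household_correlation_equals_1", "halfmix"),
)


def test_gxe_components(
    data: LikelihoodData,
    base_model: int = 1,
    full_fit: FitResult | None = None,
    m_adjust: int = 1,
    **fit_kw,
) -> list[TestResult]:
    """Stage-3 single-parameter tests against the full GxE fit.

    Each of gamma_g, lambda_g, gamma_e (plus gamma_c, lambda_c for model-2
    traits) is fixed at its null value in turn and refitted.  Gamma tests use
    chi2(1); lambda tests use the half-mixture, and when the full fit's
    lambda estimate already sits on the boundary the constrained optimum
    coincides with the unconstrained one, so the statistic is exactly 0 and
    the p-value exactly 0.5.
    """
    household = base_model == 2
    spec = gxe_spec(household=household)
    if full_fit is None:
        full_fit = fit_ml(data, spec, **fit_kw)
    results = []
    for pname, label, null in _COMPONENT_TESTS:
        if pname not in spec.free:
            continue
        estimate = getattr(full_fit.params, pname)
        if pname.startswith("lambda") and estimate < BOUNDARY_TOL:
            stat = 0.0
            fit_null = None
        else:
            # warm-start the null fit from the full-model optimum
            fit_null = constrained_fit(data, spec, {pname: 0.0},
                                       start=full_fit.params, **fit_kw)
            stat = lrt_statistic(full_fit.loglik, fit_null.loglik)
        p = lrt_p(stat, null)
        p_adj = float(adjust_pvalues([p], m=m_adjust)[0])
        results.append(TestResult(label, stat, null, p, p_adj, stage=3,
                                  fit_full=full_fit, fit_null=fit_null))
    return results
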