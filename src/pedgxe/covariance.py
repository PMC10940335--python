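"""Variance/correlation functions of a continuous environment and the
phenotypic covariance matrix they assemble.

The model indexes each variance component by an individual's standardized
socioeconomic score z (zSES).  Component variances are exponential in z so
they stay positive::

    sigma_g^2(z) = exp(alpha_g + gamma_g * z)      additive genetic
    sigma_e^2(z) = exp(alpha_e + gamma_e * z)      residual environmental
    sigma_c^2(z) = exp(alpha_c + gamma_c * z)      household (optional)

and the genetic / household correlations between two individuals decay
exponentially in their environmental distance::

    rho_g(z_i, z_j) = exp(-lambda_g * |z_i - z_j|)
    rho_c(z_i, z_j) = exp(-lambda_c * |z_i - z_j|)

The phenotypic covariance for a family block is then::

    Omega_ij = K_ij * sqrt(sigma_g^2(z_i) sigma_g^2(z_j)) * rho_g(z_i, z_j)
             + H_ij * sqrt(sigma_c^2(z_i) sigma_c^2(z_j)) * rho_c(z_i, z_j)
             + 1[i == j] * sigma_e^2(z_i)

with K the additive relationship (2*kinship) matrix and H the household
indicator.  gamma = 0 recovers a homogeneous variance; lambda = 0 recovers a
correlation of 1, i.e. the classical polygenic (model 1) or polygenic +
household (model 2) decomposition.  Genotype-by-environment interaction is
variance heterogeneity (gamma_g != 0) and/or genetic correlation below one
(lambda_g > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GxEParams",
    "ModelSpec",
    "variance_fn",
    "decay_corr_fn",
    "build_covariance",
    "heritability_at",
    "function_grid",
]

#: parameters that may be freed beyond the baseline alphas and beta
GXE_PARAMS = ("gamma_g", "lambda_g", "gamma_e", "gamma_c", "lambda_c")


@dataclass(frozen=True)
class GxEParams:
    """Variance-model parameters on the log-variance / decay-rate scale.

    alphas are log baseline variances (dimensionless), gammas are log-variance
    slopes per zSES unit, lambdas are nonnegative decay rates per zSES unit.
    ``beta`` holds the mean-model coefficients (intercept first).
    """

    alpha_g: float = 0.0
    gamma_g: float = 0.0
    lambda_g: float = 0.0
    alpha_e: float = 0.0
    gamma_e: float = 0.0
    alpha_c: float = 0.0
    gamma_c: float = 0.0
    lambda_c: float = 0.0
    beta: tuple[float, ...] = ()

    def __post_init__(self):
        if self.lambda_g < 0 or self.lambda_c < 0:
            raise ValueError("decay rates lambda_g / lambda_c must be >= 0")

    def with_(self, **kw) -> "GxEParams":
        return replace(self, **kw)

    def sigma_g2(self, z):
        return variance_fn(self.alpha_g, self.gamma_g, z)

    def sigma_e2(self, z):
        return variance_fn(self.alpha_e, self.gamma_e, z)

    def sigma_c2(self, z):
        return variance_fn(self.alpha_c, self.gamma_c, z)


@dataclass(frozen=True)
class ModelSpec:
    """Which variance components exist and which GxE parameters are free.

    The residual component is always present.  A null model is expressed by
    dropping a component (sigma^2 = 0 exactly) or by removing a parameter from
    ``free`` (it is then fixed: gammas at 0, lambdas at 0).
    """

    genetic: bool = True
    household: bool = False
    free: frozenset[str] = frozenset()

    def __post_init__(self):
        bad = set(self.free) - set(GXE_PARAMS)
        if bad:
            raise ValueError(f"unknown free parameters: {sorted(bad)}")
        if not self.genetic and ({"gamma_g", "lambda_g"} & set(self.free)):
            raise ValueError("genetic GxE parameters require the genetic component")
        if not self.household and ({"gamma_c", "lambda_c"} & set(self.free)):
            raise ValueError("household GxE parameters require the household component")

    def drop(self, *names: str) -> "ModelSpec":
        """Spec with the named parameters constrained back to their null value."""
        return replace(self, free=self.free - set(names))

    @property
    def components(self) -> tuple[str, ...]:
        out = []
        if self.genetic:
            out.append("genetic")
        if self.household:
            out.append("household")
        out.append("residual")
        return tuple(out)


# -- canonical specs --------------------------------------------------------

def sporadic_spec(household: bool = False) -> ModelSpec:
    """No genetic component (sigma_g^2 = 0): the heritability null."""
    return ModelSpec(genetic=False, household=household)


def model1_spec() -> ModelSpec:
    """Polygenic decomposition sigma_p^2 = sigma_g^2 + sigma_e^2."""
    return ModelSpec(genetic=True, household=False)


def model2_spec() -> ModelSpec:
    """Polygenic + household: sigma_p^2 = sigma_g^2 + sigma_c^2 + sigma_e^2."""
    return ModelSpec(genetic=True, household=True)


def gxe_spec(household: bool = False) -> ModelSpec:
    """Full GxE model: free gamma_g, lambda_g, gamma_e (plus gamma_c, lambda_c
    when the household component is carried)."""
    free = {"gamma_g", "lambda_g", "gamma_e"}
    if household:
        free |= {"gamma_c", "lambda_c"}
    return ModelSpec(genetic=True, household=household, free=frozenset(free))


def effective_params(params: GxEParams, spec: ModelSpec) -> GxEParams:
    """Zero out parameters the spec holds fixed at their null values."""
    kw = {}
    for name in GXE_PARAMS:
        if name not in spec.free and getattr(params, name) != 0.0:
            kw[name] = 0.0
    return params.with_(**kw) if kw else params


# -- the functions themselves ------------------------------------------------

def variance_fn(alpha: float, gamma: float, z):
    """Component variance exp(alpha + gamma * z); strictly positive."""
    return np.exp(alpha + gamma * np.asarray(z, dtype=float))


def decay_corr_fn(lam: float, zi, zj):
    """Correlation exp(-lambda * |zi - zj|), in (0, 1]; symmetric in (zi, zj)."""
    if lam < 0:
        raise ValueError(f"decay rate must be >= 0, got {lam}")
    return np.exp(-lam * np.abs(np.asarray(zi, dtype=float) - np.asarray(zj, dtype=float)))


def _component_matrix(alpha: float, gamma: float, lam: float, z: np.ndarray) -> np.ndarray:
    """sqrt(sigma^2(z_i) sigma^2(z_j)) * exp(-lam |z_i - z_j|) as an n x n array."""
    half = np.exp(0.5 * (alpha + gamma * z))  # sigma(z_i)
    outer = np.outer(half, half)
    if lam != 0.0:
        outer *= np.exp(-lam * np.abs(z[:, None] - z[None, :]))
    return outer


def build_covariance(
    params: GxEParams,
    spec: ModelSpec,
    kin: np.ndarray,
    hh: np.ndarray | None,
    z: np.ndarray,
) -> np.ndarray:
    """Assemble the phenotypic covariance Omega for one family block.

    ``kin`` is the block of the additive relationship (2*phi) matrix, ``hh``
    the household indicator block (ignored unless the spec carries the
    household component), ``z`` the block's zSES values.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    p = effective_params(params, spec)
    for name in ("alpha_g", "gamma_g", "lambda_g", "alpha_e", "gamma_e",
                 "alpha_c", "gamma_c", "lambda_c"):
        if not np.isfinite(getattr(p, name)):
            raise ValueError(f"non-finite parameter {name}")
    omega = np.zeros((n, n))
    if spec.genetic:
        kin = np.asarray(kin, dtype=float)
        if kin.shape != (n, n):
            raise ValueError("kinship block not conformable with z")
        omega += kin * _component_matrix(p.alpha_g, p.gamma_g, p.lambda_g, z)
    if spec.household:
        if hh is None:
            raise ValueError("household component requested but no household matrix")
        hh = np.asarray(hh, dtype=float)
        omega += hh * _component_matrix(p.alpha_c, p.gamma_c, p.lambda_c, z)
    omega[np.diag_indices(n)] += np.exp(p.alpha_e + p.gamma_e * z)
    return omega


def heritability_at(params: GxEParams, spec: ModelSpec, z) -> tuple[np.ndarray, np.ndarray]:
    """(h^2, c^2) at environment value(s) z: component shares of the total
    phenotypic variance sigma_p^2(z)."""
    p = effective_params(params, spec)
    z = np.asarray(z, dtype=float)
    sg2 = p.sigma_g2(z) if spec.genetic else np.zeros_like(z)
    sc2 = p.sigma_c2(z) if spec.household else np.zeros_like(z)
    sp2 = sg2 + sc2 + p.sigma_e2(z)
    return sg2 / sp2, sc2 / sp2


def function_grid(params: GxEParams, spec: ModelSpec, z_grid) -> dict[str, pd.DataFrame]:
    """Evaluate the fitted variance functions over a z grid.

    Returns ``{"components": long-format (component, z, value) with sigma_p^2
    as the component sum, "surface": (z_i, z_j, cov) genetic covariance
    surface sqrt(sigma_g^2(z_i) sigma_g^2(z_j)) * rho_g}``.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    p = effective_params(params, spec)
    rows = []
    total = np.zeros_like(z_grid)
    if spec.genetic:
        sg2 = p.sigma_g2(z_grid)
        rows.append(pd.DataFrame({"component": "sigma_g2", "z": z_grid, "value": sg2}))
        total = total + sg2
    if spec.household:
        sc2 = p.sigma_c2(z_grid)
        rows.append(pd.DataFrame({"component": "sigma_c2", "z": z_grid, "value": sc2}))
        total = total + sc2
    se2 = p.sigma_e2(z_grid)
    rows.append(pd.DataFrame({"component": "sigma_e2", "z": z_grid, "value": se2}))
    total = total + se2
    rows.append(pd.DataFrame({"component": "sigma_p2", "z": z_grid, "value": total}))
    if spec.genetic:
        diffs = np.abs(z_grid[:, None] - z_grid[None, :])
        rows.append(
            pd.DataFrame(
                {"component": "rho_g", "z": diffs.ravel(),
                 "value": np.exp(-p.lambda_g * diffs).ravel()}
            ).drop_duplicates(subset="z")
        )
        surface = _component_matrix(p.alpha_g, p.gamma_g, p.lambda_g, z_grid)
        zi, zj = np.meshgrid(z_grid, z_grid, indexing="ij")
        surf = pd.DataFrame({"z_i": zi.ravel(), "z_j": zj.ravel(), "cov": surface.ravel()})
    else:
        surf = pd.DataFrame(columns=["z_i", "z_j", "cov"])
    return {"components": pd.concat(rows, ignore_index=True), "surface": surf}
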