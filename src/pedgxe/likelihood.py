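"""Family-blocked multivariate-normal likelihood and maximum-likelihood
fitting of the variance-component models.

The phenotype vector of each family block b is modelled as

    y_b ~ MVN(X_b beta, Omega_b(theta))

with Omega_b assembled by :func:`pedgxe.covariance.build_covariance` from the
block's kinship and household structure and the individuals' zSES values.
Blocks are independent (all cross-block covariance entries are zero), so the
log-likelihood is the sum of the per-block MVN log-densities.

Fitting maximizes the profile likelihood over the variance parameters theta
(log baseline variances alpha, log-variance slopes gamma, decay rates
lambda >= 0), with the mean coefficients beta concentrated out by GLS at each
theta; by the envelope theorem the profile gradient equals the partial
derivative at the GLS solution, so the analytic gradient

    d l / d theta_k = -1/2 sum_b tr[(Omega_b^-1 - s_b s_b') dOmega_b/dtheta_k],
    s_b = Omega_b^-1 (y_b - X_b beta_hat)

is exact.  Decay rates are optimized on their natural scale with a bound at
zero so the boundary null (genetic correlation identically 1) is attainable
exactly.  Standard errors come from the inverse central-difference Hessian of
the profile likelihood at interior optima; parameters on the boundary are
flagged and get no SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .covariance import (
    GXE_PARAMS,
    GxEParams,
    ModelSpec,
    build_covariance,
    effective_params,
    heritability_at,
)
from .pedigree import Pedigree, compute_kinship, family_blocks, household_matrix

__all__ = ["FitError", "BlockData", "LikelihoodData", "FitResult",
           "prepare_data", "loglik", "fit_ml", "constrained_fit"]

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)

#: canonical order of variance parameters in the optimization vector
_THETA_ORDER = ("alpha_g", "gamma_g", "lambda_g",
                "alpha_c", "gamma_c", "lambda_c",
                "alpha_e", "gamma_e")

#: loglik change below this counts as converged; lambda below 1e-6 counts
#: as sitting on its boundary
LOGLIK_TOL = 1e-8
BOUNDARY_TOL = 1e-6


class FitError(RuntimeError):
    """Raised when a model cannot be fitted on the given data."""


@dataclass
class BlockData:
    """One family block's data, aligned row-wise."""

    ids: list[str]
    y: np.ndarray
    X: np.ndarray
    kin: np.ndarray
    hh: np.ndarray
    z: np.ndarray
    # precomputed geometry for gradients
    zsum_half: np.ndarray = field(init=False)   # (z_i + z_j) / 2
    zdist: np.ndarray = field(init=False)       # |z_i - z_j|

    def __post_init__(self):
        self.zsum_half = 0.5 * (self.z[:, None] + self.z[None, :])
        self.zdist = np.abs(self.z[:, None] - self.z[None, :])


@dataclass
class LikelihoodData:
    """Complete-case data partitioned into independent family blocks."""

    blocks: list[BlockData]
    x_names: list[str]

    @property
    def n(self) -> int:
        return sum(len(b.y) for b in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def trait_variance(self) -> float:
        y = np.concatenate([b.y for b in self.blocks])
        return float(np.var(y, ddof=1))


def prepare_data(
    ped: Pedigree,
    frame: pd.DataFrame,
    trait: str = "y",
    zses: str = "zses",
    covariates: tuple[str, ...] = (),
    include_zses_in_mean: bool = True,
) -> LikelihoodData:
    """Join a phenotype frame (must carry an ``id`` column) to the pedigree
    structure and partition it into family blocks.

    Kinship is computed on the *full* pedigree — individuals missing the
    trait still transmit relatedness — and only afterwards are rows with a
    missing trait, zSES or covariate dropped from y and Omega.
    """
    kin = compute_kinship(ped)
    hh = household_matrix(ped)
    blocks = family_blocks(ped)

    df = frame.copy()
    df["id"] = df["id"].astype(str)
    df = df.set_index("id")
    unknown = set(df.index) - set(ped.ids)
    if unknown:
        raise FitError(f"phenotype rows for ids absent from the pedigree: {sorted(unknown)[:5]}")

    cols = [trait, zses, *covariates]
    usable = df.index[np.all(np.isfinite(df[cols].to_numpy(dtype=float)), axis=1)]
    usable = set(usable)

    x_names = ["intercept"] + (["zses"] if include_zses_in_mean else []) + list(covariates)
    out_blocks: list[BlockData] = []
    for members in blocks:
        ids = sorted(members & usable)
        if not ids:
            continue
        sub = df.loc[ids]
        z = sub[zses].to_numpy(dtype=float)
        x_cols = [np.ones(len(ids))]
        if include_zses_in_mean:
            x_cols.append(z)
        for c in covariates:
            x_cols.append(sub[c].to_numpy(dtype=float))
        out_blocks.append(
            BlockData(
                ids=ids,
                y=sub[trait].to_numpy(dtype=float),
                X=np.column_stack(x_cols),
                kin=kin.loc[ids, ids].to_numpy(),
                hh=hh.loc[ids, ids].to_numpy(),
                z=z,
            )
        )
    if not out_blocks:
        raise FitError("no usable (complete-case) individuals")
    return LikelihoodData(blocks=out_blocks, x_names=x_names)


# -- likelihood evaluation ---------------------------------------------------

def loglik(params: GxEParams, spec: ModelSpec, data: LikelihoodData) -> float:
    """Blocked MVN log-likelihood at the given parameters (nats).

    ``params.beta`` must either match the design columns of ``data`` or be
    empty (interpreted as all-zero mean).
    """
    total = 0.0
    for b in data.blocks:
        omega = build_covariance(params, spec, b.kin, b.hh, b.z)
        if params.beta:
            if len(params.beta) != b.X.shape[1]:
                raise ValueError(
                    f"beta has length {len(params.beta)}, design has {b.X.shape[1]} columns"
                )
            r = b.y - b.X @ np.asarray(params.beta)
        else:
            r = b.y
        try:
            cf = linalg.cho_factor(omega, lower=True)
        except linalg.LinAlgError as err:
            raise FitError(
                f"covariance not positive definite in block containing {b.ids[0]!r}"
            ) from err
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        quad = float(r @ linalg.cho_solve(cf, r))
        total += -0.5 * (len(r) * _LOG2PI + logdet + quad)
    return total


def _theta_names(spec: ModelSpec, fixed: dict[str, float]) -> list[str]:
    names = []
    for name in _THETA_ORDER:
        if name in fixed:
            continue
        if name.endswith("_g") and not spec.genetic:
            continue
        if name.endswith("_c") and not spec.household:
            continue
        if name.startswith(("gamma", "lambda")) and name not in spec.free:
            continue
        names.append(name)
    return names


def _params_from_theta(theta, names, fixed) -> GxEParams:
    kw = dict(fixed)
    kw.update(zip(names, theta))
    kw = {k: v for k, v in kw.items() if k in GxEParams.__dataclass_fields__}
    kw.setdefault("lambda_g", 0.0)
    kw.setdefault("lambda_c", 0.0)
    # guard the dataclass invariant against optimizer round-off
    kw["lambda_g"] = max(kw["lambda_g"], 0.0)
    kw["lambda_c"] = max(kw["lambda_c"], 0.0)
    return GxEParams(**kw)


def _profile_nll_and_grad(theta, names, fixed, spec, data):
    """Negative profile log-likelihood and its gradient over theta.

    beta is concentrated out by GLS across all blocks jointly.
    """
    p = _params_from_theta(theta, names, fixed)
    factors = []
    k = data.blocks[0].X.shape[1]
    xtox = np.zeros((k, k))
    xtoy = np.zeros(k)
    for b in data.blocks:
        omega = build_covariance(p, spec, b.kin, b.hh, b.z)
        try:
            cf = linalg.cho_factor(omega, lower=True)
        except linalg.LinAlgError:
            return np.inf, np.zeros(len(names))
        oinv_x = linalg.cho_solve(cf, b.X)
        oinv_y = linalg.cho_solve(cf, b.y)
        xtox += b.X.T @ oinv_x
        xtoy += b.X.T @ oinv_y
        factors.append((cf, omega))
    try:
        beta = linalg.solve(xtox, xtoy, assume_a="pos")
    except linalg.LinAlgError:
        return np.inf, np.zeros(len(names))

    nll = 0.0
    grad = np.zeros(len(names))
    for b, (cf, omega) in zip(data.blocks, factors):
        r = b.y - b.X @ beta
        s = linalg.cho_solve(cf, r)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        nll += 0.5 * (len(r) * _LOG2PI + logdet + float(r @ s))

        n_b = len(r)
        oinv = linalg.cho_solve(cf, np.eye(n_b))
        a = oinv - np.outer(s, s)
        e_diag = np.exp(p.alpha_e + p.gamma_e * b.z)
        if spec.genetic:
            g_part = omega - np.diag(e_diag)
            if spec.household:
                half_c = np.exp(0.5 * (p.alpha_c + p.gamma_c * b.z))
                c_part = b.hh * np.outer(half_c, half_c)
                if p.lambda_c != 0.0:
                    c_part *= np.exp(-p.lambda_c * b.zdist)
                g_part = g_part - c_part
        else:
            g_part = None
            if spec.household:
                c_part = omega - np.diag(e_diag)
        for j, name in enumerate(names):
            if name == "alpha_g":
                d = g_part
            elif name == "gamma_g":
                d = g_part * b.zsum_half
            elif name == "lambda_g":
                d = -g_part * b.zdist
            elif name == "alpha_c":
                d = c_part
            elif name == "gamma_c":
                d = c_part * b.zsum_half
            elif name == "lambda_c":
                d = -c_part * b.zdist
            elif name == "alpha_e":
                grad[j] += 0.5 * float(np.diag(a) @ e_diag)
                continue
            elif name == "gamma_e":
                grad[j] += 0.5 * float(np.diag(a) @ (e_diag * b.z))
                continue
            grad[j] += 0.5 * float(np.sum(a * d))
    _profile_nll_and_grad.last_beta = beta
    return nll, grad


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model specification."""

    params: GxEParams
    spec: ModelSpec
    loglik: float
    converged: bool
    status: str                       # "converged" | "max-iter" | "boundary"
    free_names: list[str]
    se: dict[str, float]              # NaN for boundary parameters
    boundary: dict[str, bool]
    beta_se: dict[str, float]
    x_names: list[str]
    n: int
    n_blocks: int
    n_starts: int
    best_start: int

    def heritability(self, z=0.0) -> tuple[float, float]:
        """(h^2, c^2) at environment value z under the fitted parameters."""
        h2, c2 = heritability_at(self.params, self.spec, z)
        return float(h2), float(c2)

    def h2_se(self, data: LikelihoodData, z: float = 0.0) -> float:
        """Delta-method SE of h^2(z) from the profile-likelihood Hessian."""
        cov, names = _theta_cov(self, data)
        if cov is None:
            return float("nan")

        def h2_of(theta):
            p = _params_from_theta(theta, names, _fixed_for(self))
            return float(heritability_at(p, self.spec, z)[0])

        theta0 = np.array([getattr(self.params, n) for n in names])
        grad = _num_grad(h2_of, theta0)
        return float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    def c2_se(self, data: LikelihoodData, z: float = 0.0) -> float:
        cov, names = _theta_cov(self, data)
        if cov is None:
            return float("nan")

        def c2_of(theta):
            p = _params_from_theta(theta, names, _fixed_for(self))
            return float(heritability_at(p, self.spec, z)[1])

        theta0 = np.array([getattr(self.params, n) for n in names])
        grad = _num_grad(c2_of, theta0)
        return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def _fixed_for(fit: FitResult) -> dict[str, float]:
    return {n: getattr(fit.params, n) for n in _THETA_ORDER if n not in fit.free_names}


def _num_grad(f, x0, h=1e-5):
    g = np.zeros(len(x0))
    for i in range(len(x0)):
        step = h * (1.0 + abs(x0[i]))
        xp, xm = x0.copy(), x0.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2 * step)
    return g


def _num_hessian(f, x0, h=1e-4):
    k = len(x0)
    hess = np.zeros((k, k))
    steps = h * (1.0 + np.abs(x0))
    f0 = f(x0)
    for i in range(k):
        for j in range(i, k):
            xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
            xpp[i] += steps[i]; xpp[j] += steps[j]
            xpm[i] += steps[i]; xpm[j] -= steps[j]
            xmp[i] -= steps[i]; xmp[j] += steps[j]
            xmm[i] -= steps[i]; xmm[j] -= steps[j]
            hess[i, j] = hess[j, i] = (
                f(xpp) - f(xpm) - f(xmp) + f(xmm)
            ) / (4 * steps[i] * steps[j])
    return hess


def _theta_cov(fit: FitResult, data: LikelihoodData):
    """Covariance of the free variance parameters (inverse observed
    information of the profile likelihood), restricted to interior ones."""
    names = fit.free_names
    if not names:
        return None, names
    fixed = _fixed_for(fit)
    interior = [n for n in names if not fit.boundary.get(n, False)]
    if not interior:
        return None, names

    def nll_of(theta_int):
        full = {**fixed, **{n: getattr(fit.params, n) for n in names}}
        full.update(zip(interior, theta_int))
        theta = [full[n] for n in names]
        val, _ = _profile_nll_and_grad(np.asarray(theta), names, fixed, fit.spec, data)
        return val

    theta0 = np.array([getattr(fit.params, n) for n in interior])
    hess = _num_hessian(nll_of, theta0)
    try:
        # pseudo-inverse tolerates the near-singular information matrices
        # that arise when a variance component is close to vanishing
        cov_int = linalg.pinvh(hess)
    except linalg.LinAlgError:
        return None, names
    # embed into the full free-parameter space (boundary rows/cols zero)
    cov = np.zeros((len(names), len(names)))
    idx = [names.index(n) for n in interior]
    cov[np.ix_(idx, idx)] = cov_int
    return cov, names


def _auto_starts(data: LikelihoodData, spec: ModelSpec, names, n_starts, rng):
    """Moment-style first start plus seeded jittered restarts."""
    v = max(data.trait_variance, 1e-8)
    n_active = 1 + int(spec.genetic) + int(spec.household)
    base = {
        "alpha_g": np.log(0.4 * v) if n_active > 1 else np.log(v),
        "alpha_c": np.log(0.15 * v),
        "alpha_e": np.log(v / n_active) if n_active > 1 else np.log(0.6 * v),
        "gamma_g": 0.0, "gamma_e": 0.0, "gamma_c": 0.0,
        "lambda_g": 0.05, "lambda_c": 0.05,
    }
    starts = [np.array([base[n] for n in names])]
    for _ in range(n_starts - 1):
        jitter = rng.normal(0.0, 0.5, size=len(names))
        theta = starts[0] + jitter
        for i, n in enumerate(names):
            if n.startswith("lambda"):
                theta[i] = abs(theta[i])
        starts.append(theta)
    return starts


def _bounds(data: LikelihoodData, names):
    v = max(data.trait_variance, 1e-8)
    lo_alpha, hi_alpha = np.log(v) - 20.0, np.log(v) + 5.0
    out = []
    for n in names:
        if n.startswith("alpha"):
            out.append((lo_alpha, hi_alpha))
        elif n.startswith("gamma"):
            out.append((-5.0, 5.0))
        else:  # lambda
            out.append((0.0, 20.0))
    return out


def fit_ml(
    data: LikelihoodData,
    spec: ModelSpec,
    start: GxEParams | str = "auto",
    bounds=None,
    seed: int = 0,
    n_starts: int = 5,
    fixed: dict[str, float] | None = None,
    compute_se: bool = True,
) -> FitResult:
    """Maximize the blocked profile likelihood over the free parameters.

    ``start="auto"`` uses a moment-style initial point plus ``n_starts - 1``
    seeded jittered restarts and returns the best local optimum.  ``fixed``
    maps parameter names to frozen values (used by :func:`constrained_fit`).
    """
    fixed = dict(fixed or {})
    names = _theta_names(spec, fixed)
    k_mean = data.blocks[0].X.shape[1]
    if data.n <= len(names) + k_mean + 1:
        raise FitError(
            f"non-identifiable: {data.n} observations for {len(names)} variance "
            f"parameters and {k_mean} mean coefficients"
        )
    if data.n_blocks < 2:
        log.warning("only %d family block(s); variance components may be "
                    "poorly identified", data.n_blocks)

    rng = np.random.default_rng(seed)
    if isinstance(start, GxEParams):
        theta0 = np.array([getattr(start, n) for n in names])
        starts = [theta0]
        for _ in range(n_starts - 1):
            jitter = rng.normal(0.0, 0.5, size=len(names))
            t = theta0 + jitter
            for i, n in enumerate(names):
                if n.startswith("lambda"):
                    t[i] = abs(t[i])
            starts.append(t)
    else:
        starts = _auto_starts(data, spec, names, n_starts, rng)
    box = bounds if bounds is not None else _bounds(data, names)

    best = None
    best_start = -1
    diagnostics = []
    for s_idx, theta_start in enumerate(starts):
        theta_start = np.clip(theta_start, [b[0] for b in box], [b[1] for b in box]) \
            if box else theta_start
        res = optimize.minimize(
            _profile_nll_and_grad,
            theta_start,
            args=(names, fixed, spec, data),
            jac=True,
            method="L-BFGS-B",
            bounds=box,
            options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 500},
        )
        diagnostics.append((s_idx, res.success, float(res.fun)))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 0.0):
            best = res
            best_start = s_idx
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"all starts failed to converge: {diagnostics}")

    theta_hat = best.x
    # re-evaluate to recover the GLS beta at the optimum
    _profile_nll_and_grad(theta_hat, names, fixed, spec, data)
    beta = _profile_nll_and_grad.last_beta
    params = _params_from_theta(theta_hat, names, fixed).with_(beta=tuple(beta))

    boundary = {}
    for i, n in enumerate(names):
        lo = box[i][0] if box else None
        at_zero = n.startswith("lambda") and theta_hat[i] < BOUNDARY_TOL
        at_lo = lo is not None and theta_hat[i] - lo < BOUNDARY_TOL
        boundary[n] = bool(at_zero or (n.startswith("alpha") and at_lo))
    any_boundary = any(boundary.values())
    status = "boundary" if any_boundary else ("converged" if best.success else "max-iter")

    fit = FitResult(
        params=params,
        spec=spec,
        loglik=-float(best.fun),
        converged=bool(best.success),
        status=status,
        free_names=names,
        se={n: float("nan") for n in names},
        boundary=boundary,
        beta_se={n: float("nan") for n in data.x_names},
        x_names=list(data.x_names),
        n=data.n,
        n_blocks=data.n_blocks,
        n_starts=len(starts),
        best_start=best_start,
    )
    if compute_se and names:
        cov, _ = _theta_cov(fit, data)
        if cov is not None:
            for i, n in enumerate(names):
                var = cov[i, i]
                fit.se[n] = float(np.sqrt(var)) if (var > 0 and not boundary[n]) else float("nan")
        fit.beta_se = _beta_se(fit, data)
    return fit


def _beta_se(fit: FitResult, data: LikelihoodData) -> dict[str, float]:
    k = data.blocks[0].X.shape[1]
    xtox = np.zeros((k, k))
    for b in data.blocks:
        omega = build_covariance(fit.params, fit.spec, b.kin, b.hh, b.z)
        cf = linalg.cho_factor(omega, lower=True)
        xtox += b.X.T @ linalg.cho_solve(cf, b.X)
    try:
        cov = linalg.inv(xtox)
    except linalg.LinAlgError:
        return {n: float("nan") for n in data.x_names}
    return {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(data.x_names)}


def constrained_fit(
    data: LikelihoodData,
    spec: ModelSpec,
    constraints: dict[str, float],
    **kw,
) -> FitResult:
    """Fit with the listed free parameters fixed at the given values.

    Used to build every null model in the testing hierarchy, e.g.
    ``constrained_fit(data, gxe_spec(), {"gamma_g": 0.0})``.
    """
    valid = set(_theta_names(spec, {}))
    unknown = set(constraints) - valid
    if unknown:
        raise ValueError(
            f"constraints name parameters not free in this spec: {sorted(unknown)}"
        )
    return fit_ml(data, spec, fixed=constraints, **kw)
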