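import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedgxe.covariance import (
    GxEParams,
    ModelSpec,
    build_covariance,
    decay_corr_fn,
    function_grid,
    gxe_spec,
    heritability_at,
    model1_spec,
    model2_spec,
    variance_fn,
)


class TestVarianceFn:
    @pytest.mark.parametrize(
        "alpha,gamma,z,expected",
        [(0.0, 0.0, 3.7, 1.0), (np.log(2), 0.0, 5.0, 2.0), (0.0, -0.5, 1.0, np.exp(-0.5))],
    )
    def test_closed_forms(self, alpha, gamma, z, expected):
        assert variance_fn(alpha, gamma, z) == pytest.approx(expected)

    @given(st.floats(-3, 3), st.floats(-2, 2), st.floats(-4, 4))
    @settings(max_examples=50, deadline=None)
    def test_always_positive(self, alpha, gamma, z):
        assert variance_fn(alpha, gamma, z) > 0


class TestDecayCorrFn:
    def test_zero_rate_is_unity(self):
        assert decay_corr_fn(0.0, -2.1, 3.3) == 1.0

    def test_half_at_log2_unit_distance(self):
        assert decay_corr_fn(np.log(2), 0.0, 1.0) == pytest.approx(0.5)

    def test_equal_environments_unity(self):
        assert decay_corr_fn(7.3, 1.5, 1.5) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            decay_corr_fn(-0.1, 0.0, 1.0)

    @given(st.floats(0, 5), st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, lam, zi, zj):
        r = decay_corr_fn(lam, zi, zj)
        assert 0 < r <= 1
        assert r == decay_corr_fn(lam, zj, zi)


def _parent_offspring_structure():
    kin = np.array([[1.0, 0.5], [0.5, 1.0]])
    hh = np.zeros((2, 2))
    return kin, hh


class TestBuildCovariance:
    def test_reduces_to_polygenic_when_homogeneous(self):
        """gamma = lambda = 0 gives sigma_g2 * 2Phi + sigma_e2 * I exactly."""
        rng = np.random.default_rng(0)
        n = 6
        a = rng.normal(size=(n, n))
        kin = a @ a.T / n + np.eye(n)
        z = rng.normal(size=n)
        params = GxEParams(alpha_g=np.log(0.4), alpha_e=np.log(0.6))
        omega = build_covariance(params, model1_spec(), kin, None, z)
        assert np.array_equal(omega, 0.4 * kin + 0.6 * np.eye(n))

    def test_parent_offspring_unit_variances(self):
        kin, hh = _parent_offspring_structure()
        omega = build_covariance(GxEParams(), model1_spec(), kin, hh, np.zeros(2))
        assert np.array_equal(omega, np.array([[2.0, 0.5], [0.5, 2.0]]))

    def test_parent_offspring_heterogeneous_hand_computed(self):
        """alpha_g=0, gamma_g=-0.5, lambda_g=ln2, z=(0,1): off-diagonal
        0.5 * sqrt(e^-0.5) * 0.5, diagonals (2, e^-0.5 + 1)."""
        kin, hh = _parent_offspring_structure()
        params = GxEParams(gamma_g=-0.5, lambda_g=np.log(2))
        spec = gxe_spec()
        omega = build_covariance(params, spec, kin, hh, np.array([0.0, 1.0]))
        assert omega[0, 1] == pytest.approx(0.19470019576785122)
        assert omega[0, 0] == pytest.approx(2.0)
        assert omega[1, 1] == pytest.approx(np.exp(-0.5) + 1.0)

    def test_fixed_parameters_ignored_outside_spec(self):
        """A gamma set in params but not freed in the spec acts as 0."""
        kin, hh = _parent_offspring_structure()
        params = GxEParams(gamma_g=0.7, lambda_g=1.0)
        omega = build_covariance(params, model1_spec(), kin, hh, np.array([0.0, 1.0]))
        assert np.array_equal(omega, np.array([[2.0, 0.5], [0.5, 2.0]]))

    def test_household_component_restricted_to_households(self):
        kin = np.eye(2)
        hh = np.ones((2, 2))
        params = GxEParams(alpha_c=np.log(0.3), alpha_e=np.log(0.7), alpha_g=-30)
        omega = build_covariance(params, model2_spec(), kin, hh, np.zeros(2))
        assert omega[0, 1] == pytest.approx(0.3)

    def test_non_finite_parameter_rejected(self):
        kin, hh = _parent_offspring_structure()
        with pytest.raises(ValueError, match="non-finite"):
            build_covariance(GxEParams(alpha_g=np.nan), model1_spec(), kin, hh, np.zeros(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_positive_definite_property(self, seed):
        """Random kinship-like structure, random parameters: Omega is
        symmetric and Cholesky-factorable whenever sigma_e2 > 0."""
        rng = np.random.default_rng(seed)
        n = 8
        a = rng.normal(size=(n, n))
        kin = a @ a.T / n + np.eye(n)
        hh = np.zeros((n, n))
        half = rng.permutation(n)[: n // 2]
        hh[np.ix_(half, half)] = 1.0
        z = rng.normal(size=n)
        params = GxEParams(
            alpha_g=rng.normal(0, 1), gamma_g=rng.normal(0, 0.5),
            lambda_g=abs(rng.normal(0, 0.5)),
            alpha_e=rng.normal(0, 1), gamma_e=rng.normal(0, 0.5),
            alpha_c=rng.normal(-1, 0.5), gamma_c=rng.normal(0, 0.5),
            lambda_c=abs(rng.normal(0, 0.5)),
        )
        omega = build_covariance(params, gxe_spec(household=True), kin, hh, z)
        assert np.allclose(omega, omega.T)
        np.linalg.cholesky(omega)  # raises if not PD

    @pytest.mark.parametrize("lam", [0.0, 0.3, 2.0])
    def test_decay_correlation_matrix_psd(self, lam):
        rng = np.random.default_rng(42)
        z = rng.normal(size=12)
        rho = np.exp(-lam * np.abs(z[:, None] - z[None, :]))
        assert np.linalg.eigvalsh(rho).min() >= -1e-10


class TestHeritabilityAt:
    def test_equal_components_half(self):
        h2, c2 = heritability_at(GxEParams(), model1_spec(), 0.0)
        assert h2 == pytest.approx(0.5) and c2 == 0.0

    def test_no_genetic_component_zero(self):
        h2, _ = heritability_at(GxEParams(), ModelSpec(genetic=False), 0.0)
        assert h2 == 0.0

    def test_three_component_shares(self):
        params = GxEParams(alpha_g=np.log(0.45), alpha_c=np.log(0.11), alpha_e=np.log(0.44))
        h2, c2 = heritability_at(params, model2_spec(), 0.0)
        assert h2 == pytest.approx(0.45) and c2 == pytest.approx(0.11)
        assert h2 + c2 <= 1.0


class TestFunctionGrid:
    def test_negative_gamma_monotone_decreasing(self):
        params = GxEParams(gamma_g=-0.5)
        spec = gxe_spec()
        grid = function_grid(params, spec, np.linspace(-3, 3, 13))
        sg2 = grid["components"].query("component == 'sigma_g2'")["value"].to_numpy()
        assert np.all(np.diff(sg2) < 0)

    def test_total_is_component_sum(self):
        params = GxEParams(gamma_g=-0.5, gamma_e=0.5)
        spec = gxe_spec()
        comp = function_grid(params, spec, np.linspace(-2, 2, 9))["components"]
        comp = comp[comp.component.isin(["sigma_g2", "sigma_e2", "sigma_p2"])]
        wide = comp.pivot_table(index="z", columns="component", values="value")
        assert np.allclose(wide["sigma_p2"], wide["sigma_g2"] + wide["sigma_e2"])

    def test_opposed_slopes_nonmonotone_total(self):
        """Genetic variance falling and residual rising yields a dip-shaped
        total phenotypic variance across a sign-crossing grid."""
        params = GxEParams(gamma_g=-0.5, gamma_e=0.5)
        comp = function_grid(params, gxe_spec(), np.linspace(-3, 3, 25))["components"]
        sp2 = comp.query("component == 'sigma_p2'")["value"].to_numpy()
        d = np.diff(sp2)
        assert (d < 0).any() and (d > 0).any()

    def test_surface_diagonal_equals_variance(self):
        params = GxEParams(gamma_g=-0.4, lambda_g=0.6)
        z = np.linspace(-1, 1, 5)
        out = function_grid(params, gxe_spec(), z)
        surf = out["surface"]
        diag = surf[surf.z_i == surf.z_j].sort_values("z_i")["cov"].to_numpy()
        sg2 = out["components"].query("component == 'sigma_g2'")["value"].to_numpy()
        assert np.allclose(diag, sg2)

    def test_surface_symmetric(self):
        params = GxEParams(gamma_g=-0.4, lambda_g=0.6)
        surf = function_grid(params, gxe_spec(), np.linspace(-1, 1, 5))["surface"]
        mat = surf.pivot(index="z_i", columns="z_j", values="cov").to_numpy()
        assert np.allclose(mat, mat.T)


class TestModelSpec:
    def test_lambda_requires_component(self):
        with pytest.raises(ValueError):
            ModelSpec(genetic=False, free=frozenset({"gamma_g"}))
        with pytest.raises(ValueError):
            ModelSpec(household=False, free=frozenset({"lambda_c"}))

    def test_unknown_free_name_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(free=frozenset({"gamma_x"}))

    def test_negative_lambda_rejected_in_params(self):
        with pytest.raises(ValueError):
            GxEParams(lambda_g=-0.2)
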