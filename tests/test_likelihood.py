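import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pedgxe.covariance import GxEParams, build_covariance, gxe_spec, model1_spec, sporadic_spec
from pedgxe.likelihood import FitError, constrained_fit, fit_ml, loglik, prepare_data
from pedgxe.pedigree import compute_kinship, household_matrix
from pedgxe.simulate import SimScenario, simulate_dataset

from conftest import make_pedigree, random_pedigree

SMALL = SimScenario(n_families=8, seed=0)


def dense_loglik(ped, frame, params, spec):
    """Independent oracle: one joint MVN density over all individuals,
    assembled without the block machinery."""
    kin = compute_kinship(ped)
    hh = household_matrix(ped)
    df = frame.set_index("id")
    ids = list(df.index)
    z = df["zses"].to_numpy(dtype=float)
    omega = build_covariance(params, spec, kin.loc[ids, ids].to_numpy(),
                             hh.loc[ids, ids].to_numpy(), z)
    x = np.column_stack([np.ones(len(ids)), z])
    mean = x @ np.asarray(params.beta) if params.beta else np.zeros(len(ids))
    return float(stats.multivariate_normal.logpdf(df["y"].to_numpy(), mean=mean, cov=omega))


@pytest.fixture(scope="module")
def small_data():
    ped, frame = simulate_dataset(SimScenario(n_families=8, seed=12))
    return ped, frame, prepare_data(ped, frame)


class TestLoglik:
    def test_single_individual_standard_normal(self):
        ped = make_pedigree([("a", None, None, "male", None)])
        frame = pd.DataFrame({"id": ["a"], "y": [0.0], "zses": [0.0]})
        data = prepare_data(ped, frame)
        val = loglik(GxEParams(alpha_e=0.0), sporadic_spec(), data)
        assert val == pytest.approx(-0.9189385332046727, abs=1e-12)

    def test_doubling_residual_variance_shifts_by_half_log2(self):
        ped = make_pedigree([("a", None, None, "male", None)])
        frame = pd.DataFrame({"id": ["a"], "y": [0.0], "zses": [0.0]})
        data = prepare_data(ped, frame)
        l1 = loglik(GxEParams(alpha_e=0.0), sporadic_spec(), data)
        l2 = loglik(GxEParams(alpha_e=np.log(2.0)), sporadic_spec(), data)
        assert l2 - l1 == pytest.approx(-0.5 * np.log(2.0), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_blocked_equals_dense_oracle(self, seed):
        """Block-sum equals a dense joint MVN evaluation to 1e-8."""
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng)
        sc = SimScenario(
            seed=seed,
            params=GxEParams(alpha_g=-0.6, gamma_g=-0.4, lambda_g=0.25,
                             alpha_e=-0.5, gamma_e=0.2),
            spec=gxe_spec(),
        )
        from pedgxe.simulate import simulate_covariates, simulate_trait, simulate_zses
        z = simulate_zses(ped, sc)
        y = simulate_trait(ped, z, None, sc)
        frame = pd.DataFrame({"id": ped.ids, "zses": z.to_numpy(), "y": y.to_numpy()})
        params = GxEParams(
            alpha_g=rng.normal(0, 0.5), gamma_g=rng.normal(0, 0.3),
            lambda_g=abs(rng.normal(0, 0.3)),
            alpha_e=rng.normal(0, 0.5), gamma_e=rng.normal(0, 0.3),
            beta=(rng.normal(), rng.normal()),
        )
        data = prepare_data(ped, frame)
        assert loglik(params, gxe_spec(), data) == pytest.approx(
            dense_loglik(ped, frame, params, gxe_spec()), abs=1e-8)

    def test_missing_trait_dropped_from_likelihood_not_kinship(self, small_data):
        ped, frame, _ = small_data
        frame2 = frame.copy()
        frame2.loc[frame2.index[::7], "y"] = np.nan
        data2 = prepare_data(ped, frame2)
        assert data2.n == frame2["y"].notna().sum()
        # connecting relatives still contribute structure: kinship blocks intact
        assert data2.n_blocks >= 1

    def test_beta_length_mismatch_errors(self, small_data):
        _, _, data = small_data
        with pytest.raises(ValueError, match="beta"):
            loglik(GxEParams(beta=(0.0,)), model1_spec(), data)


class TestFitML:
    def test_nesting_inequality_and_reduction(self, small_data):
        """Constrained GxE (all gammas, lambdas = 0) reproduces the model-1
        fit; the free GxE fit can only improve the likelihood."""
        _, _, data = small_data
        m1 = fit_ml(data, model1_spec(), seed=0, n_starts=2, compute_se=False)
        g_con = constrained_fit(data, gxe_spec(),
                                {"gamma_g": 0.0, "lambda_g": 0.0, "gamma_e": 0.0},
                                seed=0, n_starts=2, compute_se=False)
        g_free = fit_ml(data, gxe_spec(), seed=0, n_starts=2, compute_se=False)
        assert g_con.loglik == pytest.approx(m1.loglik, abs=1e-6)
        assert g_free.loglik >= m1.loglik - 1e-9

    def test_location_scale_equivariance(self, small_data):
        """Adding a constant moves only the intercept; multiplying by c adds
        2 ln c to the fitted log-variances."""
        ped, frame, data = small_data
        fit0 = fit_ml(data, model1_spec(), seed=0, n_starts=2, compute_se=False)
        shifted = frame.copy()
        shifted["y"] = shifted["y"] + 5.0
        fit_sh = fit_ml(prepare_data(ped, shifted), model1_spec(), seed=0,
                        n_starts=2, compute_se=False)
        assert fit_sh.params.beta[0] == pytest.approx(fit0.params.beta[0] + 5.0, abs=1e-4)
        assert fit_sh.params.alpha_g == pytest.approx(fit0.params.alpha_g, abs=1e-4)

        scaled = frame.copy()
        scaled["y"] = scaled["y"] * 3.0
        fit_sc = fit_ml(prepare_data(ped, scaled), model1_spec(), seed=0,
                        n_starts=2, compute_se=False)
        assert fit_sc.params.alpha_g == pytest.approx(
            fit0.params.alpha_g + 2 * np.log(3.0), abs=1e-4)
        assert fit_sc.params.alpha_e == pytest.approx(
            fit0.params.alpha_e + 2 * np.log(3.0), abs=1e-4)

    def test_degenerate_data_refused(self):
        ped = make_pedigree([
            ("a", None, None, "male", "h1"),
            ("b", None, None, "female", "h1"),
        ])
        frame = pd.DataFrame({"id": ["a", "b"], "y": [0.1, -0.2], "zses": [0.5, -0.5]})
        data = prepare_data(ped, frame)
        with pytest.raises(FitError, match="non-identifiable"):
            fit_ml(data, model1_spec())

    def test_constraint_on_unknown_parameter_errors(self, small_data):
        _, _, data = small_data
        with pytest.raises(ValueError, match="not free"):
            constrained_fit(data, model1_spec(), {"gamma_g": 0.0})

    def test_fully_constrained_equals_direct_evaluation(self, small_data):
        """Fixing every free GxE parameter leaves only alphas; the fitted
        loglik must match a direct loglik evaluation at the estimates."""
        _, _, data = small_data
        fit = constrained_fit(data, gxe_spec(),
                              {"gamma_g": 0.3, "lambda_g": 0.2, "gamma_e": -0.1},
                              seed=0, n_starts=2, compute_se=False)
        direct = loglik(fit.params, gxe_spec(), data)
        assert direct == pytest.approx(fit.loglik, abs=1e-8)

    def test_boundary_lambda_flagged_without_se(self, small_data):
        """Under homogeneous truth the decay rate typically lands on its
        boundary and must be flagged with no SE."""
        _, _, data = small_data
        fit = fit_ml(data, gxe_spec(), seed=0, n_starts=2)
        if fit.params.lambda_g < 1e-6:
            assert fit.boundary["lambda_g"]
            assert np.isnan(fit.se["lambda_g"])
        # interior parameters always get finite SEs
        assert np.isfinite(fit.se["alpha_g"]) or fit.boundary["alpha_g"]

    def test_consistency_with_more_families(self):
        """Estimator bias for (alpha_g, gamma_g) shrinks as families grow."""
        truth = GxEParams(alpha_g=np.log(0.45), gamma_g=-0.5, lambda_g=0.0,
                          alpha_e=np.log(0.55))
        spec = gxe_spec()
        biases = {}
        for n_fam in (10, 40):
            err_a, err_g = [], []
            for rep in range(4):
                sc = SimScenario(n_families=n_fam, seed=1000 + rep,
                                 params=truth, spec=spec)
                ped, frame = simulate_dataset(sc)
                fit = fit_ml(prepare_data(ped, frame), spec, seed=rep,
                             n_starts=2, compute_se=False)
                err_a.append(fit.params.alpha_g - truth.alpha_g)
                err_g.append(fit.params.gamma_g - truth.gamma_g)
            biases[n_fam] = (abs(np.mean(err_a)), abs(np.mean(err_g)))
        # RMS-style reduction: the large-sample bias should not exceed the
        # small-sample one by more than Monte-Carlo noise
        assert sum(biases[40]) < sum(biases[10]) + 0.15
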