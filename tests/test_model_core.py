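"""Density and random-effects-estimation checks against analytic oracles."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from loda import (
    MarkerSpec,
    PatientRecord,
    RandomEffectsMixture,
    StructuralError,
    UnsupportedMethodError,
    conditional_log_density,
    estimate_random_effects,
    marginal_log_density,
    random_effects_log_density,
)
from loda.model_core import parameter_vector

from conftest import make_gaussian_params


def single_marker_model(family="gaussian", phi=1.0, mu0=0.0, d=1.0):
    spec = MarkerSpec("m", family)
    resid = {"m": phi} if family == "gaussian" else {}
    params = make_gaussian_params([spec], [mu0], [[d]], resid)
    return spec, params


class TestConditionalLogDensity:
    def test_gaussian_at_mean_unit_sd(self):
        spec, params = single_marker_model(phi=1.0)
        patient = PatientRecord("p", None, {"m": ([0.0], [0.7])})
        val = conditional_log_density(patient, np.array([0.7]), params, [spec])
        assert val == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_bernoulli_symmetry_at_zero(self):
        spec, params = single_marker_model("bernoulli")
        patient = PatientRecord("p", None, {"m": ([1.0], [1.0])})
        val = conditional_log_density(patient, np.array([0.0]), params, [spec])
        assert val == pytest.approx(math.log(0.5), abs=1e-12)

    def test_mixed_markers_term_by_term_oracle(self):
        """Sum over two markers x three visits must equal the per-observation
        exponential-family log densities computed independently."""
        specs = [
            MarkerSpec("g", "gaussian", has_random_slope=True),
            MarkerSpec("c", "poisson", has_random_slope=True),
        ]
        mu = np.array([1.0, -0.05, 2.0, 0.02])
        D = np.diag([0.2, 0.01, 0.3, 0.01])
        params = make_gaussian_params(specs, mu, D, {"g": 0.5})
        t = np.array([0.0, 2.0, 5.0])
        yg = np.array([1.2, 0.8, 1.5])
        yc = np.array([6.0, 9.0, 7.0])
        patient = PatientRecord("p", None, {"g": (t, yg), "c": (t, yc)})
        b = np.array([0.9, -0.02, 1.8, 0.05])

        expected = 0.0
        for tj, yj in zip(t, yg):
            expected += stats.norm.logpdf(yj, loc=b[0] + b[1] * tj, scale=0.5)
        for tj, yj in zip(t, yc):
            expected += stats.poisson.logpmf(yj, np.exp(b[2] + b[3] * tj))
        got = conditional_log_density(patient, b, params, specs)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_maximised_at_conditional_mean(self):
        """For Gaussian observations the conditional density peaks when the
        data sit exactly on the patient's regression line."""
        spec, params = single_marker_model(phi=0.7)
        b = np.array([0.3])
        base = PatientRecord("p", None, {"m": ([0.0, 1.0], [0.3, 0.3])})
        best = conditional_log_density(base, b, params, [spec])
        for delta in (-0.5, -0.1, 0.1, 0.5):
            worse = PatientRecord(
                "p", None, {"m": ([0.0, 1.0], [0.3 + delta, 0.3])}
            )
            assert conditional_log_density(worse, b, params, [spec]) < best

    def test_dimension_mismatch(self):
        spec, params = single_marker_model()
        patient = PatientRecord("p", None, {"m": ([0.0], [0.0])})
        with pytest.raises(StructuralError):
            conditional_log_density(patient, np.zeros(3), params, [spec])


class TestRandomEffectsLogDensity:
    def test_standard_normal_mode(self):
        q = 3
        mix = RandomEffectsMixture([1.0], np.zeros((1, q)), np.eye(q)[None])
        val = random_effects_log_density(np.zeros(q), mix)
        assert val == pytest.approx(-q / 2 * math.log(2 * math.pi), abs=1e-9)

    def test_equal_components_collapse(self):
        mu = np.array([[0.5, -0.2], [0.5, -0.2]])
        C = np.stack([np.eye(2) * 0.5] * 2)
        mix2 = RandomEffectsMixture([0.4, 0.6], mu, C)
        mix1 = RandomEffectsMixture([1.0], mu[:1], C[:1])
        b = np.array([0.1, 0.3])
        assert random_effects_log_density(b, mix2) == pytest.approx(
            random_effects_log_density(b, mix1), rel=1e-12
        )

    def test_two_component_direct_evaluation(self):
        rng = np.random.default_rng(3)
        mu = rng.standard_normal((2, 2))
        C = np.stack([np.eye(2) * 0.7, np.eye(2) * 1.3])
        w = [0.3, 0.7]
        mix = RandomEffectsMixture(w, mu, C)
        b = rng.standard_normal(2)
        expected = math.log(
            w[0] * stats.multivariate_normal.pdf(b, mu[0], C[0])
            + w[1] * stats.multivariate_normal.pdf(b, mu[1], C[1])
        )
        assert random_effects_log_density(b, mix) == pytest.approx(expected, rel=1e-9)

    def test_integrates_to_one_1d(self):
        mix = RandomEffectsMixture(
            [0.4, 0.6], np.array([[-1.0], [2.0]]), np.array([[[0.5]], [[2.0]]])
        )
        total, _ = quad(
            lambda x: math.exp(random_effects_log_density(np.array([x]), mix)),
            -15, 15,
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(StructuralError):
            RandomEffectsMixture([1.0], np.zeros((1, 2)), np.array([[[1.0, 2.0], [2.0, 1.0]]]))


class TestMarginalLogDensity:
    def test_degenerate_covariance_equals_conditional_at_mean(self):
        spec = MarkerSpec("m", "gaussian")
        params = make_gaussian_params([spec], [0.4], [[0.0]], {"m": 0.8})
        patient = PatientRecord("p", None, {"m": ([0.0, 1.0], [0.2, 0.6])})
        marg = marginal_log_density(patient, params, [spec], method="closed_form")
        cond = conditional_log_density(patient, np.array([0.4]), params, [spec])
        assert marg == pytest.approx(cond, abs=1e-5)

    def test_scalar_closed_form_hand_formula(self):
        spec, params = single_marker_model(phi=0.6, mu0=1.2, d=0.5**2)
        patient = PatientRecord("p", None, {"m": ([3.0], [0.9])})
        # one observation: y ~ Normal(mu, z^2 d + phi^2) with z = 1
        expected = stats.norm.logpdf(0.9, loc=1.2, scale=math.sqrt(0.25 + 0.36))
        got = marginal_log_density(patient, params, [spec], method="closed_form")
        assert got == pytest.approx(expected, rel=1e-9)

    def test_monte_carlo_agrees_with_closed_form(self, gaussian_toy):
        params, specs, patient = gaussian_toy
        exact = marginal_log_density(patient, params, specs, method="closed_form")
        mc, se = marginal_log_density(
            patient, params, specs, method="monte_carlo",
            n_draws=40_000, seed=9, return_se=True,
        )
        assert abs(mc - exact) < 3 * se

    def test_monte_carlo_error_shrinks(self, gaussian_toy):
        """The MC error decreases with the number of draws (~ 1/sqrt(n))."""
        params, specs, patient = gaussian_toy
        exact = marginal_log_density(patient, params, specs, method="closed_form")
        errs = []
        for n in (10**3, 10**4, 10**5):
            vals = [
                marginal_log_density(
                    patient, params, specs, method="monte_carlo", n_draws=n, seed=s
                )
                for s in range(5)
            ]
            errs.append(np.sqrt(np.mean([(v - exact) ** 2 for v in vals])))
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < errs[0] / 3  # consistent with root-n decay

    def test_closed_form_requires_gaussian(self):
        spec, params = single_marker_model("poisson")
        patient = PatientRecord("p", None, {"m": ([0.0], [2.0])})
        with pytest.raises(UnsupportedMethodError):
            marginal_log_density(patient, params, [spec], method="closed_form")

    def test_seeded_repeatability(self, gaussian_toy):
        params, specs, patient = gaussian_toy
        a = marginal_log_density(patient, params, specs, "monte_carlo", 500, seed=4)
        b = marginal_log_density(patient, params, specs, "monte_carlo", 500, seed=4)
        assert a == b


class TestEstimateRandomEffects:
    def test_no_observations_returns_prior_mean(self, two_gaussian_specs):
        mu = np.array([3.5, -0.01, 0.2, 0.01])
        params = make_gaussian_params(
            two_gaussian_specs, mu, np.eye(4) * 0.1, {"albumin": 0.3, "lbili": 0.4}
        )
        patient = PatientRecord("p", None, {"albumin": ([], []), "lbili": ([], [])})
        for method in ("closed_form", "laplace"):
            est = estimate_random_effects(patient, params, two_gaussian_specs, method)
            assert est == pytest.approx(mu, abs=1e-8)

    def test_conjugate_normal_oracle(self, gaussian_toy):
        """Closed form must match dense Bayesian linear-model algebra:
        posterior mean of b with prior N(mu, D) and likelihood N(Xb, Sigma)."""
        params, specs, patient = gaussian_toy
        mix = params.random_effects
        mu, D = mix.means[0], mix.covariances[0]
        t = patient.observations["albumin"][0]
        Z = np.zeros((4, 4))
        Z[0, :2] = [1.0, t[0]]
        Z[1, :2] = [1.0, t[1]]
        Z[2, 2:] = [1.0, t[0]]
        Z[3, 2:] = [1.0, t[1]]
        y = np.concatenate(
            [patient.observations["albumin"][1], patient.observations["lbili"][1]]
        )
        Sigma = np.diag([0.3**2, 0.3**2, 0.4**2, 0.4**2])
        P = np.linalg.inv(D) + Z.T @ np.linalg.inv(Sigma) @ Z
        m = np.linalg.solve(
            P, np.linalg.inv(D) @ mu + Z.T @ np.linalg.inv(Sigma) @ y
        )
        got = estimate_random_effects(patient, params, specs, "closed_form")
        assert got == pytest.approx(m, rel=1e-8)

    def test_laplace_exact_for_gaussian(self, gaussian_toy):
        params, specs, patient = gaussian_toy
        cf = estimate_random_effects(patient, params, specs, "closed_form")
        la = estimate_random_effects(patient, params, specs, "laplace")
        assert la == pytest.approx(cf, abs=1e-6)

    def test_shrinks_toward_mean_as_noise_grows(self):
        """Monotone shrinkage toward the prior mean in the residual SD."""
        spec = MarkerSpec("m", "gaussian")
        patient = PatientRecord("p", None, {"m": ([0.0, 1.0], [2.0, 2.0])})
        dists = []
        for phi in (0.1, 0.5, 1.0, 3.0, 10.0):
            params = make_gaussian_params([spec], [0.0], [[1.0]], {"m": phi})
            est = estimate_random_effects(patient, params, [spec])
            dists.append(abs(est[0]))
        assert all(a > b for a, b in zip(dists, dists[1:]))


def test_parameter_vector_labels_roundtrip(two_gaussian_specs):
    mu = np.array([3.5, -0.01, 0.2, 0.01])
    D = np.diag([0.09, 1e-4, 0.25, 4e-4])
    params = make_gaussian_params(
        two_gaussian_specs, mu, D, {"albumin": 0.3, "lbili": 0.4}
    )
    vec = parameter_vector(params, two_gaussian_specs)
    assert vec["E[albumin:intercept]"] == pytest.approx(3.5)
    assert vec["SD[lbili:intercept]"] == pytest.approx(0.5)
    assert vec["Corr[albumin:intercept,lbili:intercept]"] == 0.0
    assert vec["SD[albumin:residual]"] == 0.3
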