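"""Group-probability arithmetic, classification rules, and LOOCV plumbing."""

import numpy as np
import pytest

from loda import (
    MCMCConfig,
    MarkerSpec,
    PatientRecord,
    PriorProbabilities,
    StructuralError,
    classify,
    group_probabilities,
    loocv_predict,
    marginal_log_density,
    predict_patients,
)
from loda.model_core import random_effect_layout
from loda.mcmc_fit import PosteriorSamples

from conftest import make_gaussian_params, make_posterior_from_params, tiny_scenario
from loda.synthetic_data import simulate_dataset

SQRT2PI = np.sqrt(2.0 * np.pi)


@pytest.fixture
def gaussian_pair():
    """Two single-marker Gaussian group models with near-zero random-effect
    variance, so the marginal density is a plain normal in the residual SD."""
    spec = MarkerSpec("m", "gaussian")
    # group 0: density 0.5 at y=0; group 1: density 1.0 at y=0
    p0 = make_gaussian_params([spec], [0.0], [[1e-12]], {"m": 2.0 / SQRT2PI})
    p1 = make_gaussian_params([spec], [0.0], [[1e-12]], {"m": 1.0 / SQRT2PI})
    s0 = make_posterior_from_params(p0, [spec], M=1)
    s1 = make_posterior_from_params(p1, [spec], M=1)
    patient = PatientRecord("p", None, {"m": ([0.0], [0.0])})
    return spec, s0, s1, patient


class TestGroupProbabilities:
    def test_identical_models_give_uniform_probabilities(self, two_gaussian_specs):
        mu = np.array([3.5, -0.01, 0.2, 0.01])
        params = make_gaussian_params(
            two_gaussian_specs, mu, np.eye(4) * 0.2, {"albumin": 0.3, "lbili": 0.4}
        )
        samples = make_posterior_from_params(params, two_gaussian_specs, M=4)
        patient = PatientRecord(
            "p", None,
            {"albumin": ([0.0, 5.0], [3.3, 3.6]), "lbili": ([0.0, 5.0], [0.1, 0.4])},
        )
        res = group_probabilities(
            patient, [samples, samples], PriorProbabilities((0.5, 0.5))
        )
        for app, probs in res.probabilities.items():
            np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-9)

    def test_bayes_rule_arithmetic(self, gaussian_pair):
        """pi=(0.8, 0.2), densities (0.5, 1.0) -> P(group 1) = 1/3."""
        spec, s0, s1, patient = gaussian_pair
        res = group_probabilities(
            patient, [s0, s1], PriorProbabilities((0.8, 0.2)), approach="marginal"
        )
        assert res.probabilities["marginal"][1] == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_probabilities_sum_to_one(self, gaussian_pair):
        spec, s0, s1, patient = gaussian_pair
        res = group_probabilities(patient, [s0, s1], PriorProbabilities((0.3, 0.7)))
        for probs in res.probabilities.values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(probs >= 0)

    def test_prior_monotonicity(self, gaussian_pair):
        """Raising a group's prior strictly raises its probability."""
        spec, s0, s1, patient = gaussian_pair
        p_small = group_probabilities(
            patient, [s0, s1], PriorProbabilities((0.9, 0.1)), "marginal"
        ).probabilities["marginal"][1]
        p_large = group_probabilities(
            patient, [s0, s1], PriorProbabilities((0.8, 0.2)), "marginal"
        ).probabilities["marginal"][1]
        assert p_large > p_small

    def test_single_group_probability_one(self, gaussian_pair):
        spec, s0, _, patient = gaussian_pair
        res = group_probabilities(patient, [s0], PriorProbabilities((1.0,)))
        for probs in res.probabilities.values():
            assert probs[0] == pytest.approx(1.0)

    def test_mismatched_draw_counts_rejected(self, gaussian_pair):
        spec, s0, s1, patient = gaussian_pair
        s1big = PosteriorSamples(
            specs=s1.specs, layout=s1.layout,
            mu=np.vstack([s1.mu, s1.mu]), D=np.vstack([s1.D, s1.D]),
            alpha={k: np.vstack([v, v]) for k, v in s1.alpha.items()},
            phi={k: np.concatenate([v, v]) for k, v in s1.phi.items()},
        )
        with pytest.raises(StructuralError):
            group_probabilities(patient, [s0, s1big], PriorProbabilities((0.5, 0.5)))

    def test_marginal_closed_form_vs_monte_carlo(self, two_gaussian_specs):
        """Probabilities from the closed-form marginal agree with a manual
        Monte-Carlo marginal evaluation through Bayes' rule."""
        rng = np.random.default_rng(0)
        specs = two_gaussian_specs
        mu0 = np.array([3.5, -0.01, 0.2, 0.01])
        mu1 = np.array([3.1, -0.02, 0.8, 0.03])
        D = np.diag([0.07, 1e-4, 0.25, 2e-4])
        p0 = make_gaussian_params(specs, mu0, D, {"albumin": 0.3, "lbili": 0.4})
        p1 = make_gaussian_params(specs, mu1, D, {"albumin": 0.3, "lbili": 0.4})
        t = np.array([0.0, 6.0, 12.0])
        patient = PatientRecord(
            "p", None,
            {"albumin": (t, np.array([3.4, 3.2, 3.3])),
             "lbili": (t, np.array([0.5, 0.7, 0.6]))},
        )
        priors = PriorProbabilities((0.8, 0.2))
        res = group_probabilities(
            patient,
            [make_posterior_from_params(p0, specs, 1),
             make_posterior_from_params(p1, specs, 1)],
            priors, "marginal",
        ).probabilities["marginal"]
        logf = np.array(
            [
                marginal_log_density(patient, p, specs, "monte_carlo",
                                     n_draws=60_000, seed=11)
                for p in (p0, p1)
            ]
        )
        z = np.log(priors.probs) + logf
        mc_probs = np.exp(z - z.max())
        mc_probs /= mc_probs.sum()
        np.testing.assert_allclose(res, mc_probs, atol=0.02)


class TestClassify:
    def test_argmax(self):
        assert classify([0.3, 0.7]) == 1

    def test_argmax_tie_goes_low(self):
        assert classify([0.5, 0.5]) == 0

    def test_cutoff_threshold_semantics(self):
        assert classify([0.8, 0.2], "cutoff", cutoff=0.19, positive_group=1) == 1
        assert classify([0.8, 0.2], "cutoff", cutoff=0.21, positive_group=1) == 0
        # ties at the cutoff are negative calls (strict inequality)
        assert classify([0.8, 0.2], "cutoff", cutoff=0.2, positive_group=1) == 0

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            classify([0.5, 0.5], "cutoff", cutoff=1.5)
        with pytest.raises(ValueError):
            classify([0.2, 0.3, 0.5], "cutoff", cutoff=0.5)


def _stub_fit(patients, specs, config):
    """Cheap moment-based pseudo-fit standing in for the MCMC sampler in
    LOOCV plumbing tests (three identical draws at crude estimates)."""
    layout = random_effect_layout(specs)
    q = sum(s.n_random for s in specs)
    mu = np.zeros(q)
    resid = {}
    for s in specs:
        vals = np.concatenate([p.observations[s.name][1] for p in patients])
        idx = layout[s.name]
        mu[idx[0]] = vals.mean()
        resid[s.name] = max(vals.std(), 0.1)
    params = make_gaussian_params(specs, mu, np.eye(q) * 0.05, resid)
    return make_posterior_from_params(params, specs, M=3)


class TestLoocv:
    def test_exact_mode_refit_count(self):
        scn = tiny_scenario(2, 2)
        patients = simulate_dataset(scn, seed=1)
        calls = []

        def counting_fit(patients_, specs_, cfg_):
            calls.append(len(patients_))
            return _stub_fit(patients_, specs_, cfg_)

        loocv_predict(
            patients, scn.specs, MCMCConfig.fast(), mode="exact",
            fit_fn=counting_fit, n_draws=50,
        )
        # 2 shared fits plus one refit per held-out patient
        assert len(calls) == 2 + 4

    def test_fit_once_single_fit_per_group(self):
        scn = tiny_scenario(3, 2)
        patients = simulate_dataset(scn, seed=2)
        calls = []

        def counting_fit(patients_, specs_, cfg_):
            calls.append(len(patients_))
            return _stub_fit(patients_, specs_, cfg_)

        table = loocv_predict(
            patients, scn.specs, MCMCConfig.fast(), mode="fit_once",
            fit_fn=counting_fit, n_draws=50,
        )
        assert len(calls) == 2
        assert len(table) == 5
        probs = table[[c for c in table.columns if c.startswith("P_marginal")]]
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_fit_once_close_to_exact(self):
        """With ~50 patients per group, removing one patient perturbs the fit
        by O(1/n): fit_once and exact probabilities agree within 0.05."""
        scn = tiny_scenario(50, 50)
        patients = simulate_dataset(scn, seed=3)
        kw = dict(fit_fn=_stub_fit, n_draws=80, approaches=("marginal",))
        once = loocv_predict(patients, scn.specs, MCMCConfig.fast(), mode="fit_once", **kw)
        exact = loocv_predict(patients, scn.specs, MCMCConfig.fast(), mode="exact", **kw)
        diff = np.abs(
            once["P_marginal_1"].to_numpy() - exact["P_marginal_1"].to_numpy()
        )
        assert diff.max() < 0.05

    def test_group_with_single_patient_rejected(self):
        scn = tiny_scenario(3, 1)
        patients = simulate_dataset(scn, seed=4)
        with pytest.raises(StructuralError):
            loocv_predict(patients, scn.specs, MCMCConfig.fast(), fit_fn=_stub_fit)

    def test_training_proportion_priors(self):
        scn = tiny_scenario(8, 2)
        patients = simulate_dataset(scn, seed=5)
        pri = PriorProbabilities.from_counts([8, 2])
        assert pri.probs == (0.8, 0.2)
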