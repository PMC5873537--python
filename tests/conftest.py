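"""Shared fixtures: small hand-built models and a miniature scenario."""

import numpy as np
import pytest

from loda import (
    GroupModelParameters,
    MarkerSpec,
    PatientRecord,
    PosteriorSamples,
    RandomEffectsMixture,
)
from loda.model_core import random_effect_layout
from loda.synthetic_data import scenario_from_mapping


def make_gaussian_params(specs, mu, D, residual_sd, fixed=None):
    """Assemble GroupModelParameters for a list of marker specs."""
    layout = random_effect_layout(specs)
    fixed = fixed or {}
    return GroupModelParameters(
        fixed_effects={
            s.name: np.asarray(fixed.get(s.name, np.zeros(s.n_fixed)))
            for s in specs
        },
        residual_sd=dict(residual_sd),
        random_effects=RandomEffectsMixture(
            weights=np.array([1.0]),
            means=np.asarray(mu, dtype=float)[None],
            covariances=np.asarray(D, dtype=float)[None],
        ),
        layout=layout,
    )


def make_posterior_from_params(params, specs, M=3):
    """Degenerate posterior: M identical draws of one parameter set."""
    mix = params.random_effects
    return PosteriorSamples(
        specs=list(specs),
        layout=params.layout,
        mu=np.tile(mix.means[0], (M, 1)),
        D=np.tile(mix.covariances[0], (M, 1, 1)),
        alpha={s.name: np.tile(params.fixed_effects[s.name], (M, 1)) for s in specs},
        phi={
            s.name: np.full(M, params.residual_sd[s.name])
            for s in specs
            if s.dispersion_present
        },
    )


@pytest.fixture
def two_gaussian_specs():
    return [
        MarkerSpec("albumin", "gaussian", has_random_slope=True),
        MarkerSpec("lbili", "gaussian", has_random_slope=True),
    ]


@pytest.fixture
def gaussian_toy(two_gaussian_specs):
    """All-Gaussian toy model: 2 markers, q=4, plus a two-visit patient."""
    rng = np.random.default_rng(42)
    A = rng.standard_normal((4, 4)) * 0.1
    D = A @ A.T + np.diag([0.3, 0.01, 0.5, 0.02])
    mu = np.array([3.5, -0.01, 0.2, 0.01])
    params = make_gaussian_params(
        two_gaussian_specs, mu, D, {"albumin": 0.3, "lbili": 0.4}
    )
    t = np.array([0.0, 6.0])
    patient = PatientRecord(
        "p0",
        None,
        {
            "albumin": (t, np.array([3.4, 3.2])),
            "lbili": (t, np.array([0.6, 0.9])),
        },
    )
    return params, two_gaussian_specs, patient


def tiny_scenario(n0=14, n1=10, seed=0):
    """Miniature two-group, two-Gaussian-marker scenario for fast studies."""
    corr = [
        ["a:intercept", "a:slope", -0.1],
        ["a:intercept", "b:intercept", 0.2],
        ["b:intercept", "b:slope", -0.2],
    ]
    def group(resid_a, resid_b):
        return {
            "means": {"a": {"intercept": 1.0, "slope": 0.0},
                      "b": {"intercept": -1.0, "slope": 0.0}},
            "residual_sd": {"a": resid_a, "b": resid_b},
            "random_effect_sd": {"a": {"intercept": 0.3, "slope": 0.02},
                                 "b": {"intercept": 0.4, "slope": 0.03}},
            "correlations": corr,
        }
    return scenario_from_mapping(
        {
            "name": "tiny",
            "group_sizes": [n0, n1],
            "visit_windows_days": [[150.0, 210.0], [340.0, 400.0], [700.0, 780.0]],
            "markers": [
                {"name": "a", "family": "gaussian", "random_slope": True},
                {"name": "b", "family": "gaussian", "random_slope": True},
            ],
            "groups": [group(0.5, 0.6), group(0.2, 0.25)],
            "seed": seed,
        }
    )
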