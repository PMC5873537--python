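"""Group-membership probabilities and classification rules.

For a new patient with longitudinal history ``y`` and group-specific
posterior draws, Bayes' theorem gives, draw by draw,

    P(U = g | y) = pi_g f_g(y) / sum_h pi_h f_h(y),

where ``f_g`` is one of three predictive densities:

* ``marginal`` — density of the observed trajectories with the random
  effects integrated out (closed form for all-Gaussian models, Monte Carlo
  integration otherwise, with common random numbers across groups);
* ``conditional`` — observation density evaluated at the patient's
  group- and draw-specific random-effects estimate b-hat;
* ``random_effects`` — the random-effects density itself evaluated at b-hat.

The reported probability is the average of the per-draw probabilities over
the retained MCMC draws (an average of ratios, not a ratio of averages).
All density arithmetic is in log space with log-sum-exp normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    DegenerateInputError,
    GroupData,
    MarkerSpec,
    PatientRecord,
    StructuralError,
    _chol,
    _estimate_b_gaussian,
    _estimate_b_laplace,
    _log_mean_exp,
    _marginal_gaussian_closed_form,
)
from .mcmc_fit import MCMCConfig, PosteriorSamples, fit_group_model

__all__ = [
    "APPROACHES",
    "PriorProbabilities",
    "GroupProbabilityResult",
    "group_probabilities",
    "predict_patients",
    "classify",
    "loocv_predict",
]

APPROACHES = ("marginal", "conditional", "random_effects")


@dataclass(frozen=True)
class PriorProbabilities:
    """Prior group-membership probabilities pi_g (nonnegative, summing to 1)."""

    probs: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("priors must be nonnegative and sum to 1")

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "PriorProbabilities":
        """Empirical priors from group sizes in the training population."""
        c = np.asarray(counts, dtype=float)
        return cls(tuple(c / c.sum()))

    @property
    def log(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(np.asarray(self.probs))


@dataclass
class GroupProbabilityResult:
    """Per-approach group-membership probability vectors for one patient."""

    patient_id: str
    probabilities: dict[str, np.ndarray]

    def __post_init__(self):
        for app, p in self.probabilities.items():
            p = np.asarray(p, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-10:
                raise StructuralError(
                    f"approach {app!r}: probabilities must be nonnegative and sum to 1"
                )
            self.probabilities[app] = p


def _ranef_logpdf_batch(bhat: np.ndarray, mu: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Multivariate-normal log density of each row of ``bhat``."""
    L = _chol(D)
    u = np.linalg.solve(L, (bhat - mu).T).T
    return (
        -0.5 * (u**2).sum(axis=1)
        - np.log(np.diag(L)).sum()
        - 0.5 * mu.size * math.log(2.0 * math.pi)
    )


def _per_draw_log_densities(gd: GroupData, params, approaches, eps) -> dict[str, np.ndarray]:
    """Log predictive density of every patient in ``gd`` under one draw of
    one group's parameters; returns {approach: (n,) array}."""
    mix = params.random_effects
    out: dict[str, np.ndarray] = {}
    need_bhat = "conditional" in approaches or "random_effects" in approaches
    if need_bhat:
        if gd.all_gaussian:
            bhat = _estimate_b_gaussian(gd, params)
        else:
            bhat = _estimate_b_laplace(gd, params)
    if "marginal" in approaches:
        if gd.all_gaussian and mix.K == 1:
            out["marginal"] = _marginal_gaussian_closed_form(gd, params)
        else:
            B = mix.means[0] + eps @ _chol(mix.covariances[0]).T
            ll = gd.conditional_log_lik(params, B)  # (draws, n)
            out["marginal"] = _log_mean_exp(ll, axis=0)
    if "conditional" in approaches:
        out["conditional"] = gd.conditional_log_lik(params, bhat)
    if "random_effects" in approaches:
        out["random_effects"] = _ranef_logpdf_batch(
            bhat, mix.means[0], mix.covariances[0]
        )
    return out


def predict_patients(
    patients: Sequence[PatientRecord],
    specs: Sequence[MarkerSpec],
    samples_by_group: Sequence[PosteriorSamples],
    priors: PriorProbabilities,
    approaches: Sequence[str] = APPROACHES,
    n_draws: int = 500,
    prediction_draws: int | None = None,
    seed=0,
) -> pd.DataFrame:
    """Group-membership probabilities for a set of patients.

    Draws are paired across groups by index; ``prediction_draws`` selects an
    evenly spaced subset of the retained draws to average over (all draws if
    ``None``).  ``n_draws`` is the Monte Carlo size of the marginal
    integration when no closed form applies; the same standard-normal draws
    are reused for every group within one MCMC draw (common random numbers).
    Returns one row per patient with columns ``P_<approach>_<g>``.
    """
    approaches = list(approaches)
    for app in approaches:
        if app not in APPROACHES:
            raise ValueError(f"unknown approach {app!r}")
    G = len(samples_by_group)
    if len(priors.probs) != G:
        raise StructuralError("one prior probability per group is required")
    Ms = {s.M for s in samples_by_group}
    if len(Ms) != 1:
        raise StructuralError(
            "posterior sample sizes differ across groups; draws cannot be paired"
        )
    for p in patients:
        if sum(p.n_obs(s.name) for s in specs) == 0:
            raise DegenerateInputError(
                f"patient {p.patient_id!r} has no observations"
            )
    gd = GroupData(patients, specs)
    idx = (
        samples_by_group[0].subsample_indices(prediction_draws)
        if prediction_draws is not None
        else np.arange(samples_by_group[0].M)
    )
    rng = np.random.default_rng(seed)
    n = gd.n
    log_prior = priors.log
    accum = {app: np.zeros((n, G)) for app in approaches}
    for m in idx:
        eps = (
            rng.standard_normal((n_draws, gd.q))
            if ("marginal" in approaches and not gd.all_gaussian)
            else None
        )
        logf = {app: np.empty((n, G)) for app in approaches}
        for g in range(G):
            dens = _per_draw_log_densities(
                gd, samples_by_group[g].params(int(m)), approaches, eps
            )
            for app in approaches:
                logf[app][:, g] = dens[app]
        for app in approaches:
            z = logf[app] + log_prior[None, :]
            zmax = z.max(axis=1, keepdims=True)
            if not np.all(np.isfinite(zmax)):
                bad = int(np.argmax(~np.isfinite(zmax[:, 0])))
                raise DegenerateInputError(
                    f"all group densities vanished for patient "
                    f"{patients[bad].patient_id!r} ({app})"
                )
            w = np.exp(z - zmax)
            accum[app] += w / w.sum(axis=1, keepdims=True)
    rows = []
    for i, p in enumerate(patients):
        row: dict = {"patient_id": p.patient_id, "true_group": p.group}
        for app in approaches:
            probs = accum[app][i] / len(idx)
            for g in range(G):
                row[f"P_{app}_{g}"] = probs[g]
        rows.append(row)
    return pd.DataFrame(rows)


def group_probabilities(
    patient: PatientRecord,
    samples_by_group: Sequence[PosteriorSamples],
    priors: PriorProbabilities,
    approach: str | Sequence[str] = APPROACHES,
    n_draws: int = 500,
    prediction_draws: int | None = None,
    seed=0,
) -> GroupProbabilityResult:
    """Posterior group-membership probabilities for a single patient."""
    approaches = [approach] if isinstance(approach, str) else list(approach)
    specs = samples_by_group[0].specs
    table = predict_patients(
        [patient], specs, samples_by_group, priors, approaches,
        n_draws=n_draws, prediction_draws=prediction_draws, seed=seed,
    )
    G = len(samples_by_group)
    probs = {
        app: np.array([table.loc[0, f"P_{app}_{g}"] for g in range(G)])
        for app in approaches
    }
    return GroupProbabilityResult(patient_id=patient.patient_id, probabilities=probs)


def classify(
    probabilities,
    rule: str = "argmax",
    cutoff: float | None = None,
    positive_group: int = 1,
) -> int:
    """Assign a group from a probability vector.

    ``argmax`` picks the modal group (ties go to the lower index);
    ``cutoff`` (two-group case) assigns ``positive_group`` iff its
    probability strictly exceeds ``cutoff``.
    """
    if isinstance(probabilities, GroupProbabilityResult):
        if len(probabilities.probabilities) != 1:
            raise ValueError("pass a single-approach result or a plain vector")
        probs = next(iter(probabilities.probabilities.values()))
    else:
        probs = np.asarray(probabilities, dtype=float)
    if rule == "argmax":
        return int(np.argmax(probs))
    if rule != "cutoff":
        raise ValueError(f"unknown classification rule {rule!r}")
    if probs.size != 2:
        raise ValueError("the cutoff rule applies to two-group problems only")
    if cutoff is None or not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    other = 1 - positive_group
    return positive_group if probs[positive_group] > cutoff else other


def _split_by_group(patients: Sequence[PatientRecord]) -> dict[int, list[PatientRecord]]:
    groups: dict[int, list[PatientRecord]] = {}
    for p in patients:
        if p.group is None:
            raise StructuralError(f"patient {p.patient_id!r} has no group label")
        groups.setdefault(int(p.group), []).append(p)
    return dict(sorted(groups.items()))


def loocv_predict(
    patients: Sequence[PatientRecord],
    specs: Sequence[MarkerSpec],
    mcmc_config: MCMCConfig,
    approaches: Sequence[str] = APPROACHES,
    mode: str = "fit_once",
    seed=0,
    n_draws: int = 500,
    prediction_draws: int | None = None,
    priors: PriorProbabilities | None = None,
    fit_fn: Callable | None = None,
) -> pd.DataFrame:
    """Cross-validated group probabilities for every labelled patient.

    ``exact`` mode refits the held-out patient's own group model without
    them for every patient (the other groups' models are shared), so a
    patient is never predicted from a model that saw their data.
    ``fit_once`` fits each group model once on all its patients and predicts
    everyone from those shared fits — a documented approximation whose
    leave-one-out perturbation is O(1/n), used for replicated simulation
    studies.  Priors default to the training group proportions.
    """
    if mode not in ("fit_once", "exact"):
        raise ValueError(f"unknown LOOCV mode {mode!r}")
    fit = fit_fn or fit_group_model
    by_group = _split_by_group(patients)
    labels = list(by_group)
    if labels != list(range(len(labels))):
        raise StructuralError("group labels must be consecutive integers from 0")
    for g, members in by_group.items():
        if len(members) < 2:
            raise StructuralError(f"group {g} has fewer than 2 patients")
    if priors is None:
        priors = PriorProbabilities.from_counts([len(by_group[g]) for g in labels])

    ss = np.random.SeedSequence(seed)
    fit_seeds = ss.generate_state(len(labels) + 1)
    pred_seed = int(fit_seeds[-1] % (2**31))

    def fit_group(g, members):
        cfg = MCMCConfig(
            **{
                **mcmc_config.__dict__,
                "seed": int(fit_seeds[g] % (2**31)),
            }
        )
        return fit(members, specs, cfg)

    shared = [fit_group(g, by_group[g]) for g in labels]

    if mode == "fit_once":
        return predict_patients(
            patients, specs, shared, priors, approaches,
            n_draws=n_draws, prediction_draws=prediction_draws, seed=pred_seed,
        )

    frames = []
    for p in patients:
        g = int(p.group)
        held_out = [q for q in by_group[g] if q.patient_id != p.patient_id]
        models = list(shared)
        models[g] = fit_group(g, held_out)
        frames.append(
            predict_patients(
                [p], specs, models, priors, approaches,
                n_draws=n_draws, prediction_draws=prediction_draws, seed=pred_seed,
            )
        )
    return pd.concat(frames, ignore_index=True)
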