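"""Synthetic longitudinal datasets for the two-group simulation scenarios.

A ``ScenarioDefinition`` bundles group sizes, a visit schedule (day 0 plus
uniform windows), per-group true model parameters and the marker structure.
Two presets ship with the package:

* ``scenario1`` — four markers (two Gaussian, one Poisson count, one
  Bernoulli indicator with a fixed time slope); the groups differ in mean
  profiles and share a common 7x7 random-effects covariance.
* ``scenario2`` — the two Gaussian markers only; the groups share means and
  random-effects covariance and differ solely in residual error scale.

``simulate_dataset`` draws, per patient: the visit days, one random-effects
vector from the group's (mixture-of-)normal distribution, and observations
from the family distribution at the linear predictor.  Identical seeds give
byte-identical datasets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .model_core import (
    MONTHS_PER_DAY,
    GroupModelParameters,
    MarkerSpec,
    PatientRecord,
    RandomEffectsMixture,
    StructuralError,
    random_effect_layout,
)

__all__ = [
    "ScenarioDefinition",
    "builtin_scenario",
    "scenario_from_mapping",
    "simulate_dataset",
    "assemble_covariance",
]


@dataclass
class ScenarioDefinition:
    """Generative design of one simulation scenario."""

    name: str
    group_sizes: list[int]
    visit_windows_days: list[tuple[float, float]]
    specs: list[MarkerSpec]
    group_params: list[GroupModelParameters]
    months_per_day: float = MONTHS_PER_DAY
    seed: int = 0

    def __post_init__(self):
        if len(self.group_sizes) != len(self.group_params):
            raise StructuralError("one parameter set per group is required")
        last_hi = 0.0
        for lo, hi in self.visit_windows_days:
            if not (lo < hi) or lo < last_hi:
                raise StructuralError(
                    "visit windows must be increasing and non-overlapping"
                )
            last_hi = hi
        for params in self.group_params:
            params.validate_against(self.specs)

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)


def assemble_covariance(sd, corr, repair: bool = False) -> np.ndarray:
    """Build D = diag(sd) R diag(sd) from per-effect SDs and pairwise
    correlations.

    ``corr`` may be a full correlation matrix or a mapping from index pairs
    ``(i, j)`` to correlations; unlisted pairs are 0.  The result is checked
    for positive definiteness; with ``repair=True`` a non-PD matrix is
    projected to the nearest positive definite matrix by eigenvalue clipping.
    """
    sd = np.asarray(sd, dtype=float)
    if sd.ndim != 1 or np.any(sd <= 0):
        raise StructuralError("per-effect SDs must be a 1-d array of positives")
    q = sd.size
    if isinstance(corr, Mapping):
        R = np.eye(q)
        for (i, j), rho in corr.items():
            R[i, j] = R[j, i] = float(rho)
    else:
        R = np.array(corr, dtype=float)
        if R.shape != (q, q) or not np.allclose(R, R.T, atol=1e-10):
            raise StructuralError("correlation matrix must be symmetric q x q")
    if not np.allclose(np.diag(R), 1.0):
        raise StructuralError("correlation matrix must have unit diagonal")
    if np.any(np.abs(R) > 1.0 + 1e-12):
        raise StructuralError("correlations must lie in [-1, 1]")
    D = sd[:, None] * R * sd[None, :]
    evals = np.linalg.eigvalsh(D)
    if evals.min() <= 0:
        if not repair:
            raise StructuralError(
                "assembled covariance is not positive definite "
                f"(min eigenvalue {evals.min():.3g}); pass repair=True to "
                "project to the nearest positive definite matrix"
            )
        w, V = np.linalg.eigh(D)
        D = (V * np.clip(w, 1e-8, None)) @ V.T
    return D


# ---------------------------------------------------------------------------
# Scenario construction from structured config
# ---------------------------------------------------------------------------

_TOP_KEYS = {"name", "group_sizes", "visit_windows_days", "markers", "groups", "seed"}
_MARKER_KEYS = {"name", "family", "random_intercept", "random_slope", "fixed_slope"}
_GROUP_KEYS = {"means", "fixed", "residual_sd", "random_effect_sd", "correlations"}


def _reject_unknown(mapping: Mapping, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise StructuralError(f"{context}: unknown keys {sorted(unknown)}")


def scenario_from_mapping(cfg: Mapping) -> ScenarioDefinition:
    """Build a ``ScenarioDefinition`` from a parsed YAML/JSON mapping."""
    _reject_unknown(cfg, _TOP_KEYS, "scenario config")
    specs = []
    for m in cfg["markers"]:
        _reject_unknown(m, _MARKER_KEYS, f"marker {m.get('name')!r}")
        specs.append(
            MarkerSpec(
                name=m["name"],
                family=m["family"],
                has_random_intercept=bool(m.get("random_intercept", True)),
                has_random_slope=bool(m.get("random_slope", False)),
                has_fixed_slope=bool(m.get("fixed_slope", False)),
            )
        )
    layout = random_effect_layout(specs)
    effect_index: dict[str, int] = {}
    for s in specs:
        idx = layout[s.name]
        pos = 0
        if s.has_random_intercept:
            effect_index[f"{s.name}:intercept"] = int(idx[pos])
            pos += 1
        if s.has_random_slope:
            effect_index[f"{s.name}:slope"] = int(idx[pos])
    q = sum(s.n_random for s in specs)

    group_params = []
    for gi, g in enumerate(cfg["groups"]):
        _reject_unknown(g, _GROUP_KEYS, f"group {gi}")
        mu = np.zeros(q)
        sd = np.zeros(q)
        for s in specs:
            means = g["means"].get(s.name, {})
            sds = g["random_effect_sd"].get(s.name, {})
            for term in ("intercept", "slope"):
                key = f"{s.name}:{term}"
                if key in effect_index:
                    if term not in means or term not in sds:
                        raise StructuralError(
                            f"group {gi}: missing mean or SD for effect {key!r}"
                        )
                    mu[effect_index[key]] = float(means[term])
                    sd[effect_index[key]] = float(sds[term])
        corr: dict[tuple[int, int], float] = {}
        for e1, e2, rho in g.get("correlations", []):
            if e1 not in effect_index or e2 not in effect_index:
                raise StructuralError(
                    f"group {gi}: correlation names unknown effect ({e1!r}, {e2!r})"
                )
            rho = float(rho)
            if abs(rho) > 1:
                raise StructuralError(
                    f"group {gi}: correlation [{e1}, {e2}] = {rho} outside [-1, 1]"
                )
            corr[(effect_index[e1], effect_index[e2])] = rho
        try:
            D = assemble_covariance(sd, corr)
        except StructuralError as exc:
            raise StructuralError(f"group {gi}: {exc}") from exc
        fixed = {
            s.name: np.array(
                [float(g.get("fixed", {}).get(s.name, {}).get("slope", 0.0))]
            )
            if s.has_fixed_slope
            else np.empty(0)
            for s in specs
        }
        resid = {k: float(v) for k, v in g.get("residual_sd", {}).items()}
        group_params.append(
            GroupModelParameters(
                fixed_effects=fixed,
                residual_sd=resid,
                random_effects=RandomEffectsMixture(
                    weights=np.array([1.0]), means=mu[None], covariances=D[None]
                ),
                layout=layout,
            )
        )

    return ScenarioDefinition(
        name=str(cfg["name"]),
        group_sizes=[int(n) for n in cfg["group_sizes"]],
        visit_windows_days=[(float(a), float(b)) for a, b in cfg["visit_windows_days"]],
        specs=specs,
        group_params=group_params,
        seed=int(cfg.get("seed", 0)),
    )


def builtin_scenario(name: str) -> ScenarioDefinition:
    """Return one of the shipped scenario presets (``scenario1``/``scenario2``)."""
    if name not in ("scenario1", "scenario2"):
        raise KeyError(f"unknown builtin scenario {name!r}")
    text = (
        importlib.resources.files("loda.presets").joinpath(f"{name}.yaml").read_text()
    )
    return scenario_from_mapping(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_dataset(scn: ScenarioDefinition, seed=None,
                     return_random_effects: bool = False):
    """Simulate one replicate dataset.

    Every patient receives all markers at the same four visits: day 0 plus
    one uniform draw per declared window, converted to months.  Returns the
    list of ``PatientRecord`` (and, optionally, the matrix of drawn
    random-effects vectors for diagnostic use).
    """
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    records: list[PatientRecord] = []
    all_b = []
    pid = 0
    for g, (size, params) in enumerate(zip(scn.group_sizes, scn.group_params)):
        lows = np.array([w[0] for w in scn.visit_windows_days])
        highs = np.array([w[1] for w in scn.visit_windows_days])
        days = np.concatenate(
            [np.zeros((size, 1)), rng.uniform(lows, highs, size=(size, lows.size))],
            axis=1,
        )
        tm = days * scn.months_per_day  # (size, n_visits)
        B = params.random_effects.sample(size, rng)
        all_b.append(B)
        values: dict[str, np.ndarray] = {}
        for s in scn.specs:
            idx = params.layout[s.name]
            eta = np.zeros_like(tm)
            pos = 0
            if s.has_random_intercept:
                eta += B[:, idx[pos]][:, None]
                pos += 1
            if s.has_random_slope:
                eta += B[:, idx[pos]][:, None] * tm
            if s.has_fixed_slope:
                eta += params.fixed_effects[s.name][0] * tm
            if s.family == "gaussian":
                y = eta + params.residual_sd[s.name] * rng.standard_normal(tm.shape)
            elif s.family == "poisson":
                y = rng.poisson(np.exp(eta)).astype(float)
            else:
                y = (rng.random(tm.shape) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
            values[s.name] = y
        for i in range(size):
            records.append(
                PatientRecord(
                    patient_id=f"p{pid:04d}",
                    group=g,
                    observations={
                        s.name: (tm[i], values[s.name][i]) for s in scn.specs
                    },
                )
            )
            pid += 1
    if return_random_effects:
        return records, np.concatenate(all_b, axis=0)
    return records
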