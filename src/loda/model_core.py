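"""Core model types and densities for longitudinal discriminant analysis.

The data model is a multivariate generalised linear mixed model (MGLMM): each
of R longitudinal markers (Gaussian, Poisson or Bernoulli) observed repeatedly
over time follows a GLMM whose linear predictor combines marker-specific fixed
coefficients with a patient-level random-effects vector ``b`` shared across
markers,

    h_r^{-1}( E[Y_rj | b] ) = x_rj' a_r + z_rj' b ,

with canonical links (identity / log / logit) per family.  The joint
random-effects distribution is a mixture of multivariate normals (a single
component in all fitted models here).  Group-specific parameter sets
(``GroupModelParameters``) drive three predictive densities used for
classification:

* the conditional density of the observations given ``b``,
* the marginal density with ``b`` integrated out (closed form when every
  marker is Gaussian, Monte Carlo otherwise), and
* the random-effects density itself, evaluated at a patient-specific
  estimate of ``b``.

Everything downstream (MCMC fitting, group-probability computation, the
simulation study) consumes the types and functions defined here.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "MONTHS_PER_DAY",
    "LodaError",
    "StructuralError",
    "NumericError",
    "UnsupportedMethodError",
    "ConvergenceError",
    "DegenerateInputError",
    "MarkerSpec",
    "PatientRecord",
    "RandomEffectsMixture",
    "GroupModelParameters",
    "DesignRow",
    "random_effect_layout",
    "design_row",
    "conditional_log_density",
    "random_effects_log_density",
    "marginal_log_density",
    "estimate_random_effects",
    "parameter_names",
    "parameter_vector",
]

# Calendar conversion used when visit schedules are recorded in days while the
# model clock runs in months.
MONTHS_PER_DAY = 12.0 / 365.25

# Ridge added to covariance diagonals before factorisation so that degenerate
# (rank-deficient) matrices remain factorisable.
_COV_RIDGE = 1e-10

_FAMILIES = ("gaussian", "poisson", "bernoulli")
_CANONICAL_LINK = {"gaussian": "identity", "poisson": "log", "bernoulli": "logit"}


class LodaError(Exception):
    """Base class for errors raised by this package."""


class StructuralError(LodaError):
    """Model structure is inconsistent (dimensions, layouts, invalid matrices)."""


class NumericError(LodaError):
    """A computation produced non-finite intermediate values."""


class UnsupportedMethodError(LodaError):
    """A closed-form method was requested outside its domain of validity."""


class ConvergenceError(LodaError):
    """An iterative solver failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DegenerateInputError(LodaError):
    """Input carries no usable information (e.g. all densities vanish)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerSpec:
    """Structure of one marker's GLMM: family, link and design flags.

    ``dispersion_present`` is implied by the family (only Gaussian markers
    carry a residual standard deviation).  A marker must have at least one
    random term, and a random slope excludes a separate fixed slope.
    """

    name: str
    family: str
    has_random_intercept: bool = True
    has_random_slope: bool = False
    has_fixed_slope: bool = False

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise StructuralError(
                f"marker {self.name!r}: unknown family {self.family!r}"
            )
        if not (self.has_random_intercept or self.has_random_slope):
            raise StructuralError(
                f"marker {self.name!r}: needs a random intercept or slope"
            )
        if self.has_random_slope and self.has_fixed_slope:
            raise StructuralError(
                f"marker {self.name!r}: random slope excludes a fixed slope"
            )

    @property
    def link(self) -> str:
        return _CANONICAL_LINK[self.family]

    @property
    def dispersion_present(self) -> bool:
        return self.family == "gaussian"

    @property
    def n_random(self) -> int:
        return int(self.has_random_intercept) + int(self.has_random_slope)

    @property
    def n_fixed(self) -> int:
        return int(self.has_fixed_slope)

    def validate_values(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if self.family == "poisson":
            if np.any(values < 0) or np.any(values != np.round(values)):
                raise StructuralError(
                    f"marker {self.name!r}: Poisson values must be "
                    "nonnegative integers"
                )
        elif self.family == "bernoulli":
            if not np.isin(values, (0.0, 1.0)).all():
                raise StructuralError(
                    f"marker {self.name!r}: Bernoulli values must be 0/1"
                )
        elif not np.all(np.isfinite(values)):
            raise StructuralError(
                f"marker {self.name!r}: Gaussian values must be finite"
            )


@dataclass
class PatientRecord:
    """One patient's longitudinal observations, keyed by marker name.

    ``observations`` maps marker name to ``(times, values)`` arrays; times are
    in months, strictly increasing within a marker, and markers may have
    different numbers of observations.  ``group`` is the prognostic group
    label (``None`` while unknown).
    """

    patient_id: str
    group: int | None
    observations: dict[str, tuple[np.ndarray, np.ndarray]]
    covariates: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        clean = {}
        for name, (t, y) in self.observations.items():
            t = np.asarray(t, dtype=float)
            y = np.asarray(y, dtype=float)
            if t.shape != y.shape or t.ndim != 1:
                raise StructuralError(
                    f"patient {self.patient_id!r}, marker {name!r}: times and "
                    "values must be 1-d arrays of equal length"
                )
            if t.size and np.any(t < 0):
                raise StructuralError(
                    f"patient {self.patient_id!r}, marker {name!r}: times must "
                    "be nonnegative"
                )
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise StructuralError(
                    f"patient {self.patient_id!r}, marker {name!r}: times must "
                    "be strictly increasing"
                )
            clean[name] = (t, y)
        self.observations = clean

    def n_obs(self, marker: str) -> int:
        if marker not in self.observations:
            return 0
        return self.observations[marker][0].size


@dataclass
class RandomEffectsMixture:
    """Mixture-of-normals distribution of the joint random-effects vector."""

    weights: np.ndarray
    means: np.ndarray  # (K, q)
    covariances: np.ndarray  # (K, q, q)

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None, :, :]
        K, q = self.means.shape
        if self.weights.shape != (K,) or self.covariances.shape != (K, q, q):
            raise StructuralError("mixture weight/mean/covariance shapes disagree")
        if np.any(self.weights < 0) or not math.isclose(
            self.weights.sum(), 1.0, abs_tol=1e-8
        ):
            raise StructuralError("mixture weights must be nonnegative and sum to 1")
        for k in range(K):
            C = self.covariances[k]
            if not np.allclose(C, C.T, atol=1e-8):
                raise StructuralError(f"component {k}: covariance not symmetric")
            if np.linalg.eigvalsh(C).min() <= -1e-10:
                raise StructuralError(f"component {k}: covariance not positive definite")

    @property
    def K(self) -> int:
        return self.weights.size

    @property
    def q(self) -> int:
        return self.means.shape[1]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` random-effects vectors."""
        comp = rng.choice(self.K, size=n, p=self.weights / self.weights.sum())
        eps = rng.standard_normal((n, self.q))
        out = np.empty((n, self.q))
        for k in range(self.K):
            sel = comp == k
            if sel.any():
                L = _chol(self.covariances[k])
                out[sel] = self.means[k] + eps[sel] @ L.T
        return out


@dataclass
class GroupModelParameters:
    """Full parameter set (psi, theta) of one group's MGLMM.

    ``fixed_effects`` maps marker name to its fixed-coefficient vector (for
    the canonical designs used here, a length-1 slope for markers with a fixed
    time effect, empty otherwise).  ``residual_sd`` holds the Gaussian
    markers' residual standard deviations.  ``layout`` maps marker name to the
    indices its random effects occupy in the joint q-vector.
    """

    fixed_effects: dict[str, np.ndarray]
    residual_sd: dict[str, float]
    random_effects: RandomEffectsMixture
    layout: dict[str, np.ndarray]

    def __post_init__(self):
        self.fixed_effects = {
            k: np.atleast_1d(np.asarray(v, dtype=float))
            for k, v in self.fixed_effects.items()
        }
        self.layout = {
            k: np.asarray(v, dtype=int) for k, v in self.layout.items()
        }
        q = self.random_effects.q
        used = np.concatenate([v for v in self.layout.values()]) if self.layout else []
        if sorted(used) != list(range(q)):
            raise StructuralError(
                "random-effect layout must partition 0..q-1 exactly"
            )

    @property
    def q(self) -> int:
        return self.random_effects.q

    def validate_against(self, specs: Sequence[MarkerSpec]) -> None:
        for s in specs:
            if self.fixed_effects.get(s.name, np.empty(0)).size != s.n_fixed:
                raise StructuralError(
                    f"marker {s.name!r}: fixed-coefficient length does not "
                    "match its design"
                )
            if self.layout.get(s.name, np.empty(0, int)).size != s.n_random:
                raise StructuralError(
                    f"marker {s.name!r}: random-effect layout does not match "
                    "its design"
                )
            if s.dispersion_present and s.name not in self.residual_sd:
                raise StructuralError(
                    f"marker {s.name!r}: Gaussian marker needs a residual SD"
                )


@dataclass(frozen=True)
class DesignRow:
    """Fixed- and random-design vectors for one observation of one marker."""

    x: np.ndarray
    z: np.ndarray


def random_effect_layout(specs: Sequence[MarkerSpec]) -> dict[str, np.ndarray]:
    """Canonical layout: markers in order, intercept before slope."""
    layout, pos = {}, 0
    for s in specs:
        layout[s.name] = np.arange(pos, pos + s.n_random)
        pos += s.n_random
    return layout


def design_row(spec: MarkerSpec, t: float) -> DesignRow:
    """Design vectors at time ``t`` (months) for one marker observation."""
    z = []
    if spec.has_random_intercept:
        z.append(1.0)
    if spec.has_random_slope:
        z.append(t)
    x = [t] if spec.has_fixed_slope else []
    return DesignRow(np.asarray(x), np.asarray(z))


# ---------------------------------------------------------------------------
# Batched data container
# ---------------------------------------------------------------------------


def _chol(A: np.ndarray) -> np.ndarray:
    """Cholesky with a tiny diagonal ridge; accepts stacked matrices."""
    A = np.asarray(A, dtype=float)
    eye = np.eye(A.shape[-1])
    try:
        return np.linalg.cholesky(A + _COV_RIDGE * eye)
    except np.linalg.LinAlgError as exc:
        raise StructuralError(f"matrix not positive definite: {exc}") from exc


class GroupData:
    """Padded, mask-weighted arrays for a set of patients sharing one design.

    For each marker ``r``: ``t[r]`` (n, J_r) observation times, ``y[r]``
    values, ``w[r]`` 0/1 observation mask, ``Z[r]`` (n, J_r, q_r) random
    design and ``X[r]`` (n, J_r, p_r) fixed design.  Padding rows carry zero
    weight and contribute nothing to any density.
    """

    def __init__(self, patients: Sequence[PatientRecord], specs: Sequence[MarkerSpec]):
        self.specs = list(specs)
        self.patients = list(patients)
        self.layout = random_effect_layout(specs)
        self.q = sum(s.n_random for s in specs)
        n = len(patients)
        self.n = n
        self.t, self.y, self.w, self.Z, self.X = {}, {}, {}, {}, {}
        for s in specs:
            J = max((p.n_obs(s.name) for p in patients), default=0)
            J = max(J, 1)  # keep arrays non-empty for broadcasting
            t = np.zeros((n, J))
            y = np.zeros((n, J))
            w = np.zeros((n, J))
            for i, p in enumerate(patients):
                if s.name in p.observations:
                    ti, yi = p.observations[s.name]
                    s.validate_values(yi)
                    t[i, : ti.size] = ti
                    y[i, : yi.size] = yi
                    w[i, : yi.size] = 1.0
            Zcols = []
            if s.has_random_intercept:
                Zcols.append(np.ones_like(t))
            if s.has_random_slope:
                Zcols.append(t)
            Z = np.stack(Zcols, axis=-1) * w[..., None]
            X = (t * w)[..., None] if s.has_fixed_slope else np.zeros((n, J, 0))
            self.t[s.name], self.y[s.name], self.w[s.name] = t, y, w
            self.Z[s.name], self.X[s.name] = Z, X
        # Pre-computed Poisson normalising constants (independent of params).
        self._lgamma = {
            s.name: gammaln(self.y[s.name] + 1.0) * self.w[s.name]
            for s in specs
            if s.family == "poisson"
        }
        self.gauss_idx = np.concatenate(
            [self.layout[s.name] for s in specs if s.family == "gaussian"]
            or [np.empty(0, int)]
        ).astype(int)
        self.nongauss_idx = np.array(
            sorted(set(range(self.q)) - set(self.gauss_idx.tolist())), dtype=int
        )
        self.all_gaussian = all(s.family == "gaussian" for s in specs)

    # -- batched conditional log density -----------------------------------

    def linear_predictor(self, spec: MarkerSpec, params: GroupModelParameters,
                         B: np.ndarray) -> np.ndarray:
        """eta for one marker.  ``B`` is (..., q); result (..., n, J)."""
        idx = self.layout[spec.name]
        Z = self.Z[spec.name]
        Br = np.asarray(B)[..., idx]
        if Br.ndim == 2 and Br.shape[0] == self.n:  # per-patient vectors
            eta = np.einsum("njk,nk->nj", Z, Br)
        else:  # shared draws broadcast over patients
            eta = np.einsum("njk,...k->...nj", Z, Br)
        alpha = params.fixed_effects.get(spec.name, np.empty(0))
        if alpha.size:
            eta = eta + self.X[spec.name] @ alpha
        return eta

    def marker_log_lik(self, spec: MarkerSpec, params: GroupModelParameters,
                       B: np.ndarray) -> np.ndarray:
        """Masked per-patient log likelihood of one marker; (..., n)."""
        eta = self.linear_predictor(spec, params, B)
        y, w = self.y[spec.name], self.w[spec.name]
        if spec.family == "gaussian":
            phi = params.residual_sd[spec.name]
            ll = -0.5 * ((y - eta) / phi) ** 2 - math.log(phi) - 0.5 * math.log(2 * math.pi)
        elif spec.family == "poisson":
            with np.errstate(over="ignore"):
                ll = y * eta - np.exp(eta) - self._lgamma[spec.name]
        else:  # bernoulli, logit link
            ll = y * eta - np.logaddexp(0.0, eta)
        return (ll * w).sum(axis=-1)

    def conditional_log_lik(self, params: GroupModelParameters,
                            B: np.ndarray) -> np.ndarray:
        out = 0.0
        for s in self.specs:
            out = out + self.marker_log_lik(s, params, B)
        return out

    # -- stacked Gaussian machinery (closed forms) --------------------------

    def gaussian_stack(self, params: GroupModelParameters):
        """Stack all Gaussian markers' observations into flat per-patient
        arrays: residual-adjusted y, Z (n, Jtot, q), residual variances and
        mask.  Padded rows get unit residual variance and zero design."""
        rs, Zs, vs, ws = [], [], [], []
        for s in self.specs:
            if s.family != "gaussian":
                continue
            idx = self.layout[s.name]
            w = self.w[s.name]
            resid = self.y[s.name].copy()
            alpha = params.fixed_effects.get(s.name, np.empty(0))
            if alpha.size:
                resid = resid - self.X[s.name] @ alpha
            Zfull = np.zeros((self.n, w.shape[1], self.q))
            Zfull[..., idx] = self.Z[s.name]
            rs.append(resid * w)
            Zs.append(Zfull)
            vs.append(np.where(w > 0, params.residual_sd[s.name] ** 2, 1.0))
            ws.append(w)
        return (
            np.concatenate(rs, axis=1),
            np.concatenate(Zs, axis=1),
            np.concatenate(vs, axis=1),
            np.concatenate(ws, axis=1),
        )


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------


def _check_b(b: np.ndarray, q: int) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if b.shape != (q,):
        raise StructuralError(f"random-effects vector has shape {b.shape}, expected ({q},)")
    return b


def conditional_log_density(patient: PatientRecord, b: np.ndarray,
                            params: GroupModelParameters,
                            specs: Sequence[MarkerSpec]) -> float:
    """Log density of the patient's observations given random effects ``b``.

    Sum over markers and visits of exponential-family log densities with
    linear predictor ``x'a + z'b`` through the canonical link.
    """
    params.validate_against(specs)
    gd = GroupData([patient], specs)
    b = _check_b(b, gd.q)
    val = float(gd.conditional_log_lik(params, b[None, :])[0])
    if not np.isfinite(val):
        for s in specs:
            eta = gd.linear_predictor(s, params, b[None, :])
            if not np.all(np.isfinite(eta * gd.w[s.name])):
                j = int(np.argmax(~np.isfinite(eta[0])))
                raise NumericError(
                    f"non-finite linear predictor for marker {s.name!r}, "
                    f"observation {j}"
                )
        raise NumericError("non-finite conditional log density")
    return val


def _mvn_logpdf(b: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    L = _chol(cov)
    u = np.linalg.solve(L, b - mean)
    return float(
        -0.5 * u @ u - np.log(np.diag(L)).sum() - 0.5 * b.size * math.log(2 * math.pi)
    )


def random_effects_log_density(b: np.ndarray, mix: RandomEffectsMixture) -> float:
    """Log of the mixture-of-normals random-effects density at ``b``."""
    b = _check_b(b, mix.q)
    comps = np.array(
        [
            math.log(max(w, 1e-300)) + _mvn_logpdf(b, m, C)
            for w, m, C in zip(mix.weights, mix.means, mix.covariances)
        ]
    )
    m = comps.max()
    return float(m + math.log(np.exp(comps - m).sum()))


def _marginal_gaussian_closed_form(gd: GroupData, params: GroupModelParameters) -> np.ndarray:
    """Exact log marginal density for all-Gaussian, single-component models;
    vectorised over the patients in ``gd``.  y ~ N(Xa + Z mu, Z D Z' + S)."""
    mix = params.random_effects
    mu, D = mix.means[0], mix.covariances[0]
    resid, Z, v, w = gd.gaussian_stack(params)
    r = resid - np.einsum("njk,k->nj", Z, mu)
    V = np.einsum("njk,kl,nml->njm", Z, D, Z) + np.einsum(
        "jk,nj->njk", np.eye(r.shape[1]), v
    )
    L = _chol(V)
    u = np.linalg.solve(L, r[..., None])[..., 0]
    logdet = 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=-1)
    # padded rows have v=1, r=0, Z=0: contribute 0 to both terms
    n_obs = w.sum(axis=1)
    return -0.5 * (u**2).sum(axis=-1) - 0.5 * logdet - 0.5 * n_obs * math.log(2 * math.pi)


def _log_mean_exp(a: np.ndarray, axis: int = 0):
    m = np.max(a, axis=axis, keepdims=True)
    out = np.log(np.mean(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out


def marginal_log_density(patient: PatientRecord, params: GroupModelParameters,
                         specs: Sequence[MarkerSpec], method: str = "auto",
                         n_draws: int = 10_000, seed=None,
                         return_se: bool = False):
    """Log marginal density of the patient's markers, random effects
    integrated out.

    ``closed_form`` (all-Gaussian, single-component only) evaluates the exact
    multivariate normal density; ``monte_carlo`` averages the conditional
    density over ``n_draws`` samples from the random-effects distribution with
    log-sum-exp stabilisation.  With ``return_se`` the Monte Carlo method also
    returns a delta-method standard error of the log density (0 for the
    closed form).
    """
    params.validate_against(specs)
    gd = GroupData([patient], specs)
    mix = params.random_effects
    if method == "auto":
        method = "closed_form" if (gd.all_gaussian and mix.K == 1) else "monte_carlo"
    if method == "closed_form":
        if not (gd.all_gaussian and mix.K == 1):
            raise UnsupportedMethodError(
                "closed-form marginal requires all-Gaussian markers and a "
                "single-component random-effects distribution"
            )
        val = float(_marginal_gaussian_closed_form(gd, params)[0])
        return (val, 0.0) if return_se else val
    if method != "monte_carlo":
        raise UnsupportedMethodError(f"unknown marginal method {method!r}")
    rng = np.random.default_rng(seed)
    B = mix.sample(n_draws, rng)
    ll = gd.conditional_log_lik(params, B)[:, 0]  # (n_draws,)
    val = float(_log_mean_exp(ll))
    if return_se:
        w = np.exp(ll - ll.max())
        se = float(np.std(w) / (np.mean(w) * math.sqrt(n_draws)))
        return val, se
    return val


# ---------------------------------------------------------------------------
# Random-effects estimation (single-component models)
# ---------------------------------------------------------------------------


def _require_single_component(mix: RandomEffectsMixture) -> None:
    if mix.K != 1:
        raise UnsupportedMethodError(
            "random-effects estimation is supported for single-component "
            "random-effects distributions only"
        )


def _estimate_b_gaussian(gd: GroupData, params: GroupModelParameters) -> np.ndarray:
    """Posterior mean of b under an all-Gaussian model (conjugate algebra);
    vectorised over patients: b = mu + D Z' V^{-1} (y - Xa - Z mu)."""
    mix = params.random_effects
    mu, D = mix.means[0], mix.covariances[0]
    resid, Z, v, _ = gd.gaussian_stack(params)
    r = resid - np.einsum("njk,k->nj", Z, mu)
    V = np.einsum("njk,kl,nml->njm", Z, D, Z) + np.einsum(
        "jk,nj->njk", np.eye(r.shape[1]), v
    )
    sol = np.linalg.solve(V, r[..., None])[..., 0]
    return mu + np.einsum("kl,njl,nj->nk", D, Z, sol)


def _laplace_gradient_hessian(gd: GroupData, params: GroupModelParameters,
                              B: np.ndarray):
    """Gradient and Hessian of the conditional log likelihood at per-patient
    B (n, q), summed over markers; returns (grad (n,q), hess (n,q,q))."""
    n, q = gd.n, gd.q
    grad = np.zeros((n, q))
    hess = np.zeros((n, q, q))
    for s in gd.specs:
        idx = gd.layout[s.name]
        Z, y, w = gd.Z[s.name], gd.y[s.name], gd.w[s.name]
        eta = gd.linear_predictor(s, params, B)
        if s.family == "gaussian":
            inv_v = 1.0 / params.residual_sd[s.name] ** 2
            resid = (y - eta) * w * inv_v
            W = w * inv_v
        elif s.family == "poisson":
            mu_ = np.exp(np.clip(eta, -700, 700))
            resid = (y - mu_) * w
            W = mu_ * w
        else:
            p = 1.0 / (1.0 + np.exp(-eta))
            resid = (y - p) * w
            W = p * (1.0 - p) * w
        grad[:, idx] += np.einsum("njk,nj->nk", Z, resid)
        hess[np.ix_(range(n), idx, idx)] -= np.einsum("nj,njk,njl->nkl", W, Z, Z)
    return grad, hess


def _estimate_b_laplace(gd: GroupData, params: GroupModelParameters,
                        max_iter: int = 60, tol: float = 1e-9) -> np.ndarray:
    """Posterior mode of b by damped Newton iteration, vectorised over
    patients.  The objective (log likelihood + normal prior) is concave for
    the canonical families, so Newton with step halving converges."""
    mix = params.random_effects
    _require_single_component(mix)
    mu, D = mix.means[0], mix.covariances[0]
    Dinv = np.linalg.inv(D + _COV_RIDGE * np.eye(gd.q))
    B = np.tile(mu, (gd.n, 1))

    def objective(Bcur):
        diff = Bcur - mu
        prior = -0.5 * np.einsum("nk,kl,nl->n", diff, Dinv, diff)
        return gd.conditional_log_lik(params, Bcur) + prior

    obj = objective(B)
    for _ in range(max_iter):
        grad, hess = _laplace_gradient_hessian(gd, params, B)
        grad = grad - (B - mu) @ Dinv
        hess = hess - Dinv
        step = np.linalg.solve(-hess, grad[..., None])[..., 0]
        gnorm = np.abs(grad).max(axis=1)
        if np.all(gnorm < tol):
            break
        scale = np.ones(gd.n)
        for _ in range(30):  # per-patient step halving
            cand = B + scale[:, None] * step
            new_obj = objective(cand)
            bad = ~(new_obj >= obj - 1e-12)
            if not bad.any():
                break
            scale[bad] *= 0.5
        B = B + scale[:, None] * step
        obj = objective(B)
    else:
        grad, _ = _laplace_gradient_hessian(gd, params, B)
        grad = grad - (B - mu) @ Dinv
        if np.abs(grad).max() > 1e-4:
            raise ConvergenceError(
                "Newton iteration for the random-effects mode did not converge",
                last_iterate=B,
            )
    return B


def estimate_random_effects(patient: PatientRecord, params: GroupModelParameters,
                            specs: Sequence[MarkerSpec],
                            method: str = "auto") -> np.ndarray:
    """Patient-specific random-effects estimate under one group's parameters.

    ``closed_form`` (all-Gaussian models) returns the exact posterior mean;
    ``laplace`` returns the posterior mode found by Newton iteration, used as
    a mean surrogate for models with non-Gaussian markers (for all-Gaussian
    models the two coincide).
    """
    params.validate_against(specs)
    _require_single_component(params.random_effects)
    gd = GroupData([patient], specs)
    if method == "auto":
        method = "closed_form" if gd.all_gaussian else "laplace"
    if method == "closed_form":
        if not gd.all_gaussian:
            raise UnsupportedMethodError(
                "closed-form random-effects estimation requires all-Gaussian markers"
            )
        return _estimate_b_gaussian(gd, params)[0]
    if method != "laplace":
        raise UnsupportedMethodError(f"unknown estimation method {method!r}")
    return _estimate_b_laplace(gd, params)[0]


# ---------------------------------------------------------------------------
# Parameter naming (used by posterior summaries and recovery tables)
# ---------------------------------------------------------------------------


def parameter_names(specs: Sequence[MarkerSpec]) -> list[str]:
    """Canonical parameter labels: means (random-effect means and fixed
    coefficients), random-effect SDs, pairwise correlations, residual SDs."""
    labels = []
    effect_labels = _effect_labels(specs)
    for s in specs:
        if s.has_random_intercept:
            labels.append(f"E[{s.name}:intercept]")
        if s.has_random_slope:
            labels.append(f"E[{s.name}:slope]")
        if s.has_fixed_slope:
            labels.append(f"E[{s.name}:slope]")
    labels += [f"SD[{e}]" for e in effect_labels]
    for i in range(len(effect_labels)):
        for j in range(i + 1, len(effect_labels)):
            labels.append(f"Corr[{effect_labels[i]},{effect_labels[j]}]")
    labels += [f"SD[{s.name}:residual]" for s in specs if s.dispersion_present]
    return labels


def _effect_labels(specs: Sequence[MarkerSpec]) -> list[str]:
    out = []
    for s in specs:
        if s.has_random_intercept:
            out.append(f"{s.name}:intercept")
        if s.has_random_slope:
            out.append(f"{s.name}:slope")
    return out


def parameter_vector(params: GroupModelParameters,
                     specs: Sequence[MarkerSpec]) -> dict[str, float]:
    """Flatten a parameter set into the canonical labelled scalar map."""
    params.validate_against(specs)
    mix = params.random_effects
    _require_single_component(mix)
    mu, D = mix.means[0], mix.covariances[0]
    layout = params.layout
    out: dict[str, float] = {}
    for s in specs:
        idx = layout[s.name]
        pos = 0
        if s.has_random_intercept:
            out[f"E[{s.name}:intercept]"] = float(mu[idx[pos]])
            pos += 1
        if s.has_random_slope:
            out[f"E[{s.name}:slope]"] = float(mu[idx[pos]])
        if s.has_fixed_slope:
            out[f"E[{s.name}:slope]"] = float(params.fixed_effects[s.name][0])
    sd = np.sqrt(np.diag(D))
    effect_labels = _effect_labels(specs)
    for e, s_val in zip(effect_labels, sd):
        out[f"SD[{e}]"] = float(s_val)
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, D / np.where(denom > 0, denom, 1.0), 0.0)
    for i in range(len(effect_labels)):
        for j in range(i + 1, len(effect_labels)):
            out[f"Corr[{effect_labels[i]},{effect_labels[j]}]"] = float(corr[i, j])
    for s in specs:
        if s.dispersion_present:
            out[f"SD[{s.name}:residual]"] = float(params.residual_sd[s.name])
    return out
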