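"""Bayesian estimation of one group's MGLMM by Markov chain Monte Carlo.

The sampler is a block Gibbs scheme with Metropolis steps where no conjugate
update exists:

* patient random effects ``b_i`` — exact multivariate-normal draw for the
  Gaussian-marker coordinates (conditionally conjugate); for the coordinates
  attached to Poisson/Bernoulli markers, an independence Metropolis-Hastings
  step per marker block, proposing from a Newton-mode (Laplace) normal
  approximation of the block's conditional posterior;
* joint "scale moves" that rescale one coordinate's deviations and D's
  matching row/column together, traversing the slowly mixing variance
  direction of the hierarchy;
* Gaussian-marker fixed coefficients and residual precisions — conjugate
  normal / gamma draws;
* non-Gaussian fixed coefficients — adaptive random-walk Metropolis;
* the random-effects mean ``mu`` — conjugate normal draw given the ``b_i``;
* the random-effects covariance ``D`` — conjugate inverse-Wishart draw.

Priors are weakly informative: N(0, 1e4) on every mean-type coefficient,
Gamma(1, 0.005) on residual precisions, and a Huang-Wand hierarchical
inverse-Wishart on ``D`` (marginal half-t on each random-effect SD, uniform
correlations; see docs/methods.md).  Proposal scales adapt toward
a target acceptance rate during burn-in only, so the retained chain is a
valid Markov chain.  Fitting supports single-component random-effects
distributions, as used throughout the simulation study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .model_core import (
    GroupData,
    GroupModelParameters,
    LodaError,
    MarkerSpec,
    PatientRecord,
    RandomEffectsMixture,
    StructuralError,
    _chol,
    parameter_names,
)

__all__ = ["MCMCConfig", "PosteriorSamples", "SamplerError",
           "fit_group_model", "posterior_summary"]

# Prior hyperparameters (see module docstring).
_MEAN_PRIOR_PRECISION = 1e-4          # N(0, 1e4) on coefficients and mu
_PHI_PRIOR_SHAPE = 1.0                # Gamma(1, 0.005) on 1/phi^2
_PHI_PRIOR_RATE = 0.005
# Huang-Wand hierarchical prior on D: D | a ~ inverse-Wishart(nu+q-1,
# 2*nu*diag(1/a_k)), a_k ~ inverse-gamma(1/2, 1/A^2); marginally each
# random-effect SD has a half-t(nu) prior with scale A and the correlations
# are uniform.  A plain inverse-Wishart with a fixed scalar scale either
# dominates the tiny slope variances (scale too large) or loses its
# degeneracy barrier and piles mass on |corr| -> 1 (scale too small); the
# adaptive diagonal scale avoids both.
_HW_NU = 2.0
_HW_SCALE_A = 10.0

# Laplace independence proposals for non-Gaussian random-effect blocks.
_NEWTON_STEPS = 4
_PROPOSAL_INFLATION = 1.3             # widen proposal covariance for tail cover


def _block_grad_curv(gd, spec, params, b, x, idx):
    """Gradient and curvature (negative Hessian) of one marker's log
    likelihood with respect to its own random-effect block, evaluated with
    that block set to ``x`` (n, k); other coordinates taken from ``b``."""
    B_full = b.copy()
    B_full[:, idx] = x
    Z, y, w = gd.Z[spec.name], gd.y[spec.name], gd.w[spec.name]
    eta = gd.linear_predictor(spec, params, B_full)
    if spec.family == "poisson":
        mu_ = np.exp(np.clip(eta, -700, 30))
        resid = (y - mu_) * w
        W = mu_ * w
    else:  # bernoulli
        p = 1.0 / (1.0 + np.exp(-eta))
        resid = (y - p) * w
        W = p * (1.0 - p) * w
    grad = np.einsum("njk,nj->nk", Z, resid)
    curv = np.einsum("nj,njk,njl->nkl", W, Z, Z)
    return grad, curv


class SamplerError(LodaError):
    """The chain reached a non-finite state."""


@dataclass
class MCMCConfig:
    """Chain length and tuning constants.

    ``n_kept`` draws are retained after ``burn_in`` iterations, keeping every
    ``thin``-th iteration.  ``default()`` is the cluster-scale profile
    (10,000 kept, 1:10 thinning, burn-in 500); ``fast()`` is a desk-scale
    profile (1,000 kept, 1:2 thinning, burn-in 200).
    """

    n_kept: int = 10_000
    burn_in: int = 500
    thin: int = 10
    seed: int = 0
    target_acceptance: float = 0.35
    initial_step: float = 0.4
    adapt_rate: float = 1.0
    scale_moves: bool = True

    def __post_init__(self):
        if self.n_kept <= 0:
            raise ValueError("n_kept must be positive; an empty chain is not a fit")
        if self.burn_in < 0 or self.thin < 1:
            raise ValueError("burn_in must be >= 0 and thin >= 1")

    @classmethod
    def default(cls, seed: int = 0) -> "MCMCConfig":
        return cls(n_kept=10_000, burn_in=500, thin=10, seed=seed)

    @classmethod
    def fast(cls, seed: int = 0) -> "MCMCConfig":
        return cls(n_kept=1_000, burn_in=200, thin=2, seed=seed)

    @classmethod
    def profile(cls, name: str, seed: int = 0) -> "MCMCConfig":
        if name == "full":
            return cls.default(seed)
        if name == "fast":
            return cls.fast(seed)
        raise KeyError(f"unknown MCMC profile {name!r}")


@dataclass
class PosteriorSamples:
    """Retained draws of one group's model parameters.

    Draws are stored columnarly (``mu``: (M, q); ``D``: (M, q, q); per-marker
    fixed coefficients and residual SDs) and materialised on demand as
    ``GroupModelParameters`` via :meth:`params`.
    """

    specs: list[MarkerSpec]
    layout: dict[str, np.ndarray]
    mu: np.ndarray
    D: np.ndarray
    alpha: dict[str, np.ndarray]
    phi: dict[str, np.ndarray]
    acceptance: dict[str, float] = field(default_factory=dict)
    b_draws: np.ndarray | None = None

    @property
    def M(self) -> int:
        return self.mu.shape[0]

    @property
    def q(self) -> int:
        return self.mu.shape[1]

    def params(self, m: int) -> GroupModelParameters:
        return GroupModelParameters(
            fixed_effects={k: v[m] for k, v in self.alpha.items()},
            residual_sd={k: float(v[m]) for k, v in self.phi.items()},
            random_effects=RandomEffectsMixture(
                weights=np.array([1.0]),
                means=self.mu[m][None],
                covariances=self.D[m][None],
            ),
            layout=self.layout,
        )

    def subsample_indices(self, n: int) -> np.ndarray:
        """Evenly spaced draw indices (deterministic)."""
        n = min(n, self.M)
        return np.unique(np.linspace(0, self.M - 1, n).round().astype(int))

    def parameter_draws(self) -> pd.DataFrame:
        """All draws flattened to the canonical labelled parameters; (M, P)."""
        cols: dict[str, np.ndarray] = {}
        for s in self.specs:
            idx = self.layout[s.name]
            pos = 0
            if s.has_random_intercept:
                cols[f"E[{s.name}:intercept]"] = self.mu[:, idx[pos]]
                pos += 1
            if s.has_random_slope:
                cols[f"E[{s.name}:slope]"] = self.mu[:, idx[pos]]
            if s.has_fixed_slope:
                cols[f"E[{s.name}:slope]"] = self.alpha[s.name][:, 0]
        sd = np.sqrt(np.diagonal(self.D, axis1=1, axis2=2))  # (M, q)
        labels = []
        for s in self.specs:
            if s.has_random_intercept:
                labels.append(f"{s.name}:intercept")
            if s.has_random_slope:
                labels.append(f"{s.name}:slope")
        for j, lab in enumerate(labels):
            cols[f"SD[{lab}]"] = sd[:, j]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                cols[f"Corr[{labels[i]},{labels[j]}]"] = self.D[:, i, j] / (
                    sd[:, i] * sd[:, j]
                )
        for s in self.specs:
            if s.dispersion_present:
                cols[f"SD[{s.name}:residual]"] = self.phi[s.name]
        return pd.DataFrame(cols)


def _hpd_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the sorted draws."""
    x = np.sort(draws)
    M = x.size
    m = max(1, min(M, math.ceil(level * M)))
    widths = x[m - 1 :] - x[: M - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def posterior_summary(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, highest-posterior-density interval and SD per parameter."""
    if not 0.0 < level < 1.0:
        raise ValueError("credibility level must lie strictly in (0, 1)")
    if samples.M < 2:
        raise ValueError("posterior summary requires at least two draws")
    draws = samples.parameter_draws()
    rows = []
    for name in draws.columns:
        x = draws[name].to_numpy()
        lo, hi = _hpd_interval(x, level)
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "hpd_low": lo,
                "hpd_high": hi,
                "sd": float(x.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


def _init_state(gd: GroupData):
    """Initial values from crude per-patient moment fits.

    Each patient's random effects start at simple link-scale estimates
    (per-patient mean / log-mean / smoothed logit, with a per-patient least
    squares slope for markers carrying a random slope); ``mu`` and ``D``
    start at the empirical mean and covariance of those estimates.  Starting
    the hierarchy at the data's own spread avoids the sticky near-degenerate
    state a collapsed initialisation produces for weakly informed variance
    components (binary markers with few visits).
    """
    q, n = gd.q, gd.n
    b = np.zeros((n, q))
    phi = {}
    alpha = {s.name: np.zeros(s.n_fixed) for s in gd.specs}
    for s in gd.specs:
        y, w, t = gd.y[s.name], gd.w[s.name], gd.t[s.name]
        n_i = np.maximum(w.sum(axis=1), 1.0)
        ysum = (y * w).sum(axis=1)
        if s.family == "gaussian":
            level = ysum / n_i
            resid2 = (((y - level[:, None]) ** 2) * w).sum() / w.sum()
            phi[s.name] = math.sqrt(max(resid2, 1e-6))
        elif s.family == "poisson":
            level = np.log((ysum + 0.5) / n_i)
        else:
            level = np.log((ysum + 0.5) / (n_i - ysum + 0.5))
        idx = gd.layout[s.name]
        pos = 0
        if s.has_random_intercept:
            b[:, idx[pos]] = level
            pos += 1
        if s.has_random_slope:
            tbar = (t * w).sum(axis=1) / n_i
            tc = (t - tbar[:, None]) * w
            stt = (tc**2).sum(axis=1)
            # link-scale working response for the slope estimate
            if s.family == "gaussian":
                resp = y
            elif s.family == "poisson":
                resp = np.log(y + 0.5)
            else:
                resp = y
            slope = np.where(stt > 0, (tc * resp).sum(axis=1) / np.maximum(stt, 1e-12), 0.0)
            b[:, idx[pos]] = slope
    mu = b.mean(axis=0)
    D = np.cov(b.T) if n > 1 else np.eye(q)
    D = np.atleast_2d(D) + 1e-4 * np.eye(q)
    return mu, D, b, alpha, phi


def fit_group_model(patients, specs, config: MCMCConfig) -> PosteriorSamples:
    """Fit one prognostic group's MGLMM; returns the retained posterior draws.

    Requires at least two patients and observations for every declared
    marker.  Seeded configurations are exactly repeatable.
    """
    specs = list(specs)
    if len(patients) < 2:
        raise StructuralError("fitting requires at least two patients")
    gd = GroupData(patients, specs)
    for s in specs:
        if gd.w[s.name].sum() == 0:
            raise StructuralError(f"marker {s.name!r} has no observations")
    rng = np.random.default_rng(config.seed)
    n, q = gd.n, gd.q
    G_idx, N_idx = gd.gauss_idx, gd.nongauss_idx
    gauss_specs = [s for s in specs if s.family == "gaussian"]
    ng_specs = [s for s in specs if s.family != "gaussian"]
    mh_alpha_specs = [s for s in ng_specs if s.n_fixed > 0]

    mu, D, b, alpha, phi = _init_state(gd)

    # Precomputations for the Gaussian conjugate blocks.
    ZtZ = {
        s.name: np.einsum("njk,njl->nkl", gd.Z[s.name], gd.Z[s.name])
        for s in gauss_specs
    }
    XtX = {
        s.name: np.einsum("njk,njl->kl", gd.X[s.name], gd.X[s.name])
        for s in gauss_specs
        if s.n_fixed
    }

    # Adaptive Metropolis state for the non-Gaussian fixed coefficients.
    log_step_a = {s.name: math.log(config.initial_step) for s in mh_alpha_specs}
    acc_b_sum = {s.name: 0.0 for s in ng_specs}
    acc_b_n = 0
    acc_a_sum = {s.name: 0.0 for s in mh_alpha_specs}
    acc_a_n = 0
    log_step_s = np.full(q, math.log(0.3))
    a_hw = np.ones(q)
    _coord_marker = {}
    for s in specs:
        for k in gd.layout[s.name]:
            _coord_marker[int(k)] = s

    def _pack_params():
        return GroupModelParameters(
            fixed_effects=dict(alpha),
            residual_sd=dict(phi),
            random_effects=RandomEffectsMixture(
                weights=np.array([1.0]), means=mu[None], covariances=D[None]
            ),
            layout=gd.layout,
        )

    total = config.burn_in + config.n_kept * config.thin
    kept_mu = np.empty((config.n_kept, q))
    kept_D = np.empty((config.n_kept, q, q))
    kept_alpha = {s.name: np.empty((config.n_kept, s.n_fixed)) for s in specs}
    kept_phi = {s.name: np.empty(config.n_kept) for s in gauss_specs}
    kept = 0

    eye_q = np.eye(q)
    for it in range(total):
        adapting = it < config.burn_in
        Lam = np.linalg.inv(D + 1e-12 * eye_q)

        # --- b: Gaussian coordinates, exact conditional draw ---------------
        if G_idx.size:
            Lam_GG = Lam[np.ix_(G_idx, G_idx)]
            prior_h = np.tile(Lam_GG @ mu[G_idx], (n, 1))
            if N_idx.size:
                Lam_GN = Lam[np.ix_(G_idx, N_idx)]
                prior_h -= (b[:, N_idx] - mu[N_idx]) @ Lam_GN.T
            A = np.tile(Lam_GG, (n, 1, 1))
            h = prior_h.copy()
            for s in gauss_specs:
                idx = gd.layout[s.name]
                inv_v = 1.0 / phi[s.name] ** 2
                gpos = np.searchsorted(G_idx, idx)
                A[np.ix_(range(n), gpos, gpos)] += ZtZ[s.name] * inv_v
                resid = gd.y[s.name] * gd.w[s.name]
                if s.n_fixed:
                    resid = resid - (gd.X[s.name] @ alpha[s.name]) * gd.w[s.name]
                h[:, gpos] += np.einsum("njk,nj->nk", gd.Z[s.name], resid) * inv_v
            L = np.linalg.cholesky(A)
            mean = np.linalg.solve(A, h[..., None])[..., 0]
            eps = rng.standard_normal((n, G_idx.size))
            # draw = mean + L^{-T} eps
            pert = np.linalg.solve(np.transpose(L, (0, 2, 1)), eps[..., None])[..., 0]
            b[:, G_idx] = mean + pert

        # --- b: non-Gaussian coordinates, Laplace independence Metropolis-
        # Hastings, one block per marker, conditioning on the rest ----------
        # A local random walk mixes these weakly informed coordinates too
        # slowly: their draws stay close to the conditional mean given the
        # other coordinates, which inflates the estimated cross-correlations
        # in D and collapses the block's variance.  Proposing from a
        # Newton-mode normal approximation of the conditional posterior
        # decorrelates successive draws and removes that feedback.
        params_now = _pack_params()
        for s in ng_specs:
            idx = gd.layout[s.name]
            rest = np.array(sorted(set(range(q)) - set(idx.tolist())), dtype=int)
            k = idx.size
            Lam_bb = Lam[np.ix_(idx, idx)]
            hB = np.tile(Lam_bb @ mu[idx], (n, 1))
            if rest.size:
                Lam_br = Lam[np.ix_(idx, rest)]
                hB = hB - (b[:, rest] - mu[rest]) @ Lam_br.T
            m_cond = np.linalg.solve(Lam_bb, hB.T).T  # conditional prior mean

            def prior_quad(bb):
                return -0.5 * np.einsum("nk,kl,nl->n", bb, Lam_bb, bb) + (
                    bb * hB
                ).sum(axis=1)

            def block_target(bb):
                B_full = b.copy()
                B_full[:, idx] = bb
                return gd.marker_log_lik(s, params_now, B_full) + prior_quad(bb)

            # Newton mode of the conditional posterior, started from the
            # conditional prior mean so the proposal is state-independent.
            x = m_cond.copy()
            H = np.tile(Lam_bb, (n, 1, 1))
            for _ in range(_NEWTON_STEPS):
                grad, H_lik = _block_grad_curv(gd, s, params_now, b, x, idx)
                H = H_lik + Lam_bb
                g = grad - np.einsum("kl,nl->nk", Lam_bb, x - m_cond)
                step = np.linalg.solve(H, g[..., None])[..., 0]
                bad = ~np.isfinite(step).all(axis=1)
                step[bad] = 0.0
                x = x + np.clip(step, -5.0, 5.0)
            Lh = np.linalg.cholesky(H)

            def prop_logq(bb):
                d = bb - x
                u = np.einsum("nkl,nl->nk", np.transpose(Lh, (0, 2, 1)), d)
                return (
                    -0.5 / _PROPOSAL_INFLATION * (u**2).sum(axis=1)
                    + np.log(np.diagonal(Lh, axis1=1, axis2=2)).sum(axis=1)
                )

            eps = rng.standard_normal((n, k))
            pert = np.linalg.solve(np.transpose(Lh, (0, 2, 1)), eps[..., None])[..., 0]
            prop = x + math.sqrt(_PROPOSAL_INFLATION) * pert
            cur = b[:, idx].copy()
            log_ratio = (
                block_target(prop)
                - block_target(cur)
                + prop_logq(cur)
                - prop_logq(prop)
            )
            accept = np.log(rng.random(n)) < log_ratio
            rows = accept.nonzero()[0]
            if rows.size:
                b[np.ix_(rows, idx)] = prop[rows]
            if not adapting:
                acc_b_sum[s.name] += accept.mean()
        if not adapting:
            acc_b_n += 1

        # --- fixed coefficients --------------------------------------------
        for s in gauss_specs:
            if not s.n_fixed:
                continue
            idx = gd.layout[s.name]
            inv_v = 1.0 / phi[s.name] ** 2
            resid = (gd.y[s.name] - np.einsum("njk,nk->nj", gd.Z[s.name], b[:, idx])) * gd.w[s.name]
            P = XtX[s.name] * inv_v + _MEAN_PRIOR_PRECISION * np.eye(s.n_fixed)
            hvec = np.einsum("njk,nj->k", gd.X[s.name], resid) * inv_v
            La = np.linalg.cholesky(P)
            mean = np.linalg.solve(P, hvec)
            alpha[s.name] = mean + np.linalg.solve(
                La.T, rng.standard_normal(s.n_fixed)
            )
        params_now = _pack_params()
        for s in mh_alpha_specs:
            cur = alpha[s.name]
            cur_ll = gd.marker_log_lik(s, params_now, b).sum() - 0.5 * _MEAN_PRIOR_PRECISION * (cur @ cur)
            prop_a = cur + math.exp(log_step_a[s.name]) * rng.standard_normal(s.n_fixed)
            alpha[s.name] = prop_a
            params_prop = _pack_params()
            new_ll = gd.marker_log_lik(s, params_prop, b).sum() - 0.5 * _MEAN_PRIOR_PRECISION * (prop_a @ prop_a)
            log_ratio = new_ll - cur_ll
            if math.log(rng.random()) < log_ratio:
                accepted = 1.0
            else:
                alpha[s.name] = cur
                accepted = 0.0
            aprob = math.exp(min(0.0, log_ratio))
            if adapting:
                gamma = config.adapt_rate / (it + 1) ** 0.6
                log_step_a[s.name] += gamma * (aprob - config.target_acceptance)
            else:
                acc_a_sum[s.name] += accepted
        if not adapting:
            acc_a_n += 1

        # --- residual variances --------------------------------------------
        for s in gauss_specs:
            idx = gd.layout[s.name]
            eta = np.einsum("njk,nk->nj", gd.Z[s.name], b[:, idx])
            if s.n_fixed:
                eta = eta + gd.X[s.name] @ alpha[s.name]
            ssr = (((gd.y[s.name] - eta) ** 2) * gd.w[s.name]).sum()
            N_obs = gd.w[s.name].sum()
            prec = rng.gamma(_PHI_PRIOR_SHAPE + 0.5 * N_obs,
                             1.0 / (_PHI_PRIOR_RATE + 0.5 * ssr))
            phi[s.name] = 1.0 / math.sqrt(prec)

        # --- random-effects mean and covariance ----------------------------
        P_mu = n * Lam + _MEAN_PRIOR_PRECISION * eye_q
        h_mu = Lam @ b.sum(axis=0)
        Lmu = np.linalg.cholesky(P_mu)
        mu = np.linalg.solve(P_mu, h_mu) + np.linalg.solve(
            Lmu.T, rng.standard_normal(q)
        )
        centred = b - mu
        S_post = 2.0 * _HW_NU * np.diag(1.0 / a_hw) + centred.T @ centred
        D = invwishart.rvs(df=_HW_NU + q - 1 + n, scale=S_post, random_state=rng)
        D = np.atleast_2d(D)
        Dinv_new = np.linalg.inv(D + 1e-12 * eye_q)
        a_hw = (
            _HW_NU * np.diag(Dinv_new) + 1.0 / _HW_SCALE_A**2
        ) / rng.gamma(0.5 * (_HW_NU + q), 1.0, size=q)

        # --- joint scale moves ---------------------------------------------
        # Variance components are the slow direction of a Gibbs scan: given
        # the b's, D barely moves, and given D the b's barely spread.  A
        # Metropolis move that rescales coordinate k's deviations (b_k - mu_k)
        # and D's k-th row/column by a common factor c traverses that
        # direction directly.  The normal prior terms and the b-Jacobian
        # cancel exactly, leaving the marker likelihood, the inverse-Wishart
        # prior ratio and a residual Jacobian factor c^(q+1).
        params_now = _pack_params()
        Dinv = np.linalg.inv(D + 1e-12 * eye_q)
        for k in (range(q) if config.scale_moves else ()):
            s_k = _coord_marker[k]
            logc = math.exp(log_step_s[k]) * rng.standard_normal()
            c = math.exp(logc)
            b_prop = b.copy()
            b_prop[:, k] = mu[k] + c * (b[:, k] - mu[k])
            cur_ll = gd.marker_log_lik(s_k, params_now, b).sum()
            new_ll = gd.marker_log_lik(s_k, params_now, b_prop).sum()
            log_ratio = (
                new_ll
                - cur_ll
                - (_HW_NU + q - 1) * logc
                - (_HW_NU / a_hw[k]) * Dinv[k, k] * (1.0 / c**2 - 1.0)
            )
            if math.log(rng.random()) < log_ratio:
                b = b_prop
                D[k, :] *= c
                D[:, k] *= c
                Dinv[k, :] /= c
                Dinv[:, k] /= c
            aprob = math.exp(min(0.0, log_ratio))
            if adapting:
                gamma = config.adapt_rate / (it + 1) ** 0.6
                log_step_s[k] += gamma * (aprob - config.target_acceptance)

        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(mu)) and np.all(np.isfinite(D))):
            raise SamplerError(f"non-finite sampler state at iteration {it}")

        if not adapting and (it - config.burn_in) % config.thin == config.thin - 1:
            kept_mu[kept] = mu
            kept_D[kept] = D
            for s in specs:
                if s.n_fixed:
                    kept_alpha[s.name][kept] = alpha[s.name]
            for s in gauss_specs:
                kept_phi[s.name][kept] = phi[s.name]
            kept += 1

    acceptance = {}
    for s in ng_specs:
        if acc_b_n:
            acceptance[f"b[{s.name}]"] = float(acc_b_sum[s.name] / acc_b_n)
    for s in mh_alpha_specs:
        if acc_a_n:
            acceptance[f"alpha[{s.name}]"] = acc_a_sum[s.name] / acc_a_n

    return PosteriorSamples(
        specs=specs,
        layout=gd.layout,
        mu=kept_mu[:kept],
        D=kept_D[:kept],
        alpha={k: v[:kept] for k, v in kept_alpha.items()},
        phi={k: v[:kept] for k, v in kept_phi.items()},
        acceptance=acceptance,
    )
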