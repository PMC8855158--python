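"""Posterior-mode estimation and nonparametric bootstrap inference.

The joint density is maximized with L-BFGS over an unconstrained, non-centered
parameterization:

* positive scales (kappa, tau, omega, zeta, sigma_beta, sigma_delta) are
  optimized as logarithms, with the log-transform volume adjustment added to
  the objective — the raw density is unbounded along the horseshoe funnel
  (kappa -> 0 with alpha -> alpha_tilde), whereas the adjusted objective is
  bounded above;
* loadings are non-centered: alpha_{gf;t} = alpha_tilde_gf + kappa_{gf;t}
  tau_f eta_{gf;t} with eta ~ Normal(0, 1) as the free parameter, and likewise
  alpha_tilde_gf = zeta [omega_gf] eta_tilde_gf.

Uncertainty comes from a within-group nonparametric bootstrap: cells are
resampled with replacement independently inside each condition (group sizes
preserved), the mode is re-estimated on each replicate, and the replicate
correlation structures provide draws of rho_{gg';t} and theta_{gg'}.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace

import numpy as np
from joblib import Parallel, delayed
from scipy.optimize import minimize
from scipy.special import gammaln

from .model import (CountDataset, ModelSpec, ParameterState, half_cauchy_logpdf,
                    _LOG_2PI)
from .network import marginal_correlation, pairs_to_vector

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when optimization (or too many bootstrap replicates) fails."""


@dataclass
class FitResult:
    """A posterior-mode estimate: the state at the optimum and diagnostics."""

    state: ParameterState
    log_joint: float
    converged: bool
    n_iterations: int
    seed: int


@dataclass
class BootstrapResult:
    """Replicate draws of the edge statistics from the within-group bootstrap."""

    M_b: int
    theta_draws: np.ndarray      # (n_converged, P)
    rho0_draws: np.ndarray
    rho1_draws: np.ndarray
    converged: np.ndarray        # (M_b,) per-replicate flags
    base_seed: int

    @property
    def n_converged(self) -> int:
        return int(np.sum(self.converged))


class _Objective:
    """Negative adjusted log-joint and its gradient on the unconstrained scale.

    Parameter vector layout: beta (G), delta (G), lam (N*F), eta (G*F*2),
    eta_tilde (G*F), log kappa (G*F*2), log tau (F), [log omega (G*F), DHS
    only], log zeta, log sigma_beta, log sigma_delta.
    """

    def __init__(self, dataset: CountDataset, spec: ModelSpec):
        self.spec = spec
        self.G, self.N = dataset.n_genes, dataset.n_cells
        self.F = spec.n_factors
        self.dhs = spec.variant == "DHS"
        self.cap = spec.log_mean_cap
        self.idx = [dataset.group_indices(t) for t in (0, 1)]
        self.y = [dataset.counts[:, self.idx[t]].astype(float) for t in (0, 1)]
        self.lgamma_const = float(np.sum(gammaln(dataset.counts + 1.0)))
        G, N, F = self.G, self.N, self.F
        sizes = [G, G, N * F, G * F * 2, G * F, G * F * 2, F]
        if self.dhs:
            sizes.append(G * F)
        sizes += [1, 1, 1]
        self.offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.n_params = int(self.offsets[-1])

    def _split(self, x: np.ndarray) -> list[np.ndarray]:
        return [x[self.offsets[k]:self.offsets[k + 1]]
                for k in range(len(self.offsets) - 1)]

    def unpack(self, x: np.ndarray) -> ParameterState:
        """Natural-parameterization state at an unconstrained point."""
        G, N, F = self.G, self.N, self.F
        parts = self._split(x)
        beta, delta = parts[0], parts[1]
        lam = parts[2].reshape(N, F)
        eta = parts[3].reshape(G, F, 2)
        eta_t = parts[4].reshape(G, F)
        kappa = np.exp(parts[5].reshape(G, F, 2))
        tau = np.exp(parts[6])
        k = 7
        if self.dhs:
            omega = np.exp(parts[k].reshape(G, F))
            k += 1
        else:
            omega = np.ones((G, F))
        zeta = float(np.exp(parts[k][0]))
        sb = float(np.exp(parts[k + 1][0]))
        sd = float(np.exp(parts[k + 2][0]))
        alpha_tilde = zeta * (omega * eta_t if self.dhs else eta_t)
        alpha = alpha_tilde[:, :, None] + kappa * tau[None, :, None] * eta
        return ParameterState(beta=beta.copy(), delta=delta.copy(), alpha=alpha,
                              alpha_tilde=alpha_tilde, kappa=kappa, tau=tau,
                              omega=omega, zeta=zeta, sigma_beta=sb,
                              sigma_delta=sd, lam=lam)

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        G, N, F = self.G, self.N, self.F
        parts = self._split(x)
        beta, delta = parts[0], parts[1]
        lam = parts[2].reshape(N, F)
        eta = parts[3].reshape(G, F, 2)
        eta_t = parts[4].reshape(G, F)
        u_kappa = parts[5].reshape(G, F, 2)
        u_tau = parts[6]
        k = 7
        if self.dhs:
            u_omega = parts[k].reshape(G, F)
            omega = np.exp(u_omega)
            k += 1
        else:
            omega = None
        u_zeta, u_sb, u_sd = parts[k][0], parts[k + 1][0], parts[k + 2][0]
        kappa = np.exp(u_kappa)
        tau = np.exp(u_tau)
        zeta = np.exp(u_zeta)
        sb, sd = np.exp(u_sb), np.exp(u_sd)

        scale_t = zeta * omega if self.dhs else zeta  # d alpha_tilde / d eta_tilde
        alpha_tilde = scale_t * eta_t
        ktau = kappa * tau[None, :, None]
        alpha = alpha_tilde[:, :, None] + ktau * eta   # (G, F, 2)

        L = 0.0
        grad = np.zeros_like(x)
        g_parts = self._split(grad)
        g_beta, g_delta = g_parts[0], g_parts[1]
        g_lam = g_parts[2].reshape(N, F)
        g_eta = g_parts[3].reshape(G, F, 2)
        g_eta_t = g_parts[4].reshape(G, F)
        g_ukap = g_parts[5].reshape(G, F, 2)
        g_utau = g_parts[6]
        kk = 7
        if self.dhs:
            g_uom = g_parts[kk].reshape(G, F)
            kk += 1
        g_uzeta, g_usb, g_usd = (g_parts[kk], g_parts[kk + 1], g_parts[kk + 2])

        A_alpha = np.zeros((G, F, 2))  # dL/dalpha_{gf;t}
        for t in (0, 1):
            idx = self.idx[t]
            if idx.size == 0:
                continue
            a_t = alpha[:, :, t]                       # (G, F)
            lam_t = lam[idx]                           # (Nt, F)
            raw = (beta + t * delta - 0.5 * np.sum(a_t * a_t, axis=1))[:, None] \
                + a_t @ lam_t.T                        # (G, Nt)
            m = np.minimum(raw, self.cap)
            mu = np.exp(m)
            yt = self.y[t]
            L += float(np.sum(yt * m - mu))
            R = (yt - mu) * (raw < self.cap)           # dL/dm
            rs = R.sum(axis=1)                         # (G,)
            g_beta += rs
            if t == 1:
                g_delta += rs
            g_lam[idx] += R.T @ a_t
            A_alpha[:, :, t] = R @ lam_t - rs[:, None] * a_t
        L -= self.lgamma_const

        # standard-normal priors on lam, eta, eta_tilde
        L += -0.5 * float(np.sum(lam * lam)) - 0.5 * N * F * _LOG_2PI
        L += -0.5 * float(np.sum(eta * eta)) - 0.5 * G * F * 2 * _LOG_2PI
        L += -0.5 * float(np.sum(eta_t * eta_t)) - 0.5 * G * F * _LOG_2PI
        g_lam -= lam
        g_eta += A_alpha * ktau - eta
        A_sum = A_alpha.sum(axis=2)                    # (G, F)
        g_eta_t += A_sum * scale_t - eta_t

        # half-Cauchy hyperpriors + log-scale volume adjustments
        def hc_term(u, val):
            # sum of log hc(e^u) + u; returns (value, d/du elementwise)
            return (float(np.sum(half_cauchy_logpdf(val) + u)),
                    -2.0 * val * val / (1.0 + val * val) + 1.0)

        v, d = hc_term(u_kappa, kappa)
        L += v
        g_ukap += A_alpha * (tau[None, :, None] * eta) * kappa + d
        v, d = hc_term(u_tau, tau)
        L += v
        g_utau += np.sum(A_alpha * (kappa * eta), axis=(0, 2)) * tau + d
        if self.dhs:
            v, d = hc_term(u_omega, omega)
            L += v
            g_uom += A_sum * alpha_tilde + d
        v, d = hc_term(u_zeta, zeta)
        L += v
        g_uzeta += float(np.sum(A_sum * alpha_tilde)) + d
        # beta, delta priors and their scale hyperpriors
        ssb = float(np.sum(beta * beta))
        ssd = float(np.sum(delta * delta))
        L += -0.5 * G * _LOG_2PI - G * u_sb - 0.5 * ssb / sb ** 2
        L += -0.5 * G * _LOG_2PI - G * u_sd - 0.5 * ssd / sd ** 2
        g_beta -= beta / sb ** 2
        g_delta -= delta / sd ** 2
        v, d = hc_term(u_sb, sb)
        L += v
        g_usb += ssb / sb ** 2 - G + d
        v, d = hc_term(u_sd, sd)
        L += v
        g_usd += ssd / sd ** 2 - G + d

        return -L, -grad

    def initial_point(self, rng: np.random.Generator, init_scale: float) -> np.ndarray:
        """Random start: free location blocks ~ Normal(0, init_scale^2), log-scales 0."""
        x = np.zeros(self.n_params)
        n_loc = self.offsets[5]  # beta..eta_tilde are the location blocks
        x[:n_loc] = init_scale * rng.standard_normal(n_loc)
        return x


def map_fit(dataset: CountDataset, spec: ModelSpec) -> FitResult:
    """Posterior-mode estimate by quasi-Newton maximization of the adjusted joint.

    Runs ``spec.n_restarts`` random initializations (seeded from ``spec.seed``)
    and returns the best objective value; ties go to the lowest restart index.
    ``log_joint`` is the adjusted (unconstrained-scale) objective at the optimum.
    """
    obj = _Objective(dataset, spec)
    best = None
    any_finite = False
    for r in range(spec.n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, r]))
        x0 = obj.initial_point(rng, spec.init_scale)
        res = minimize(obj, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": spec.max_iterations,
                                "ftol": spec.tol, "gtol": spec.grad_tol,
                                "maxfun": 10 * spec.max_iterations})
        if not np.isfinite(res.fun):
            continue
        any_finite = True
        if best is None or res.fun < best[0].fun:
            best = (res, r)
    if not any_finite:
        raise ConvergenceError(
            f"all {spec.n_restarts} restarts diverged (variant={spec.variant}, "
            f"F={spec.n_factors}, seed={spec.seed})")
    res, _ = best
    return FitResult(state=obj.unpack(res.x), log_joint=float(-res.fun),
                     converged=bool(res.success), n_iterations=int(res.nit),
                     seed=spec.seed)


def resample_within_groups(dataset: CountDataset, seed: int) -> CountDataset:
    """Bootstrap resample of cells with replacement, independently per condition.

    Group sizes are preserved exactly; the gene set is unchanged.  Duplicated
    cells get fresh latent-factor slots when the model is refit downstream.
    """
    rng = np.random.default_rng(seed)
    cols = np.empty(dataset.n_cells, dtype=int)
    pos = 0
    for t in (0, 1):
        idx = dataset.group_indices(t)
        cols[pos:pos + idx.size] = rng.choice(idx, size=idx.size, replace=True)
        pos += idx.size
    groups = np.concatenate([np.zeros(dataset.group_indices(0).size, dtype=np.int8),
                             np.ones(dataset.group_indices(1).size, dtype=np.int8)])
    return CountDataset(counts=dataset.counts[:, cols], groups=groups,
                        gene_ids=dataset.gene_ids,
                        cell_ids=np.asarray(dataset.cell_ids)[cols])


def _one_replicate(dataset: CountDataset, spec: ModelSpec, seed: int):
    data_b = resample_within_groups(dataset, seed)
    t0 = time.perf_counter()
    try:
        fit = map_fit(data_b, replace(spec, seed=seed))
    except ConvergenceError:
        return None
    rho0 = marginal_correlation(fit.state.alpha_for_group(0))
    rho1 = marginal_correlation(fit.state.alpha_for_group(1))
    logger.debug("replicate seed=%d done in %.2fs (converged=%s)",
                 seed, time.perf_counter() - t0, fit.converged)
    return pairs_to_vector(rho0), pairs_to_vector(rho1)


def bootstrap(dataset: CountDataset, spec: ModelSpec, M_b: int = 1000,
              base_seed: int | None = None, n_jobs: int = 1,
              restarts_per_replicate: int = 1) -> BootstrapResult:
    """Within-group bootstrap of the differential correlation statistic.

    For each replicate b (seeded ``base_seed + b`` so partial runs are
    resumable): resample cells within each condition, re-estimate the posterior
    mode, convert each condition's loadings to its marginal correlation matrix,
    and record the edge vectors rho0, rho1 and theta = rho0 - rho1.  Replicates
    are independent, so results do not depend on execution order or on
    ``n_jobs``.  By default each replicate uses a single cold start: the
    replicate-to-replicate resampling supplies the variability the intervals
    measure, and one start per replicate keeps the cost linear in ``M_b``.
    Failed replicates are dropped (with a logged count); more than 20% failures
    raises ``ConvergenceError``.
    """
    if M_b < 2:
        raise ValueError("M_b must be >= 2")
    if base_seed is None:
        base_seed = spec.seed
    rep_spec = replace(spec, n_restarts=restarts_per_replicate)
    seeds = [base_seed + b for b in range(M_b)]
    results = Parallel(n_jobs=n_jobs)(
        delayed(_one_replicate)(dataset, rep_spec, s) for s in seeds)
    converged = np.array([r is not None for r in results])
    n_fail = int(np.sum(~converged))
    if n_fail > 0.2 * M_b:
        raise ConvergenceError(
            f"{n_fail}/{M_b} bootstrap replicates failed to converge; consider a "
            f"looser tolerance or a different number of factors")
    if n_fail:
        logger.warning("%d/%d bootstrap replicates dropped (non-convergence)",
                       n_fail, M_b)
    ok = [r for r in results if r is not None]
    rho0 = np.vstack([r[0] for r in ok])
    rho1 = np.vstack([r[1] for r in ok])
    return BootstrapResult(M_b=M_b, theta_draws=rho0 - rho1, rho0_draws=rho0,
                           rho1_draws=rho1, converged=converged,
                           base_seed=base_seed)
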