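"""Generative model: Poisson counts driven by latent factors with horseshoe-shrunk loadings.

The observation model for gene ``g`` in cell ``i`` (condition ``t_i`` in {0, 1}) is

    Y_gi | lambda_i ~ Poisson(mu_gi),
    log mu_gi = beta_g + t_i * delta_g
                + sum_f lambda_if * alpha_{gf;t_i}
                - sum_f alpha_{gf;t_i}^2 / 2,

with cell factors lambda_if ~ Normal(0, 1).  The quadratic adjustment term makes
E[Y_gi] = exp(beta_g + t_i delta_g) regardless of loading magnitudes, so the
loadings control only co-expression and overdispersion.

Loadings are shrunk hierarchically.  In both variants the condition-specific
loadings share a center:

    alpha_{gf;t} ~ Normal(alpha_tilde_gf, kappa_{gf;t}^2 tau_f^2),
    kappa_{gf;t}, tau_f ~ half-Cauchy(0, 1).

The single-horseshoe variant (SHS) puts alpha_tilde_gf ~ Normal(0, zeta^2);
the double-horseshoe variant (DHS) adds a second horseshoe,
alpha_tilde_gf ~ Normal(0, omega_gf^2 zeta^2) with omega_gf ~ half-Cauchy(0, 1),
to additionally sparsify the shared base network.  beta_g ~ Normal(0, sigma_beta^2)
and delta_g ~ Normal(0, sigma_delta^2) with half-Cauchy(0, 1) scale hyperpriors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

LOG_2_OVER_PI = math.log(2.0 / math.pi)
_LOG_2PI = math.log(2.0 * math.pi)

VARIANTS = ("SHS", "DHS")


class DimensionError(ValueError):
    """Raised when array shapes are inconsistent with (G, N, F)."""


@dataclass
class CountDataset:
    """A genes x cells integer count matrix with a binary condition label per cell.

    ``groups[i] == 0`` marks the control/reference condition, ``1`` the treatment.
    """

    counts: np.ndarray
    groups: np.ndarray
    gene_ids: np.ndarray | None = None
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.groups = np.asarray(self.groups)
        if self.counts.ndim != 2:
            raise DimensionError("counts must be a 2-D genes x cells matrix")
        G, N = self.counts.shape
        if self.groups.shape != (N,):
            raise DimensionError(
                f"groups has shape {self.groups.shape}, expected ({N},)"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            if not np.all(as_int == np.floor(as_int)):
                bad = np.argwhere(as_int != np.floor(as_int))[0]
                raise ValueError(
                    f"counts must be integral; first offender at gene {bad[0]}, cell {bad[1]}"
                )
            self.counts = as_int.astype(np.int64)
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"counts must be non-negative; first offender at gene {bad[0]}, cell {bad[1]}"
            )
        if not set(np.unique(self.groups)) <= {0, 1}:
            raise ValueError("groups must take values in {0, 1}")
        if 0 not in self.groups or 1 not in self.groups:
            raise ValueError("both group labels (0 and 1) must be present")
        self.groups = self.groups.astype(np.int8)
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene{g + 1}" for g in range(G)])
        else:
            self.gene_ids = np.asarray(self.gene_ids)
            if len(self.gene_ids) != G:
                raise DimensionError("gene_ids length must match number of genes")
            if len(set(map(str, self.gene_ids))) != G:
                raise ValueError("duplicate gene ids")
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell{i + 1}" for i in range(N)])
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            if len(self.cell_ids) != N:
                raise DimensionError("cell_ids length must match number of cells")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def group_indices(self, t: int) -> np.ndarray:
        return np.flatnonzero(self.groups == t)


@dataclass
class ModelSpec:
    """Variant, number of latent factors and optimizer settings for one fit."""

    variant: str = "SHS"
    n_factors: int = 7
    seed: int = 0
    max_iterations: int = 2000
    tol: float = 1e-8
    grad_tol: float = 1e-6
    n_restarts: int = 3
    init_scale: float = 0.1
    log_mean_cap: float = 30.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.n_factors < 1:
            raise ValueError("n_factors must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class ParameterState:
    """Every model parameter at one point of parameter space.

    ``omega`` is carried for both variants but enters the density only under DHS,
    so a single container can be evaluated under either prior.
    """

    beta: np.ndarray        # (G,)
    delta: np.ndarray       # (G,)
    alpha: np.ndarray       # (G, F, 2), [..., t] are the condition-t loadings
    alpha_tilde: np.ndarray  # (G, F)
    kappa: np.ndarray       # (G, F, 2), > 0
    tau: np.ndarray         # (F,), > 0
    omega: np.ndarray       # (G, F), > 0
    zeta: float
    sigma_beta: float
    sigma_delta: float
    lam: np.ndarray         # (N, F) cell factors

    def __post_init__(self) -> None:
        for name in ("beta", "delta", "alpha", "alpha_tilde", "kappa", "tau", "omega", "lam"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        G = self.beta.shape[0]
        if self.alpha.ndim != 3 or self.alpha.shape[2] != 2:
            raise DimensionError("alpha must have shape (G, F, 2)")
        F = self.alpha.shape[1]
        expected = {
            "delta": (G,),
            "alpha": (G, F, 2),
            "alpha_tilde": (G, F),
            "kappa": (G, F, 2),
            "tau": (F,),
            "omega": (G, F),
        }
        for name, shape in expected.items():
            if getattr(self, name).shape != shape:
                raise DimensionError(
                    f"{name} has shape {getattr(self, name).shape}, expected {shape}"
                )
        if self.lam.ndim != 2 or self.lam.shape[1] != F:
            raise DimensionError("lam must have shape (N, F)")
        for name in ("kappa", "tau", "omega"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        for name in ("zeta", "sigma_beta", "sigma_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def n_genes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_factors(self) -> int:
        return self.alpha.shape[1]

    @property
    def n_cells(self) -> int:
        return self.lam.shape[0]

    def alpha_for_group(self, t: int) -> np.ndarray:
        """Loading matrix (G, F) of condition ``t``."""
        return self.alpha[:, :, t]

    @classmethod
    def zeros(cls, G: int, N: int, F: int) -> "ParameterState":
        """All location parameters 0, all scales 1."""
        return cls(
            beta=np.zeros(G),
            delta=np.zeros(G),
            alpha=np.zeros((G, F, 2)),
            alpha_tilde=np.zeros((G, F)),
            kappa=np.ones((G, F, 2)),
            tau=np.ones(F),
            omega=np.ones((G, F)),
            zeta=1.0,
            sigma_beta=1.0,
            sigma_delta=1.0,
            lam=np.zeros((N, F)),
        )

    def with_lam(self, lam: np.ndarray) -> "ParameterState":
        return replace(self, lam=np.asarray(lam, dtype=float))


@dataclass
class MomentSummary:
    """Marginal (over cell factors) mean and variance of one count."""

    mean: float
    variance: float


def half_cauchy_logpdf(x) -> np.ndarray | float:
    """Log-density of the standard half-Cauchy, log[2 / (pi (1 + x^2))], for x > 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("half-Cauchy support is x > 0")
    out = LOG_2_OVER_PI - np.log1p(x * x)
    return out if out.ndim else float(out)


def _normal_logpdf(x, sd) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = np.asarray(sd, dtype=float)
    return -0.5 * _LOG_2PI - np.log(sd) - 0.5 * (x / sd) ** 2


def log_mean(state: ParameterState, dataset: CountDataset,
             log_mean_cap: float = 30.0) -> np.ndarray:
    """The G x N matrix of log mu_gi, clipped from above at ``log_mean_cap``.

    Entry (g, i) is beta_g + t_i delta_g + sum_f lambda_if alpha_{gf;t_i}
    - sum_f alpha_{gf;t_i}^2 / 2.
    """
    if state.n_cells != dataset.n_cells or state.n_genes != dataset.n_genes:
        raise DimensionError(
            f"state is (G={state.n_genes}, N={state.n_cells}) but dataset is "
            f"(G={dataset.n_genes}, N={dataset.n_cells})"
        )
    G, N = dataset.n_genes, dataset.n_cells
    out = np.empty((G, N))
    for t in (0, 1):
        idx = dataset.group_indices(t)
        if idx.size == 0:
            continue
        a_t = state.alpha_for_group(t)                    # (G, F)
        base = state.beta + t * state.delta - 0.5 * np.sum(a_t * a_t, axis=1)
        out[:, idx] = base[:, None] + a_t @ state.lam[idx].T
    return np.minimum(out, log_mean_cap)


def log_joint_density(state: ParameterState, dataset: CountDataset,
                      spec: ModelSpec) -> float:
    """Joint log-density of counts and all parameters in the natural parameterization.

    Sums the Poisson likelihood (constants included), the standard-normal factor
    prior, the hierarchical loading priors of the requested variant, and the
    half-Cauchy hyperpriors.
    """
    lm = log_mean(state, dataset, spec.log_mean_cap)
    y = dataset.counts
    total = float(np.sum(y * lm - np.exp(lm) - gammaln(y + 1.0)))
    total += float(np.sum(_normal_logpdf(state.lam, 1.0)))
    # alpha | alpha_tilde, kappa, tau
    sd_alpha = state.kappa * state.tau[None, :, None]
    total += float(np.sum(_normal_logpdf(state.alpha - state.alpha_tilde[:, :, None], sd_alpha)))
    total += float(np.sum(half_cauchy_logpdf(state.kappa)))
    total += float(np.sum(half_cauchy_logpdf(state.tau)))
    if spec.variant == "DHS":
        total += float(np.sum(half_cauchy_logpdf(state.omega)))
        total += float(np.sum(_normal_logpdf(state.alpha_tilde, state.omega * state.zeta)))
    else:
        total += float(np.sum(_normal_logpdf(state.alpha_tilde, state.zeta)))
    total += float(half_cauchy_logpdf(state.zeta))
    total += float(half_cauchy_logpdf(state.sigma_beta))
    total += float(half_cauchy_logpdf(state.sigma_delta))
    total += float(np.sum(_normal_logpdf(state.beta, state.sigma_beta)))
    total += float(np.sum(_normal_logpdf(state.delta, state.sigma_delta)))
    return total


def marginal_moments(beta_g: float, delta_g: float, t: int,
                     alpha_row: np.ndarray) -> MomentSummary:
    """Marginal mean and variance of Y_gi after integrating out the cell factors.

    mean = exp(beta_g + t delta_g);
    variance = mean * (1 + mean * (prod_f exp(alpha_{gf;t}^2) - 1)) >= mean,
    with equality exactly when every loading is zero (Poisson limit).
    """
    alpha_row = np.asarray(alpha_row, dtype=float)
    mean = math.exp(beta_g + t * delta_g)
    excess = math.expm1(float(np.sum(alpha_row ** 2)))
    variance = mean * (1.0 + mean * excess)
    return MomentSummary(mean=mean, variance=variance)


def sample_counts(state: ParameterState, groups: np.ndarray, seed: int,
                  log_mean_cap: float = 30.0) -> CountDataset:
    """Forward-simulate counts from the model at ``state``.

    Cell factors are drawn fresh from Normal(0, 1) — ``state.lam`` is ignored —
    then Y_gi ~ Poisson(mu_gi).  Deterministic given ``seed``.
    """
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    N = len(groups)
    F = state.n_factors
    lam = rng.standard_normal((N, F))
    sim_state = state.with_lam(lam)
    dummy = CountDataset(counts=np.zeros((state.n_genes, N), dtype=np.int64),
                         groups=groups)
    lm = log_mean(sim_state, dummy, log_mean_cap)
    if np.any(lm >= log_mean_cap):
        logger.warning("log-mean hit the cap (%.1f) in %d entries; counts clipped",
                       log_mean_cap, int(np.sum(lm >= log_mean_cap)))
    counts = rng.poisson(np.exp(lm))
    return CountDataset(counts=counts, groups=groups)
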