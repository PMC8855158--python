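"""Co-expression structure implied by the loading matrices.

The individual loadings alpha_{gf;t} are rotation non-identifiable, but the Gram
matrix A_t = alpha_t alpha_t^T is identifiable and equals the covariance of the
log-means within condition t.  Its correlation normalisation

    rho_{gg';t} = A_t(g,g') / sqrt(A_t(g,g) A_t(g',g'))

is the within-condition co-expression network, and theta_{gg'} = rho_{gg';0} -
rho_{gg';1} is the differential edge statistic.  Edge-level uncertainty is
summarised from replicate draws (bootstrap replicates or posterior samples) by
percentile intervals and an approximate p-value: the smallest level at which the
interval excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CorrelationPair:
    """Within-condition correlation matrices for control (rho0) and treatment (rho1)."""

    rho0: np.ndarray
    rho1: np.ndarray

    def __post_init__(self) -> None:
        self.rho0 = np.asarray(self.rho0, dtype=float)
        self.rho1 = np.asarray(self.rho1, dtype=float)
        if self.rho0.shape != self.rho1.shape:
            raise ValueError("rho0 and rho1 must have the same shape")


def edge_count(G: int) -> int:
    """Number of unordered gene pairs, G(G-1)/2."""
    if G < 2:
        raise ValueError("need at least 2 genes to form an edge")
    return G * (G - 1) // 2


def edge_index(G: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the P = G(G-1)/2 unordered pairs (g < g'), in
    lexicographic order."""
    return np.triu_indices(G, k=1)


def pairs_to_vector(mat: np.ndarray) -> np.ndarray:
    """Extract the upper-triangle (g < g') entries of a square matrix as a vector."""
    ii, jj = edge_index(mat.shape[0])
    return mat[ii, jj]


def factor_covariance(alpha_t: np.ndarray) -> np.ndarray:
    """Gram matrix A_t = alpha_t alpha_t^T: covariance of log-means within a condition."""
    alpha_t = np.asarray(alpha_t, dtype=float)
    return alpha_t @ alpha_t.T


def marginal_correlation(alpha_t: np.ndarray, var_floor: float = 1e-12) -> np.ndarray:
    """Correlation of log-means implied by a loading matrix.

    Genes whose factor variance sum_f alpha_{gf;t}^2 falls below ``var_floor``
    have no factor-driven variation; their off-diagonal correlations are set to
    0 (unconnected) and their diagonal to 1 by convention.
    """
    if var_floor <= 0:
        raise ValueError("var_floor must be positive")
    A = factor_covariance(alpha_t)
    d = np.diag(A).copy()
    degenerate = d < var_floor
    d_safe = np.where(degenerate, 1.0, d)
    denom = np.sqrt(np.outer(d_safe, d_safe))
    rho = A / denom
    rho[degenerate, :] = 0.0
    rho[:, degenerate] = 0.0
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def correlation_difference(pair: CorrelationPair) -> np.ndarray:
    """Elementwise control-minus-treatment correlation difference theta = rho0 - rho1."""
    return pair.rho0 - pair.rho1


def approx_p_values(draws: np.ndarray) -> np.ndarray:
    """Approximate p-value per column of an (M, P) draw matrix.

    2 * min(#draws <= 0, #draws >= 0) / M, floored at the empirical resolution
    2/M so that a unanimous sign never reports p = 0, and capped at 1.
    """
    draws = np.asarray(draws, dtype=float)
    M = draws.shape[0]
    n_le = np.sum(draws <= 0, axis=0)
    n_ge = np.sum(draws >= 0, axis=0)
    p = 2.0 * np.minimum(n_le, n_ge) / M
    return np.clip(p, 2.0 / M, 1.0)


def percentile_interval(draws: np.ndarray, level_alpha: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Classical percentile-bootstrap interval per column of an (M, P) matrix.

    Uses the order-statistic convention: the k-th smallest and k-th largest
    draws with k = floor((M + 1) * level_alpha / 2), clipped to [1, M].  At
    small M this is slightly wider than interpolated quantiles, which keeps
    edge calls honest at the resolution the draws support.
    """
    draws = np.sort(np.asarray(draws, dtype=float), axis=0)
    M = draws.shape[0]
    k = int((M + 1) * level_alpha / 2)
    k = min(max(k, 1), M)
    return draws[k - 1], draws[M - k]


def _interval_summary(draws: np.ndarray, level_alpha: float) -> pd.DataFrame:
    """Mean, percentile interval, approximate p and significance per column."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need an (M, P) draw matrix with M >= 2")
    if not np.all(np.isfinite(draws)):
        raise ValueError("draws must be finite")
    if not 0 < level_alpha < 1:
        raise ValueError("level_alpha must lie in (0, 1)")
    lower, upper = percentile_interval(draws, level_alpha)
    return pd.DataFrame({
        "estimate": draws.mean(axis=0),
        "lower": lower,
        "upper": upper,
        "approx_p": approx_p_values(draws),
        "significant": (lower > 0) | (upper < 0),
    })


@dataclass
class EdgeTable:
    """Per unordered gene pair (g < g'): group correlations, their difference,
    a percentile interval for the difference, and an approximate p-value."""

    gene1: np.ndarray          # integer gene index, g < g'
    gene2: np.ndarray
    rho0_hat: np.ndarray
    rho1_hat: np.ndarray
    theta_hat: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    approx_p: np.ndarray
    significant: np.ndarray
    level_alpha: float = 0.05

    def __post_init__(self) -> None:
        n = len(self.gene1)
        for name in ("gene2", "rho0_hat", "rho1_hat", "theta_hat",
                     "lower", "upper", "approx_p", "significant"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    @property
    def n_edges(self) -> int:
        return len(self.gene1)

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.significant))

    def significant_pairs(self) -> set[tuple[int, int]]:
        return {(int(g), int(h))
                for g, h in zip(self.gene1[self.significant],
                                self.gene2[self.significant])}

    def to_frame(self, gene_ids: np.ndarray | None = None) -> pd.DataFrame:
        """Tabular form; gene columns become string ids when ``gene_ids`` given."""
        g1, g2 = self.gene1, self.gene2
        if gene_ids is not None:
            gene_ids = np.asarray(gene_ids)
            g1, g2 = gene_ids[g1], gene_ids[g2]
        return pd.DataFrame({
            "gene1": g1, "gene2": g2,
            "rho0_hat": self.rho0_hat, "rho1_hat": self.rho1_hat,
            "theta_hat": self.theta_hat,
            "ci_lower": self.lower, "ci_upper": self.upper,
            "approx_p": self.approx_p, "significant": self.significant,
        })


def summarize_edges(theta_draws: np.ndarray, rho0_draws: np.ndarray,
                    rho1_draws: np.ndarray, level_alpha: float = 0.05,
                    gene1: np.ndarray | None = None,
                    gene2: np.ndarray | None = None) -> EdgeTable:
    """Edge-level summary of replicate draws of the differential statistic.

    ``theta_draws`` etc. are (M, P) with one column per unordered pair in
    lexicographic order.  The interval is a percentile interval at level
    1 - level_alpha; an edge is significant when the interval excludes zero.
    """
    theta_draws = np.asarray(theta_draws, dtype=float)
    summ = _interval_summary(theta_draws, level_alpha)
    P = theta_draws.shape[1]
    if gene1 is None or gene2 is None:
        # recover G from P = G(G-1)/2
        G = int(round((1 + math.sqrt(1 + 8 * P)) / 2))
        if edge_count(G) != P:
            raise ValueError(f"P={P} is not a triangular number; pass gene1/gene2")
        gene1, gene2 = edge_index(G)
    return EdgeTable(
        gene1=np.asarray(gene1), gene2=np.asarray(gene2),
        rho0_hat=np.asarray(rho0_draws, dtype=float).mean(axis=0),
        rho1_hat=np.asarray(rho1_draws, dtype=float).mean(axis=0),
        theta_hat=summ["estimate"].to_numpy(),
        lower=summ["lower"].to_numpy(), upper=summ["upper"].to_numpy(),
        approx_p=summ["approx_p"].to_numpy(),
        significant=summ["significant"].to_numpy(),
        level_alpha=level_alpha,
    )


def summarize_group_edges(rho_draws: np.ndarray, level_alpha: float = 0.05,
                          gene1: np.ndarray | None = None,
                          gene2: np.ndarray | None = None) -> pd.DataFrame:
    """Within-condition edge calls: same interval machinery applied to rho draws."""
    summ = _interval_summary(np.asarray(rho_draws, dtype=float), level_alpha)
    P = summ.shape[0]
    if gene1 is None or gene2 is None:
        G = int(round((1 + math.sqrt(1 + 8 * P)) / 2))
        if edge_count(G) != P:
            raise ValueError(f"P={P} is not a triangular number; pass gene1/gene2")
        gene1, gene2 = edge_index(G)
    summ.insert(0, "gene2", np.asarray(gene2))
    summ.insert(0, "gene1", np.asarray(gene1))
    return summ.rename(columns={"estimate": "rho_hat"})


def top_fraction_edges(theta_hat: np.ndarray, fraction: float,
                       gene1: np.ndarray | None = None,
                       gene2: np.ndarray | None = None) -> np.ndarray:
    """Indices of the ceil(fraction * P) edges with the largest |theta_hat|.

    Ties are broken by lexicographic gene-pair order for reproducibility.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    if theta_hat.size == 0:
        raise ValueError("empty edge statistic vector")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    P = theta_hat.size
    k = math.ceil(fraction * P)
    if gene1 is None or gene2 is None:
        gene1 = np.zeros(P, dtype=int)
        gene2 = np.arange(P)
    order = np.lexsort((np.asarray(gene2), np.asarray(gene1), -np.abs(theta_hat)))
    return np.sort(order[:k])


@dataclass
class FactorSelection:
    """Proportion of significant differential edges per candidate factor count."""

    grid: list[int]
    proportions: list[float]
    chosen_F: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "F": self.grid,
            "proportion_differential": self.proportions,
            "chosen": [f == self.chosen_F for f in self.grid],
        })


def select_factors(edge_tables: dict[int, EdgeTable], G: int) -> FactorSelection:
    """Pick the factor count at the peak of the differential-edge proportion curve.

    The proportion of significant differential edges typically rises with F and
    then plateaus; the chosen F is the one with the maximal proportion among
    candidates F > 5 (ties resolved to the smallest such F).
    """
    grid = sorted(edge_tables)
    if not any(f > 5 for f in grid):
        raise ValueError("factor grid must contain values > 5")
    P = edge_count(G)
    proportions = [edge_tables[f].n_significant / P for f in grid]
    candidates = [(f, p) for f, p in zip(grid, proportions) if f > 5]
    best_p = max(p for _, p in candidates)
    chosen = min(f for f, p in candidates if p == best_p)
    return FactorSelection(grid=grid, proportions=proportions, chosen_F=chosen)
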