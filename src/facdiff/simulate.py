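"""Benchmark data with known differential co-expression structure.

Counts are generated by the NORTA (NORmal To Anything) recipe: draw a latent
vector Z ~ MVN(0, Sigma_t) per cell, push each coordinate through the standard
normal CDF, then through the quantile function of a per-gene zero-inflated
negative binomial (ZINB).  The marginals therefore carry the zero-inflation and
overdispersion of real scRNA-seq data while the latent correlation matrices
Sigma_0 / Sigma_1 encode the designed networks.  Note the generating model is
deliberately different from the factor model used for estimation.

Designs sort genes into equal contiguous groups; genes inside a group are
highly correlated in both conditions, and a chosen set of between-group block
pairs differs between Sigma_0 and Sigma_1 — those block members form the true
differential edge set used for scoring.  Truth is defined on the design
(latent-Gaussian) scale; the induced count-scale correlation is attenuated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CountDataset
from .network import edge_index


@dataclass
class ZinbParams:
    """Per-gene zero-inflated negative binomial parameters.

    ``mu`` is the negative-binomial mean, ``r`` the size (dispersion) parameter
    and ``pi`` the structural-zero probability; the marginal mean is (1-pi)*mu.
    """

    mu: np.ndarray
    r: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        if not (self.mu.shape == self.r.shape == self.pi.shape):
            raise ValueError("mu, r, pi must have equal lengths")
        if np.any(self.mu <= 0) or np.any(self.r <= 0):
            raise ValueError("mu and r must be positive")
        if np.any(self.pi < 0) or np.any(self.pi >= 1):
            raise ValueError("pi must lie in [0, 1)")

    @property
    def n_genes(self) -> int:
        return len(self.mu)

    @classmethod
    def random(cls, G: int, seed: int) -> "ZinbParams":
        """Seedable defaults in typical scRNA-seq ranges:
        log mu ~ Uniform(log 0.5, log 20), r ~ Uniform(0.5, 3), pi ~ Uniform(0.2, 0.7)."""
        rng = np.random.default_rng(seed)
        return cls(mu=np.exp(rng.uniform(np.log(0.5), np.log(20.0), G)),
                   r=rng.uniform(0.5, 3.0, G),
                   pi=rng.uniform(0.2, 0.7, G))


@dataclass
class BlockDesign:
    """Gene-group assignment plus target correlation matrices and the truth set."""

    G: int
    n_groups: int
    group_of: np.ndarray            # (G,) block label per gene
    Sigma0: np.ndarray
    Sigma1: np.ndarray
    true_diff: set[tuple[int, int]]  # unordered pairs (g < g') inside differing blocks
    diff_magnitude_range: tuple[float, float]

    def truth_flags(self) -> np.ndarray:
        """Boolean vector over the P lexicographic edges: member of true_diff."""
        ii, jj = edge_index(self.G)
        return np.array([(int(a), int(b)) in self.true_diff for a, b in zip(ii, jj)])


def nearest_pd_repair(Sigma: np.ndarray, min_eig: float = 1e-8,
                      max_change: float = 0.05, n_iter: int = 100) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Alternates eigenvalue clipping (at ``min_eig``) with unit-diagonal
    restoration until the smallest eigenvalue is acceptable.  Raises if any
    entry moves more than ``max_change`` — a sign the requested design is too
    aggressive to be a correlation matrix.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if not np.allclose(Sigma, Sigma.T):
        raise ValueError("input must be symmetric")
    out = Sigma.copy()
    for _ in range(n_iter):
        w, V = np.linalg.eigh(out)
        if w.min() >= min_eig:
            break
        w = np.clip(w, min_eig, None)
        out = (V * w) @ V.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
    else:
        raise ValueError("PSD repair did not converge")
    delta = float(np.max(np.abs(out - Sigma)))
    if delta > max_change:
        raise ValueError(
            f"PSD repair changed an entry by {delta:.3f} > {max_change}; "
            f"design too aggressive")
    return out


def _superblock_partition(n_pairs: int, n_blocks: int) -> list[int]:
    """Disjoint clique sizes whose pair counts sum to exactly ``n_pairs``.

    Differing block pairs are laid out as disjoint cliques ("superblocks") of
    gene groups so the altered correlations stay mutually coherent —
    scattering strong changes over arbitrary block pairs makes the target
    matrices wildly non-positive-definite, whereas clique placement keeps them
    valid.  Among the feasible partitions the one with the most cliques (then
    the smallest largest clique) is chosen, which also spreads the difference
    levels across cliques.
    """
    best: list[int] | None = None

    def rec(remaining: int, budget: int, sizes: list[int], max_k: int) -> None:
        nonlocal best
        if remaining == 0:
            if best is None or (len(sizes), -max(sizes)) > (len(best), -max(best)):
                best = list(sizes)
            return
        top = min(max_k, budget, int((1 + math.isqrt(1 + 8 * remaining)) // 2))
        for k in range(top, 1, -1):
            p = k * (k - 1) // 2
            if p <= remaining:
                rec(remaining - p, budget - k, sizes + [k], k)

    rec(n_pairs, n_blocks, [], n_blocks)
    if best is None:
        raise ValueError(
            f"cannot realize {n_pairs} differing block pairs with "
            f"{n_blocks} gene groups")
    return best


def build_block_design(G: int, n_groups: int = 10, within_r: float = 0.8,
                       between_r_base: float = 0.1, n_diff_blocks: int = 13,
                       delta_levels: tuple[float, ...] = (0.3, 0.6, 0.9),
                       sign_flip: bool = False, seed: int = 0) -> BlockDesign:
    """Construct two block correlation matrices differing on chosen block pairs.

    Genes are sorted into ``n_groups`` equal contiguous groups.  Within-group
    correlation is ``within_r`` in both conditions; between-group blocks share
    ``between_r_base`` except for ``n_diff_blocks`` block pairs whose
    correlation differs between conditions.  The differing pairs form disjoint
    cliques of blocks (membership chosen by ``seed``), each clique carrying
    one difference level d cycled from ``delta_levels``, so both targets stay
    (essentially) valid correlation matrices.

    For a differing pair with level d the control/treatment values are
    ``base + 2d/3`` and ``base - d/3``, so |Delta rho| = d exactly with the
    stronger association in the control group.  With ``sign_flip`` each clique
    is split into two camps and cross-camp pairs instead get
    ``-(base + d/3)`` in the treatment — opposite correlation directions,
    |Delta rho| = 2*base + d.  The true differential edge set is every gene
    pair inside a differing block pair: n_diff_blocks * (G/n_groups)^2 edges.
    """
    if G % n_groups:
        raise ValueError("G must be divisible by n_groups")
    B = G // n_groups
    n_block_pairs = n_groups * (n_groups - 1) // 2
    if n_diff_blocks > n_block_pairs:
        raise ValueError("n_diff_blocks exceeds available between-group block pairs")
    rng = np.random.default_rng(seed)
    group_of = np.repeat(np.arange(n_groups), B)

    base = np.full((G, G), between_r_base)
    for k in range(n_groups):
        sl = slice(k * B, (k + 1) * B)
        base[sl, sl] = within_r
    np.fill_diagonal(base, 1.0)
    Sigma0, Sigma1 = base.copy(), base.copy()

    true_diff: set[tuple[int, int]] = set()
    if n_diff_blocks > 0:
        order = rng.permutation(n_groups)
        sizes = _superblock_partition(n_diff_blocks, n_groups)
        levels = list(delta_levels)
        pos = 0
        for ci, size in enumerate(sizes):
            members = sorted(order[pos:pos + size])
            pos += size
            camp = {b: i % 2 for i, b in enumerate(members)}  # sign_flip camps
            d = levels[ci % len(levels)]
            for i in range(size):
                for j in range(i + 1, size):
                    bi, bj = members[i], members[j]
                    v0 = between_r_base + 2 * d / 3
                    if sign_flip and camp[bi] != camp[bj]:
                        v1 = -(between_r_base + d / 3)
                    else:
                        v1 = between_r_base - d / 3
                    si = slice(bi * B, (bi + 1) * B)
                    sj = slice(bj * B, (bj + 1) * B)
                    for S, v in ((Sigma0, v0), (Sigma1, v1)):
                        S[si, sj] = v
                        S[sj, si] = v
                    for g in range(bi * B, (bi + 1) * B):
                        for h in range(bj * B, (bj + 1) * B):
                            true_diff.add((min(g, h), max(g, h)))

    Sigma0 = nearest_pd_repair(Sigma0)
    Sigma1 = nearest_pd_repair(Sigma1)
    if true_diff:
        diffs = np.array([abs(Sigma0[g, h] - Sigma1[g, h]) for g, h in true_diff])
        mag_range = (float(diffs.min()), float(diffs.max()))
    else:
        mag_range = (0.0, 0.0)
    return BlockDesign(G=G, n_groups=n_groups, group_of=group_of, Sigma0=Sigma0,
                       Sigma1=Sigma1, true_diff=true_diff,
                       diff_magnitude_range=mag_range)


def zinb_quantile(p, params: ZinbParams, gene: int = 0) -> np.ndarray | int:
    """ZINB quantile: smallest integer y with pi + (1-pi) NB_CDF(y) >= p."""
    p = np.asarray(p, dtype=float)
    if np.any(p >= 1) or np.any(p < 0):
        raise ValueError("p must lie in [0, 1)")
    mu, r, pi = params.mu[gene], params.r[gene], params.pi[gene]
    nb_p = r / (r + mu)  # scipy's success probability
    q = (p - pi) / (1.0 - pi)
    out = np.where(p <= pi, 0.0, stats.nbinom.ppf(np.clip(q, 0.0, 1.0), r, nb_p))
    out = out.astype(np.int64)
    return out if out.ndim else int(out)


def norta_sample(design: BlockDesign, zinb: ZinbParams, N0: int, N1: int,
                 seed: int) -> tuple[CountDataset, BlockDesign]:
    """Draw a two-condition count dataset through the Gaussian copula.

    Control cells use Sigma0, treatment cells Sigma1; each latent coordinate is
    mapped through Phi and the gene's ZINB quantile function.
    """
    if zinb.n_genes != design.G:
        raise ValueError(f"zinb has {zinb.n_genes} genes but design has {design.G}")
    rng = np.random.default_rng(seed)
    G = design.G
    counts = np.empty((G, N0 + N1), dtype=np.int64)
    col = 0
    for Sigma, n in ((design.Sigma0, N0), (design.Sigma1, N1)):
        L = np.linalg.cholesky(Sigma + 1e-10 * np.eye(G))
        Z = rng.standard_normal((n, G)) @ L.T           # (n, G)
        U = stats.norm.cdf(Z)
        U = np.clip(U, 0.0, 1.0 - 1e-12)
        for g in range(G):
            counts[g, col:col + n] = zinb_quantile(U[:, g], zinb, g)
        col += n
    groups = np.concatenate([np.zeros(N0, dtype=np.int8), np.ones(N1, dtype=np.int8)])
    return CountDataset(counts=counts, groups=groups), design


_SCHEMES = {
    "sim1": dict(G=50, N=1000),
    "sim2": dict(G=50, N=500),
    "sim3": dict(G=50, N=2000),
    "sim4": dict(G=100, N=1000),
}


def make_sim_scheme(name: str, structure: str = "A", seed: int = 0,
                    ) -> tuple[CountDataset, BlockDesign]:
    """One of the four benchmark schemes, with cells split equally across groups.

    sim1 = (G=50, N=1000), sim2 = (G=50, N=500), sim3 = (G=50, N=2000),
    sim4 = (G=100, N=1000); 13 differing between-group blocks throughout, so
    325 true differential edges at G=50 and 1,300 at G=100.  Structure "B"
    flips correlation signs across conditions (larger differences).  ZINB
    marginal parameters are drawn per gene from documented ranges, seeded.
    """
    if name not in _SCHEMES:
        raise ValueError(f"unknown scheme {name!r}; choose from {sorted(_SCHEMES)}")
    if structure not in ("A", "B"):
        raise ValueError("structure must be 'A' or 'B'")
    G, N = _SCHEMES[name]["G"], _SCHEMES[name]["N"]
    sign_flip = structure == "B"
    design = build_block_design(G=G, n_groups=10, n_diff_blocks=13,
                                delta_levels=(0.3, 0.6, 0.9),
                                sign_flip=sign_flip, seed=seed)
    zinb = ZinbParams.random(G, seed=seed + 1)
    return norta_sample(design, zinb, N // 2, N - N // 2, seed=seed + 2)


def truth_table(design: BlockDesign, gene_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Per-edge truth: designed correlations and the differential flag."""
    ii, jj = edge_index(design.G)
    g1, g2 = ii, jj
    if gene_ids is not None:
        gene_ids = np.asarray(gene_ids)
        g1, g2 = gene_ids[ii], gene_ids[jj]
    return pd.DataFrame({
        "gene1": g1, "gene2": g2,
        "rho0_true": design.Sigma0[ii, jj],
        "rho1_true": design.Sigma1[ii, jj],
        "is_diff": design.truth_flags(),
    })
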