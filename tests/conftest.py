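import numpy as np
import pytest

from facdiff.model import CountDataset, ModelSpec, ParameterState


@pytest.fixture
def tiny_dataset() -> CountDataset:
    """4 genes x 10 cells of fixed Poisson counts, half control half treatment."""
    rng = np.random.default_rng(11)
    return CountDataset(counts=rng.poisson(2.0, (4, 10)),
                        groups=np.array([0] * 5 + [1] * 5))


@pytest.fixture
def random_state() -> ParameterState:
    """A moderate random parameter state at G=3, N=8, F=2."""
    rng = np.random.default_rng(7)
    G, N, F = 3, 8, 2
    return ParameterState(
        beta=rng.normal(0, 0.5, G), delta=rng.normal(0, 0.5, G),
        alpha=rng.normal(0, 0.5, (G, F, 2)),
        alpha_tilde=rng.normal(0, 0.5, (G, F)),
        kappa=rng.uniform(0.5, 2.0, (G, F, 2)), tau=rng.uniform(0.5, 2.0, F),
        omega=rng.uniform(0.5, 2.0, (G, F)), zeta=1.3, sigma_beta=0.8,
        sigma_delta=1.1, lam=rng.normal(0, 1, (N, F)))


def strong_two_factor_state(G: int = 10, seed: int = 5) -> ParameterState:
    """A generating state with two clearly separated factor blocks.

    Both conditions have a two-block structure, but the treatment regroups the
    genes, so each condition's correlation matrix has strong and varied
    off-diagonal entries and the two differ on many pairs.
    """
    rng = np.random.default_rng(seed)
    F = 2
    alpha = np.zeros((G, F, 2))
    half = G // 2
    # control: genes [0, half) on factor 1, [half, G) on factor 2
    alpha[:half, 0, 0] = 1.0
    alpha[half:, 1, 0] = 1.0
    # treatment: alternate genes between the factors
    alpha[0::2, 0, 1] = 1.0
    alpha[1::2, 1, 1] = 0.9
    alpha += rng.normal(0, 0.05, alpha.shape)
    return ParameterState(
        beta=np.full(G, np.log(5.0)), delta=np.zeros(G), alpha=alpha,
        alpha_tilde=alpha.mean(axis=2), kappa=np.ones((G, F, 2)),
        tau=np.ones(F), omega=np.ones((G, F)), zeta=1.0, sigma_beta=1.0,
        sigma_delta=1.0, lam=np.zeros((1, F)))
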