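"""Model density, moments and forward simulation."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from facdiff.model import (CountDataset, DimensionError, ModelSpec,
                           ParameterState, half_cauchy_logpdf,
                           log_joint_density, log_mean, marginal_moments,
                           sample_counts)


class TestCountDataset:
    def test_rejects_non_integer_counts(self):
        with pytest.raises(ValueError, match="integral"):
            CountDataset(counts=np.array([[0.5, 1.0]]), groups=np.array([0, 1]))

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            CountDataset(counts=np.array([[-1, 2]]), groups=np.array([0, 1]))

    def test_requires_both_groups(self):
        with pytest.raises(ValueError, match="both group labels"):
            CountDataset(counts=np.array([[1, 2]]), groups=np.array([0, 0]))

    def test_rejects_mismatched_ids(self):
        with pytest.raises(DimensionError):
            CountDataset(counts=np.array([[1, 2]]), groups=np.array([0, 1]),
                         gene_ids=["a", "b"])


class TestLogMean:
    def test_all_zero_parameters_give_zero_log_mean(self, tiny_dataset):
        state = ParameterState.zeros(4, 10, 3)
        assert np.all(log_mean(state, tiny_dataset) == 0.0)

    def test_linear_terms_only(self):
        ds = CountDataset(counts=np.zeros((1, 2), dtype=int),
                          groups=np.array([0, 1]))
        state = ParameterState.zeros(1, 2, 1)
        state.beta[:] = 1.0
        state.delta[:] = 2.0
        lm = log_mean(state, ds)
        assert lm[0, 0] == pytest.approx(1.0)   # control: beta only
        assert lm[0, 1] == pytest.approx(3.0)   # treatment: beta + delta

    def test_hand_evaluated_factor_contribution(self):
        # G=1, N=1... need both groups present, so add a treatment cell
        ds = CountDataset(counts=np.zeros((1, 2), dtype=int),
                          groups=np.array([0, 1]))
        state = ParameterState.zeros(1, 2, 2)
        state.lam[0] = [1.0, -1.0]
        state.alpha[0, :, 0] = [0.5, 0.5]
        # (0.5 - 0.5) - (0.25 + 0.25)/2 = -0.25
        assert log_mean(state, ds)[0, 0] == pytest.approx(-0.25)

    def test_cap_applied(self, tiny_dataset):
        state = ParameterState.zeros(4, 10, 1)
        state.beta[:] = 100.0
        assert np.all(log_mean(state, tiny_dataset, log_mean_cap=30.0) == 30.0)

    def test_shape_mismatch_raises(self, tiny_dataset):
        with pytest.raises(DimensionError):
            log_mean(ParameterState.zeros(5, 10, 2), tiny_dataset)


class TestHalfCauchy:
    @pytest.mark.parametrize("x, expected", [
        (1.0, math.log(1.0 / math.pi)),
        (1e-12, math.log(2.0 / math.pi)),
    ])
    def test_printed_density_values(self, x, expected):
        assert half_cauchy_logpdf(x) == pytest.approx(expected, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            half_cauchy_logpdf(0.0)
        with pytest.raises(ValueError):
            half_cauchy_logpdf(-1.0)

    def test_integrates_to_one(self):
        total, _ = quad(lambda x: math.exp(half_cauchy_logpdf(x)), 1e-12, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestLogJointDensity:
    def test_term_by_term_oracle(self):
        """G=N=F=1 at the all-zero/unit state: hand-sum every density term."""
        ds = CountDataset(counts=np.array([[0, 0]]), groups=np.array([0, 1]))
        state = ParameterState.zeros(1, 2, 1)
        spec = ModelSpec(variant="SHS", n_factors=1)
        norm0 = -0.5 * math.log(2 * math.pi)   # standard normal at 0
        hc1 = half_cauchy_logpdf(1.0)
        expected = (
            2 * (-1.0)            # Poisson pmf at y=0, mu=1: -mu
            + 2 * norm0           # lam (N=2, F=1)
            + 2 * norm0           # alpha | alpha_tilde, both groups
            + 2 * hc1 + hc1       # kappa (x2), tau
            + norm0               # alpha_tilde ~ N(0, zeta^2), zeta=1
            + 3 * hc1             # zeta, sigma_beta, sigma_delta
            + 2 * norm0           # beta, delta
        )
        assert log_joint_density(state, ds, spec) == pytest.approx(expected)

    def test_changing_counts_changes_only_poisson_term(self, random_state):
        spec = ModelSpec(variant="SHS", n_factors=2)
        y1 = np.ones((3, 8), dtype=int)
        y2 = 2 * y1
        groups = np.array([0] * 4 + [1] * 4)
        d1 = CountDataset(counts=y1, groups=groups)
        d2 = CountDataset(counts=y2, groups=groups)
        lm = log_mean(random_state, d1)
        poisson_delta = float(np.sum((y2 - y1) * lm
                                     - gammaln(y2 + 1.0) + gammaln(y1 + 1.0)))
        assert (log_joint_density(random_state, d2, spec)
                - log_joint_density(random_state, d1, spec)
                == pytest.approx(poisson_delta))

    def test_shs_dhs_identity_at_unit_omega(self, random_state, tiny_dataset):
        """With omega = 1 the variants differ exactly by sum_gf log hc(1)."""
        rng = np.random.default_rng(3)
        ds = CountDataset(counts=rng.poisson(2.0, (3, 8)),
                          groups=np.array([0] * 4 + [1] * 4))
        state = random_state
        state.omega[:] = 1.0
        shs = log_joint_density(state, ds, ModelSpec(variant="SHS", n_factors=2))
        dhs = log_joint_density(state, ds, ModelSpec(variant="DHS", n_factors=2))
        G, F = 3, 2
        assert dhs - shs == pytest.approx(G * F * half_cauchy_logpdf(1.0))

    def test_poisson_term_unimodal_in_count(self, random_state):
        """Moving one count away from its mean can only lower the density."""
        groups = np.array([0] * 4 + [1] * 4)
        base = CountDataset(counts=np.full((3, 8), 2), groups=groups)
        spec = ModelSpec(variant="SHS", n_factors=2)
        lm = log_mean(random_state, base)
        g, i = 1, 2
        mode = int(np.floor(np.exp(lm[g, i])))
        densities = []
        for y in (mode, mode + 3, mode + 6):
            c = base.counts.copy()
            c[g, i] = y
            densities.append(log_joint_density(
                random_state, CountDataset(counts=c, groups=groups), spec))
        assert densities[0] > densities[1] > densities[2]

    def test_non_positive_scale_rejected(self):
        with pytest.raises(ValueError):
            state = ParameterState.zeros(1, 2, 1)
            state.kappa[0, 0, 0] = 0.0
            ParameterState(**{f: getattr(state, f) for f in
                              ("beta", "delta", "alpha", "alpha_tilde", "kappa",
                               "tau", "omega", "zeta", "sigma_beta",
                               "sigma_delta", "lam")})


class TestMarginalMoments:
    def test_poisson_limit_when_loadings_zero(self):
        m = marginal_moments(0.7, 0.2, 1, np.zeros(3))
        assert m.variance == pytest.approx(m.mean)

    def test_direct_evaluation_single_loading(self):
        m = marginal_moments(0.0, 0.0, 0, np.array([1.0]))
        assert m.mean == pytest.approx(1.0)
        assert m.variance == pytest.approx(1.0 + (math.e - 1.0))

    def test_exp_additivity_of_mean(self):
        m = marginal_moments(math.log(2), math.log(3), 1, np.zeros(2))
        assert m.mean == pytest.approx(6.0)

    def test_strict_overdispersion_with_nonzero_loading(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            row = rng.normal(0, 0.8, 3)
            row[rng.integers(3)] = max(0.2, abs(row[0]))
            m = marginal_moments(rng.normal(), rng.normal(), 1, row)
            assert m.variance > m.mean


class TestSampleCounts:
    def test_poisson_one_at_zero_state(self):
        state = ParameterState.zeros(1, 1, 2)
        n = 100_000
        groups = np.array([0] * (n // 2) + [1] * (n // 2))
        ds = sample_counts(state, groups, seed=42)
        se = math.sqrt(1.0 / n)
        assert abs(ds.counts.mean() - 1.0) < 4 * se

    def test_mean_matches_exp_beta(self):
        state = ParameterState.zeros(1, 1, 2)
        state.beta[:] = math.log(5.0)
        n = 100_000
        groups = np.array([0] * (n - 1) + [1])
        ds = sample_counts(state, groups, seed=43)
        ctrl = ds.counts[0, :-1]
        se = math.sqrt(5.0 / (n - 1))
        assert abs(ctrl.mean() - 5.0) < 4 * se

    def test_variance_matches_marginal_moments(self):
        """Monte-Carlo oracle for the closed-form overdispersed variance."""
        state = ParameterState.zeros(1, 1, 2)
        state.beta[:] = math.log(3.0)
        state.alpha[0, :, 0] = [0.6, -0.4]
        n = 100_000
        groups = np.array([0] * (n - 1) + [1])
        ds = sample_counts(state, groups, seed=44)
        ctrl = ds.counts[0, :-1].astype(float)
        m = marginal_moments(math.log(3.0), 0.0, 0, state.alpha[0, :, 0])
        # SE of the sample variance via the empirical fourth moment
        dev = ctrl - ctrl.mean()
        se_var = math.sqrt((np.mean(dev ** 4) - np.var(ctrl) ** 2) / len(ctrl))
        assert abs(ctrl.var() - m.variance) < 4 * se_var
        assert ctrl.var() > ctrl.mean()   # overdispersed in sample too

    def test_reproducible_given_seed(self):
        state = ParameterState.zeros(3, 1, 2)
        groups = np.array([0, 0, 1, 1])
        a = sample_counts(state, groups, seed=7)
        b = sample_counts(state, groups, seed=7)
        assert np.array_equal(a.counts, b.counts)
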