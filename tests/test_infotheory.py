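"""Tests of mutual information, Blahut-Arimoto, binning and bias correction."""

import math

import numpy as np
import pytest

from cdchannel.infotheory import (
    Channel,
    InputDistribution,
    analytic_channel,
    bias_corrected_capacity,
    bin_count_rule,
    blahut_arimoto,
    capacity_from_analytic,
    empirical_channel,
    mi_landscape,
    mutual_information,
    mutual_information_from_samples,
)
from cdchannel.model import (
    CountDistribution,
    InputGrid,
    PromoterControl,
    promoter_rates,
    transcript_distribution,
)


def h2(eps: float) -> float:
    """Binary entropy in bits."""
    return -(eps * math.log2(eps) + (1 - eps) * math.log2(1 - eps))


def bsc(eps: float) -> np.ndarray:
    return np.array([[1 - eps, eps], [eps, 1 - eps]])


def brute_force_capacity(Q: np.ndarray, resolution: float = 1e-3) -> float:
    """Exhaustive search over the input simplex (3 inputs) for max I(p, Q).

    Uses I(p) = H(pQ) - sum_j p_j H(Q_j), fully vectorized over a
    simplex grid, as an oracle independent of the alternating
    optimization.
    """
    n = int(round(1 / resolution))
    i, j = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    keep = (i + j) <= n
    P = np.column_stack([i[keep], j[keep], n - i[keep] - j[keep]]) / n

    def entropy_bits(M):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(M > 0, M * np.log2(M), 0.0)
        return -t.sum(axis=-1)

    return float((entropy_bits(P @ Q) - P @ entropy_bits(Q)).max())


class TestMutualInformation:
    def test_noiseless_binary_channel(self):
        assert mutual_information([0.5, 0.5], np.eye(2)) == pytest.approx(1.0)

    def test_identical_rows_carry_nothing(self):
        Q = np.tile([0.2, 0.3, 0.5], (4, 1))
        assert mutual_information(np.full(4, 0.25), Q) == pytest.approx(0.0, abs=1e-12)

    def test_bsc_closed_form(self):
        got = mutual_information([0.5, 0.5], bsc(0.25))
        assert got == pytest.approx(1 - h2(0.25), rel=1e-9)

    def test_output_relabeling_invariance(self, rng):
        Q = rng.dirichlet(np.ones(6), size=3)
        p = np.array([0.2, 0.5, 0.3])
        perm = rng.permutation(6)
        assert mutual_information(p, Q) == pytest.approx(
            mutual_information(p, Q[:, perm]), rel=1e-12
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            mutual_information([0.5, 0.5], np.eye(3))

    def test_from_samples_zero_and_positive(self, rng):
        x = np.repeat([0, 1], 500)
        y_same = rng.normal(size=1000)
        assert mutual_information_from_samples(x, y_same, 8) < 0.02
        y_split = np.concatenate([rng.normal(0, 1, 500), rng.normal(30, 1, 500)])
        assert mutual_information_from_samples(x, y_split, 8) == pytest.approx(
            1.0, abs=0.01
        )


class TestBlahutArimoto:
    def test_identity_channel(self):
        for n in (2, 4, 8):
            est = blahut_arimoto(np.eye(n))
            assert est.capacity_bits == pytest.approx(math.log2(n), abs=1e-9)
            assert np.allclose(est.optimal_input.p, 1 / n, atol=1e-6)
            assert est.converged

    def test_useless_bsc(self):
        assert blahut_arimoto(bsc(0.5)).capacity_bits == pytest.approx(0.0, abs=1e-9)

    def test_bsc_closed_form_capacity(self):
        est = blahut_arimoto(bsc(0.11))
        assert est.capacity_bits == pytest.approx(1 - h2(0.11), abs=1e-4)

    def test_matches_brute_force_on_random_channels(self, rng):
        for _ in range(3):
            Q = rng.dirichlet(np.full(3, 0.8), size=3)
            ba = blahut_arimoto(Q, tol=1e-9).capacity_bits
            bf = brute_force_capacity(Q)
            # the simplex grid undershoots by O(resolution); BA must not
            assert ba >= bf - 1e-9
            assert abs(ba - bf) < 1e-4

    def test_capacity_at_least_uniform_mi(self, rng):
        Q = rng.dirichlet(np.ones(5), size=4)
        est = blahut_arimoto(Q)
        assert est.capacity_bits >= mutual_information(np.full(4, 0.25), Q) - 1e-12

    def test_objective_monotone_in_iterations(self, rng):
        Q = rng.dirichlet(np.ones(4), size=4)
        caps = [
            blahut_arimoto(Q, tol=0.0, max_iter=k).capacity_bits
            for k in range(1, 12)
        ]
        assert np.all(np.diff(caps) >= -1e-12)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            blahut_arimoto(np.array([[0.5, 0.4], [0.5, 0.5]]))

    def test_non_convergence_flagged(self, rng):
        Q = rng.dirichlet(np.ones(8), size=8)
        est = blahut_arimoto(Q, tol=1e-12, max_iter=2)
        assert not est.converged


class TestChannelContainers:
    def test_row_validation(self):
        with pytest.raises(ValueError):
            Channel(np.array([0.0, 1.0]), np.array([[0.6, 0.3], [0.5, 0.5]]))
        with pytest.raises(ValueError):
            Channel(np.array([0.0, 1.0]), np.array([[1.1, -0.1], [0.5, 0.5]]))

    def test_drop_empty_outputs(self):
        Q = np.array([[0.5, 0.0, 0.5], [0.25, 0.0, 0.75]])
        chan = Channel(np.array([0.0, 1.0]), Q).drop_empty_outputs()
        assert chan.n_outputs == 2

    def test_input_distribution_moments(self):
        p = InputDistribution(np.array([0.25, 0.5, 0.25]))
        grid = np.array([0.0, 0.5, 1.0])
        assert p.mean(grid) == pytest.approx(0.5)
        assert p.std(grid) == pytest.approx(math.sqrt(0.125))
        with pytest.raises(ValueError):
            InputDistribution(np.array([0.5, 0.6]))


class TestEmpiricalChannel:
    def test_identical_samples_single_bin(self):
        samples = [np.full(10, 3.0), np.full(12, 3.0)]
        chan = empirical_channel(samples, nb=4)
        assert blahut_arimoto(chan).capacity_bits == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_supports_reach_log2J(self, rng):
        samples = [rng.uniform(10 * j, 10 * j + 1, 200) for j in range(4)]
        est = blahut_arimoto(empirical_channel(samples, nb=40))
        assert est.capacity_bits == pytest.approx(2.0, abs=1e-6)

    def test_matches_analytic_poisson_channel(self, rng):
        """Sampled Poisson channel vs its analytic pmf, binned identically."""
        lams = [2.0, 8.0, 20.0]
        samples = [rng.poisson(lam, 30_000).astype(float) for lam in lams]
        chan = empirical_channel(samples, nb=25)
        c_emp = blahut_arimoto(chan).capacity_bits
        dists = [CountDistribution.poisson(lam) for lam in lams]
        support = max(d.support_max for d in dists)
        ks = np.arange(support + 1)
        Q = np.vstack([
            np.histogram(ks, bins=chan.bin_edges, weights=d.pmf(ks))[0]
            for d in dists
        ])
        Q /= Q.sum(axis=1, keepdims=True)
        c_analytic = blahut_arimoto(Q).capacity_bits
        assert abs(c_emp - c_analytic) < 0.05

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            empirical_channel([np.array([1.0])], nb=4)
        with pytest.raises(ValueError):
            empirical_channel([rng.normal(size=10)], nb=1)


class TestBiasCorrection:
    def test_single_full_fraction_equals_naive(self, rng):
        samples = [rng.poisson(lam, 500).astype(float) for lam in (1.0, 10.0)]
        est = bias_corrected_capacity(samples, nb=8, fractions=[1.0], seed=0)
        naive = blahut_arimoto(empirical_channel(samples, 8)).capacity_bits
        assert est.capacity_bits == pytest.approx(naive, abs=1e-12)

    def test_zero_information_channel_deflated(self, rng):
        """Identical conditional laws: naive estimate inflated, corrected ~0."""
        samples = [rng.poisson(5, 300).astype(float) for _ in range(11)]
        naive = blahut_arimoto(empirical_channel(samples, 16)).capacity_bits
        est = bias_corrected_capacity(samples, nb=16, seed=1)
        assert naive > 0.02
        assert est.capacity_bits < 0.02
        assert est.capacity_bits <= naive

    def test_recovers_analytic_capacity(self, ctrl):
        """Sampled telegraph NB channel vs its exact BA capacity."""
        grid = InputGrid.uniform(16)
        dists = [
            transcript_distribution(*promoter_rates(x, ctrl), 0.1, 0.1)
            for x in grid.values
        ]
        c_exact = capacity_from_analytic(dists, grid).capacity_bits
        gen = np.random.default_rng(7)
        samples = [d.rvs(10_000, gen).astype(float) for d in dists]
        nb = int(max(s.max() for s in samples)) + 1
        est = bias_corrected_capacity(samples, nb=nb, n_replicates=5, seed=3)
        assert abs(est.capacity_bits - c_exact) < 0.05

    def test_bin_sweep_plateaus(self, rng):
        samples = [rng.poisson(lam, 2_000).astype(float) for lam in (1.0, 30.0)]
        est = bias_corrected_capacity(samples, nb=None, n_replicates=3, seed=2)
        assert est.nb >= 4
        assert "nb_sweep" in est.bias_record
        assert est.capacity_bits == pytest.approx(1.0, abs=0.05)

    def test_validation(self, rng):
        samples = [rng.poisson(5, 20).astype(float) for _ in range(3)]
        with pytest.raises(ValueError):
            bias_corrected_capacity(samples, nb=4, fractions=[0.0, 1.0])
        with pytest.raises(ValueError):
            bias_corrected_capacity(samples, nb=4, fractions=[0.01])
        with pytest.raises(ValueError):
            bias_corrected_capacity(samples, nb=4, n_replicates=0)


class TestBinCountRule:
    @pytest.mark.parametrize(
        "c, eta, expected",
        [(1.0, 1.0, 4), (3.0, 0.5, 12), (0.0, 0.1, 2), (2.0, 1.0, 8)],
    )
    def test_examples(self, c, eta, expected):
        assert bin_count_rule(c, eta) == expected

    def test_monotone_and_above_2_to_c(self):
        for c in np.linspace(0, 5, 21):
            for eta in (0.1, 0.5, 1.0, 2.0):
                nb = bin_count_rule(c, eta)
                assert nb > 2**c
        assert bin_count_rule(2.0, 1.0) <= bin_count_rule(2.5, 1.0)
        assert bin_count_rule(2.0, 1.0) <= bin_count_rule(2.0, 1.5)

    def test_invalid_eta(self):
        with pytest.raises(ValueError):
            bin_count_rule(1.0, 0.0)
        with pytest.raises(ValueError):
            bin_count_rule(-1.0, 0.5)


class TestAnalyticCapacity:
    def test_identical_distributions_zero(self):
        dists = [CountDistribution.poisson(5.0)] * 4
        assert capacity_from_analytic(dists).capacity_bits == pytest.approx(
            0.0, abs=1e-9
        )

    def test_well_separated_poissons_near_one_bit(self):
        dists = [CountDistribution.poisson(1.0), CountDistribution.poisson(100.0)]
        assert capacity_from_analytic(dists).capacity_bits == pytest.approx(
            1.0, abs=0.01
        )

    def test_channel_support_mass_guard(self):
        dists = [CountDistribution.poisson(5.0), CountDistribution.poisson(50.0)]
        # a support far below the widest mean must trip the mass guard
        with pytest.raises(ValueError, match="mass"):
            analytic_channel(dists, support_max=10)


class TestLandscape:
    @pytest.fixture
    def transcript_channel(self, ctrl):
        grid = InputGrid.uniform(16)
        dists = [
            transcript_distribution(*promoter_rates(x, ctrl), 0.5, 0.5)
            for x in grid.values
        ]
        return analytic_channel(dists, grid)

    def test_point_mass_zero_information(self, transcript_channel):
        vals = mi_landscape(transcript_channel, np.array([0.4]), np.array([0.0]))
        assert vals[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_bounded_by_capacity(self, transcript_channel):
        """Capacity is the supremum over all input distributions, so every
        landscape value sits below it.  For this low-power channel the
        optimal input is bimodal (mass at both extremes), which no
        unimodal family member can reach, so the gap is genuine."""
        cap = blahut_arimoto(transcript_channel).capacity_bits
        means = np.linspace(0.0, 1.0, 21)
        stds = np.linspace(0.0, 0.8, 17)
        grid = mi_landscape(transcript_channel, means, stds)
        assert grid.max() <= cap + 1e-9
        assert grid.shape == (17, 21)

    def test_argmax_reaches_capacity_for_unimodal_optimum(self):
        """When the capacity-achieving input is near uniform (well-separated
        outputs), the wide-std landscape cell attains it."""
        chan = Channel(np.linspace(0, 1, 8), np.eye(8))
        cap = blahut_arimoto(chan).capacity_bits
        grid = mi_landscape(chan, np.array([0.5]), np.array([0.1, 1.0, 10.0]))
        assert grid.max() <= cap + 1e-9
        assert grid.max() > cap - 0.05
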